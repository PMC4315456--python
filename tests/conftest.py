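import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hvrforest import rf_training, simulate
from hvrforest.hvr_extraction import extract_all
from hvrforest.reference_db import ReferenceRecord


@pytest.fixture(scope="session")
def fixture_data():
    """Default synthetic reference (3x2x2x2x3 genera x 5 sequences, seed 1)."""
    design = simulate.FixtureDesign()
    records, manifest = simulate.generate_reference(design, seed=1)
    return design, records, manifest


@pytest.fixture(scope="session")
def hvr_records(fixture_data):
    """V3-analog region sequences excised from the fixture, with lineages."""
    design, records, _ = fixture_data
    pair = design.primer_pairs()["V3"]
    lineage_of = {r.id: r.lineage for r in records}
    hits, misses = extract_all(records, pair)
    assert not misses
    return [
        ReferenceRecord(h.source_id, h.sequence, lineage_of[h.source_id])
        for h in hits
    ]


@pytest.fixture(scope="session")
def trained_bundle(hvr_records):
    """Small per-rank forests over every fixture region sequence (memorization)."""
    return rf_training.train_region_models(
        hvr_records, "V3", ntree=80, seed=11, compute_importance=False
    )
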