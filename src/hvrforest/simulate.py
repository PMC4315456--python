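"""Synthetic 16S-like references with planted primer sites and a toy taxonomy.

Real 16S rRNA genes interleave conserved primer-binding blocks with
hypervariable cores.  The generator emulates exactly that structure: a root
sequence of conserved blocks (which contain the designed primer sites,
bit-identical across all emitted sequences) flanking variable cores, and a
balanced taxonomy tree descended by applying a per-rank substitution rate to
the cores only.  Every emitted sequence therefore carries each planted
region at a known coordinate, and the accompanying manifest records the
ground truth (lineage, coordinates, per-rank group counts) that the other
modules are tested against.

What this does *not* emulate: 16S secondary structure, compositional bias,
PCR chimeras, indels, or the wildly unbalanced group sizes of a real
database — so passing tests demonstrate correct mechanics and planted-signal
recovery, not field accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .evaluation import inject_mutations
from .hvr_extraction import PrimerPair, reverse_complement
from .reference_db import (
    CLASSIFY_RANKS,
    RANKS,
    Lineage,
    ReferenceRecord,
    write_reference,
)

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RegionDesign:
    """One planted region: concrete primers flanking a variable core."""

    name: str
    forward: str
    reverse: str  # 5'->3' on the reverse strand, as in a primer table
    core_length: int


# Fixed synthetic primers (length 20, unambiguous) for two planted regions
# whose core lengths sit inside the real-HVR length range (~86-542 nt).
DEFAULT_REGIONS: tuple[RegionDesign, ...] = (
    RegionDesign("V3", "ACTGGCTTAACGGCTAGCTA", "TCGATCGGATGCTAAGCCTA", 150),
    RegionDesign("V4", "GATCCTAGGCATTCAGACGT", "AGGTCACCTTGAACGGCTAT", 207),
)

#: Per-rank substitution rates applied to variable cores at each split of the
#: taxonomy tree.  Genus-level 0.05 keeps sibling genera >= ~5% apart in their
#: cores; the within-genus (sequence) rate is small enough that exact
#: duplicates of the genus core occur, giving multi-member dereplication
#: clusters from which test reads can be held out.
DEFAULT_DIVERGENCE: dict[str, float] = {
    "phylum": 0.20,
    "class": 0.12,
    "order": 0.08,
    "family": 0.06,
    "genus": 0.05,
}


@dataclass
class FixtureDesign:
    n_phyla: int = 3
    n_classes_per_phylum: int = 2
    n_orders_per_class: int = 2
    n_families_per_order: int = 2
    n_genera_per_family: int = 3
    n_sequences_per_genus: int = 5
    regions: tuple[RegionDesign, ...] = DEFAULT_REGIONS
    divergence: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIVERGENCE))
    sequence_divergence: float = 0.005
    spacer_length: int = 40
    kingdom: str = "Bacteria"
    primer_corrupt_fraction: float = 0.0

    def fanouts(self) -> dict[str, int]:
        return {
            "phylum": self.n_phyla,
            "class": self.n_classes_per_phylum,
            "order": self.n_orders_per_class,
            "family": self.n_families_per_order,
            "genus": self.n_genera_per_family,
        }

    def n_sequences(self) -> int:
        n = self.n_sequences_per_genus
        for fan in self.fanouts().values():
            n *= fan
        return n

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.fanouts().values()) or self.n_sequences_per_genus < 1:
            raise ValueError("all fan-outs must be >= 1")
        for rank, rate in self.divergence.items():
            if not 0.0 <= rate <= 0.5:
                raise ValueError(f"divergence rate at {rank} must lie in [0, 0.5]")
        if not 0.0 <= self.primer_corrupt_fraction <= 1.0:
            raise ValueError("primer_corrupt_fraction must lie in [0,1]")
        if self.n_sequences() > 10 ** 6:
            raise ValueError(
                f"design would emit {self.n_sequences()} sequences (> 1e6); refusing"
            )

    def primer_pairs(self) -> dict[str, PrimerPair]:
        return {
            r.name: PrimerPair(r.name, r.forward, r.reverse) for r in self.regions
        }


@dataclass
class FixtureManifest:
    """Ground truth for a generated fixture, serializable to JSON."""

    seed: int
    design: dict
    sequences: list[dict]  # id, lineage, regions {name: [start,end]}, corrupted
    rank_group_counts: dict[str, dict[str, int]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)

    def lineage_of(self, seq_id: str) -> Lineage:
        for s in self.sequences:
            if s["id"] == seq_id:
                return Lineage.parse(s["lineage"])
        raise KeyError(seq_id)


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _ACGT[rng.integers(4, size=length)]


def _mutate_core(core: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = core.copy()
    hit = np.flatnonzero(rng.random(out.size) < rate)
    for i in hit:
        choices = _ACGT[_ACGT != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def generate_reference(
    design: FixtureDesign, seed: int = 0
) -> tuple[list[ReferenceRecord], FixtureManifest]:
    """Emit the synthetic reference records and their ground-truth manifest.

    Deterministic per seed.  Conserved blocks (spacers and primer sites) are
    identical in every sequence; only the cores diverge down the taxonomy
    tree, so primer coverage is 1.0 by construction unless
    `primer_corrupt_fraction` asks for scrambled forward-primer sites in
    that fraction of sequences.
    """
    rng = np.random.default_rng(seed)

    # fixed template: spacer + [fwd, core slot, rev-site] per region + spacer
    spacers = [_random_dna(rng, design.spacer_length) for _ in range(len(design.regions) + 1)]
    root_cores = [_random_dna(rng, r.core_length) for r in design.regions]

    # coordinates of each region's core within the assembled sequence
    coords: dict[str, tuple[int, int]] = {}
    pos = design.spacer_length
    for region, core in zip(design.regions, root_cores):
        pos += len(region.forward)
        coords[region.name] = (pos, pos + region.core_length)
        pos += region.core_length + len(region.reverse) + design.spacer_length

    def assemble(cores: Sequence[np.ndarray], corrupt: bool) -> str:
        parts: list[np.ndarray] = []
        for i, (region, core) in enumerate(zip(design.regions, cores)):
            fwd = region.forward
            if corrupt:
                fwd = "".join(
                    chr(b) for b in _mutate_core(
                        np.frombuffer(fwd.encode(), dtype=np.uint8), 0.5, rng
                    )
                )
            parts.append(spacers[i])
            parts.append(np.frombuffer(fwd.encode(), dtype=np.uint8))
            parts.append(core)
            parts.append(
                np.frombuffer(reverse_complement(region.reverse).encode(), dtype=np.uint8)
            )
        parts.append(spacers[-1])
        return np.concatenate(parts).tobytes().decode("ascii")

    # descend the taxonomy tree, diverging the cores at each rank split
    leaves: list[tuple[Lineage, list[np.ndarray]]] = []

    def descend(rank_i: int, name_prefix: str, names: list[str], cores: list[np.ndarray]):
        rank = CLASSIFY_RANKS[rank_i]
        fan = design.fanouts()[rank]
        rate = float(design.divergence.get(rank, 0.0))
        for child in range(1, fan + 1):
            label = f"{name_prefix}{child}" if rank == "phylum" else f"{name_prefix}.{child}"
            child_cores = [_mutate_core(c, rate, rng) for c in cores]
            child_names = names + [label]
            if rank_i + 1 < len(CLASSIFY_RANKS):
                descend(rank_i + 1, label, child_names, child_cores)
            else:
                full = [design.kingdom] + child_names + [""]  # kingdom..genus, species empty
                leaves.append((Lineage(tuple(full)), child_cores))

    descend(0, "P", [], root_cores)

    n_total = design.n_sequences()
    n_corrupt = int(round(design.primer_corrupt_fraction * n_total))
    corrupt_idx = set(
        rng.choice(n_total, size=n_corrupt, replace=False).tolist()
    ) if n_corrupt else set()

    records: list[ReferenceRecord] = []
    seq_entries: list[dict] = []
    counter = 0
    for lineage, genus_cores in leaves:
        for _copy in range(design.n_sequences_per_genus):
            cores = [
                _mutate_core(c, design.sequence_divergence, rng) for c in genus_cores
            ]
            corrupted = counter in corrupt_idx
            seq = assemble(cores, corrupted)
            sid = f"fx{counter:05d}"
            records.append(ReferenceRecord(sid, seq, lineage))
            seq_entries.append(
                {
                    "id": sid,
                    "lineage": lineage.to_greengenes(),
                    "regions": {name: list(span) for name, span in coords.items()},
                    "corrupted": corrupted,
                }
            )
            counter += 1

    group_counts: dict[str, dict[str, int]] = {}
    for rank in CLASSIFY_RANKS:
        tally: dict[str, int] = {}
        for r in records:
            label = r.lineage.at(rank)
            tally[label] = tally.get(label, 0) + 1
        group_counts[rank] = tally

    manifest = FixtureManifest(
        seed=int(seed),
        design={
            **{k: v for k, v in asdict(design).items() if k not in ("regions", "divergence")},
            "regions": [asdict(r) for r in design.regions],
            "divergence": dict(design.divergence),
        },
        sequences=seq_entries,
        rank_group_counts=group_counts,
    )
    return records, manifest


def write_fixture(
    records: Sequence[ReferenceRecord],
    manifest: FixtureManifest,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write reference FASTA, taxonomy TSV and manifest JSON under `out_dir`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "reference.fasta",
        "taxonomy": out_dir / "taxonomy.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_reference(records, paths["fasta"], paths["taxonomy"])
    manifest.to_json(paths["manifest"])
    return paths


def generate_reads(
    records: Sequence[ReferenceRecord],
    manifest: FixtureManifest,
    region: str,
    n_per_sequence: int = 1,
    mutation_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], dict[str, Lineage]]:
    """Simulated amplicon reads for one planted region, with a truth table.

    Each read is the region's core (primers already excluded, as after
    trimming) with substitutions injected at `mutation_rate`; the truth table
    maps read id to the source lineage.
    """
    entries = {s["id"]: s for s in manifest.sequences}
    if not entries or region not in next(iter(entries.values()))["regions"]:
        raise ValueError(f"region {region!r} is not planted in this fixture")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth: dict[str, Lineage] = {}
    for record in records:
        start, end = entries[record.id]["regions"][region]
        core = record.sequence[start:end]
        lineage = record.lineage
        for i in range(n_per_sequence):
            rid = f"{record.id}_{region}_r{i}"
            reads.append((rid, inject_mutations(core, mutation_rate, rng=rng)))
            truth[rid] = lineage
    return reads, truth
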