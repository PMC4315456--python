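"""Taxonomic assignment of amplicon reads and QIIME-compatible output.

Each read is featurized with the model bundle's k-mer size and variable
subset; each rank's forest then votes, and the taxon with the largest vote
fraction is reported for that rank.  Ranks are predicted independently
(phylum .. genus); an optional "consistent" mode instead walks down the
ranks keeping only taxa that are children of the taxon chosen one rank
above.  Assignments are written as the tab-separated taxonomy table QIIME
consumes: query id, rank-tagged lineage, confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from . import kmer_features
from .hvr_extraction import reverse_complement
from .reference_db import CLASSIFY_RANKS, RANK_TAGS, normalize_sequence
from .rf_training import BundleSet

UNCLASSIFIED = "Unclassified"

Read = Union[tuple[str, str], SeqRecord]


@dataclass
class RankCall:
    taxon: str
    vote: float


@dataclass
class ClassificationResult:
    query_id: str
    region: str
    calls: dict[str, RankCall] = field(default_factory=dict)
    lineage: str = ""
    orientation_used: str = "forward"
    reason: str = ""  # e.g. "too_short" when the read yields no valid k-mer


def _as_pairs(reads: Iterable[Read]) -> list[tuple[str, str]]:
    pairs = []
    for r in reads:
        if isinstance(r, tuple):
            pairs.append((r[0], normalize_sequence(r[1])))
        else:
            pairs.append((r.id, normalize_sequence(str(r.seq))))
    return pairs


def read_queries(path: str | Path) -> list[tuple[str, str]]:
    """Load query reads from FASTA or FASTQ (qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [(r.id, normalize_sequence(str(r.seq))) for r in SeqIO.parse(str(path), fmt)]


def _rank_votes(bundle_set: BundleSet, X: np.ndarray) -> dict[str, np.ndarray]:
    """Per-rank vote-fraction matrices (rows = reads, columns = label space)."""
    return {
        rank: bundle_set.bundles[rank].model.predict_proba(X)
        for rank in bundle_set.ranks()
    }


def _assemble_lineage(bundle_set: BundleSet, calls: dict[str, RankCall]) -> str:
    parts = []
    if bundle_set.kingdom:
        parts.append(f"{RANK_TAGS['kingdom']}__{bundle_set.kingdom}")
    for rank in CLASSIFY_RANKS:
        call = calls.get(rank)
        name = "" if call is None or call.taxon == UNCLASSIFIED else call.taxon
        parts.append(f"{RANK_TAGS[rank]}__{name}")
    return ";".join(parts)


def classify_reads(
    reads: Iterable[Read],
    bundle_set: BundleSet,
    region: str | None = None,
    confidence_threshold: float = 0.0,
    consistent: bool = False,
    auto_orient: bool = False,
) -> list[ClassificationResult]:
    """Assign a lineage to every read with the per-rank forests.

    A rank whose top vote fraction falls below `confidence_threshold` is
    reported Unclassified, and so are all ranks below it.  Reads too short
    to yield a single valid k-mer are Unclassified at every rank with reason
    ``too_short``.  With `auto_orient`, each read and its reverse complement
    are scored at the phylum rank and the better orientation is kept.
    """
    if region is not None and region != bundle_set.region:
        raise ValueError(
            f"no model bundle for region {region!r} (models are for "
            f"{bundle_set.region!r})"
        )
    for rank, b in bundle_set.bundles.items():
        if b.k != bundle_set.k:
            raise ValueError(f"rank {rank} bundle k={b.k} mismatches set k={bundle_set.k}")

    pairs = _as_pairs(reads)
    if not pairs:
        return []
    k = bundle_set.k
    subset = bundle_set.bundles[bundle_set.ranks()[0]].variable_subset

    oriented: list[tuple[str, str, str]] = []  # id, seq, orientation
    if auto_orient:
        for rid, seq in pairs:
            oseq, flag = orient_read((rid, seq), bundle_set)
            oriented.append((rid, oseq, flag))
    else:
        oriented = [(rid, seq, "forward") for rid, seq in pairs]

    vectors = [kmer_features.kmer_frequencies(seq, k) for _, seq, _ in oriented]
    X, _ = kmer_features.featurize_batch(
        [seq for _, seq, _ in oriented], k, subset
    )
    votes = _rank_votes(bundle_set, X)

    results: list[ClassificationResult] = []
    for i, (rid, seq, flag) in enumerate(oriented):
        res = ClassificationResult(rid, bundle_set.region, orientation_used=flag)
        if vectors[i].valid_kmer_count == 0:
            res.reason = "too_short"
            for rank in bundle_set.ranks():
                res.calls[rank] = RankCall(UNCLASSIFIED, 0.0)
        else:
            blocked = False
            parent_taxon: str | None = None
            for rank in bundle_set.ranks():
                bundle = bundle_set.bundles[rank]
                proba = votes[rank][i]
                labels = np.asarray(bundle.label_space)
                if blocked:
                    res.calls[rank] = RankCall(UNCLASSIFIED, 0.0)
                    continue
                mask = np.ones(len(labels), dtype=bool)
                if consistent and parent_taxon is not None:
                    pm = bundle_set.parent_maps.get(rank, {})
                    mask = np.array(
                        [parent_taxon in pm.get(l, []) for l in labels], dtype=bool
                    )
                    if not mask.any():
                        res.calls[rank] = RankCall(UNCLASSIFIED, 0.0)
                        blocked = True
                        continue
                masked = np.where(mask, proba, -1.0)
                j = int(masked.argmax())
                top, vote = str(labels[j]), float(proba[j])
                if vote < confidence_threshold:
                    res.calls[rank] = RankCall(UNCLASSIFIED, vote)
                    blocked = True
                else:
                    res.calls[rank] = RankCall(top, vote)
                    parent_taxon = top
        res.lineage = _assemble_lineage(bundle_set, res.calls)
        results.append(res)
    return results


def orient_read(read: Read, bundle_set: BundleSet) -> tuple[str, str]:
    """Pick the read orientation the phylum forest is most confident about.

    Both the read and its reverse complement are scored at the phylum rank;
    the orientation with the higher top vote fraction wins, ties going to
    forward.  Returns (oriented sequence, ``forward``|``reverse``).
    """
    rid, seq = _as_pairs([read])[0]
    rc = reverse_complement(seq)
    first_rank = bundle_set.ranks()[0]
    bundle = bundle_set.bundles[first_rank]
    X, _ = kmer_features.featurize_batch([seq, rc], bundle_set.k, bundle.variable_subset)
    proba = bundle.model.predict_proba(X)
    if proba[1].max() > proba[0].max():
        return rc, "reverse"
    return seq, "forward"


def write_qiime_assignments(
    results: Sequence[ClassificationResult], path: str | Path
) -> None:
    """Write assignments as QIIME-style taxonomy TSV: id, lineage, confidence.

    Confidence is the minimum vote fraction over the ranks that received an
    assignment (0 when nothing was assigned).  Rows follow input order, so
    repeated runs on the same inputs are byte-identical.
    """
    results = list(results)
    if not results:
        raise ValueError("no classification results to write")
    with open(path, "w") as fh:
        for res in results:
            assigned = [
                c.vote for c in res.calls.values() if c.taxon != UNCLASSIFIED
            ]
            conf = min(assigned) if assigned else 0.0
            fh.write(f"{res.query_id}\t{res.lineage}\t{conf:.4f}\n")


def parse_qiime_assignments(path: str | Path) -> list[tuple[str, str, float]]:
    """Read back a QIIME-style taxonomy TSV (id, lineage string, confidence)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rid, lineage, conf = line.rstrip("\n").split("\t")
            rows.append((rid, lineage, float(conf)))
    return rows
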