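"""Redundancy removal before training (CD-HIT-style greedy clustering).

Identical or near-identical training sequences inflate apparent performance,
so each rank group is dereplicated before model fitting: at identity 1 for
the short hypervariable regions (and for full-length sequences at ranks
above genus), and at 0.999 for full-length sequences at genus.

Global identity between two sequences is defined alignment-free: for
equal-length sequences it is Hamming identity; for unequal lengths the
shorter is slid ungapped along the longer and the best match count is
divided by the *longer* length.  Lengths differing by more than
(1 - threshold) x longer length cannot reach the threshold and are rejected
without comparison.  At thresholds this close to 1 nearly every merge is a
<=1-mismatch pair, which this definition handles exactly; word-filter
heuristics and banded alignment of the original CD-HIT are deliberately not
reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass
class Cluster:
    """One dereplication cluster; the representative is always a member."""

    representative_id: str
    representative_seq: str
    member_ids: list[str] = field(default_factory=list)
    identity_threshold: float = 1.0

    def __len__(self) -> int:
        return len(self.member_ids)


def _with_ids(
    sequences: Sequence[str] | Sequence[tuple[str, str]],
    ids: Sequence[str] | None,
) -> list[tuple[str, str]]:
    seqs = list(sequences)
    if seqs and isinstance(seqs[0], tuple):
        return list(seqs)  # type: ignore[return-value]
    if ids is None:
        ids = [str(i) for i in range(len(seqs))]
    if len(ids) != len(seqs):
        raise ValueError("ids and sequences differ in length")
    return list(zip(ids, seqs))  # type: ignore[arg-type]


def pairwise_identity(a: str, b: str, threshold: float | None = None) -> float:
    """Global ungapped identity: best offset match count / longer length.

    With `threshold` given, pairs whose length difference already rules out
    reaching it short-circuit to 0.0.
    """
    if len(a) < len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    if la == 0:
        return 1.0
    if threshold is not None and (la - lb) > (1.0 - threshold) * la + 1e-9:
        return 0.0
    best = 0
    for offset in range(la - lb + 1):
        matches = sum(x == y for x, y in zip(a[offset:offset + lb], b))
        if matches > best:
            best = matches
    return best / la


def dereplicate_exact(
    sequences: Sequence[str] | Sequence[tuple[str, str]],
    ids: Sequence[str] | None = None,
) -> list[Cluster]:
    """Cluster at identity 1: exact string equality only.

    The representative of each cluster is its first-seen member, and clusters
    are returned in order of representative appearance, so the output is
    deterministic for a given input order.
    """
    pairs = _with_ids(sequences, ids)
    if not pairs:
        raise ValueError("dereplicate_exact requires a nonempty input")
    clusters: dict[str, Cluster] = {}
    for sid, seq in pairs:
        if seq not in clusters:
            clusters[seq] = Cluster(sid, seq, [], 1.0)
        clusters[seq].member_ids.append(sid)
    return list(clusters.values())


def dereplicate_greedy(
    sequences: Sequence[str] | Sequence[tuple[str, str]],
    threshold: float,
    ids: Sequence[str] | None = None,
) -> list[Cluster]:
    """Greedy incremental clustering at a sub-unit identity threshold.

    Sequences are visited longest-first (ties keep input order, the CD-HIT
    convention); each joins the first existing cluster whose representative
    it matches at >= threshold global identity, otherwise it founds a new
    cluster with itself as representative.  Representatives are therefore the
    longest member of their cluster.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0,1); use dereplicate_exact for 1")
    pairs = _with_ids(sequences, ids)
    if not pairs:
        raise ValueError("dereplicate_greedy requires a nonempty input")
    order = sorted(range(len(pairs)), key=lambda i: (-len(pairs[i][1]), i))
    clusters: list[Cluster] = []
    for i in order:
        sid, seq = pairs[i]
        for cl in clusters:
            if pairwise_identity(cl.representative_seq, seq, threshold) >= threshold:
                cl.member_ids.append(sid)
                break
        else:
            clusters.append(Cluster(sid, seq, [sid], threshold))
    return clusters


def dereplicate(
    sequences: Sequence[str] | Sequence[tuple[str, str]],
    threshold: float = 1.0,
    ids: Sequence[str] | None = None,
) -> list[Cluster]:
    """Route to exact clustering at threshold 1, greedy otherwise."""
    if threshold >= 1.0:
        return dereplicate_exact(sequences, ids)
    return dereplicate_greedy(sequences, threshold, ids)


def representatives(clusters: Iterable[Cluster]) -> list[tuple[str, str]]:
    return [(c.representative_id, c.representative_seq) for c in clusters]


def write_cluster_table(
    clusters: Iterable[Cluster],
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """TSV of (representative_id, member_id, identity-to-representative).

    Member identities are recomputed from `sequences` (id -> sequence) when
    given; without it, members of a threshold-1 cluster are identical to the
    representative by construction and reported as 1.
    """
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_id\tidentity\n")
        for c in clusters:
            for mid in c.member_ids:
                if mid == c.representative_id or sequences is None:
                    ident = 1.0
                else:
                    ident = pairwise_identity(c.representative_seq, sequences[mid])
                fh.write(f"{c.representative_id}\t{mid}\t{ident:.6f}\n")
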