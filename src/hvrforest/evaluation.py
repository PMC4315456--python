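"""Evaluation harness: cluster-aware splitting, error injection, and the
seven macro-averaged performance metrics.

The test protocol mirrors how the classifier is meant to be stressed: about
10% of the members of every dereplication cluster are held out, held-out
region sequences receive random substitutions at a 1% per-base rate to
emulate sequencing error, and predictions are scored one-vs-rest per rank
group.  Per group the seven measures are

    sensitivity = TP/(TP+FN)            specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)            accuracy    = (TP+TN)/(TP+FP+FN+TN)
    G-mean      = sqrt(sens x spec)     F-measure   = 2PR/(P+R)
    MCC = (TPxTN - FPxFN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and the region-level report is the unweighted (macro) mean over groups;
groups where a denominator vanishes are excluded from that metric's average
and counted.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dereplication import Cluster
from .reference_db import CLASSIFY_RANKS, Lineage

METRIC_NAMES = (
    "sensitivity", "specificity", "precision", "accuracy",
    "g_mean", "f_measure", "mcc",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for one rank group."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricRow:
    """The seven measures for one group; None marks a zero-denominator case."""

    group: str
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    accuracy: float | None = None
    g_mean: float | None = None
    f_measure: float | None = None
    mcc: float | None = None


def split_per_cluster(
    clusters: Sequence[Cluster],
    test_fraction: float = 0.10,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Hold out ~`test_fraction` members of every multi-member cluster.

    Each cluster with >= 2 members contributes round(test_fraction x size),
    at least 1, randomly chosen members to the test set; singletons go
    wholly to training.  Train and test are disjoint and together cover
    every id.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0,1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cluster in clusters:
        members = list(cluster.member_ids)
        if len(members) < 2:
            train.extend(members)
            continue
        n_test = max(1, int(math.floor(test_fraction * len(members) + 0.5)))
        n_test = min(n_test, len(members) - 1)  # never empty a cluster's train side
        picked = rng.choice(len(members), size=n_test, replace=False)
        picked_set = set(picked.tolist())
        for i, mid in enumerate(members):
            (test if i in picked_set else train).append(mid)
    if not test:
        warnings.warn("all clusters are singletons; test set is empty", stacklevel=2)
    return train, test


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def inject_mutations(
    sequence: str,
    rate: float = 0.01,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Substitute each position independently with probability `rate`.

    A substitution draws uniformly from the three other bases, so it is
    never silent and length is preserved; positions holding a non-ACGT
    symbol are replaced by a uniformly random different symbol from ACGT.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0,1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode("ascii")


def _label_at(value: Lineage | str, rank: str) -> str:
    if isinstance(value, Lineage):
        return value.at(rank)
    return Lineage.parse(value).at(rank)


def confusion_by_group(
    truth: Mapping[str, Lineage | str],
    predicted: Mapping[str, Lineage | str],
    rank: str,
) -> tuple[dict[str, ConfusionCounts], int]:
    """One-vs-rest confusion counts per taxon at `rank`.

    Truth and predictions must cover the same query ids.  Reads whose truth
    is unlabelled at the rank are excluded and counted; a prediction of
    Unclassified (or empty) simply never matches any group's taxon.
    """
    if set(truth) != set(predicted):
        raise ValueError("truth and prediction ids do not match")
    rows = []
    excluded = 0
    for rid in truth:
        t = _label_at(truth[rid], rank)
        if t == "":
            excluded += 1
            continue
        p = _label_at(predicted[rid], rank)
        if p == "Unclassified":
            p = ""
        rows.append((t, p))
    taxa = sorted({t for t, _ in rows})
    n = len(rows)
    counts: dict[str, ConfusionCounts] = {}
    for taxon in taxa:
        tp = sum(1 for t, p in rows if t == taxon and p == taxon)
        fp = sum(1 for t, p in rows if t != taxon and p == taxon)
        fn = sum(1 for t, p in rows if t == taxon and p != taxon)
        counts[taxon] = ConfusionCounts(tp, fp, fn, n - tp - fp - fn)
    return counts, excluded


def compute_metrics(counts: ConfusionCounts, group: str = "") -> MetricRow:
    """The seven measures from one confusion quadruple.

    Any metric whose denominator is zero is left undefined (None) rather
    than clamped, and is later excluded from macro-averaging.
    """
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    acc = ratio(tp + tn, tp + fp + fn + tn)
    g = math.sqrt(sens * spec) if sens is not None and spec is not None else None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f = 2 * prec * sens / (prec + sens)
    else:
        f = None
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None
    return MetricRow(group, sens, spec, prec, acc, g, f, mcc)


@dataclass
class MacroSummary:
    """Macro-averaged metrics with, per metric, the count of undefined groups."""

    means: dict[str, float | None] = field(default_factory=dict)
    n_defined: dict[str, int] = field(default_factory=dict)
    n_undefined: dict[str, int] = field(default_factory=dict)


def macro_average(rows: Sequence[MetricRow]) -> MacroSummary:
    """Unweighted mean of each metric over the groups where it is defined."""
    if not rows:
        raise ValueError("macro_average needs at least one group row")
    summary = MacroSummary()
    for name in METRIC_NAMES:
        values = [getattr(r, name) for r in rows]
        defined = [v for v in values if v is not None]
        summary.n_defined[name] = len(defined)
        summary.n_undefined[name] = len(values) - len(defined)
        summary.means[name] = sum(defined) / len(defined) if defined else None
    return summary


def metric_report(
    truth: Mapping[str, Lineage | str],
    predicted: Mapping[str, Lineage | str],
    ranks: Sequence[str] = CLASSIFY_RANKS,
) -> tuple[pd.DataFrame, dict[str, MacroSummary]]:
    """Per-group metric table plus the per-rank macro summaries."""
    records = []
    summaries: dict[str, MacroSummary] = {}
    for rank in ranks:
        counts, _excluded = confusion_by_group(truth, predicted, rank)
        rows = [compute_metrics(c, group=g) for g, c in counts.items()]
        if rows:
            summaries[rank] = macro_average(rows)
        for r in rows:
            rec = {"rank": rank, "group": r.group}
            rec.update({m: getattr(r, m) for m in METRIC_NAMES})
            records.append(rec)
    return pd.DataFrame(records), summaries


def rank_accuracy(
    truth: Mapping[str, Lineage | str],
    predicted: Mapping[str, Lineage | str],
    rank: str,
) -> float:
    """Plain multi-class accuracy at one rank over reads labelled there."""
    pairs = [
        (_label_at(truth[rid], rank), _label_at(predicted[rid], rank))
        for rid in truth
        if _label_at(truth[rid], rank) != ""
    ]
    if not pairs:
        raise ValueError(f"no reads labelled at rank {rank}")
    return sum(t == p for t, p in pairs) / len(pairs)


def write_report(
    table: pd.DataFrame,
    summaries: Mapping[str, MacroSummary],
    tsv_path: str | Path,
    json_path: str | Path,
) -> None:
    table.to_csv(tsv_path, sep="\t", index=False)
    payload = {
        rank: {
            "macro_means": s.means,
            "n_defined": s.n_defined,
            "n_undefined": s.n_undefined,
        }
        for rank, s in summaries.items()
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))
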