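"""Per-rank random-forest training with the OOB-driven tuning protocol.

One forest is trained per taxonomic rank (phylum .. genus) on k-mer
frequency vectors.  The forest algorithm itself is delegated to
scikit-learn's ``RandomForestClassifier``; this module owns the protocol
around it:

* the default mtry rule — half of the square root of the number of possible
  k-mers, e.g. floor(sqrt(256)/2) = 8 for 4-mers;
* the tuneRF-style mtry search (stepFactor 1.5, improve 0.02) driven by the
  out-of-bag (OOB) error, the classification error on the roughly one third
  of examples each tree did not draw into its bootstrap sample;
* OOB permutation variable importance (mean decrease in OOB accuracy when a
  variable's values are shuffled), the randomForest convention;
* the variable-pruning experiment that repeatedly drops the 25 least
  important variables (256 -> 231 -> 206 -> 181 for 4-mers) and records the
  OOB error curve;
* the ntree saturation curve, justifying the working default ntree = 1000.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import kmer_features
from .reference_db import CLASSIFY_RANKS, Lineage, ReferenceRecord, build_parent_maps
from .dereplication import dereplicate, representatives

BUNDLE_FORMAT_VERSION = "1"


def default_mtry(k: int) -> int:
    """Default number of split candidates: floor(sqrt(4^k) / 2), at least 1."""
    return max(1, int(math.floor(math.sqrt(kmer_features.feature_space_size(k)) / 2)))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _as_int_seed(seed: int | None) -> int:
    return 0 if seed is None else int(seed) % (2 ** 31 - 1)


def _fit_forest(
    X: np.ndarray, y: np.ndarray, ntree: int, mtry: int, seed: int | None
) -> tuple[RandomForestClassifier, float]:
    """Fit a bagged forest and return it with its OOB error (1 - OOB accuracy)."""
    mtry = int(np.clip(mtry, 1, X.shape[1]))
    clf = RandomForestClassifier(
        n_estimators=int(ntree),
        max_features=mtry,
        bootstrap=True,
        oob_score=True,
        random_state=_as_int_seed(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # very small ntree can leave a sample with no OOB vote; the estimate
        # is still usable for relative comparisons
        warnings.simplefilter("ignore", UserWarning)
        clf.fit(X, y)
    return clf, float(1.0 - clf.oob_score_)


@dataclass
class TuneTrace:
    """mtry values visited by the OOB search, with the chosen optimum."""

    trace: list[tuple[int, float]]
    chosen_mtry: int

    @property
    def best_oob_error(self) -> float:
        return min(err for _, err in self.trace)


def tune_mtry(
    features: np.ndarray,
    labels: Sequence[str],
    ntree: int = 100,
    step_factor: float = 1.5,
    improve: float = 0.02,
    seed: int | None = None,
    mtry_start: int | None = None,
) -> TuneTrace:
    """Search for the mtry with least OOB error, tuneRF-style.

    Starting from the default mtry, the search walks upward (multiply by
    `step_factor`, round half-up) and then downward (divide), continuing in a
    direction while the relative OOB improvement over the best error so far
    exceeds `improve`.  Every forest uses the same seed, so the trace is
    deterministic for a given input.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty feature matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate label space: need >= 2 distinct labels")
    n_var = X.shape[1]
    start = mtry_start if mtry_start is not None else max(
        1, _round_half_up(math.sqrt(n_var) / 2)
    )
    start = int(np.clip(start, 1, n_var))

    cache: dict[int, float] = {}

    def oob(mtry: int) -> float:
        if mtry not in cache:
            cache[mtry] = _fit_forest(X, y, ntree, mtry, seed)[1]
        return cache[mtry]

    trace: list[tuple[int, float]] = [(start, oob(start))]
    best_err = trace[0][1]
    for step in (step_factor, 1.0 / step_factor):
        cur = start
        while True:
            nxt = int(np.clip(_round_half_up(cur * step), 1, n_var))
            if nxt == cur:
                break
            if best_err == 0.0:
                break  # cannot improve on a perfect OOB fit
            err = oob(nxt)
            if (nxt, err) not in trace:
                trace.append((nxt, err))
            if (best_err - err) / best_err > improve:
                best_err = err
                cur = nxt
            else:
                break
    chosen = min(trace, key=lambda t: t[1])[0]
    return TuneTrace(trace, chosen)


def oob_permutation_importance(
    clf: RandomForestClassifier,
    X: np.ndarray,
    y: Sequence[str],
    seed: int | None = None,
) -> np.ndarray:
    """Mean decrease in per-tree OOB accuracy when each variable is permuted.

    For every tree, accuracy on its out-of-bag examples is compared with the
    accuracy after shuffling one column among those examples; the drop is
    averaged over trees.  A constant column scores ~0; an informative one
    scores positive.  Uses the fitted trees' fast prediction path directly,
    which keeps 256 variables x hundreds of trees tractable.
    """
    X32 = np.ascontiguousarray(np.asarray(X), dtype=np.float32)
    class_index = {c: i for i, c in enumerate(clf.classes_)}
    y_enc = np.array([class_index[v] for v in np.asarray(y)])
    n, p = X32.shape
    rng = np.random.default_rng(_as_int_seed(seed))
    importance = np.zeros(p)
    n_used = 0
    for tree, inbag in zip(clf.estimators_, clf.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[inbag] = False
        idx = np.flatnonzero(oob_mask)
        if idx.size == 0:
            continue
        n_used += 1
        Xo = X32[idx].copy()
        yo = y_enc[idx]
        votes = tree.tree_.predict(Xo)  # (n_oob, 1, n_classes) leaf counts
        base_acc = (votes.reshape(len(idx), -1).argmax(axis=1) == yo).mean()
        perm = rng.permutation(idx.size)
        for j in range(p):
            col = Xo[:, j].copy()
            Xo[:, j] = col[perm]
            votes = tree.tree_.predict(Xo)
            acc = (votes.reshape(len(idx), -1).argmax(axis=1) == yo).mean()
            importance[j] += base_acc - acc
            Xo[:, j] = col
    return importance / max(n_used, 1)


@dataclass
class RankModelBundle:
    """One trained forest for one taxonomic rank, plus its tuning metadata."""

    rank: str
    label_space: list[str]
    k: int
    variable_subset: list[str]
    mtry: int
    ntree: int
    oob_error: float
    permutation_importance: np.ndarray | None
    model: RandomForestClassifier
    training_manifest: dict = field(default_factory=dict)


def train_rank_model(
    features: np.ndarray,
    labels: Sequence[str],
    rank: str,
    k: int,
    ntree: int = 1000,
    mtry: int | None = None,
    seed: int | None = None,
    variable_subset: Sequence[str] | str = "all",
    compute_importance: bool = True,
    small_class_policy: str = "drop",
) -> RankModelBundle:
    """Train the forest for one rank and record OOB error and importances.

    Labels represented by fewer than 2 training sequences are, per
    `small_class_policy`, either dropped with a warning (``drop``) or a hard
    error (``error``): a single example can never be out-of-bag-validated.
    `mtry` defaults to the k-mer rule (8 for k=4); pass the value chosen by
    `tune_mtry` to reproduce the tuned protocol.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels differ in length")
    columns = kmer_features.resolve_subset(k, variable_subset)
    if X.shape[1] != len(columns):
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns but the variable subset "
            f"has {len(columns)}"
        )

    label_counts = pd.Series(y).value_counts()
    small = label_counts[label_counts < 2].index.tolist()
    if small:
        if small_class_policy == "error":
            raise ValueError(f"labels with < 2 training sequences at {rank}: {small}")
        warnings.warn(
            f"dropping {len(small)} label(s) with < 2 training sequences at {rank}",
            stacklevel=2,
        )
        keep = ~np.isin(y, small)
        X, y = X[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate label space: need >= 2 distinct labels")

    if mtry is None:
        mtry = default_mtry(k)
    mtry = int(np.clip(mtry, 1, X.shape[1]))
    clf, oob_error = _fit_forest(X, y, ntree, mtry, seed)
    importance = (
        oob_permutation_importance(clf, X, y, seed) if compute_importance else None
    )
    manifest = {
        "counts_per_label": {str(l): int(c) for l, c in pd.Series(y).value_counts().items()},
        "dropped_labels": [str(l) for l in small],
        "seed": seed,
        "trained_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return RankModelBundle(
        rank=rank,
        label_space=[str(c) for c in clf.classes_],
        k=k,
        variable_subset=columns,
        mtry=mtry,
        ntree=int(ntree),
        oob_error=oob_error,
        permutation_importance=importance,
        model=clf,
        training_manifest=manifest,
    )


def variable_pruning_experiment(
    features: np.ndarray,
    labels: Sequence[str],
    block: int = 25,
    steps: int = 3,
    ntree: int = 100,
    mtry: int = 8,
    seed: int | None = None,
) -> pd.DataFrame:
    """OOB error as the least-important variables are pruned in blocks.

    A full-set forest ranks variables by OOB permutation importance; then
    `steps` successively smaller subsets are formed by removing the `block`
    least important variables each time (256 -> 231 -> 206 -> 181 with the
    defaults on a 4-mer feature space).  Returns a (n_variables, oob_error)
    table; `block=0` yields the full-set row only.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    p = X.shape[1]
    if block < 0 or steps < 0:
        raise ValueError("block and steps must be non-negative")
    if block * steps >= p:
        raise ValueError("pruning schedule would remove every variable")
    clf, err = _fit_forest(X, y, ntree, mtry, seed)
    rows = [(p, err)]
    if block > 0:
        order = np.argsort(
            oob_permutation_importance(clf, X, y, seed), kind="stable"
        )  # ascending importance
        keep = np.ones(p, dtype=bool)
        for _ in range(steps):
            prune = [j for j in order if keep[j]][:block]
            keep[prune] = False
            cols = np.flatnonzero(keep)
            _, err = _fit_forest(X[:, cols], y, ntree, min(mtry, len(cols)), seed)
            rows.append((int(keep.sum()), err))
    return pd.DataFrame(rows, columns=["n_variables", "oob_error"])


def ntree_saturation_curve(
    features: np.ndarray,
    labels: Sequence[str],
    mtry: int,
    ntree_grid: Sequence[int],
    seed: int | None = None,
) -> pd.DataFrame:
    """OOB error at each forest size in an ascending ntree grid (common seed)."""
    grid = list(ntree_grid)
    if grid != sorted(grid):
        raise ValueError("ntree_grid must be ascending")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rows = [(int(nt), _fit_forest(X, y, nt, mtry, seed)[1]) for nt in grid]
    return pd.DataFrame(rows, columns=["ntree", "oob_error"])


@dataclass
class BundleSet:
    """The per-rank bundles for one region, plus shared classification metadata."""

    region: str
    k: int
    bundles: dict[str, RankModelBundle]
    kingdom: str | None = None
    parent_maps: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def ranks(self) -> list[str]:
        return [r for r in CLASSIFY_RANKS if r in self.bundles]


def train_region_models(
    records: Sequence[ReferenceRecord],
    region: str,
    k: int = 4,
    ntree: int = 1000,
    mtry: int | None = None,
    seed: int | None = None,
    ranks: Sequence[str] = CLASSIFY_RANKS,
    derep_threshold: float = 1.0,
    tune: bool = False,
    compute_importance: bool = True,
    small_class_policy: str = "drop",
) -> BundleSet:
    """Full training protocol for one region's extracted sequences.

    Per rank: group by taxon, dereplicate within each group (threshold 1 for
    short regions), pool the representatives, and train that rank's forest.
    With `tune=True` mtry is chosen per rank by the OOB search instead of the
    default rule.
    """
    records = list(records)
    X_all, _ = kmer_features.featurize_batch((r.sequence for r in records), k)
    index_of = {r.id: i for i, r in enumerate(records)}
    lineages = {r.id: r.lineage for r in records}

    bundles: dict[str, RankModelBundle] = {}
    for rank in ranks:
        by_label: dict[str, list[ReferenceRecord]] = {}
        for r in records:
            label = r.lineage.at(rank)
            if label:
                by_label.setdefault(label, []).append(r)
        train_ids: list[str] = []
        train_labels: list[str] = []
        for label, members in by_label.items():
            clusters = dereplicate([(m.id, m.sequence) for m in members], derep_threshold)
            for rep_id, _seq in representatives(clusters):
                train_ids.append(rep_id)
                train_labels.append(label)
        X = X_all[[index_of[i] for i in train_ids]]
        rank_mtry = mtry
        if tune:
            rank_mtry = tune_mtry(X, train_labels, ntree=min(ntree, 200), seed=seed).chosen_mtry
        bundles[rank] = train_rank_model(
            X,
            train_labels,
            rank,
            k,
            ntree=ntree,
            mtry=rank_mtry,
            seed=seed,
            compute_importance=compute_importance,
            small_class_policy=small_class_policy,
        )

    kingdoms = {l.at("kingdom") for l in lineages.values() if l.at("kingdom")}
    return BundleSet(
        region=region,
        k=k,
        bundles=bundles,
        kingdom=kingdoms.pop() if len(kingdoms) == 1 else None,
        parent_maps=build_parent_maps(lineages),
    )


# ---------------------------------------------------------------------------
# persistence: one subdirectory per rank, JSON manifests, joblib models

def save_bundle_set(bundle_set: BundleSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    top = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "region": bundle_set.region,
        "k": bundle_set.k,
        "kingdom": bundle_set.kingdom,
        "ranks": bundle_set.ranks(),
        "parent_maps": bundle_set.parent_maps,
    }
    (directory / "manifest.json").write_text(json.dumps(top, indent=1))
    for rank, b in bundle_set.bundles.items():
        sub = directory / rank
        sub.mkdir(exist_ok=True)
        manifest = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "rank": b.rank,
            "k": b.k,
            "mtry": b.mtry,
            "ntree": b.ntree,
            "oob_error": b.oob_error,
            "label_space": b.label_space,
            "variable_subset": b.variable_subset,
            "permutation_importance": (
                None
                if b.permutation_importance is None
                else [float(v) for v in b.permutation_importance]
            ),
            "training_manifest": b.training_manifest,
        }
        (sub / "manifest.json").write_text(json.dumps(manifest, indent=1))
        joblib.dump(b.model, sub / "model.joblib")


def load_bundle_set(directory: str | Path) -> BundleSet:
    directory = Path(directory)
    top = json.loads((directory / "manifest.json").read_text())
    if top.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"model directory {directory} has format version "
            f"{top.get('format_version')!r}; this build reads {BUNDLE_FORMAT_VERSION!r}"
        )
    bundles: dict[str, RankModelBundle] = {}
    for rank in top["ranks"]:
        sub = directory / rank
        m = json.loads((sub / "manifest.json").read_text())
        if m.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValueError(f"rank manifest {sub} has a mismatched format version")
        imp = m["permutation_importance"]
        bundles[rank] = RankModelBundle(
            rank=m["rank"],
            label_space=m["label_space"],
            k=m["k"],
            variable_subset=m["variable_subset"],
            mtry=m["mtry"],
            ntree=m["ntree"],
            oob_error=m["oob_error"],
            permutation_importance=None if imp is None else np.array(imp),
            model=joblib.load(sub / "model.joblib"),
            training_manifest=m["training_manifest"],
        )
    return BundleSet(
        region=top["region"],
        k=top["k"],
        bundles=bundles,
        kingdom=top.get("kingdom"),
        parent_maps={r: dict(v) for r, v in top.get("parent_maps", {}).items()},
    )
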