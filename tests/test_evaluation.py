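import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hvrforest.dereplication import Cluster
from hvrforest.evaluation import (
    ConfusionCounts,
    compute_metrics,
    confusion_by_group,
    inject_mutations,
    macro_average,
    split_per_cluster,
)
from hvrforest.reference_db import Lineage


def make_cluster(rep, members):
    return Cluster(rep, "A" * 10, list(members), 1.0)


def lin(phylum="", genus=""):
    return Lineage(("Bacteria", phylum, "", "", "", genus, ""))


# --- split_per_cluster -----------------------------------------------------

def test_split_ten_member_cluster():
    train, test = split_per_cluster([make_cluster("a0", [f"a{i}" for i in range(10)])],
                                    0.10, seed=0)
    assert len(test) == 1 and len(train) == 9
    assert set(train) | set(test) == {f"a{i}" for i in range(10)}
    assert not set(train) & set(test)


def test_split_all_singletons_warns():
    clusters = [make_cluster(f"s{i}", [f"s{i}"]) for i in range(5)]
    with pytest.warns(UserWarning, match="singleton"):
        train, test = split_per_cluster(clusters, 0.10, seed=0)
    assert test == [] and len(train) == 5


def test_split_allocations_match_arithmetic():
    sizes = [1, 2, 7, 10, 25, 33]
    clusters = [
        make_cluster(f"c{j}_0", [f"c{j}_{i}" for i in range(s)])
        for j, s in enumerate(sizes)
    ]
    train, test = split_per_cluster(clusters, 0.10, seed=3)
    expected = sum(max(1, math.floor(0.10 * s + 0.5)) for s in sizes if s >= 2)
    assert len(test) == expected
    assert len(train) + len(test) == sum(sizes)


# --- inject_mutations ------------------------------------------------------

def test_mutation_rate_zero_is_identity():
    assert inject_mutations("ACGTACGT", 0.0, seed=1) == "ACGTACGT"


def test_mutation_rate_one_never_silent():
    out = inject_mutations("AAAA", 1.0, seed=2)
    assert len(out) == 4 and "A" not in out and set(out) <= set("CGT")


def test_mutation_calibration_binomial():
    """1,000 x 200 nt at 1%: observed fraction within 3 binomial SE of 0.01."""
    rng = np.random.default_rng(123)
    n, L, rate = 1000, 200, 0.01
    diffs = 0
    for _ in range(n):
        seq = "".join(rng.choice(list("ACGT"), L))
        mut = inject_mutations(seq, rate, rng=rng)
        diffs += sum(a != b for a, b in zip(seq, mut))
    observed = diffs / (n * L)
    se = math.sqrt(rate * (1 - rate) / (n * L))
    assert abs(observed - rate) <= 3 * se


def test_mutation_deterministic_per_seed():
    s = "ACGT" * 50
    assert inject_mutations(s, 0.05, seed=9) == inject_mutations(s, 0.05, seed=9)
    assert inject_mutations(s, 0.05, seed=9) != inject_mutations(s, 0.05, seed=10)


# --- confusion_by_group ----------------------------------------------------

def test_confusion_perfect_two_groups():
    truth = {f"a{i}": lin("A") for i in range(5)} | {f"b{i}": lin("B") for i in range(5)}
    counts, excluded = confusion_by_group(truth, truth, "phylum")
    assert excluded == 0
    for taxon in ("A", "B"):
        c = counts[taxon]
        assert (c.TP, c.FP, c.FN, c.TN) == (5, 0, 0, 5)


def test_confusion_all_predicted_one_group():
    truth = {f"a{i}": lin("A") for i in range(4)} | {f"b{i}": lin("B") for i in range(3)}
    pred = {k: lin("A") for k in truth}
    counts, _ = confusion_by_group(truth, pred, "phylum")
    assert counts["A"].FP == 3 and counts["A"].TP == 4
    assert counts["B"].FN == 3 and counts["B"].TP == 0


def test_confusion_excludes_unlabelled_truth():
    truth = {"a": lin("A"), "b": lin("")}
    pred = {"a": lin("A"), "b": lin("A")}
    counts, excluded = confusion_by_group(truth, pred, "phylum")
    assert excluded == 1 and counts["A"].total == 1


def test_confusion_id_mismatch_rejected():
    with pytest.raises(ValueError, match="ids"):
        confusion_by_group({"a": lin("A")}, {"b": lin("A")}, "phylum")


def test_confusion_matches_bruteforce_tally():
    rng = np.random.default_rng(11)
    taxa = ["A", "B", "C", "D"]
    truth = {f"r{i}": lin(rng.choice(taxa)) for i in range(80)}
    pred = {k: lin(rng.choice(taxa)) for k in truth}
    counts, _ = confusion_by_group(truth, pred, "phylum")
    for taxon, c in counts.items():
        tp = sum(1 for k in truth
                 if truth[k].at("phylum") == taxon and pred[k].at("phylum") == taxon)
        fp = sum(1 for k in truth
                 if truth[k].at("phylum") != taxon and pred[k].at("phylum") == taxon)
        fn = sum(1 for k in truth
                 if truth[k].at("phylum") == taxon and pred[k].at("phylum") != taxon)
        assert (c.TP, c.FP, c.FN) == (tp, fp, fn)
        assert c.total == 80


# --- compute_metrics / macro_average ---------------------------------------

def sklearn_oracle(c):
    """Independent implementation via sklearn on expanded label arrays."""
    from sklearn.metrics import (
        accuracy_score,
        f1_score,
        matthews_corrcoef,
        precision_score,
        recall_score,
    )

    y_true = [1] * (c.TP + c.FN) + [0] * (c.FP + c.TN)
    y_pred = [1] * c.TP + [0] * c.FN + [1] * c.FP + [0] * c.TN
    sens = recall_score(y_true, y_pred, zero_division=np.nan)
    spec = recall_score(y_true, y_pred, pos_label=0, zero_division=np.nan)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": precision_score(y_true, y_pred, zero_division=np.nan),
        "accuracy": accuracy_score(y_true, y_pred),
        "g_mean": math.sqrt(sens * spec),
        "f_measure": f1_score(y_true, y_pred),
        "mcc": matthews_corrcoef(y_true, y_pred),
    }


def test_metrics_perfect_case():
    row = compute_metrics(ConfusionCounts(50, 0, 0, 50))
    for m in ("sensitivity", "specificity", "precision", "accuracy",
              "g_mean", "f_measure", "mcc"):
        assert getattr(row, m) == pytest.approx(1.0)


def test_metrics_symmetric_case():
    row = compute_metrics(ConfusionCounts(25, 25, 25, 25))
    for m in ("sensitivity", "specificity", "precision", "accuracy"):
        assert getattr(row, m) == pytest.approx(0.5)
    assert row.mcc == pytest.approx(0.0)


def test_metrics_zero_denominators_undefined():
    row = compute_metrics(ConfusionCounts(0, 0, 0, 10))
    assert row.sensitivity is None and row.precision is None
    assert row.specificity == 1.0


@given(st.lists(st.integers(0, 60), min_size=4, max_size=4))
def test_metrics_match_independent_oracle(quad):
    tp, fp, fn, tn = quad
    c = ConfusionCounts(tp, fp, fn, tn)
    row = compute_metrics(c)
    if min(tp + fn, tn + fp, tp + fp) == 0 or row.mcc is None:
        return  # undefined cases are handled by the zero-denominator test
    oracle = sklearn_oracle(c)
    for m, v in oracle.items():
        ours = getattr(row, m)
        if ours is None:  # zero-denominator convention differs from sklearn's
            continue
        assert ours == pytest.approx(v, abs=1e-12)


def test_metric_bounds_properties():
    rng = np.random.default_rng(2)
    for _ in range(50):
        c = ConfusionCounts(*rng.integers(0, 100, size=4))
        row = compute_metrics(c)
        if row.mcc is not None:
            assert -1.0 - 1e-12 <= row.mcc <= 1.0 + 1e-12
        if row.g_mean is not None:
            assert row.g_mean <= max(row.sensitivity, row.specificity) + 1e-12
            assert row.g_mean ** 2 == pytest.approx(
                row.sensitivity * row.specificity
            )


def test_macro_average_cases():
    r1 = compute_metrics(ConfusionCounts(8, 2, 2, 8), "g1")
    summary = macro_average([r1, r1])
    assert summary.means["precision"] == pytest.approx(r1.precision)

    r2 = compute_metrics(ConfusionCounts(4, 1, 1, 14), "g2")
    r1.precision, r2.precision = 0.8, 0.9
    assert macro_average([r1, r2]).means["precision"] == pytest.approx(0.85)


def test_macro_average_skips_undefined_and_counts_them():
    defined = compute_metrics(ConfusionCounts(5, 0, 5, 10), "a")
    undefined = compute_metrics(ConfusionCounts(0, 0, 0, 20), "b")
    summary = macro_average([defined, undefined])
    assert summary.means["sensitivity"] == pytest.approx(0.5)
    assert summary.n_undefined["sensitivity"] == 1
    assert summary.n_defined["sensitivity"] == 1


def test_macro_average_all_undefined_flagged():
    rows = [compute_metrics(ConfusionCounts(0, 0, 0, 9), "x")]
    summary = macro_average(rows)
    assert summary.means["sensitivity"] is None


def test_specificity_accuracy_near_one_with_many_groups():
    """With >= 50 one-vs-rest groups, TN dominates and both metrics -> 1."""
    rng = np.random.default_rng(4)
    n_groups, per = 60, 5
    truth = {}
    pred = {}
    for g in range(n_groups):
        for i in range(per):
            rid = f"g{g}_{i}"
            truth[rid] = lin(f"T{g}")
            # mostly right, some confusion with a neighbour group
            pred[rid] = lin(f"T{g}" if rng.random() < 0.8 else f"T{(g+1) % n_groups}")
    counts, _ = confusion_by_group(truth, pred, "phylum")
    rows = [compute_metrics(c, g) for g, c in counts.items()]
    summary = macro_average(rows)
    assert summary.means["specificity"] > 0.99
    assert summary.means["accuracy"] > 0.99
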