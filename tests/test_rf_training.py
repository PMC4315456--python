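import numpy as np
import pytest

from hvrforest import rf_training as rf
from hvrforest.kmer_features import kmer_names


def separable_data(n_per=30, n_labels=2, p=20, seed=0):
    """Labels with disjoint feature support: perfectly separable."""
    X = np.zeros((n_per * n_labels, p))
    y = []
    block = p // n_labels
    for i in range(n_labels):
        X[i * n_per:(i + 1) * n_per, i * block:(i + 1) * block] = 1.0
        y += [chr(ord("A") + i)] * n_per
    rng = np.random.default_rng(seed)
    X += rng.normal(0, 0.01, X.shape)
    return X, np.array(y)


@pytest.mark.parametrize("k,expected", [(4, 8), (2, 2), (5, 16), (3, 4)])
def test_default_mtry_rule(k, expected):
    assert rf.default_mtry(k) == expected


def test_tune_separable_reaches_zero_oob():
    X, y = separable_data()
    trace = rf.tune_mtry(X, y, ntree=60, seed=1)
    assert trace.best_oob_error == 0.0
    assert trace.chosen_mtry == min(trace.trace, key=lambda t: t[1])[0]


def test_tune_null_labels_near_majority_error():
    """Labels independent of features: OOB error ~ majority-class error."""
    rng = np.random.default_rng(5)
    X = rng.random((300, 30))
    y = rng.choice(["A", "B"], 300, p=[0.5, 0.5])
    majority_error = 1.0 - max(np.mean(y == "A"), np.mean(y == "B"))
    trace = rf.tune_mtry(X, y, ntree=150, seed=2)
    for _, err in trace.trace:
        assert err == pytest.approx(majority_error, abs=0.12)


def test_tune_deterministic_per_seed():
    rng = np.random.default_rng(7)
    X = rng.random((120, 25))
    y = rng.choice(["A", "B", "C"], 120)
    t1 = rf.tune_mtry(X, y, ntree=80, seed=9)
    t2 = rf.tune_mtry(X, y, ntree=80, seed=9)
    assert t1.trace == t2.trace and t1.chosen_mtry == t2.chosen_mtry


def test_tune_rejects_single_label():
    X = np.random.default_rng(0).random((20, 5))
    with pytest.raises(ValueError, match="degenerate label space"):
        rf.tune_mtry(X, ["A"] * 20, ntree=10, seed=0)


def test_train_separable_three_labels():
    X, y = separable_data(n_per=20, n_labels=3, p=30)
    b = rf.train_rank_model(
        X, y, "genus", 4, ntree=100, seed=1, variable_subset=kmer_names(4)[:30]
    )
    assert b.oob_error == 0.0
    assert sorted(b.label_space) == ["A", "B", "C"]
    assert b.mtry == 8 and b.ntree == 100


def test_constant_feature_has_zero_importance():
    X, y = separable_data(p=20)
    X[:, 13] = 0.42
    b = rf.train_rank_model(
        X, y, "genus", 4, ntree=80, seed=3, variable_subset=kmer_names(4)[:20]
    )
    assert b.permutation_importance[13] == pytest.approx(0.0, abs=1e-12)


def test_planted_feature_ranks_first_by_importance():
    rng = np.random.default_rng(4)
    X = rng.random((240, 40))
    y = np.where(X[:, 7] > 0.5, "hi", "lo")
    b = rf.train_rank_model(
        X, y, "genus", 4, ntree=120, seed=4, variable_subset=kmer_names(4)[:40]
    )
    assert int(np.argmax(b.permutation_importance)) == 7


def test_small_class_policy():
    X, y = separable_data(n_per=10, n_labels=2, p=10)
    X = np.vstack([X, X[:1]])
    y = np.append(y, "C")  # singleton label
    with pytest.raises(ValueError, match="< 2 training sequences"):
        rf.train_rank_model(X, y, "genus", 4, ntree=20, seed=0,
                            variable_subset=kmer_names(4)[:10],
                            small_class_policy="error")
    with pytest.warns(UserWarning, match="dropping"):
        b = rf.train_rank_model(X, y, "genus", 4, ntree=20, seed=0,
                                variable_subset=kmer_names(4)[:10])
    assert "C" not in b.label_space


def test_pruning_schedule_sizes():
    rng = np.random.default_rng(1)
    X = rng.random((120, 256))
    y = np.where(X[:, 0] > 0.5, "A", "B")
    table = rf.variable_pruning_experiment(X, y, seed=1)
    assert table["n_variables"].tolist() == [256, 231, 206, 181]


def test_pruning_block_zero_single_row():
    X, y = separable_data()
    table = rf.variable_pruning_experiment(X, y, block=0, ntree=30, mtry=4, seed=0)
    assert len(table) == 1 and table["n_variables"].iloc[0] == X.shape[1]


def test_pruning_spares_error_until_informative_variables_go():
    """With 10 informative of 60 variables, pruning 3 x 10 blocks removes
    only uninformative variables, so the OOB error does not rise."""
    rng = np.random.default_rng(6)
    n = 300
    X = rng.random((n, 60))
    y = np.where(X[:, :10].sum(axis=1) > 5.0, "A", "B")
    table = rf.variable_pruning_experiment(
        X, y, block=10, steps=3, ntree=100, mtry=8, seed=6
    )
    assert table["n_variables"].tolist() == [60, 50, 40, 30]
    assert table["oob_error"].iloc[3] <= table["oob_error"].iloc[0] + 0.05


def test_ntree_curve_shapes():
    X, y = separable_data()
    single = rf.ntree_saturation_curve(X, y, mtry=4, ntree_grid=[50], seed=0)
    assert len(single) == 1 and single["oob_error"].iloc[0] == 0.0
    with pytest.raises(ValueError, match="ascending"):
        rf.ntree_saturation_curve(X, y, 4, [100, 50], seed=0)


def test_ntree_error_nonincreasing_median_over_seeds():
    rng = np.random.default_rng(8)
    X = rng.random((200, 30))
    y = np.where(X[:, 3] + rng.normal(0, 0.35, 200) > 0.5, "A", "B")
    grid = [25, 100, 400]
    curves = np.array([
        rf.ntree_saturation_curve(X, y, mtry=5, ntree_grid=grid, seed=s)["oob_error"]
        for s in range(5)
    ])
    med = np.median(curves, axis=0)
    assert med[0] >= med[-1] - 0.02  # non-increasing within Monte-Carlo slack


def test_reproducibility_identical_seeds(hvr_records):
    from hvrforest.kmer_features import featurize_batch

    sample = hvr_records[::3][:120]  # stride to mix phyla
    X, _ = featurize_batch([r.sequence for r in sample], 4)
    y = [r.lineage.at("phylum") for r in sample]
    b1 = rf.train_rank_model(X, y, "phylum", 4, ntree=50, seed=5)
    b2 = rf.train_rank_model(X, y, "phylum", 4, ntree=50, seed=5)
    assert b1.oob_error == b2.oob_error
    np.testing.assert_array_equal(
        b1.permutation_importance, b2.permutation_importance
    )
    np.testing.assert_array_equal(b1.model.predict(X), b2.model.predict(X))
    assert 0.0 <= b1.oob_error <= 1.0
    assert sorted(b1.label_space) == sorted(set(y))


def test_bundle_save_load_round_trip(tmp_path, trained_bundle):
    from hvrforest.rf_training import load_bundle_set, save_bundle_set

    save_bundle_set(trained_bundle, tmp_path / "models")
    back = load_bundle_set(tmp_path / "models")
    assert back.region == trained_bundle.region and back.k == trained_bundle.k
    for rank in trained_bundle.ranks():
        a, b = trained_bundle.bundles[rank], back.bundles[rank]
        assert a.label_space == b.label_space
        assert a.oob_error == b.oob_error and a.mtry == b.mtry


def test_bundle_version_mismatch_refused(tmp_path, trained_bundle):
    import json

    from hvrforest.rf_training import load_bundle_set, save_bundle_set

    d = tmp_path / "models"
    save_bundle_set(trained_bundle, d)
    manifest = json.loads((d / "manifest.json").read_text())
    manifest["format_version"] = "0"
    (d / "manifest.json").write_text(json.dumps(manifest))
    with pytest.raises(ValueError, match="format version"):
        load_bundle_set(d)
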