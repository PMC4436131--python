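"""Blocked CV structure, per-family feature selection, consensus rules."""

import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import NearestCentroid

from crdmarkers import classify, simulate
from crdmarkers.errors import ConfigError, DataError


def test_blocked_folds_partition_and_no_zt_leakage(paper_design):
    train = paper_design[paper_design["stage"].isin(["baseline", "rec14"])]
    folds = classify.blocked_folds(train)
    assert len(folds) == 6
    all_test = [s for f in folds for s in f.test_ids]
    assert sorted(all_test) == sorted(train["sample_id"])
    assert len(set(all_test)) == len(all_test)
    zt_of = dict(zip(train["sample_id"], train["zt"]))
    for fold in folds:
        test_zts = {zt_of[s] for s in fold.test_ids}
        train_zts = {zt_of[s] for s in fold.train_ids}
        assert test_zts == {fold.zt}
        assert not test_zts & train_zts


def test_blocked_folds_two_zts_and_single_zt_error():
    design = simulate.generate_design(stages=("baseline",), zts=(0, 12), replicates=2)
    assert len(classify.blocked_folds(design)) == 2
    single = simulate.generate_design(stages=("baseline",), zts=(0,), replicates=4)
    with pytest.raises(DataError):
        classify.blocked_folds(single)


def nsc_oracle(X, y, shrinkage):
    """Independent soft-thresholding reference for the shrunken centroids."""
    X = np.asarray(X, float)
    classes = sorted(set(y))
    n, p = X.shape
    overall = X.mean(axis=0)
    centroids, ds = [], []
    pooled = np.zeros(p)
    for c in classes:
        block = X[np.asarray(y) == c]
        centroids.append(block.mean(axis=0))
        pooled += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
    s = np.sqrt(pooled / (n - len(classes)))
    s0 = np.median(s)
    shrunk = []
    for c, cent in zip(classes, centroids):
        nk = (np.asarray(y) == c).sum()
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        d = (cent - overall) / (mk * (s + s0))
        d = np.sign(d) * np.clip(np.abs(d) - shrinkage, 0.0, None)
        ds.append(d)
        shrunk.append(overall + mk * (s + s0) * d)
    return np.vstack(shrunk), np.vstack(ds)


@pytest.mark.parametrize("seed", range(8))
def test_nsc_matches_hand_rolled_oracle(seed):
    rng = np.random.default_rng(seed)
    n, p = rng.integers(4, 9), rng.integers(1, 6)
    X = rng.normal(size=(n, p))
    y = np.array(["a", "b"] * ((n + 1) // 2))[:n]
    shrinkage = float(rng.uniform(0, 2))
    model = classify.NearestShrunkenCentroid(shrinkage).fit(X, y)
    oracle_centroids, oracle_d = nsc_oracle(X, y, shrinkage)
    np.testing.assert_allclose(model.shrunken_centroids_, oracle_centroids, atol=1e-12)
    np.testing.assert_allclose(model.deviations_, oracle_d, atol=1e-12)
    assert list(model.selected_mask_) == list(np.any(oracle_d != 0, axis=0))


def test_nsc_agrees_with_sklearn_shrunken_centroids(rng):
    X = rng.normal(size=(12, 6))
    y = np.repeat(["a", "b"], 6)
    X[y == "b", :2] += 1.5
    mine = classify.NearestShrunkenCentroid(0.7).fit(X, y)
    ref = NearestCentroid(shrink_threshold=0.7).fit(X, y)
    np.testing.assert_allclose(mine.shrunken_centroids_, ref.centroids_, atol=1e-10)


def test_separable_instance_selected_by_every_method():
    rng = np.random.default_rng(0)
    n = 16
    y = np.repeat([classify.LABEL_ND, classify.LABEL_CRD], n // 2)
    X = rng.normal(0, 0.05, size=(n, 20))
    X[y == classify.LABEL_CRD, 3] += 3.0
    X[y == classify.LABEL_CRD, 11] -= 3.0
    frame = pd.DataFrame(X, columns=[f"p{i}" for i in range(20)])
    for method in classify.METHODS:
        spec = classify.ClassifierSpec(method=method, top_k=2, n_trees=200, seed=1)
        model, selected = classify.fit_and_select(frame, y, spec)
        assert {"p3", "p11"} <= set(selected), method
        assert (model.predict(frame.to_numpy(float)) == y).all(), method


def test_single_class_training_rejected():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)))
    with pytest.raises(DataError):
        classify.fit_and_select(X, np.array(["CRD"] * 6), classify.ClassifierSpec("linear_svm"))


def test_permuted_labels_give_chance_accuracy(rng):
    """With labels shuffled independently of the data, blocked CV sits at 0.5."""
    design = simulate.generate_design(stages=("baseline", "rec14"), replicates={"baseline": 2, "rec14": 1})
    X = rng.normal(size=(30, len(design)))
    matrix = pd.DataFrame(X, index=[f"p{i}" for i in range(30)], columns=design["sample_id"])
    accs = []
    spec = classify.ClassifierSpec("linear_svm", top_k=5)
    for i in range(100):
        shuffled = design.copy()
        shuffled["stage"] = rng.permutation(shuffled["stage"].to_numpy())
        try:
            result = classify.evaluate_blocked_cv(matrix, shuffled, [spec])
        except DataError:  # a fold may lose one class entirely
            continue
        accs.append(result.accuracies["linear_svm"])
    mean_acc = np.mean(accs)
    assert abs(mean_acc - 0.5) < 0.06


@pytest.mark.parametrize(
    "fold_sets, expected",
    [
        ([{"a"}] * 4 + [set()] * 2, {"a"}),  # 4 of 6 folds: in
        ([{"a"}] * 3 + [set()] * 3, set()),  # exactly half: out (strict majority)
        ([{"a", "b"}] * 6, {"a", "b"}),  # unanimous
    ],
)
def test_per_classifier_majority_rule(fold_sets, expected):
    assert classify.per_classifier_consensus(fold_sets) == expected


def test_majority_threshold_monotonicity(rng):
    fold_sets = [set(rng.choice(20, size=rng.integers(1, 15), replace=False)) for _ in range(6)]
    sizes = [
        len(classify.per_classifier_consensus(fold_sets, majority=m))
        for m in np.linspace(0.0, 0.99, 12)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_cross_classifier_intersection(caplog):
    probes, genes = classify.cross_classifier_consensus(
        {"x": {"A", "B", "C"}, "y": {"B", "C", "D"}, "z": {"B", "C"}},
        annotation={"B": "gene1", "C": "gene1"},
    )
    assert probes == {"B", "C"}
    assert genes == ["gene1"]
    with caplog.at_level(logging.WARNING):
        empty, _ = classify.cross_classifier_consensus([{"A"}, {"B"}])
    assert empty == set()
    assert any("empty" in r.message for r in caplog.records)
    with pytest.raises(DataError):
        classify.cross_classifier_consensus([{"A"}])


def test_blocked_cv_on_study_recovers_planted_probes(small_study):
    consensus = small_study.consensus
    truth = small_study.truth.set_index("gene")
    planted = {f"{g}_p1" for g in truth.index[truth["archetype"] == "crd_responsive"]}
    assert consensus.consensus_probes <= set.union(*consensus.majority_sets.values())
    for method_set in consensus.majority_sets.values():
        assert consensus.consensus_probes <= method_set
    assert len(consensus.consensus_probes & planted) >= 8
    assert len(consensus.consensus_probes - planted) <= 2
    assert all(a >= 0.9 for a in consensus.accuracies.values())


def test_external_prediction_monotone_in_planted_dose(small_study):
    """One shift carries 1/6 of the full effect: CRD calls rise with dose."""
    ext = small_study.external_predictions
    by_stage = ext.groupby("stage")["frac_crd"].mean()
    assert by_stage["shift1"] < by_stage["shift6"]
    assert by_stage["rec5"] > by_stage["shift1"]


def test_external_prediction_empty_consensus_rejected(small_study):
    with pytest.raises(DataError, match="majority threshold"):
        classify.predict_external_stages(
            small_study.matrix, small_study.design, set(),
            classify.default_specs(["linear_svm"]),
        )


def test_classifier_spec_validation():
    with pytest.raises(ConfigError):
        classify.ClassifierSpec(method="boosting")
    with pytest.raises(ConfigError):
        classify.ClassifierSpec(method="linear_svm", top_k=0)
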