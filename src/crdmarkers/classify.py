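"""Time-point-blocked consensus classification of CRD vs non-disrupted.

Samples are labelled CRD (both rotation protocols pooled, by default the
14-day-recovery animals) or ND (baseline). Cross-validation is
"leave-one-time-point-out": each fold's test set is every sample sharing
one Zeitgeber time, so a classifier is always evaluated on an unseen time
of day and replicate time-point samples never straddle the train/test
boundary.

Three classifier families are supported: random forests, linear-kernel
support vector machines and nearest shrunken centroids (soft-thresholded
class centroids, the PAM approach). Each fold yields a selected probe set;
probes kept in a strict majority of folds form a per-classifier consensus,
and probes present in every classifier's consensus form the cross-classifier
consensus used as the candidate biomarker panel.

Feature-inclusion rules per family: RF and linear SVM take the ``top_k``
probes by impurity importance and absolute weight respectively; NSC takes
the probes with any non-zero shrunken centroid component at the shrinkage
chosen by inner cross-validation (ties broken toward the sparsest model).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigError, DataError
from .normalize import annotate_and_deduplicate

logger = logging.getLogger(__name__)

LABEL_CRD = "CRD"
LABEL_ND = "ND"

METHODS = ("random_forest", "linear_svm", "nearest_shrunken_centroid")


@dataclass(frozen=True)
class ClassifierSpec:
    method: str
    top_k: int = 50
    n_trees: int = 1000
    svm_c: float = 1.0
    shrinkage: float | None = None  # None -> choose by inner CV
    shrinkage_grid_size: int = 30
    inner_cv_splits: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigError(f"unknown classifier method {self.method!r}; choose from {METHODS}")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")


def default_specs(
    methods: Sequence[str] = METHODS, *, top_k: int = 50, n_trees: int = 1000,
    svm_c: float = 1.0, seed: int = 0,
) -> list[ClassifierSpec]:
    return [
        ClassifierSpec(method=m, top_k=top_k, n_trees=n_trees, svm_c=svm_c, seed=seed)
        for m in methods
    ]


def crd_labels(
    design: pd.DataFrame,
    nd_stages: Sequence[str] = ("baseline",),
    crd_stages: Sequence[str] = ("rec14",),
) -> pd.Series:
    """Two-class labels over the training stages; other samples are dropped."""
    labels = pd.Series(index=design["sample_id"].to_numpy(), dtype=object, name="label")
    labels[design[design["stage"].isin(nd_stages)]["sample_id"].to_numpy()] = LABEL_ND
    labels[design[design["stage"].isin(crd_stages)]["sample_id"].to_numpy()] = LABEL_CRD
    return labels.dropna()


@dataclass(frozen=True)
class Fold:
    zt: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def blocked_folds(design: pd.DataFrame) -> list[Fold]:
    """Leave-one-time-point-out folds: one fold per distinct ZT."""
    zts = sorted(design["zt"].unique())
    if len(zts) < 2:
        raise DataError("blocked cross-validation needs >= 2 distinct ZTs")
    folds = []
    for zt in zts:
        test = design[design["zt"] == zt]["sample_id"]
        train = design[design["zt"] != zt]["sample_id"]
        folds.append(Fold(zt=int(zt), train_ids=tuple(train), test_ids=tuple(test)))
    return folds


class NearestShrunkenCentroid:
    """Nearest shrunken centroid classifier (soft-thresholded centroids).

    Per class k and feature j the standardized centroid deviation is
    ``d_kj = (xbar_kj - xbar_j) / (m_k * (s_j + s0))`` with pooled
    within-class standard deviation ``s_j``, fudge factor ``s0`` the median
    of the ``s_j``, and ``m_k = sqrt(1/n_k - 1/n)``. Soft-thresholding
    ``d'_kj = sign(d_kj) * max(|d_kj| - shrinkage, 0)`` shrinks centroids
    toward the overall centroid; features with all components at zero drop
    out of the model. Classification minimizes the standardized squared
    distance to the shrunken centroids minus twice the log class prior.
    """

    def __init__(self, shrinkage: float = 0.0):
        if shrinkage < 0:
            raise ConfigError("shrinkage must be >= 0")
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise DataError("training data contains a single class")
        n, p = X.shape
        k = len(self.classes_)
        overall = X.mean(axis=0)
        centroids = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        within_ss = np.zeros(p)
        for idx, c in enumerate(self.classes_):
            diff = X[y == c] - centroids[idx]
            within_ss += (diff**2).sum(axis=0)
        s = np.sqrt(within_ss / (n - k))
        s0 = np.median(s)
        scale = s + s0
        scale = np.where(scale <= 0, 1e-12, scale)
        m = np.sqrt(1.0 / counts - 1.0 / n)
        d = (centroids - overall) / (m[:, None] * scale)
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.shrinkage, 0.0)
        self.overall_centroid_ = overall
        self.pooled_sd_ = s
        self.s0_ = s0
        self.deviations_ = d_shrunk
        self.shrunken_centroids_ = overall + m[:, None] * scale * d_shrunk
        self.scale_ = scale
        self.priors_ = counts / n
        return self

    @property
    def selected_mask_(self) -> np.ndarray:
        return np.any(self.deviations_ != 0.0, axis=0)

    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], len(self.classes_)))
        for idx in range(len(self.classes_)):
            diff = (X - self.shrunken_centroids_[idx]) / self.scale_
            scores[:, idx] = (diff**2).sum(axis=1) - 2.0 * np.log(self.priors_[idx])
        return scores

    def predict(self, X):
        # ties resolve to the first class in sorted order (deterministic)
        return self.classes_[np.argmin(self.decision_scores(X), axis=1)]


def choose_nsc_shrinkage(
    X, y, *, grid_size: int = 30, n_splits: int = 5, seed: int = 0
) -> float:
    """Pick the NSC shrinkage by stratified inner CV, preferring sparser fits.

    The grid spans 0 to the largest standardized deviation of the full fit.
    Among thresholds with maximal inner-CV accuracy the largest (sparsest
    surviving feature set) wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    full = NearestShrunkenCentroid(0.0).fit(X, y)
    d_max = float(np.abs(full.deviations_).max())
    if d_max == 0:
        return 0.0
    grid = np.linspace(0.0, d_max, grid_size)
    min_class = np.min(np.unique(y, return_counts=True)[1])
    splits = max(2, min(n_splits, int(min_class)))
    cv = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
    correct = np.zeros(grid_size)
    for train_idx, test_idx in cv.split(X, y):
        base = NearestShrunkenCentroid(0.0).fit(X[train_idx], y[train_idx])
        for gi, threshold in enumerate(grid):
            model = NearestShrunkenCentroid(threshold)
            model.classes_ = base.classes_
            model.priors_ = base.priors_
            model.scale_ = base.scale_
            d_shrunk = np.sign(base.deviations_) * np.maximum(
                np.abs(base.deviations_) - threshold, 0.0
            )
            model.deviations_ = d_shrunk
            m = np.sqrt(1.0 / (base.priors_ * len(train_idx)) - 1.0 / len(train_idx))
            model.shrunken_centroids_ = (
                base.overall_centroid_ + m[:, None] * base.scale_ * d_shrunk
            )
            pred = model.predict(X[test_idx])
            correct[gi] += (pred == y[test_idx]).sum()
    best = np.flatnonzero(correct == correct.max())[-1]
    return float(grid[best])


def fit_and_select(
    X: pd.DataFrame, y, spec: ClassifierSpec, seed: int | None = None
):
    """Fit one classifier on (samples x probes) data and select its probes.

    Returns ``(model, selected_probes)`` where the selection follows the
    family's inclusion rule. Raises on a single-class training set.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("training set contains a single class")
    if seed is None:
        seed = spec.seed
    probes = np.asarray(X.columns)
    values = X.to_numpy(float)
    k = min(spec.top_k, len(probes))

    if spec.method == "random_forest":
        model = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=seed, n_jobs=1
        ).fit(values, y)
        order = np.argsort(-model.feature_importances_, kind="stable")
        selected = probes[order[:k]]
    elif spec.method == "linear_svm":
        model = SVC(kernel="linear", C=spec.svm_c).fit(values, y)
        weights = np.abs(model.coef_).ravel()
        order = np.argsort(-weights, kind="stable")
        selected = probes[order[:k]]
    else:  # nearest_shrunken_centroid
        shrinkage = spec.shrinkage
        if shrinkage is None:
            shrinkage = choose_nsc_shrinkage(
                values, y,
                grid_size=spec.shrinkage_grid_size,
                n_splits=spec.inner_cv_splits,
                seed=seed,
            )
        model = NearestShrunkenCentroid(shrinkage).fit(values, y)
        selected = probes[model.selected_mask_]
    return model, list(selected)


def per_classifier_consensus(
    fold_sets: Sequence[Iterable[str]], majority: float = 0.5
) -> set[str]:
    """Probes present in strictly more than ``majority`` of the folds."""
    if not fold_sets:
        raise DataError("need at least one fold selection")
    if not 0 <= majority < 1:
        raise ConfigError("majority threshold must lie in [0, 1)")
    counts = Counter()
    for fold in fold_sets:
        counts.update(set(fold))
    cutoff = majority * len(fold_sets)
    return {probe for probe, c in counts.items() if c > cutoff}


def cross_classifier_consensus(
    sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    annotation: Mapping[str, str | None] | None = None,
) -> tuple[set[str], list[str] | None]:
    """Intersect per-classifier consensus sets; optionally annotate to genes."""
    values = list(sets.values()) if isinstance(sets, Mapping) else list(sets)
    if len(values) < 2:
        raise DataError("cross-classifier consensus needs >= 2 classifier sets")
    probes = set(values[0])
    for s in values[1:]:
        probes &= set(s)
    if not probes:
        logger.warning("cross-classifier consensus is empty")
    genes = annotate_and_deduplicate(probes, annotation) if annotation is not None else None
    return probes, genes


@dataclass
class ConsensusSet:
    fold_sets: dict[str, list[set[str]]]
    majority_sets: dict[str, set[str]]
    consensus_probes: set[str]
    consensus_genes: list[str] | None
    accuracies: dict[str, float]
    majority_threshold: float
    n_test_predictions: int = 0


def evaluate_blocked_cv(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    specs: Sequence[ClassifierSpec],
    *,
    nd_stages: Sequence[str] = ("baseline",),
    crd_stages: Sequence[str] = ("rec14",),
    majority: float = 0.5,
    annotation: Mapping[str, str | None] | None = None,
    restrict_to: Iterable[str] | None = None,
) -> ConsensusSet:
    """Blocked CV over the training stages; consensus construction + accuracy.

    Accuracy is pooled over all test-set predictions across folds, per
    classifier. ``restrict_to`` evaluates a fixed probe panel (no per-fold
    feature selection), e.g. to estimate the consensus set's own accuracy.
    """
    labels = crd_labels(design, nd_stages, crd_stages)
    sub = design[design["sample_id"].isin(labels.index)]
    X = matrix[sub["sample_id"]].T
    if restrict_to is not None:
        panel = [p for p in matrix.index if p in set(restrict_to)]
        if not panel:
            raise DataError("restrict_to panel shares no probes with the matrix")
        X = X[panel]
    y = labels.loc[X.index].to_numpy()
    folds = blocked_folds(sub)

    fold_sets: dict[str, list[set[str]]] = {s.method: [] for s in specs}
    n_correct = {s.method: 0 for s in specs}
    n_total = 0
    for fi, fold in enumerate(folds):
        train_ids, test_ids = list(fold.train_ids), list(fold.test_ids)
        y_train = labels.loc[train_ids].to_numpy()
        y_test = labels.loc[test_ids].to_numpy()
        n_total += len(test_ids)
        for spec in specs:
            model, selected = fit_and_select(
                X.loc[train_ids], y_train, spec, seed=spec.seed + fi
            )
            if restrict_to is None:
                fold_sets[spec.method].append(set(selected))
            pred = model.predict(X.loc[test_ids].to_numpy(float))
            n_correct[spec.method] += int((pred == y_test).sum())

    accuracies = {m: n_correct[m] / n_total for m in n_correct}
    if restrict_to is None:
        majority_sets = {
            m: per_classifier_consensus(fold_sets[m], majority) for m in fold_sets
        }
        if len(specs) >= 2:
            consensus_probes, consensus_genes = cross_classifier_consensus(
                majority_sets, annotation
            )
        else:
            only = next(iter(majority_sets.values()))
            consensus_probes = set(only)
            consensus_genes = (
                annotate_and_deduplicate(consensus_probes, annotation)
                if annotation is not None
                else None
            )
    else:
        majority_sets = {}
        consensus_probes, consensus_genes = set(), None
    return ConsensusSet(
        fold_sets=fold_sets,
        majority_sets=majority_sets,
        consensus_probes=consensus_probes,
        consensus_genes=consensus_genes,
        accuracies=accuracies,
        majority_threshold=majority,
        n_test_predictions=n_total,
    )


def predict_external_stages(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    consensus_probes: Iterable[str],
    specs: Sequence[ClassifierSpec],
    *,
    train_nd_stages: Sequence[str] = ("baseline",),
    train_crd_stages: Sequence[str] = ("rec14",),
    predict_stages: Sequence[str] = ("shift1", "shift6", "rec5"),
) -> pd.DataFrame:
    """Train on the consensus panel and report the CRD-classified fraction
    of each non-training (stage, protocol) group, per classifier."""
    panel = [p for p in matrix.index if p in set(consensus_probes)]
    if not panel:
        raise DataError(
            "consensus probe set is empty; relax top_k or the majority threshold"
        )
    labels = crd_labels(design, train_nd_stages, train_crd_stages)
    X_train = matrix.loc[panel, labels.index].T
    y_train = labels.to_numpy()

    rows = []
    targets = design[design["stage"].isin(predict_stages)]
    for spec in specs:
        model, _ = fit_and_select(X_train, y_train, spec)
        for (stage, protocol), group in targets.groupby(["stage", "protocol"], sort=False):
            X_new = matrix.loc[panel, group["sample_id"]].T.to_numpy(float)
            pred = model.predict(X_new)
            rows.append(
                {
                    "stage": stage,
                    "protocol": protocol,
                    "method": spec.method,
                    "n": len(group),
                    "frac_crd": float((pred == LABEL_CRD).mean()),
                }
            )
    return pd.DataFrame(rows)
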