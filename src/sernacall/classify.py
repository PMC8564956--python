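"""Cell-type classification power and correlation-heatmap clustering.

Two questions are answered here.  First, do expression profiles cluster
samples by cell type?  (Pearson correlation between samples, then
single-linkage agglomeration on the Euclidean distances between rows of
the correlation matrix — the structure behind the usual clustered
heatmap.)  Second, how much cell-type classification power does a feature
set carry?  (Linear-kernel SVM, stratified 5-fold cross-validation, with
feature subsets of a given size resampled ``n_bootstrap`` times; two
feature sets — seRNA vs eRNA — are compared per subset size with a
two-sided Mann-Whitney U test on the accuracy distributions.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import mannwhitneyu
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .matrix import ExpressionMatrix

__all__ = [
    "ClusteringResult",
    "ClassificationComparison",
    "cluster_samples",
    "classification_power",
    "compare_feature_sets",
    "compare_classification",
]

# "without regularization" for a soft-margin SVM: a large fixed penalty for
# margin violations, i.e. effectively hard-margin
DEFAULT_SVM_C = 1e3
DEFAULT_N_BOOTSTRAP = 100
DEFAULT_N_FOLDS = 5


@dataclass
class ClusteringResult:
    """Sample-correlation matrix with its single-linkage merge tree."""

    correlation: pd.DataFrame  # sample x sample Pearson
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 format
    leaf_order: np.ndarray  # permutation of sample indices

    @property
    def sample_ids(self) -> list[str]:
        return list(self.correlation.index)


def cluster_samples(expr: ExpressionMatrix) -> ClusteringResult:
    """Pearson-correlate samples, then single-linkage cluster the matrix rows.

    The distance between two samples is the Euclidean distance between
    their rows of the correlation matrix (so two samples are close when
    they correlate similarly with *everything*, the convention behind
    correlation heatmaps).  Constant sample columns have no defined
    correlation and are rejected.
    """
    values = expr.values
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    stds = values.std(axis=0)
    if (stds == 0).any():
        bad = expr.sample_ids[int(np.flatnonzero(stds == 0)[0])]
        raise ValueError(f"sample {bad!r} is constant; Pearson correlation undefined")
    corr = np.corrcoef(values.T)
    corr_df = pd.DataFrame(corr, index=expr.sample_ids, columns=expr.sample_ids)
    Z = linkage(corr, method="single", metric="euclidean")
    return ClusteringResult(
        correlation=corr_df, linkage_matrix=Z, leaf_order=np.asarray(leaves_list(Z))
    )


def classification_power(
    expr: ExpressionMatrix,
    labels: Sequence[str] | None = None,
    feature_sizes: Sequence[int] = (100,),
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    C: float = DEFAULT_SVM_C,
) -> dict[int, np.ndarray]:
    """Bootstrap cross-validated accuracies of a linear SVM per feature size.

    For each replicate, ``feature_size`` feature rows are drawn uniformly
    without replacement and a linear-kernel SVC is scored by stratified
    ``n_folds``-fold cross-validation; the replicate's accuracy is the mean
    fold accuracy.  The fold assignment is fixed across replicates (drawn
    once from ``seed``), so at ``feature_size == n_features`` all
    replicates coincide.  Labels default to the attached cell types.
    """
    y = np.asarray(labels if labels is not None else expr.cell_types())
    values = expr.values
    m, n = values.shape
    if len(y) != n:
        raise ValueError("one label per sample required")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 cell types")
    if counts.min() < n_folds:
        small = classes[int(np.argmin(counts))]
        raise ValueError(
            f"cell type {small!r} has {counts.min()} samples < {n_folds} folds; "
            "stratified cross-validation impossible"
        )
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31 - 1))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    X_full = values.T  # samples x features
    out: dict[int, np.ndarray] = {}
    for size in feature_sizes:
        if not (1 <= size <= m):
            raise ValueError(f"feature size {size} out of range 1..{m}")
        accs = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.choice(m, size=size, replace=False)
            clf = SVC(kernel="linear", C=C)
            scores = cross_val_score(clf, X_full[:, idx], y, cv=cv)
            accs[b] = scores.mean()
        out[int(size)] = accs
    return out


class UTestResult(NamedTuple):
    u_statistic: float
    p_value: float
    direction: int  # sign of median(a) - median(b)


def compare_feature_sets(acc_a: Sequence[float], acc_b: Sequence[float]) -> UTestResult:
    """Two-sided Mann-Whitney U test between two accuracy distributions."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both accuracy lists must be non-empty")
    direction = int(np.sign(np.median(a) - np.median(b)))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # zero-variance degenerate case: no evidence of any difference
        return UTestResult(len(a) * len(b) / 2.0, 1.0, 0)
    u, p = mannwhitneyu(a, b, alternative="two-sided")
    return UTestResult(float(u), float(min(p, 1.0)), direction)


@dataclass
class ClassificationComparison:
    """seRNA-vs-eRNA classification-power comparison across feature sizes."""

    feature_sizes: list[int]
    accuracies_serna: dict[int, np.ndarray]
    accuracies_erna: dict[int, np.ndarray]
    tests: dict[int, UTestResult] = field(default_factory=dict)

    def median_gap(self, size: int) -> float:
        return float(
            np.median(self.accuracies_serna[size]) - np.median(self.accuracies_erna[size])
        )

    def to_dict(self) -> dict:
        return {
            "feature_sizes": self.feature_sizes,
            "median_accuracy_serna": {
                s: float(np.median(self.accuracies_serna[s])) for s in self.feature_sizes
            },
            "median_accuracy_erna": {
                s: float(np.median(self.accuracies_erna[s])) for s in self.feature_sizes
            },
            "u_statistic": {s: self.tests[s].u_statistic for s in self.feature_sizes},
            "p_value": {s: self.tests[s].p_value for s in self.feature_sizes},
            "direction": {s: self.tests[s].direction for s in self.feature_sizes},
        }


def compare_classification(
    serna_expr: ExpressionMatrix,
    erna_expr: ExpressionMatrix,
    labels: Sequence[str] | None = None,
    feature_sizes: Sequence[int] = (10, 50, 200),
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    C: float = DEFAULT_SVM_C,
) -> ClassificationComparison:
    """Run the full seRNA-vs-eRNA power comparison.

    Both feature sets are driven by the same seed (paired randomness) but
    compared with an unpaired two-sided U test per feature size.
    """
    sizes = [int(s) for s in feature_sizes]
    acc_s = classification_power(
        serna_expr, labels, sizes, n_bootstrap, n_folds, seed=seed, C=C
    )
    acc_e = classification_power(
        erna_expr, labels, sizes, n_bootstrap, n_folds, seed=seed, C=C
    )
    tests = {s: compare_feature_sets(acc_s[s], acc_e[s]) for s in sizes}
    return ClassificationComparison(sizes, acc_s, acc_e, tests)
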