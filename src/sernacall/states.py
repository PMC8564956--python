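"""Cell-state inference from seRNA profiles by multi-restart NMF.

The (non-negative) seRNA-by-sample matrix X is factorized as X ~ W.H with
W (seRNA x state) and H (state x sample), Frobenius loss and no
regularization.  Because NMF is non-convex, the factorization is run from
many random initializations; each restart is scored by the silhouette of
the samples under their argmax-state labels and the best-scoring restart
is kept.  Silhouette is computed on the samples' input expression
profiles (Euclidean): scoring in the k-dimensional H embedding instead
would collapse all between-group structure orthogonal to the k bases and
make small-k models look spuriously tight.

The number of states k is chosen by scanning a small range.  Candidate
models whose W contains a *redundant* basis — one expressible as a
non-negative combination of the other bases — are rejected first: such a
basis captures a mixture of existing expression programs (e.g. a
transitional time point), not a new state.  Among the remaining
candidates the best silhouette wins, ties going to the smaller k.

Downstream helpers normalize H columns into per-sample state fractions,
order states by activity-weighted mean time, and pull state-enriched
seRNA signatures out of W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score

from .matrix import ExpressionMatrix

__all__ = [
    "StateDecomposition",
    "StateSignature",
    "KScanResult",
    "nmf_fit",
    "scan_k",
    "state_composition",
    "order_states_by_time",
    "state_signatures",
]

DEFAULT_N_RESTARTS = 200
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6
# a basis whose relative NNLS residual against the other bases falls below
# this is considered a combination of existing states, not a new one
DEFAULT_REDUNDANCY_THRESHOLD = 0.75


@dataclass
class StateDecomposition:
    """Best-of-restarts NMF factorization with per-sample state labels."""

    W: np.ndarray  # feature x state
    H: np.ndarray  # state x sample
    k: int
    reconstruction_error: float  # Frobenius norm of X - W.H
    silhouette: float
    state_of_sample: np.ndarray  # argmax over H columns, ties -> lowest state
    n_restarts: int
    seed: int
    basis_redundancy: float = 1.0  # min relative NNLS residual across bases
    feature_ids: list[str] | None = field(default=None)
    sample_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("NMF factors must be non-negative")


@dataclass(frozen=True)
class StateSignature:
    """seRNAs enriched in one state, sorted by descending enrichment."""

    state: int
    serna_ids: tuple[str, ...]
    enrichment_scores: tuple[float, ...]


def _as_array(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(X, ExpressionMatrix):
        return X.values, X.feature_ids, X.sample_ids
    arr = np.asarray(X, dtype=float)
    return arr, None, None


def _basis_redundancy(W: np.ndarray) -> float:
    """Min over bases of the relative NNLS residual against the other bases.

    Near 0 when some basis is (almost) a non-negative combination of the
    rest; near 1 when every basis carries its own expression program.
    """
    k = W.shape[1]
    if k < 2:
        return 1.0
    worst = 1.0
    for s in range(k):
        norm = np.linalg.norm(W[:, s])
        if norm == 0:
            return 0.0
        others = np.delete(W, s, axis=1)
        _, residual = nnls(others, W[:, s])
        worst = min(worst, residual / norm)
    return float(worst)


def nmf_fit(
    X,
    k: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    solver: str = "mu",
) -> StateDecomposition:
    """Fit NMF from ``n_restarts`` random initializations, keep the best.

    Initial factors are drawn uniform(0, 1) scaled by sqrt(mean(X)/k) so
    the initial product matches X in overall magnitude.  Each restart is
    scored by the silhouette of the samples (input profiles, Euclidean)
    under argmax-state labels; restarts producing fewer than two distinct
    labels score -1.  Ties break by lower reconstruction error, then by
    restart order, so results are bitwise reproducible for a fixed seed.
    """
    arr, feature_ids, sample_ids = _as_array(X)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if (arr < 0).any():
        raise ValueError("X must be non-negative; run the preprocessing pipeline first")
    m, n = arr.shape
    if not (1 <= k < min(m, n)):
        raise ValueError(f"k={k} must satisfy 1 <= k < min(m, n) = {min(m, n)}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(arr.mean() / k) or 1.0
    samples = arr.T
    best_key: tuple[float, float] | None = None  # (-silhouette, error)
    best_WH: tuple[np.ndarray, np.ndarray] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(n_restarts):
            W0 = rng.uniform(size=(m, k)) * scale
            H0 = rng.uniform(size=(k, n)) * scale
            model = NMF(
                n_components=k,
                init="custom",
                solver=solver,
                beta_loss="frobenius",
                max_iter=max_iter,
                tol=tol,
                alpha_W=0.0,
                alpha_H=0.0,
            )
            W = model.fit_transform(arr, W=W0, H=H0)
            H = model.components_
            labels = np.argmax(H, axis=0)
            n_labels = len(np.unique(labels))
            if 2 <= n_labels <= n - 1:
                sil = float(silhouette_score(samples, labels, metric="euclidean"))
            else:
                sil = -1.0
            err = float(np.linalg.norm(arr - W @ H))
            key = (-sil, err)
            if best_key is None or key < best_key:
                best_key = key
                best_WH = (W, H)
    assert best_key is not None and best_WH is not None
    W, H = best_WH
    return StateDecomposition(
        W=W,
        H=H,
        k=k,
        reconstruction_error=best_key[1],
        silhouette=-best_key[0],
        state_of_sample=np.argmax(H, axis=0),
        n_restarts=n_restarts,
        seed=seed,
        basis_redundancy=_basis_redundancy(W),
        feature_ids=feature_ids,
        sample_ids=sample_ids,
    )


@dataclass
class KScanResult:
    """Model-selection table over candidate state counts."""

    table: pd.DataFrame  # columns: k, silhouette, reconstruction_error, basis_redundancy, qualified
    chosen_k: int
    decompositions: dict[int, StateDecomposition]

    @property
    def best(self) -> StateDecomposition:
        return self.decompositions[self.chosen_k]


def scan_k(
    X,
    k_values: Sequence[int] = (2, 3, 4),
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    solver: str = "mu",
    redundancy_threshold: float = DEFAULT_REDUNDANCY_THRESHOLD,
) -> KScanResult:
    """Fit every candidate k and choose the best non-redundant model.

    Candidates whose best model contains a redundant basis (relative NNLS
    residual below ``redundancy_threshold``) are disqualified — the extra
    state adds no new expression program.  Among the remaining candidates
    the best silhouette wins; ties go to the smaller k.  If every
    candidate is disqualified the plain silhouette argmax is used.  The
    full table is returned so the choice can be overridden by eye.
    """
    k_values = sorted(set(int(k) for k in k_values))
    if not k_values:
        raise ValueError("k_values must be non-empty")
    decomps: dict[int, StateDecomposition] = {}
    rows = []
    for k in k_values:
        dec = nmf_fit(
            X, k, n_restarts=n_restarts, seed=seed, max_iter=max_iter, tol=tol, solver=solver
        )
        decomps[k] = dec
        rows.append(
            {
                "k": k,
                "silhouette": dec.silhouette,
                "reconstruction_error": dec.reconstruction_error,
                "basis_redundancy": dec.basis_redundancy,
                "qualified": dec.basis_redundancy >= redundancy_threshold,
            }
        )
    table = pd.DataFrame(rows)
    pool = table[table["qualified"]] if table["qualified"].any() else table
    # stable idxmax -> first max -> smaller k on ties
    chosen = int(pool.loc[pool["silhouette"].idxmax(), "k"])
    return KScanResult(table=table, chosen_k=chosen, decompositions=decomps)


def state_composition(H: np.ndarray, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Normalize H columns into per-sample state fractions summing to 1."""
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    sums = H.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if len(zero):
        j = zero[0]
        name = sample_ids[j] if sample_ids is not None else f"column {j}"
        raise ValueError(f"sample {name} has all-zero state loading")
    return H / sums


def order_states_by_time(H: np.ndarray, times: Sequence[float]) -> np.ndarray:
    """Order states by activity-weighted mean time point.

    Returns the permutation ``order`` such that ``order[0]`` is the
    original index of the earliest-active state (the "initial state"),
    and so on.  States with an all-zero activity row cannot be placed and
    go last, with a warning.
    """
    H = np.asarray(H, dtype=float)
    t = np.asarray(times, dtype=float)
    if H.shape[1] != len(t):
        raise ValueError("one time point per sample required")
    sums = H.sum(axis=1)
    mean_time = np.full(H.shape[0], np.inf)
    active = sums > 0
    mean_time[active] = (H[active] @ t) / sums[active]
    if not active.all():
        warnings.warn(
            f"states {list(np.flatnonzero(~active))} have zero activity; placed last",
            stacklevel=2,
        )
    return np.argsort(mean_time, kind="stable")


def state_signatures(
    W: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    threshold: float = 0.5,
    eps: float = 1e-12,
) -> list[StateSignature]:
    """Extract state-enriched features from W by relative loading.

    The enrichment of feature i in state s is ``W[i, s] / (sum_s' W[i, s']
    + eps)``; a feature joins the signature of every state where its score
    exceeds ``threshold`` (default 0.5: majority loading, hence at most
    one state per feature).  All-zero rows are unassigned.
    """
    W = np.asarray(W, dtype=float)
    m, k = W.shape
    if feature_ids is None:
        feature_ids = [str(i) for i in range(m)]
    scores = W / (W.sum(axis=1, keepdims=True) + eps)
    sigs = []
    for s in range(k):
        idx = np.flatnonzero(scores[:, s] > threshold)
        order = idx[np.argsort(-scores[idx, s], kind="stable")]
        sigs.append(
            StateSignature(
                state=s,
                serna_ids=tuple(feature_ids[i] for i in order),
                enrichment_scores=tuple(float(scores[i, s]) for i in order),
            )
        )
    return sigs
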