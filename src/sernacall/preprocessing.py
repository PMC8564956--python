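"""Matrix preprocessing ahead of clustering, classification and NMF.

The canonical pipeline is: log-transform (replacing the -infinity produced
by zero counts with the smallest finite log value of the matrix), drop
cell types with too few samples, then shift the global minimum to zero so
the matrix is non-negative again for factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "PreprocessSpec",
    "log_transform",
    "filter_small_cell_types",
    "shift_nonnegative",
    "nmf_input_pipeline",
]

DEFAULT_MIN_SAMPLES_PER_TYPE = 20


@dataclass(frozen=True)
class PreprocessSpec:
    """Bundle of the preprocessing knobs, mirroring the config file keys."""

    log_base: float = 10.0
    min_samples_per_type: int = DEFAULT_MIN_SAMPLES_PER_TYPE
    shift_to_zero: bool = True

    def __post_init__(self) -> None:
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        if self.min_samples_per_type < 1:
            raise ValueError("min_samples_per_type must be >= 1")


def log_transform(expr: ExpressionMatrix, base: float = 10.0) -> ExpressionMatrix:
    """Elementwise log with -infinity (from zeros) replaced by the matrix minimum.

    "Minimum" means the minimum over *finite* log-scale entries — the only
    self-consistent reading, since the literal minimum would itself be
    -infinity.  An all-zero matrix therefore has no finite minimum and is
    rejected.  Output values may be negative.
    """
    values = expr.values
    if (values < 0).any():
        raise ValueError("log transform requires a non-negative matrix")
    with np.errstate(divide="ignore"):
        logged = np.log(values) / np.log(base)
    finite = np.isfinite(logged)
    if not finite.any():
        raise ValueError("all-zero matrix: log transform has no finite minimum")
    logged[~finite] = logged[finite].min()
    return ExpressionMatrix(
        pd.DataFrame(logged, index=expr.data.index, columns=expr.data.columns),
        expr.sample_meta,
        require_nonnegative=False,
        normalization=f"log{base:g}({expr.normalization})",
    )


def filter_small_cell_types(
    expr: ExpressionMatrix,
    min_samples: int = DEFAULT_MIN_SAMPLES_PER_TYPE,
) -> ExpressionMatrix:
    """Drop samples whose cell type has fewer than ``min_samples`` samples.

    A type with exactly ``min_samples`` samples is retained.  Requires
    cell-type metadata covering every sample; the feature set is unchanged
    and retained values are untouched.
    """
    types = expr.cell_types()
    if types.isna().any():
        bad = types.index[types.isna()][0]
        raise ValueError(f"sample {bad!r} has no cell type label")
    counts = types.value_counts()
    keep_types = counts.index[counts >= min_samples]
    keep = types.index[types.isin(keep_types)]
    if len(keep) == 0:
        raise ValueError(
            f"no cell type has >= {min_samples} samples; all samples dropped"
        )
    return expr.subset_samples(list(keep))


def shift_nonnegative(matrix):
    """Subtract the global minimum so the smallest entry is exactly 0.

    Accepts an :class:`ExpressionMatrix` or any array-like; pairwise
    differences are preserved exactly.  A constant matrix maps to zeros.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values
        if not np.isfinite(values).all():
            raise ValueError("matrix must be finite")
        shifted = values - values.min()
        return ExpressionMatrix(
            pd.DataFrame(shifted, index=matrix.data.index, columns=matrix.data.columns),
            matrix.sample_meta,
            normalization=f"shifted({matrix.normalization})",
        )
    values = np.asarray(matrix, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix must be finite")
    return values - values.min()


def nmf_input_pipeline(
    expr: ExpressionMatrix, spec: PreprocessSpec = PreprocessSpec()
) -> ExpressionMatrix:
    """Canonical factorization input: log -> small-type filter -> min shift.

    The small-type filter only applies when cell-type metadata is attached
    (single-experiment time courses carry one nominal type and skip it by
    construction).
    """
    out = log_transform(expr, base=spec.log_base)
    if expr.sample_meta is not None and "cell_type" in expr.sample_meta.columns:
        out = filter_small_cell_types(out, spec.min_samples_per_type)
    if spec.shift_to_zero:
        out = shift_nonnegative(out)
    return out
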