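"""Expression matrix container: features (loci or genes) by samples.

Thin wrapper around a pandas DataFrame that pins down the orientation
(rows = features, columns = samples), enforces non-negativity for raw
normalized expression (TPM-like) input, and optionally carries per-sample
metadata (cell type label, time point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values with optional sample metadata.

    Parameters
    ----------
    data
        DataFrame indexed by feature id, columns = sample ids.
    sample_meta
        Optional DataFrame indexed by sample id with a ``cell_type`` column
        and an optional numeric ``time`` column.  When present it must cover
        every sample.
    require_nonnegative
        Raw normalized expression must be >= 0; log-transformed matrices
        are constructed with this off.
    """

    data: pd.DataFrame
    sample_meta: Optional[pd.DataFrame] = None
    require_nonnegative: bool = True
    normalization: str = field(default="unknown")

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise ValueError("no features: expression matrix is empty")
        if self.data.shape[1] == 0:
            raise ValueError("no samples: expression matrix has no columns")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if not self.data.columns.is_unique:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.require_nonnegative and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression value at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )
        if self.sample_meta is not None:
            missing = self.data.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample metadata missing for {list(missing)}")
            # align metadata rows with column order
            self.sample_meta = self.sample_meta.loc[self.data.columns]

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def cell_types(self) -> pd.Series:
        if self.sample_meta is None or "cell_type" not in self.sample_meta:
            raise ValueError("no cell_type metadata attached")
        return self.sample_meta["cell_type"]

    def times(self) -> pd.Series:
        if self.sample_meta is None or "time" not in self.sample_meta:
            raise ValueError("no time metadata attached")
        t = self.sample_meta["time"]
        if t.isna().any():
            bad = t.index[t.isna()][0]
            raise ValueError(f"sample {bad!r} has no time point")
        return t

    def with_meta(self, sample_meta: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data,
            sample_meta,
            require_nonnegative=self.require_nonnegative,
            normalization=self.normalization,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        meta = None if self.sample_meta is None else self.sample_meta.loc[list(sample_ids)]
        return ExpressionMatrix(
            self.data.loc[:, list(sample_ids)],
            meta,
            require_nonnegative=self.require_nonnegative,
            normalization=self.normalization,
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data.loc[list(feature_ids)],
            self.sample_meta,
            require_nonnegative=self.require_nonnegative,
            normalization=self.normalization,
        )
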