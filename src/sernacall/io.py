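"""Readers and writers for the plain-text formats the pipeline touches.

* BED3/BED4 (tab-separated, no header) for enhancer, gene and catalog loci.
* TSV with a header row for locus-keyed expression matrices; the first
  column ("id") holds ``chrom:start-end`` keys or gene symbols.
* Sample metadata TSV with columns ``sample_id``, ``cell_type`` and an
  optional ``time``.

Everything is 0-based half-open on read and write.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import EnhancerLocus, GeneLocus, GenomicInterval, parse_locus_id
from .matrix import ExpressionMatrix

__all__ = [
    "read_expression_matrix",
    "read_gene_expression_matrix",
    "read_bed",
    "read_gene_bed",
    "write_bed",
    "read_sample_metadata",
    "write_expression_matrix",
]

PathLike = Union[str, Path]


def read_expression_matrix(
    path: PathLike,
    sample_meta: pd.DataFrame | None = None,
    parse_keys: bool = True,
    normalization: str = "tpm",
) -> ExpressionMatrix:
    """Read a locus-keyed TSV expression table (FANTOM5-style).

    The first column holds feature keys; every other column is one sample.
    With ``parse_keys`` each key must parse as ``chrom:start-end`` (a parse
    error names the offending row).  Values must be numeric and >= 0.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no features")
    df.index = df.index.astype(str)
    if parse_keys:
        for row_key in df.index:
            try:
                parse_locus_id(row_key)
            except ValueError as exc:
                raise ValueError(f"{path}: row {row_key!r}: {exc}") from exc
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(df, sample_meta, normalization=normalization)


def read_gene_expression_matrix(
    path: PathLike, sample_meta: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Read a gene-symbol-keyed expression TSV (keys are not parsed as loci)."""
    return read_expression_matrix(path, sample_meta, parse_keys=False, normalization="rle")


def enhancers_from_matrix(expr: ExpressionMatrix) -> list[EnhancerLocus]:
    """Materialize :class:`EnhancerLocus` records from matrix row keys."""
    return [EnhancerLocus.from_id(key) for key in expr.feature_ids]


def read_bed(path: PathLike) -> list[GeneLocus]:
    """Read a BED3/BED4 file into named loci.

    The optional 4th column is the name; it defaults to ``chrom:start-end``.
    Returns :class:`GeneLocus` records (an interval plus a name) — callers
    treating the file as plain intervals can use ``locus.interval``.
    """
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty or inverted interval {chrom}:{start}-{end}"
                )
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] else interval.id
            loci.append(GeneLocus(name, interval))
    return loci


# gene annotation files are the same BED4 shape; the alias keeps call sites readable
read_gene_bed = read_bed


def write_bed(
    loci: Iterable[GeneLocus],
    path: PathLike,
    scores: Sequence[float] | None = None,
) -> None:
    """Write named intervals as BED4 (BED5 when ``scores`` is given).

    Round-trips through :func:`read_bed` on chrom/start/end/name.
    """
    loci = list(loci)
    if scores is not None and len(scores) != len(loci):
        raise ValueError("scores length does not match loci")
    with open(path, "w") as fh:
        for i, locus in enumerate(loci):
            iv = locus.interval
            fields = [iv.chrom, str(iv.start), str(iv.end), locus.symbol]
            if scores is not None:
                fields.append(f"{scores[i]:.6g}")
            fh.write("\t".join(fields) + "\n")


def read_sample_metadata(path: PathLike) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, cell_type, optional time)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_type": str})
    for col in ("sample_id", "cell_type"):
        if col not in meta.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    meta = meta.set_index("sample_id")
    if "time" in meta.columns:
        meta["time"] = pd.to_numeric(meta["time"], errors="coerce")
    return meta


def write_expression_matrix(expr: ExpressionMatrix, path: PathLike) -> None:
    df = expr.data.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def write_sample_metadata(meta: pd.DataFrame, path: PathLike) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
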