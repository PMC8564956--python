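"""Proximal-gene assignment, catalog overlap comparison, marker extraction.

Gene assignment rules:

* Enhancer-level: every gene whose locus intersects the closed +/-5 kb
  window around the enhancer midpoint is a proximal gene; if the window
  is empty, the single nearest gene (interval-gap distance) is assigned.
* seRNA-level: each stitched locus gets exactly one gene — the one
  minimizing the distance to either span end-point (zero when the gene
  overlaps the span).

Catalog comparison follows the reciprocal-fraction rule: for each
intersecting pair the overlap length is divided by each locus length;
a locus counts as overlapped when any pair gives *its own* fraction
strictly greater than the cutoff (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .caller import StitchedLocus
from .intervals import EnhancerLocus, GeneLocus, GenomicInterval, interval_gap
from .matrix import ExpressionMatrix
from .preprocessing import log_transform

__all__ = [
    "ProximalAssignment",
    "OverlapReport",
    "map_enhancers_to_genes",
    "map_sernas_to_genes",
    "compare_to_catalog",
    "extract_marker_series",
    "export_state_gene_lists",
]


@dataclass(frozen=True)
class ProximalAssignment:
    """Genes assigned to one enhancer or stitched locus."""

    feature_id: str
    gene_symbols: tuple[str, ...]
    rule_used: str  # "window" or "nearest"

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError("assignment must carry at least one gene")
        if self.rule_used not in ("window", "nearest"):
            raise ValueError(f"unknown rule {self.rule_used!r}")
        if self.rule_used == "nearest" and len(self.gene_symbols) != 1:
            raise ValueError("nearest rule assigns exactly one gene")


def _gene_sort_key(g: GeneLocus) -> tuple[int, str]:
    return (g.interval.start, g.symbol)


def _genes_by_chrom(genes: Sequence[GeneLocus]) -> dict[str, list[GeneLocus]]:
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    return by_chrom


def map_enhancers_to_genes(
    enhancers: Sequence[EnhancerLocus],
    genes: Sequence[GeneLocus],
    window_bp: int = 5_000,
) -> list[ProximalAssignment]:
    """Window-then-nearest proximal gene assignment for individual enhancers.

    All genes intersecting the closed ``[midpoint - window_bp,
    midpoint + window_bp]`` window are assigned; when the window is empty
    the nearest gene (interval gap to the enhancer, 0 if overlapping) is
    assigned instead.  Ties break by smaller gene start, then symbol.
    Enhancers on chromosomes without any annotated gene are skipped with a
    warning — no cross-chromosome distance is defined.
    """
    if not genes:
        raise ValueError("gene list is empty")
    by_chrom = _genes_by_chrom(genes)
    trees = {
        chrom: IntervalTree.from_tuples(
            (g.interval.start, g.interval.end, g) for g in gs
        )
        for chrom, gs in by_chrom.items()
    }
    out: list[ProximalAssignment] = []
    for enh in enhancers:
        chrom = enh.interval.chrom
        if chrom not in by_chrom:
            warnings.warn(
                f"enhancer {enh.id} skipped: no gene annotated on {chrom}", stacklevel=2
            )
            continue
        mid = enh.midpoint
        # closed window [mid - w, mid + w] == half-open [mid - w, mid + w + 1)
        hits = [iv.data for iv in trees[chrom].overlap(max(0, mid - window_bp), mid + window_bp + 1)]
        if hits:
            symbols = tuple(g.symbol for g in sorted(hits, key=_gene_sort_key))
            out.append(ProximalAssignment(enh.id, symbols, "window"))
        else:
            best = min(
                by_chrom[chrom],
                key=lambda g: (interval_gap(enh.interval, g.interval),) + _gene_sort_key(g),
            )
            out.append(ProximalAssignment(enh.id, (best.symbol,), "nearest"))
    return out


def _endpoint_distance(span: GenomicInterval, gene: GenomicInterval) -> int:
    """Distance from the nearer span end-point to the gene; 0 on overlap."""
    if span.overlaps(gene):
        return 0

    def point_gap(p: int) -> int:
        if p < gene.start:
            return gene.start - p
        if p >= gene.end:
            return p - (gene.end - 1)
        return 0

    return min(point_gap(span.start), point_gap(span.end))


def map_sernas_to_genes(
    stitched: Sequence[StitchedLocus], genes: Sequence[GeneLocus]
) -> list[ProximalAssignment]:
    """Assign each stitched locus its nearest gene by span end-point distance.

    The distance of a gene is the smaller of its distances to the two span
    end-points (zero when it overlaps the span); exactly one gene is
    assigned per locus, ties broken by smaller gene start then symbol.
    """
    if not genes:
        raise ValueError("gene list is empty")
    by_chrom = _genes_by_chrom(genes)
    out: list[ProximalAssignment] = []
    for locus in stitched:
        span = locus.span
        candidates = by_chrom.get(span.chrom)
        if not candidates:
            warnings.warn(
                f"stitched locus {locus.id} skipped: no gene on {span.chrom}",
                stacklevel=2,
            )
            continue
        best = min(
            candidates,
            key=lambda g: (_endpoint_distance(span, g.interval),) + _gene_sort_key(g),
        )
        out.append(ProximalAssignment(locus.id, (best.symbol,), "nearest"))
    return out


@dataclass
class OverlapReport:
    """Two-sided reciprocal-overlap comparison of locus sets."""

    n_query: int
    n_reference: int
    n_query_overlapped: int
    n_reference_overlapped: int
    pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    min_fraction: float = 0.5

    @property
    def fraction_query(self) -> float:
        return self.n_query_overlapped / self.n_query

    @property
    def fraction_reference(self) -> float:
        return self.n_reference_overlapped / self.n_reference

    def to_dict(self) -> dict:
        return {
            "n_query": self.n_query,
            "n_reference": self.n_reference,
            "n_query_overlapped": self.n_query_overlapped,
            "n_reference_overlapped": self.n_reference_overlapped,
            "fraction_query": self.fraction_query,
            "fraction_reference": self.fraction_reference,
            "min_fraction": self.min_fraction,
            "pairs": [list(p) for p in self.pairs],
        }


def _dedupe(loci: Iterable[GeneLocus]) -> list[GeneLocus]:
    seen: dict[tuple[str, int, int], GeneLocus] = {}
    for locus in loci:
        key = (locus.interval.chrom, locus.interval.start, locus.interval.end)
        seen.setdefault(key, locus)
    return list(seen.values())


def compare_to_catalog(
    query: Sequence[GeneLocus],
    reference: Sequence[GeneLocus],
    min_fraction: float = 0.5,
) -> OverlapReport:
    """Compare called loci against an external super-enhancer catalog.

    Duplicate loci (exact chrom/start/end identity) are removed on both
    sides first.  For every intersecting pair the overlap length is divided
    by each locus length; a side's locus is *overlapped* when some pair
    gives its own fraction strictly above ``min_fraction``.  Reported pairs
    are those where at least one side clears the cutoff (all intersecting
    pairs when ``min_fraction`` is 0).
    """
    if not query or not reference:
        raise ValueError("both locus sets must be non-empty")
    q = _dedupe(query)
    r = _dedupe(reference)
    ref_trees: dict[str, IntervalTree] = {}
    for j, locus in enumerate(r):
        iv = locus.interval
        ref_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)

    q_hit = np.zeros(len(q), dtype=bool)
    r_hit = np.zeros(len(r), dtype=bool)
    pairs: list[tuple[str, str, float, float]] = []
    for i, qlocus in enumerate(q):
        qiv = qlocus.interval
        tree = ref_trees.get(qiv.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(qiv.start, qiv.end), key=lambda h: h.data):
            rlocus = r[hit.data]
            riv = rlocus.interval
            ov = qiv.overlap_length(riv)
            fq = ov / qiv.length
            fr = ov / riv.length
            if fq > min_fraction:
                q_hit[i] = True
            if fr > min_fraction:
                r_hit[hit.data] = True
            if fq > min_fraction or fr > min_fraction:
                pairs.append((qlocus.symbol, rlocus.symbol, fq, fr))
    return OverlapReport(
        n_query=len(q),
        n_reference=len(r),
        n_query_overlapped=int(q_hit.sum()),
        n_reference_overlapped=int(r_hit.sum()),
        pairs=pairs,
        min_fraction=min_fraction,
    )


@dataclass
class MarkerSeries:
    """Long-format marker-gene time series plus the markers not found."""

    table: pd.DataFrame  # columns: gene, sample, time, log_expression
    missing: list[str]


def extract_marker_series(
    expr: ExpressionMatrix, markers: Sequence[str], log_base: float = 10.0
) -> MarkerSeries:
    """Log-scale time series of marker-gene expression, one row per sample.

    Markers absent from the matrix are reported in ``missing`` rather than
    failing, unless none is present.  Replicates at a time point stay as
    separate rows; collapsing is a plotting choice.
    """
    times = expr.times()
    present = [m for m in markers if m in expr.data.index]
    missing = [m for m in markers if m not in expr.data.index]
    if not present:
        raise ValueError(f"none of the requested markers found: {list(markers)}")
    sub = log_transform(expr.subset_features(present), base=log_base)
    ordered_samples = times.sort_values(kind="stable").index
    rows = []
    for gene in present:
        for sample in ordered_samples:
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "time": float(times[sample]),
                    "log_expression": float(sub.data.at[gene, sample]),
                }
            )
    return MarkerSeries(pd.DataFrame(rows), missing)


def export_state_gene_lists(
    state_sernas: Mapping[int, Sequence[str]],
    assignments: Sequence[ProximalAssignment],
    out_dir: str | Path | None = None,
) -> dict[int, list[str]]:
    """De-duplicated sorted gene-symbol list per cell state.

    ``state_sernas`` maps a state index to the seRNA ids enriched in it;
    genes come from the given proximal assignments.  When ``out_dir`` is
    set, one ``state_<i>.txt`` file is written per state (empty states
    yield an empty file and a warning).
    """
    gene_map: dict[str, tuple[str, ...]] = {a.feature_id: a.gene_symbols for a in assignments}
    lists: dict[int, list[str]] = {}
    for state, serna_ids in state_sernas.items():
        symbols: set[str] = set()
        for sid in serna_ids:
            symbols.update(gene_map.get(sid, ()))
        lists[state] = sorted(symbols)
        if not symbols:
            warnings.warn(f"state {state} has no assigned genes", stacklevel=2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for state, symbols in lists.items():
            (out_dir / f"state_{state}.txt").write_text(
                "".join(s + "\n" for s in symbols)
            )
    return lists
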