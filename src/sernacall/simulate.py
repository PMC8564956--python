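"""Synthetic datasets with planted ground truth for every pipeline stage.

The generator lays out a toy genome with two kinds of enhancers:

* *background* enhancers whose midpoints are all more than 12.5 kb apart
  (so stitching leaves them as singletons), expressing at a baseline of
  1 TPM in every sample;
* *planted clusters* of enhancers with consecutive midpoints within
  12.5 kb (so each cluster stitches into one candidate super-enhancer),
  up-regulated ``signal_ratio``-fold in the cell type mapped to the
  cluster.

Genes are placed away from cluster interiors so the gene-interruption
rule never splits a planted cluster.  Expression noise is multiplicative
log-normal with a configurable coefficient of variation — TPM-like values
are non-negative and right-skewed.  A time-course mode instead plants
disjoint per-state signature feature sets and mixes state profiles
according to a (time point x state) mixing matrix, emulating progressive
differentiation with transitional mixtures.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import EnhancerLocus, GeneLocus, GenomicInterval
from .matrix import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "TimeCourseConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_time_course",
    "fragmentation_mode",
    "default_fragmentation_config",
]

STITCH_GAP = 12_500  # must match the caller's default stitch distance
_MIN_ITEM_GAP = 13_500  # midpoint gap between placed items; > STITCH_GAP + jitter


@dataclass(frozen=True)
class TimeCourseConfig:
    """Progressive latent-state design for the differentiation mode.

    ``mixing`` has one row per time point; row t gives the fraction of each
    latent state in samples at that time and must sum to 1.  The default
    mirrors a 4-point differentiation course whose 3rd time point is an
    even mixture of the 2nd and 3rd states (a transition state).
    """

    time_points: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    mixing: tuple[tuple[float, ...], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.5, 0.5),
        (0.0, 0.0, 1.0),
    )
    n_replicates: int = 5
    n_features: int = 300
    signature_size: int = 60  # planted signature features per state

    @property
    def n_states(self) -> int:
        return len(self.mixing[0])

    def validate(self) -> None:
        if len(self.time_points) != len(self.mixing):
            raise ValueError("one mixing row per time point required")
        for row in self.mixing:
            if len(row) != self.n_states:
                raise ValueError("ragged mixing matrix")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"mixing row {row} does not sum to 1")
            if any(v < 0 for v in row):
                raise ValueError("mixing fractions must be non-negative")
        if self.n_states * self.signature_size > self.n_features:
            raise ValueError(
                "signature sets overlap: n_states * signature_size exceeds n_features"
            )
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per time point")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the toy genome and expression generator.

    Defaults describe a desk-scale dataset: 3 planted 5-enhancer clusters
    against 100 background singletons on 2 chromosomes, three cell types
    of 10 samples each, planted signal 10x baseline, log-normal noise with
    CV 0.1.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 3_000_000
    n_background_enhancers: int = 100
    n_planted_clusters: int = 3
    cluster_size: int = 5
    cluster_span_bp: int = 40_000
    n_genes: int = 20
    cell_types: tuple[tuple[str, int], ...] = (("cellA", 10), ("cellB", 10), ("cellC", 10))
    signal_ratio: float = 10.0
    noise_cv: float = 0.1
    baseline_tpm: float = 1.0
    enhancer_width: int = 300
    gene_width: int = 2_000
    split_cluster_signal: bool = False  # divide cluster-level signal across members
    time_course: TimeCourseConfig | None = None

    def validate(self) -> None:
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "n_background_enhancers",
            "cluster_size",
            "n_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_clusters < 0:
            raise ValueError("n_planted_clusters must be >= 0")
        if self.cluster_size < 2:
            raise ValueError("a planted cluster needs >= 2 enhancers")
        if self.cluster_span_bp > (self.cluster_size - 1) * STITCH_GAP:
            raise ValueError(
                "cluster_span_bp too large: consecutive midpoints would exceed the stitch gap"
            )
        if self.signal_ratio <= 1:
            raise ValueError("signal_ratio must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        if self.time_course is not None:
            self.time_course.validate()


@dataclass
class GroundTruth:
    """What the generator planted, for oracle-style verification."""

    planted_cluster_spans: list[GenomicInterval] = field(default_factory=list)
    cluster_members: list[list[str]] = field(default_factory=list)
    cluster_celltype_map: list[str] = field(default_factory=list)
    state_mixing: np.ndarray | None = None  # time point x state
    marker_features: dict[int, list[str]] = field(default_factory=dict)
    sample_state_fractions: pd.DataFrame | None = None


@dataclass
class SimulatedDataset:
    enhancers: list[EnhancerLocus]
    genes: list[GeneLocus]
    expression: ExpressionMatrix
    truth: GroundTruth
    config: SimulationConfig

    @property
    def sample_meta(self) -> pd.DataFrame:
        return self.expression.sample_meta


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def _place_items(
    rng: np.random.Generator, chrom_length: int, widths: list[int]
) -> list[int]:
    """Place item start coordinates left-to-right with > STITCH_GAP spacing.

    Gaps between consecutive items (and the chromosome ends) are at least
    ``_MIN_ITEM_GAP``, with the leftover length spread randomly, so no two
    items can ever stitch together.
    """
    n = len(widths)
    need = sum(widths) + (n + 1) * _MIN_ITEM_GAP
    if need > chrom_length:
        raise ValueError(
            f"infeasible geometry: {n} items need {need} bp > chromosome length {chrom_length}"
        )
    slack = chrom_length - need
    extra = rng.dirichlet(np.ones(n + 1)) * slack if n + 1 > 1 else np.array([slack])
    starts = []
    pos = 0
    for i, w in enumerate(widths):
        pos += _MIN_ITEM_GAP + int(extra[i])
        starts.append(pos)
        pos += w
    return starts


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a toy genome, loci and an eRNA expression matrix.

    Planted clusters are up-regulated (``signal_ratio`` x baseline) in
    their mapped cell type; with ``split_cluster_signal`` the cluster-level
    elevation is divided evenly across members, so each member rises only
    ``1 + (signal_ratio - 1)/cluster_size``-fold while the member *sum*
    keeps the full ratio — the regime where aggregation pays off.
    """
    config.validate()
    if config.time_course is not None:
        return simulate_time_course(config)
    rng = np.random.default_rng(config.seed)

    # assign clusters and background enhancers to chromosomes round-robin
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    items_per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chrom_names}
    for c in range(config.n_planted_clusters):
        items_per_chrom[chrom_names[c % len(chrom_names)]].append(("cluster", c))
    for b in range(config.n_background_enhancers):
        items_per_chrom[chrom_names[b % len(chrom_names)]].append(("background", b))

    half_w = config.enhancer_width // 2
    enhancers: list[EnhancerLocus] = []
    cluster_members: dict[int, list[str]] = {c: [] for c in range(config.n_planted_clusters)}
    cluster_spans: dict[int, GenomicInterval] = {}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    for chrom in chrom_names:
        items = items_per_chrom[chrom]
        if not items:
            continue
        rng.shuffle(items)
        widths = [
            config.cluster_span_bp + config.enhancer_width
            if kind == "cluster"
            else config.enhancer_width
            for kind, _ in items
        ]
        starts = _place_items(rng, config.chrom_length_bp, widths)
        for (kind, idx), start, width in zip(items, starts, widths):
            if kind == "background":
                iv = GenomicInterval(chrom, start, start + config.enhancer_width)
                enhancers.append(EnhancerLocus(iv))
            else:
                gap = config.cluster_span_bp // (config.cluster_size - 1)
                first_mid = start + half_w
                members = []
                for j in range(config.cluster_size):
                    mid = first_mid + j * gap
                    iv = GenomicInterval(chrom, mid - half_w, mid - half_w + config.enhancer_width)
                    members.append(EnhancerLocus(iv))
                enhancers.extend(members)
                cluster_members[idx] = [m.id for m in members]
                cluster_spans[idx] = GenomicInterval(
                    chrom,
                    min(m.interval.start for m in members),
                    max(m.interval.end for m in members),
                )
                occupied[chrom].append((start - 500, start + width + 500))

    # genes: uniform, rejected out of cluster interiors (margin keeps the
    # interruption rule away from planted gaps)
    genes: list[GeneLocus] = []
    for gi in range(config.n_genes):
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(0, config.chrom_length_bp - config.gene_width))
            end = start + config.gene_width
            if all(end <= lo or start >= hi for lo, hi in occupied[chrom]):
                genes.append(GeneLocus(f"GENE{gi:03d}", GenomicInterval(chrom, start, end)))
                break
        else:
            raise ValueError("infeasible geometry: could not place genes outside clusters")

    # expression means, then multiplicative noise
    samples = []
    sample_types = []
    for label, n_samples in config.cell_types:
        for r in range(n_samples):
            samples.append(f"{label}_{r:02d}")
            sample_types.append(label)
    type_labels = [label for label, _ in config.cell_types]
    cluster_celltype = [
        type_labels[c % len(type_labels)] for c in range(config.n_planted_clusters)
    ]
    member_ratio = (
        1.0 + (config.signal_ratio - 1.0) / config.cluster_size
        if config.split_cluster_signal
        else config.signal_ratio
    )
    feature_ids = [e.id for e in enhancers]
    means = np.full((len(feature_ids), len(samples)), config.baseline_tpm)
    row_of = {fid: i for i, fid in enumerate(feature_ids)}
    for c, members in cluster_members.items():
        active = [j for j, t in enumerate(sample_types) if t == cluster_celltype[c]]
        for fid in members:
            means[row_of[fid], active] = config.baseline_tpm * member_ratio
    values = means * _lognormal_noise(rng, config.noise_cv, means.shape)

    meta = pd.DataFrame({"cell_type": sample_types}, index=pd.Index(samples, name="sample_id"))
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=samples), meta, normalization="tpm"
    )
    truth = GroundTruth(
        planted_cluster_spans=[cluster_spans[c] for c in sorted(cluster_spans)],
        cluster_members=[cluster_members[c] for c in sorted(cluster_members)],
        cluster_celltype_map=cluster_celltype,
    )
    return SimulatedDataset(enhancers, genes, expr, truth, config)


def simulate_time_course(config: SimulationConfig) -> SimulatedDataset:
    """Generate a progressive-differentiation seRNA-profile dataset.

    Feature f of state s's signature has mean ``signal_ratio x baseline``
    in a pure state-s sample; a sample at time t mixes state profiles by
    the mixing row for t, then gets multiplicative log-normal noise.
    Signature sets are disjoint by construction; leftover features are
    constitutive baseline.
    """
    config.validate()
    tc = config.time_course
    if tc is None:
        raise ValueError("config.time_course is required")
    rng = np.random.default_rng(config.seed)

    # locus-style feature ids on the toy genome, widely spaced
    per_chrom = int(np.ceil(tc.n_features / config.n_chromosomes))
    spacing = max(50_000, config.chrom_length_bp // (per_chrom + 1))
    feature_ids = []
    for i in range(tc.n_features):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        start = (i // config.n_chromosomes + 1) * spacing
        feature_ids.append(f"{chrom}:{start}-{start + config.enhancer_width}")

    perm = rng.permutation(tc.n_features)
    signatures = {
        s: sorted(perm[s * tc.signature_size : (s + 1) * tc.signature_size])
        for s in range(tc.n_states)
    }
    profiles = np.full((tc.n_features, tc.n_states), config.baseline_tpm)
    for s, idx in signatures.items():
        profiles[idx, s] = config.baseline_tpm * config.signal_ratio

    mixing = np.asarray(tc.mixing, dtype=float)
    samples, times = [], []
    means_cols = []
    for ti, t in enumerate(tc.time_points):
        for r in range(tc.n_replicates):
            samples.append(f"t{ti}_r{r}")
            times.append(float(t))
            means_cols.append(profiles @ mixing[ti])
    means = np.column_stack(means_cols)
    values = means * _lognormal_noise(rng, config.noise_cv, means.shape)

    meta = pd.DataFrame(
        {"cell_type": "timecourse", "time": times},
        index=pd.Index(samples, name="sample_id"),
    )
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=samples), meta, normalization="tpm"
    )
    truth = GroundTruth(
        state_mixing=mixing,
        marker_features={s: [feature_ids[i] for i in idx] for s, idx in signatures.items()},
        sample_state_fractions=pd.DataFrame(
            np.repeat(mixing, tc.n_replicates, axis=0),
            index=samples,
            columns=[f"state_{s}" for s in range(tc.n_states)],
        ),
    )
    return SimulatedDataset([], [], expr, truth, config)


def fragmentation_mode(dataset: SimulatedDataset) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Paired (eRNA-level, seRNA-level) matrices from one simulated dataset.

    The eRNA matrix is the per-enhancer matrix as simulated (cluster signal
    on each member with its own independent noise); the seRNA matrix sums
    each planted cluster's member rows and keeps background enhancers as
    singleton rows, keyed by the cluster span / enhancer id.  Row sums of
    the eRNA matrix over cluster members reproduce the seRNA matrix
    exactly, by construction.
    """
    if not dataset.truth.cluster_members:
        raise ValueError("dataset has no planted clusters")
    erna = dataset.expression
    member_of: dict[str, int] = {}
    for c, members in enumerate(dataset.truth.cluster_members):
        for fid in members:
            member_of[fid] = c
    rows = []
    index = []
    for fid in erna.feature_ids:
        if fid in member_of:
            c = member_of[fid]
            span_id = dataset.truth.planted_cluster_spans[c].id
            if span_id not in index:
                member_ids = dataset.truth.cluster_members[c]
                rows.append(erna.data.loc[member_ids].sum(axis=0))
                index.append(span_id)
        else:
            rows.append(erna.data.loc[fid])
            index.append(fid)
    serna_df = pd.DataFrame(rows)
    serna_df.index = pd.Index(index)
    serna = ExpressionMatrix(serna_df, erna.sample_meta, normalization=erna.normalization)
    return erna, serna


def default_fragmentation_config(seed: int = 0) -> SimulationConfig:
    """Study conditions for the seRNA-vs-eRNA classification comparison.

    Many weak-membered clusters (split signal, high noise) against a
    small background: individually the member eRNAs are noisy
    classifiers, while their per-cluster sums average the noise away —
    the regime in which aggregation into seRNAs pays off, as it should
    for genuinely cell-type-specific super-enhancers.
    """
    return replace(
        SimulationConfig(),
        seed=seed,
        n_chromosomes=8,
        chrom_length_bp=12_000_000,
        n_planted_clusters=160,
        cluster_size=5,
        n_background_enhancers=50,
        n_genes=40,
        signal_ratio=10.0,
        noise_cv=1.2,
        split_cluster_signal=True,
    )
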