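# Methods

This note records the model, the parameter choices, the numerical
conventions, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and inputs

All intervals are 0-based half-open (BED convention); FANTOM5-style
`chrom:start-end` matrix row keys are parsed under the same convention.
The midpoint of an interval is `floor((start + end) / 2)`, so it is
integer-valued and always inside the interval.  Strand is ignored
throughout: enhancer transcription is bidirectional and no step of the
pipeline is strand-aware.  Expression matrices must be non-negative
normalized values (TPM-like); the normalization is carried as an opaque
tag, and duplicate feature keys are rejected rather than aggregated,
because silent aggregation would change summed seRNA signals.

## Stitching

Two enhancers consecutive in midpoint order join one stitched locus when
their midpoint distance is ≤ `stitch_distance` (default 12 500 bp,
inclusive; identical midpoints count as distance 0) and no gene locus
intersects the *open* genomic interval between the two midpoints.  A gene
that merely overlaps one of the enhancers does not by itself interrupt
stitching — the interruption rule is about genes *between* the combining
enhancers.  Chaining is transitive, as in ROSE-style stitching: if A–B
and B–C are joinable, {A, B, C} form one locus even when A–C exceeds the
stitch distance.  Consequences worth knowing: the number of stitched loci
is monotone non-increasing in `stitch_distance`, and summed seRNA signal
is conserved (the total over stitched loci equals the total over input
enhancer rows).

## Reflection-point calling

Candidate loci are ranked ascending by total signal — by default the sum
over *all* samples, giving one genome-wide call set; a per-sample calling
mode exists behind a flag but per-sample curves are noisier and the
default is recommended.  Rank and signal axes are min–max rescaled to the
unit square and the threshold is placed at the **tangent point of a
slope-1 line**: the rank minimizing `scaled_signal − scaled_rank`.  For a
convex ranked curve this is exactly the rank at which the discrete slope
rises above 1, i.e. the conventional ROSE elbow.  Ties (e.g. an exactly
linear curve, where the difference is identically zero, detected with an
absolute tolerance of 1e-9 on the unit square) resolve to the *highest*
rank, the most conservative choice; with the strict `signal > threshold`
rule a linear ramp therefore calls nothing, and a curve like (0, 0, 0,
10) calls exactly the outlier.  Degenerate inputs (fewer than 3 loci, or
all values equal) are rejected rather than guessed at.  Because both axes
are rescaled, calls are invariant to uniform positive scaling of the
expression matrix.

## Gene annotation and catalog overlap

Enhancer-level assignment uses a closed ±5 kb window around the enhancer
midpoint (10 001 bp): every gene intersecting the window is assigned;
when the window is empty, the single nearest gene by interval gap (0 when
overlapping) is assigned instead.  seRNA-level assignment gives each
stitched locus exactly one gene — the one minimizing the distance to
either span end-point, 0 for genes overlapping the span.  Ties resolve by
smaller gene start, then symbol, so assignments are deterministic and
independent of gene-list order.  Enhancers on chromosomes with no
annotated gene are skipped with a warning; no cross-chromosome distance
is defined.

Catalog comparison de-duplicates both sides by exact coordinates, then
for every intersecting pair divides the overlap length by each locus
length separately.  A locus counts as overlapped when any pair puts *its
own* fraction strictly above the cutoff (default 0.5); exactly 50 %
overlap does not qualify.  The relation is deliberately asymmetric — a
short query inside a long reference can be fully overlapped while the
reference is not — which is why both per-side counts and fractions are
reported.

## Preprocessing

The factorization/classification input pipeline is: log₁₀ transform with
−∞ (from zero counts) replaced by the smallest *finite* log value of the
matrix (the only self-consistent reading of "replace with the matrix
minimum" — the literal minimum would itself be −∞); removal of cell types
with fewer than 20 samples (a type with exactly 20 is kept); and a global
shift of the minimum to zero so the matrix is non-negative again for NMF.
The log base is configurable and nothing downstream depends on it.  Two
accepted artifacts of this recipe: zero-expression entries end up tied
with the smallest positive entry, and each matrix is preprocessed
independently (eRNA and seRNA matrices that enter the same comparison do
not share a replacement minimum).

## NMF state decomposition

X (features × samples, non-negative) is factorized X ≈ W·H with
scikit-learn's NMF: Frobenius loss, no regularization, multiplicative
updates, at most 500 iterations at relative tolerance 1e-6.  Because the
problem is non-convex the fit is repeated from `n_restarts` (default 200)
random initializations — entries uniform(0, 1) scaled by
`sqrt(mean(X)/k)` so the initial product matches X in magnitude — and the
restart with the best silhouette is kept, ties broken by lower
reconstruction error and then restart order (bitwise reproducible for a
fixed seed).  The multiplicative-update solver was chosen over coordinate
descent after observing that on exactly-low-rank data with noise, CD
restarts scatter across a degenerate manifold of basis-tilted optima with
indistinguishable error, whereas MU consistently lands on the symmetric
solution; for mixture samples this matters, because basis tilt directly
distorts the inferred state fractions.

**Silhouette space.** Restart and rank scores use the silhouette of the
*samples' input profiles* (Euclidean) under argmax-state labels, not of
the H columns.  The k-dimensional H embedding collapses every direction
orthogonal to the current bases, so an under-fitted k = 2 model scores
near-perfect cohesion no matter how much real structure it ignores;
scoring in data space keeps the comparison honest across k.

**Choosing k.** `scan_k` fits each candidate k and first discards
candidates whose best model contains a *redundant basis*: a W column
whose non-negative least-squares residual against the other columns,
relative to its norm, falls below 0.75.  Such a basis is a combination of
existing expression programs — typically a dedicated component for a
transitional (mixed-state) group of samples — and signals that k is past
the number of genuine states.  Empirically the statistic separates
cleanly: ≥ 0.98 at the true k, ≤ 0.69 for over-fitted k, on both 2- and
3-state designs.  Among the surviving candidates the best silhouette
wins, ties to the smaller k; if every candidate is disqualified the plain
silhouette argmax is used.  The full scan table (silhouette, error,
redundancy) is returned so the choice can always be overridden manually.

Downstream: H columns are normalized to per-sample state fractions (the
basis for "sample X is a mixture of states" statements); states are
ordered by activity-weighted mean time `Σ_j H[s,j]·t_j / Σ_j H[s,j]` and
relabeled initial/secondary/final accordingly; per-state seRNA signatures
are the features whose relative W loading for the state exceeds 0.5
(majority loading — at most one state per feature; the cutoff is a flag).
Signatures are extracted from W because features live in W; H describes
samples.

## Clustering and classification

The heatmap structure is Pearson correlation between samples on the
log-expression profile, followed by single-linkage agglomeration using
Euclidean distances *between rows of the correlation matrix* — two
samples are close when they correlate similarly with everything.
Constant samples are rejected (correlation undefined).

Classification power: linear-kernel SVC with a large fixed margin penalty
(C = 1000; an exactly unregularized soft-margin SVM does not exist, so
"without regularization" is implemented as effectively hard-margin),
stratified 5-fold cross-validation with a fold assignment drawn once per
run, accuracy = mean fold accuracy.  Per feature-subset size, 100
bootstrap replicates each draw that many feature rows uniformly without
replacement; with the subset size equal to the full feature count all
replicates coincide, a useful self-check.  The seRNA and eRNA feature
sets run from the same seed (paired randomness) but are compared with an
unpaired two-sided Mann–Whitney U test per size; when both accuracy
distributions are a single identical value the test degenerates and
p = 1 is reported with direction 0.

## Synthetic data generator

`simulate_dataset` lays out a toy genome in which ground truth is
unambiguous by construction: background enhancers are placed with all
inter-item midpoint gaps above 13.5 kb (so they can never stitch), and
each planted cluster places `cluster_size` enhancers with consecutive
midpoint gaps ≤ 12.5 kb inside a span that is kept gene-free, so each
cluster stitches into exactly one locus.  Expression is baseline 1 TPM
with multiplicative log-normal noise of configurable CV (unit mean; CAGE
TPM values are non-negative and right-skewed); each cluster is elevated
`signal_ratio`-fold (default 10) in its mapped cell type.  Defaults: 3
clusters of 5 enhancers vs 100 background singletons on 2 chromosomes,
three cell types × 10 samples, noise CV 0.1.

`simulate_time_course` emulates progressive differentiation: each latent
state owns a disjoint signature block of features (default 60 of 300)
elevated `signal_ratio`-fold in that state's profile, and a sample at
time t mixes the state profiles by its row of the mixing matrix before
noise.  The default design is 4 time points (0, 6, 12, 18) × 5
replicates with mixing rows (1,0,0), (0,1,0), (0,0.5,0.5), (0,0,1) — the
third time point is an even transitional mixture of the second and third
states.  The state-recovery benchmark feeds this matrix to NMF in linear
scale: the mixtures are exactly linear by construction and the matrix is
already non-negative and moderate-range, so no log transform is needed
there; for real CAGE data, which spans orders of magnitude, the log
pipeline above is the documented route.

`fragmentation_mode` derives a paired eRNA/seRNA matrix set from one
dataset: the eRNA matrix is the per-enhancer matrix (each member with its
own independent noise), the seRNA matrix sums each cluster's members and
keeps background enhancers as singletons, so summing eRNA rows over
members reproduces the seRNA matrix exactly.  The classification
benchmark conditions (`default_fragmentation_config`) use 160 clusters of
5 vs 50 background, `split_cluster_signal` (each member carries
`1 + (ratio−1)/size` of the elevation so the member *sum* keeps the full
ratio), and noise CV 1.2: individual members are then weak, noisy
classifiers while their sums average the noise away — the regime in which
aggregation into seRNAs genuinely pays off, and which mirrors real
super-enhancers whose constituent enhancers are individually modest.
Both matrices exceed 200 features so subset sizes up to 200 are testable.

What these simulations do *not* capture: correlated noise between nearby
loci, batch and library-size effects, the heavy tails and zero-inflation
of real CAGE counts, overlapping or nested gene annotations, and any
chromatin-level ground truth.  Passing the benchmarks shows the
implementation is correct and the statistical machinery behaves as
designed under its stated assumptions — not that real datasets will
separate as cleanly.

## Benchmark problem sizes

The test and acceptance protocols use desk-scale sizes chosen to make
ground truth exact and oracles cheap: stitching is verified against a
brute-force transitive-closure oracle on 100 random instances of up to
200 enhancers; overlap counting against an all-pairs oracle on 100 random
instance pairs; single-linkage merges against an O(n³) agglomeration
oracle on 10-sample instances; the NMF and classification protocols run
10 independent seeds each (20 NMF restarts per fit, 100 bootstrap
replicates per feature size).

## Known limitations

* The reflection point presumes a convex "hockey-stick" ranked curve; on
  multi-elbow curves the slope-1 tangent picks one elbow deterministically
  but the biological meaning of the cut is weaker.
* Gene interruption uses gene bodies only; promoter-proximal exclusion
  zones (ROSE's TSS option) are not implemented.
* NMF rank selection counts non-redundant expression programs; two states
  that differ only in magnitude (not direction) of the same program will
  be merged.
* The SVM comparison subsamples features, not samples; sample-subsampled
  learning curves are a different (also reasonable) protocol.
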