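# Methods

This note records the statistical model behind `twocalm`, the defaults
and the reasoning for every place where the design was genuinely open.

## Input model and preprocessing

A sample is a cloud of n ≥ 1 localisation events in nm (double
precision).  Unit conversion is explicit (`units_scale`); nothing is
inferred from magnitudes.  The sample volume V — used in the global
density N/V and in Ripley's K — is the volume of the axis-aligned
bounding box of the analysed cloud or ROI.  This is the simplest
reproducible convention consistent with defining a sample's "dimension"
as the minimal enclosing box; when ROIs are analysed, each ROI's own box
is used.

Outlier filtering and ROI segmentation use DBSCAN with radius ρ (nm) and
core threshold minP, where the neighbourhood count *includes the query
point* (minP = 3 ⇒ a point plus two neighbours).  Border points join the
first core cluster encountered in deterministic index-ordered expansion,
which resolves the classical DBSCAN border ambiguity reproducibly; the
implementation provably assigns a contested border point to the cluster
whose seed core has the lowest index.  ρ has no universal default — it
is a physical length and must be set per dataset.  Filtering is
idempotent: removing noise never demotes a core or border point, so a
second pass removes nothing.  Drift correction is a hook that applies an
externally estimated per-frame offset track; estimating drift is out of
scope.

## Resampling

Two clouds are compared either directly after equalization (uniform
subsampling of the larger one to min(N₁,N₂); sensible up to ~50,000
points) or, by default, through M pairs of bootstrap resamples of N
points drawn i.i.d. with replacement, N < min(N₁,N₂), the same N for
both members of a pair.  Defaults M = 100, N = 8000.  A single root seed
spawns one `SeedSequence` child per resample, so any pair is
reproducible in isolation.  With M = 1 no confidence intervals (hence no
sim_L and no second-level tests) are produced.

## Cluster features

One complete-linkage dendrogram is built per resample (points sorted
lexicographically first, so linkage ties cannot depend on row order) and
cut at every dimension d of the grid dim(i) = size_min + i·Δ.  Cutting
at height d guarantees a cluster diameter ≤ d.  Defaults: size_min
10 nm, Δ 10 nm, size_max auto = 45% of the smaller sample's minimal box
edge, capped at 1000 nm (sub-resolution scales below ~5 nm and
super-micron scales carry no cluster signal at desk scale).

Per-cluster volume estimators: **bullet** (default; Σ per-point spheres
of radius half the within-cluster nearest-neighbour distance — follows
cluster shape, no convexity assumption), **hull** (convex hull volume),
**box** (product of per-axis extents, zero extents clamped to size_min
to avoid infinite densities).  Relative density is (n_k/V_k)/(N/V),
dimensionless and scale-invariant.  Curvature is τ = λ₁/(λ₁+λ₂+λ₃) of
the unnormalised scatter matrix (τ is scale-free, so normalisation is
irrelevant); eigenvectors are not retained — nothing downstream uses
them.

Minimum cluster sizes: density needs n_k ≥ 2 (a nearest neighbour must
exist); curvature needs n_k ≥ 4, because any ≤ 3 points are coplanar and
would contribute τ ≡ 0, biasing the distribution toward flatness.
Excluded clusters are counted and reported; averages av_density(d) and
av_curv(d) are means over the clusters whose feature is defined.

The vectorised bullet computation finds within-cluster nearest
neighbours with a single 4D KD-tree query (fourth coordinate =
cluster label × 10·cloud-span), which separates clusters by more than
any spatial distance; it is tested against the per-cluster definition.

## Ripley K and H

K(d) = (V/N²)·Σ_k Σ_{l≠k} e_k(d)·1[dist ≤ d].  The edge correction is
the standard translation correction for an axis-aligned box: each
ordered pair is weighted by V / Π_a(L_a − |t_a|) with t the pair's
separation vector.  It is analytic, deterministic, and unbiased under
CSR — verified by the calibration benchmark (mean K/(4πd³/3) within
[0.95, 1.05] over 200 CSR replicates of 2000 points, d ∈ [50, 200] nm).
An uncorrected variant (e ≡ 1) exists for exact oracle tests.

H(d) = (3K/4π)^{1/3} − d; in 2D mode K is area-normalised and
H = (K/π)^{1/2} − d.  H > 0 indicates clustering at scale d, H < 0
dispersion; the maximiser d* (ties → smallest d) is the radius of
maximal aggregation and seeds the primary-cluster DBSCAN radius.  Note
a sampling asymmetry worth knowing: the *uncorrected* H is biased
negative (boundary pair losses), so CSR clouds almost never show H > 0
(≥ 90% "no aggregation"); the translation-corrected H fluctuates
symmetrically about 0, so under CSR it exceeds 0 somewhere on the grid
in most realisations, with excursions that stay small (|H| ≲ 10 nm at
n = 2000 in a (1 µm)³ box) compared to genuine clustering signals
(~100 nm for Thomas clouds).

## Two-level statistics

First level, per (d, resample-pair): two-sided asymptotic KS p-value
(p = Q_KS(√(n₁n₂/(n₁+n₂))·D); the asymptotic form is reasonable once
n₁n₂/(n₁+n₂) ≥ 4 and measured slightly conservative at n = 50) and
Wilcoxon rank-sum p-value (exact null distribution when n₁+n₂ ≤ 20 and
tie-free, otherwise normal approximation with tie correction and no
continuity correction so identical samples give exactly p = 1).  A
Peacock-style 2D KS test over paired (density, curvature) samples is
available; its p-value uses the standard 2D asymptotic shrinkage and is
flagged approximate.

Aggregation: per dimension, the row means of the KS and Wilcoxon
matrices are fused with the weighted t-norm AND (w default 0.55, in the
0.5–0.6 band; idempotent, so p AND p = p), and the density and curvature
curves are fused once more with w = 0.5.  The alternative order —
t-norm per cell, then row means — is used only to build the per-cell
aggregated matrix from which confidence bands are taken, since a band
needs the per-resample distribution.  Both orders agree in the
idempotent/degenerate cases; the row-means-first order was chosen for
the headline curve and is fixed, not data-dependent.

Second level: the directional mean-cross test compares mean(A₁[d,·])
against the bootstrap distribution A₂[d,·] (and vice versa) with the
two-sided empirical rank p-value p = min(1, 2·min(a+1, b+1)/(M+1)).
The +1 convention avoids exact-zero p-values; its floor 2/(M+1) means
M ≥ 40 is needed for the floor to clear α = 0.05 — with small M the
mean-cross p-values cannot reach significance by construction.  The
cross test (k random columns pooled, KS against the other matrix's row,
averaged over draws) is exposed with k = 5, 10 draws.

Confidence bands per dimension row: normal (mean ± z_{1−α/2}·std,
clipped to [0,1]) and BPCI (α and 1−α empirical percentiles with
outward rounding, so endpoints are observed values).  BPCI is the
default band: p-value distributions near 0 or 1 are heavily skewed and
the normal band is explicitly an approximation.

## Similarity measures and verdict

sim_M maps the curve mean m to m/2α below α and 1 − α/(2m) above —
continuous, 0.5 exactly at m = α.  sim_L = 1 − intersec/cr with
cr = α·(size_max − size_min); the integrand max(0, α − max(0, lb(d))) is
integrated trapezoidally over the grid with the first band value
extended back to size_min, so the integration interval equals cr and the
constant-band anchors (lb ≡ α → 1, lb ≡ 0 → 0, lb ≡ α/2 → 0.5) hold
exactly.  sim_L uses the BPCI lower band of the per-cell aggregated
matrix by default.  Verdicts: ≤ 0.45 dissimilar, ≥ 0.55 similar,
between marginal; the same thresholds are applied to sim_M and sim_L.
The overall verdict is governed by the combined first-level curve's
sim_M; Ripley-based similarities are auxiliary.

## MLP classifier

Fixed 11-20-2 architecture: inputs (d, p1…p10) — per-cell KS/WX p-values
for density and curvature, plus the six per-dimension mean-cross
p-values (average density ×2 directions, average curvature ×2, Ripley
K ×2) broadcast across resamples; tanh hidden layer; softmax outputs
read as posterior probabilities of (similar, dissimilar) = one-hot
(1,0)/(0,1).  Only d is standardised (z-score stored with the model);
p-values already live in [0,1].  Training: full-batch Adam (lr 0.01) on
the cross-entropy, early stopping on a 20% held-out split with patience
100, fully seeded.  Gradients are analytic and verified against central
finite differences to 1e-6 relative.  The pair-level decision is the
mean posterior over all L×M vectors (median available); posteriors in
(0.4, 0.6) should trigger re-sampling with more points rather than a
verdict.  Models serialise to versioned JSON including architecture and
standardisation, and reload bit-exactly.  Training data are always
user- or synthetically generated pair reports.

## Synthetic data

The generators emulate the structural regimes of membrane-protein
dSTORM data: CSR (the null), Thomas cluster processes (uniform parents,
Poisson(μ) offspring with Gaussian σ; parent labels retained in
metadata), fibrous and orientation-aligned ("polarized") fibre patterns
— polarized is interpreted as fibres sharing a dominant direction with a
concentration parameter, an interpretation since no canonical definition
exists — vesicle shells (radii drawn from a few-hundred-nm range with
radial thickness jitter), and mixtures, plus uniform outlier
contamination and isotropic localisation noise.  All generators return
exactly n points, re-draw out-of-box points (preserving n), and are
deterministic per seed.

They do *not* model fluorophore photophysics: no blinking-induced
repeated localisations of one molecule, no intensity-dependent
localisation precision, no astigmatic z-anisotropy, no sample drift.
Passing tests therefore demonstrate the statistical machinery on clouds
with known ground-truth structure; on real data, repeat-localisation
artefacts inflate small-scale clustering in *both* samples and the
comparison remains meaningful mainly because it is relative.

## Benchmark problem sizes

The validation suite fixes these study conditions once: null and power
benchmarks use source clouds of 6000 points in a (1.5 µm)³ box,
M = 50 resamples of N = 2000 points, dimension grid 80–480 nm in 40 nm
steps, 20 seeded runs each; the power alternative is a Thomas process
with σ = 30 nm and 60 parents at equal density.  The MLP benchmark uses
20 + 20 pairs at N = 600, M = 6 on a coarse 120–440 nm grid — small
enough that feature noise is visible, which is the point of the
classifier.  Oracle-equivalence checks run 100 random instances per
algorithm (n ≤ 300 for DBSCAN and Ripley; n ≤ 12 for the O(n³)
complete-linkage reference, n ≤ 50 for the O(n³) 2D-KS scan).
`scripts/acceptance.py` re-runs scaled versions (10 runs, 12 + 12 pairs)
of the same conditions.

## Known limitations

* The t-norm-aggregated p-curve is not a calibrated p-value: bootstrap
  resamples share points, so first-level cells are dependent and the
  null rejection rate per dimension is only bounded (≤ ~2α), not equal
  to α.  The similarity verdicts inherit this — they are effect-size
  style scores, not significance statements.
* The empirical p-value floor 2/(M+1) makes second-level tests
  uninformative for M < 2/α − 1.
* Hull volumes need ≥ 4 points in general position; in very sparse or
  flat clusters most volume estimates fall back to exclusion, and the
  density distribution then under-represents small clusters.
* The 2D multivariate KS p-value is an asymptotic approximation; use
  its statistic, or permutation wrappers, when exactness matters.
* Box-mode density with clamping introduces a floor that depends on
  size_min; bullet mode is the default for a reason.
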