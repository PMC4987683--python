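# Methods

## The impulse model and event detection

The Bry-GFP reporter signal of a differentiating EB is summarized by the
filtered count of segmented GFP points per frame (frames every 1–2 h). The
count curve is modeled as the product of two logistics,

N(t) = A · L(β₁(t − t₁)) · L(−β₂(t − t₂)),  L(x) = 1/(1 + e⁻ˣ),

with amplitude A (points), rise and decline rates β₁, β₂ (h⁻¹) and
half-peak times t₁ < t₂ (h). This form is bounded by 0 ≤ N ≤ A, vanishes at
±∞, and makes t₁/t₂ approximately the half-peak times whenever the rise
and decline are well separated (t₂ − t₁ ≫ 1/β). Of the pulse-shaped
families with exactly these five parameters it is the simplest whose two
flanks decouple cleanly, which is what the event definitions below rely
on.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective). Initialization: A₀ = max count, t₁₀/t₂₀ = first
and last raw half-max crossings, β₀ = 4/(time from first frame to raw
peak), clipped to β ∈ (10⁻³, 10) h⁻¹. These starts are deterministic
functions of the data, so fits are reproducible; a fit that ends worse
than its initialization or fails to converge raises rather than returning
silently. Series whose maximum count never reaches the onset threshold are
flagged "no signal" and excluded from timing statistics.

Events are read from the fitted curve, not the raw counts — the model's
role is to smooth counting/processing noise. The peak is the numerical
argmax on [t₁ − 5/β₁, t₂ + 5/β₂]; onset is the unique rising-flank
crossing of the threshold (default 300 points), solved by Brent's method
between a far-left bracket and the peak, absent when the peak value is
below threshold. The default threshold of 300 points is the lowest that
robustly separates onset from baseline noise; on the default synthetic
cohort the mean onset moves by < 1.5 h across thresholds 300–600 (the
analytic crossing spread of a logistic rise is ln[(A/θ₁−1)/(A/θ₂−1)]/β₁ ≈
0.8/β₁ h for A ≈ 3000).

Developmental age (DevA) is harvest time minus detected onset. It uses the
threshold crossing rather than the fitted t₁ because t₁ is poorly
constrained for EBs harvested before their peak; negative DevA (pre-onset
harvest) is returned flagged, while an undetected onset is a distinct
error.

## Point-cloud filtering and geometry

Segmentation yields 3D points with intensities, contaminated by plate and
agar clutter. Two single-pass filters clean each frame: an axis-aligned
closed bounding box (removes far clutter such as the plate-level cluster),
then a close-neighbor density filter retaining points with at least
`min_neighbors` (default 5) other points within `neighbor_radius` (default
40 µm, Euclidean, self excluded), computed with a k-d tree against the
original cloud. The neighbor filter is deliberately not iterated to a
fixpoint: a second application can remove more points, and the tests
document this semantics. Filters only ever drop points.

EB radius is the radius of the minimal enclosing circle of the 2D (xy)
projection, mirroring a circumscribed-circle measurement on a
phase-contrast image taken before onset; the computation is delegated to
`shapely.minimum_bounding_radius` and cross-checked in the tests against
an O(n³) pair/triple enumeration oracle. Because the circumscribed circle
passes through extreme points, outline noise inflates the estimate by a
few µm at realistic point densities — an intrinsic property of the
measurement, shared with the original procedure. Volume occupancy is
count/radius³ (µm⁻³), a proxy for the expressing fraction of the EB.

## Synthetic cohorts

The generator is the forward model the analysis is validated against. Per
EB it draws:

- onset ~ Normal(83.3, 3.7²) h and onset-to-peak ~ Normal(12.8, 2.2²) h
  (floored at 3 h), the within-experiment distributions of the baseline
  experiment; onset and onset-to-peak are drawn independently (no
  correlation between them is reported);
- radius from a truncated normal on [81, 176] µm whose location is solved
  so the truncated mean equals the reported 113 µm (the reported moments
  describe the observed, truncated data), sd 19 µm — independent of
  timing;
- amplitude A = min(A_free, c·R³) with A_free ~ Normal(3000, 450²) points
  and c = 3000/100³ points/µm³, so only EBs below ~100 µm are
  amplitude-limited by their size, reproducing the weak small-EB
  amplitude–size correlation;
- rates β₁ ~ logNormal(ln 0.65, 0.12²) and β₂ ~ logNormal(ln 0.3, 0.12²)
  h⁻¹. The β₁ scale is set by the threshold-robustness property above
  (spread ≈ 0.81/β₁ h must stay under 1.5 h); β₂ < β₁ matches the slower
  observed recession.

Given these latents, t₁/t₂ are solved (bisection on the half-peak gap,
then a time shift) so the detected onset and onset-to-peak of the
noiseless curve equal the drawn values exactly — with zero noise the
pipeline is a round trip. Counting noise is Poisson by default (counts of
segmented objects; variance = mean), with Gaussian and noise-free options
for tests.

Point-cloud movies place round(N(t)) GFP points uniformly on a spherical
cap centered on a random onset locus, with cap area fraction
N(t)/capacity (capacity defaults to A, so a full-amplitude signal covers
the shell); the cap therefore spreads from and recedes toward the locus,
and the patch is contiguous by construction. Shell positions get ~2 µm
radial jitter. Clutter is Poisson background strictly outside 1.2·R plus a
sparse far cluster at ≈ −2.2·R on the z axis; the bounding box catches the
far cluster and the density filter the sparse background.

Expression panels follow −ΔΔCT_g(eb) = intercept_g + slope_g·DevA(eb) +
shift_g(group) + ε and are emitted as raw CT by inverting the
normalization against two designated housekeeping genes (CT ≈ 13–14, small
noise) plus a per-EB loading offset (~0.35 cycles sd) that models
cell-number differences and cancels through the normalizers. Because
−ΔΔCT normalization pins every gene's reference-group median to zero, the
truth record stores the control-median-centered levels; recovery is then
exact (to float precision) even under noise. The default 13-gene panel
echoes the measured one: primitive-streak genes falling with DevA,
late-mesoderm genes rising, flat genes, and Wnt3 down-shifted ~2.5–4
cycles by CHIR presets.

Perturbation presets for the signaling experiment: control onset 70 h;
long CHIR (24–72 h) and Bmp4 shift onset to 50 h; long CHIR also shrinks
EBs (radius mean 85 µm); short CHIR pulses perturb expression only. The
mode-classification panel generates Wnt3 as a declining function of DevA
plus CHIR down-shifts, and genes per designed mode with effects ≥ 3
control SDs (canonical: responds to pathway activity against the ligand
trend; trend continuation: tracks realized Wnt3; decoupled: ignores CHIR;
indirect: long treatment only; uncorrelated: independent noise).

What the generator does not emulate: voxel-level imaging (optical PSF,
depth attenuation), intra-EB spatial expression structure, qPCR efficiency
differences between assays, batch effects between experimental repeats,
and any correlation structure among genes beyond their shared DevA and
Wnt3 drivers. Passing recovery tests therefore demonstrates correctness of
the algorithms under the stated statistical structure, not robustness to
those unmodeled features of real data.

## Normalization and trend estimation choices

geNorm stability M is the mean across other candidates of the SD of
pairwise CT differences; NormFinder-style stability is √(gene×group
interaction variance + mean within-group variance), reducing to the
within-group SD for a single group. The normalizer pair is accepted only
when both methods agree on the top two (any order); disagreement raises
with both rankings attached — no silent choice. The two normalizers are
combined by the arithmetic mean of their CTs (geometric mean of
expression). Genes with > 50% missing reactions or observed SD < 0.5
cycles are excluded before ranking (both thresholds configurable); failed
reactions are missing values, never CT = 30.

Nearest-neighbor imputation (for clustering and PCA only; trend analyses
use observed values) fills a missing cell from the nearest EB by RMS
distance over co-observed genes, among EBs observing that gene. It
operates on the −ΔΔCT matrix, post-normalization. Hierarchical clustering
uses d = 1 − Pearson r with average linkage.

Percent variance explained is 100·(1 − RSS/TSS) of a simple linear
regression (clipped to [0, 100]); a constant response reports 0% by
convention. The linear estimator was chosen over a smoother-based one
because it is reproducible and monotone in trend strength; the local
linear kernel smoother (Gaussian kernel, default bandwidth 25% of the
DevA range, default 50-point grid) is used for display curves and masks
grid points with negligible total kernel weight instead of extrapolating.

## Dependency-mode classification

For each gene: Pearson r against Wnt3 on control EBs (|r| < r_min = 0.5 →
not_correlated); an OLS control trend gene ~ Wnt3; per CHIR group a
residual z (median residual from the trend / control residual SD) and a
shift z (median difference from control / control SD). The decision tree,
evaluated in order with k = 2:

1. shifts ≤ k in both short pulses but > k under long CHIR →
   indirect_long_term_only;
2. shifts ≤ k in every CHIR group → decoupled_parallel (the gene ignores
   the treatment even though Wnt3 moved);
3. any |residual z| > k → canonical_regulation (the response contradicts
   the ligand level, so it is driven by pathway activity);
4. otherwise → trend_continuation (moved along the control trend to its
   low-Wnt3 end).

The ordering resolves an ambiguity in a flat rule list: once Wnt3 drops,
decoupled and indirect genes are necessarily off-trend too, so shift
criteria must be tested before the residual criterion. Both thresholds are
exposed (`r_min`, `k`). Classification is invariant to gene-wise affine
rescaling of −ΔΔCT, since all criteria are z-scores or correlations. With
~12 control EBs, sampling noise in the control trend slope propagates into
residual z at low-Wnt3 extrapolations (≈ Δw/(sd_w·√n) ≈ 1.3 expected), so
occasional trend-continuation/canonical confusions and chance correlations
of designed-independent genes bound the achievable accuracy around
95% rather than 100%.

Group shifts are median differences with an advisory Mann-Whitney flag,
Benjamini-Hochberg corrected across genes at 0.05; the flag is not used by
the mode classifier. PCA runs on the median-imputed, gene-centered matrix
(scikit-learn, full SVD) and reports percent explained variance per
component and per-group centroid projections.

## Problem sizes and numerical choices

Validation suites simulate 20–50 EBs per cohort (the scale of one imaging
experiment), 78-EB panels for variance-explained checks (the pooled panel
size), 30 EBs per perturbation arm, and 10–20 replicate seeds for
stochastic recovery statements; these sizes keep every latent within ~3
SEM of its target while the whole suite runs in well under a minute of
simulation time. Onset root-finding uses xtol 10⁻⁶ h and peak location
xatol 10⁻⁸ h; the event-calibration bisection terminates at a 10⁻⁸ h gap
width. All randomness flows through `numpy.random.Generator` seeded from a
single integer; identical seeds give byte-identical cohorts.

## Known limitations

- The impulse fit assumes a single pulse; double-pulse or non-monotone
  curves would be summarized by the nearest single pulse without warning
  beyond a large residual.
- Onset detection requires the fitted peak to clear the threshold; EBs
  harvested long before peak may fit poorly and are only protected by the
  no-signal flag and the rss-vs-initialization check.
- NormFinder is implemented as the variance decomposition described above,
  not a port of the original software; rankings agree on designed fixtures
  and degenerate cases but may differ in edge cases with very unbalanced
  groups.
- The mode classifier assumes Wnt3 is actually down-shifted by CHIR (the
  premise of the design); if a dataset lacks that shift, decoupled and
  trend-continuation calls lose their meaning.
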