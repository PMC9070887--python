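# Methods

This note records the measurement model, the numerical choices, and what
the synthetic validation does and does not establish.

## Regions of interest

All metrics are anchored to the optic disc (centre and radius R supplied
as a JSON annotation; automatic disc detection is out of scope).  Three
annuli are used: the caliber zone at radial distances (2R, 3R] — i.e.
0.5–1.0 disc *diameters* beyond the disc margin; the tortuosity and
monofractal zone at (1.5R, 3R]; and the whole field minus the disc,
(R, edge], for the multifractal analysis.  Distances run from pixel
centre to disc centre in pixel units, and the boundary rule is half-open
(`inner < d <= outer`) so that nested annuli partition cleanly.  No
boundary convention is standard in the imaging literature; the half-open
choice is arbitrary but fixed and tested.

## Vessel segmentation

Vessels are dark, roughly line-like structures on a bright background.
The detector evaluates, at each pixel and for each odd line length
L ≤ W (defaults L ∈ {1, 3, …, 15}, window W = 15), the maximum over 12
orientations (15° steps) of the mean inverted intensity along the line
minus the mean over the W×W window.  Per-scale responses and the inverted
intensity are standardized, averaged, and min–max normalized to [0, 1].
Hysteresis thresholding (defaults t_high = 0.6, t_low = 0.3, 8-connected
growth) and cleanup (drop components < 50 px, fill holes < 20 px) yield
the binary mask.  All defaults are config-overridable; they were chosen
from the line-detector literature, not fitted to any dataset.  The path
is fully deterministic — identical input gives a bit-identical mask.

Color input is reduced to the green channel (standard fundus practice);
a flag flips the dark-on-bright assumption.

## Morphometry

The mask's topological skeleton is split into branch segments at nodes of
degree ≠ 2; 1–2-step slivers connecting adjacent junction pixels are
discarded as skeletonization artifacts.  The local vessel width at a
centerline pixel is twice the Euclidean distance transform.  A segment
participates in the caliber summary when its centerline reaches both
boundaries of the caliber annulus ("passes completely through"); it
contributes the mean of its local widths inside the annulus.
Arteriole/venule labels come from a sidecar (or phantom truth); no
automatic artery/vein classification is attempted.

CRAE and CRVE combine the six widest arterioles/venules by iterated
pairing of widest with narrowest, each pair collapsing to
c·sqrt(w_a² + w_b²) with c = 0.88 (arterioles) and 0.95 (venules), an odd
leftover carrying to the next round.  Note the coefficient applies once
per round: six equal 100 μm widths give 174.84 μm (CRAE), not
0.88·√6·100.  Fewer than six widths are combined with a warning.

Tortuosity of a branch segment is chord/arc — the straight end-to-end
distance over the traced centerline length — so a straight vessel scores
exactly 1 and meanders score lower; the index is the unweighted mean over
segments whose centerline majority lies in the tortuosity annulus.  The
reciprocal (arc/chord ≥ 1) convention is available by flag; chord/arc is
the default because it is the scale on which cohort values near 0.9 are
interpretable.  Before the ratio, centerline paths are resampled at 8-px
spacing: a raw 8-connected pixel chain overstates a smooth curve's length
by several percent (staircase bias), which would depress every index;
the polygonal approximation brings a digitized semicircle within ~0.01
of its analytic 2/π.  The resampling also sets the scale below which
genuine wiggles are invisible to the index.

## Fractal and multifractal analysis

**Grids.** Box grids are evaluated at 10 origins: the raster origin plus
9 seeded pseudo-random origins in [0, δ)².  A grid offset is applied by
rolling the raster periodically rather than by shifting the grid across
the raster edge: plain shifted grids lose up to half a box per dimension
at the coarsest scales, which biased the capacity dimension of a
known-dimension test measure by +0.10; with toroidal shifts every grid
tiles the raster with full-size boxes, no edge slivers contaminate the
negative-q moments, and the recovery of analytic dimensions is exact.
When δ does not divide the raster side the trailing remainder (< δ) is
dropped after the roll.

**Scale series.** The default box sides are powers of two from 16 px up
to min(rows, cols)/4.  The 16-px floor is deliberate: below the width of
the widest vessel a binary vessel mask is locally two-dimensional (boxes
fall wholly inside a trunk), and including those scales mixes two
scaling regimes — empirically this inverted the D0 ≥ D1 ≥ D2 ordering
and inflated f(α)max well above D0 on vessel masks.  With the floor, the
box reads the local density of the vascular *network*, the ordering
holds on every validation raster, and |f(α)max − D0| < 0.001 on the
phantom suite.  Measure rasters with genuine structure at all scales
(e.g. cascades) may override the series; the cascade oracle uses
4–128 px and recovers D_q within 0.007 of the closed form over
q ∈ [−5, 5].

**Monofractal.** D_f is the least-squares slope of log N(δ) against
log(1/δ) with N aggregated as the minimum over grid origins (capacity
convention); r² is reported so poor scaling is visible, and no automatic
range pruning is applied.  Lacunarity is the mean over sizes and origins
of (σ/μ)² of the per-box foreground counts; a filled raster scores
exactly 0.

**Multifractal.** Box masses are normalized to probabilities μ_i within
each grid; Z(q, ε) = Σ μ_i^q over nonempty boxes, averaged over origins;
D_q = slope(ln Z vs ln ε)/(q − 1), with q = 1 handled by the entropy
limit (slope of Σ μ ln μ vs ln ε), on a q grid from −10 to 10 in steps
of 0.1.  τ(q) = (q − 1) D_q.  The Hölder exponent α(q) and f(q) are
estimated by the direct moment (Chhabra–Jensen) regressions — slopes of
Σ μ̂ ln μ and Σ μ̂ ln μ̂ against ln ε with μ̂ = μ^q/Σμ^q, computed in log
space so extreme moments cannot overflow.  The numerical Legendre
transform (central differences of τ) is retained as a fallback, but on
sparse binary masks the negative-q moments scale poorly (r² ≈ 0.6) and
Legendre-transforming that noise produced f(α)max overshoots of up to
0.7; the moment regressions stay bounded.  Derived scalars: D0, D1, D2;
α0 = α(0); Δα = α_max − α_min (singularity length);
A = (α0 − α_min)/(α_max − α0), reported as missing when the right branch
collapses (exact monofractals); and f(α)max, which equals D0 up to
regression error.

## Cohort statistics

Group contrasts are two-sided independent t tests, pooled-variance by
default with Welch by flag.  Spearman's ρ uses average ranks for ties.
PCA standardizes features to zero mean and unit variance before the
decomposition.  The poor-vs-good classifier (default: sigmoid-kernel SVM
with C = 1, gamma = 1/(n_features · Var), coef0 = 0; linear kernel and
logistic regression available) is evaluated by leave-one-out
cross-validation with standardization refit on each training fold, so no
statistic of the held-out patient reaches the model.  Sensitivity and
specificity are reported both with the poor class as positive and
class-weighted (the class-weighted recall equals accuracy by
construction; both conventions are printed because summary tools differ).
Ordinal collateral scores are dichotomized as {0, 1} → poor,
{2, 3} → good by default (config-overridable; the split of intermediate
grades is a study-design choice, not derivable from the data).

A caveat measured during validation: under label permutation the LOOCV
null accuracy sits at ~0.50–0.53, slightly *below* the majority-class
fraction (0.571 at 15/20), for all three learners.  This is the known
pessimism of leave-one-out — the held-out subject's class is always
underrepresented in its own training fold — and not an information leak;
the null never exceeds the baseline.

## Synthetic data: what it shows and what it does not

* **Sierpinski rasters and multiplicative cascades** have closed-form
  dimensions and exercise the estimators end to end.  They validate the
  numerics, not the biology.
* **Vessel phantoms** are branching, tapering trees of straight segments
  and circular arcs (widths 3–12 px, disc R = 20 px, 256×256 frame,
  smooth background gradient, Gaussian noise σ = 2 on a ~90-intensity
  vessel contrast), with analytic truth for masks, widths and chord/arc
  ratios.  The fan is rotated off the axis/diagonal directions, where
  strip rasterization is degenerate and distance-transform widths jump in
  quantized steps.  Branch points sit outside the caliber annulus so main
  vessels cross it unbroken.  Phantoms validate segmentation recovery
  (Dice ≥ 0.8 under noise, ≥ 0.95 without), width recovery (≤ 5% error),
  tortuosity, and the multifractal invariants — but they are far more
  regular than real fundus images (no pigmentation texture, no
  illumination falloff, no pathology), so passing them bounds
  implementation error, not clinical performance.
* **Simulated cohorts** draw group-wise Gaussians at the cohort
  descriptive statistics (21 controls, 20 good, 15 poor), with the
  capacity dimension and f(α)max coupled at ρ = 0.99 and all other
  features independent within group — real retinal metrics are mutually
  correlated, so simulated PCA variance fractions are lower than real
  ones.  They validate the statistics stage (effect-size recovery,
  classifier above the majority baseline, mean recovery at large n), not
  any claim about patients.

## Problem sizes

Default validation sizes: 256×256 phantoms, depth-9 (512×512) cascades,
order-8 Sierpinski rasters, 500-replicate power simulations at
n = 100/group, 200 label permutations, and 20 000 patients/group for
mean-recovery checks.  These sizes give standard errors well inside every
tolerance asserted in the tests while keeping a full validation run in
tens of seconds on one CPU.

## Known limitations

* Equivalence with any specific commercial/freeware toolchain's masks or
  FracLac's exact box placement is not claimed; only analytic and
  phantom-truth recovery is asserted.
* Widths below ~3 px are unreliable (distance-transform quantization).
* The μm/px scale is device-dependent and must be supplied; without it
  calibers are reported in pixels and flagged.
* Multifractal scalars on near-monofractal masks (Δα, A) are
  noise-dominated by construction; they are reported with the regression
  diagnostics needed to judge them.
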