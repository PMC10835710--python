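# Methods

This note documents the statistical model, the algorithms, the synthetic
generators and the numerical choices behind `phenocompare`, including the
places where the design was genuinely open and a choice had to be made.

## Measurement model

All comparison statistics assume the additive model

    y_ijM = μ_j + b_M + e_ijM

for subject (plot, plant, patient) j = 1…k, replicate i = 1…n, method M.
Residuals are independent with mean 0 and either a constant variance σ²_M
per method, or a per-subject variance σ²_{M,j} when the spread grows with
the subject mean (typical of canopy height, where taller stands are harder
to measure consistently). Only the difference of method offsets
b_AB = b_B − b_A is identifiable without an external reference, which is why
every routine works on two named methods.

## Bias

The default estimator takes, per subject, the difference of method means
(d_j = ȳ_jB − ȳ_jA) and applies a one-sample two-tailed t-test of
mean(d) = 0 with df = k − 1. This pairs subjects and therefore removes the
between-subject variance from the test. A `two-sample` mode (equal-variance
t-test on the two sets of subject means, df = 2k − 2) is provided for
designs where pairing is not wanted; it is less powerful and is not the
default. Degenerate inputs (zero variance of differences) return flagged
limiting values (p = 1 at zero mean, p = 0 otherwise) rather than raising,
because tied field data do occur.

## Precision

Within-subject variance is the sample variance about the subject-method
mean, df = n_j − 1, with the chi-square pivot interval
(df·s²/χ²_{1−α/2}, df·s²/χ²_{α/2}). Two estimates are compared by
F = s²_A/s²_B with a two-tailed p-value defined as

    p = min(1, 2·min(P(F ≤ f), P(F ≥ f)))

— the standard equal-tails convention; it is exactly symmetric under
swapping the methods (f → 1/f, p unchanged). The `larger_method` field is
set only when the test is significant, so a non-significant comparison never
nominates a "winner".

**Pooling.** With only a handful of replicates per subject a variance
estimate is very noisy (df = 1 at n = 2), so when variances do not depend on
the subject mean the per-subject estimates are pooled df-weighted:
σ̂² = Σ df_j s²_j / Σ df_j with df = Σ df_j. The `auto` pooling rule fits an
ordinary least squares line of variance on subject mean per method and
switches to per-subject comparisons only when the slope is significantly
positive (one-sided, at the analysis α). OLS on variances violates the
regression's normality assumptions — the fit is used only as a screening
diagnostic (and drawn dashed in panel C for visualization), never as an
inference; the recommendation can always be overridden with
`pooling="pool"` or `"per-subject"`.

**Verdict.** The report's verdict is a deterministic function of the
results: biased iff the bias test is significant; precision from the pooled
F-test when pooled, otherwise from the counts of subjects on which each
method's variance is significantly larger (fewer losses = more precise; a
tie = equally precise). Per-subject F-tests are *not* multiplicity-corrected
by default — the per-subject panel is read as a pattern, not as k separate
confirmatory tests; a Bonferroni-adjusted α can be passed explicitly by the
caller if desired.

## Limits of agreement and repeatability

LOA = mean(d) ± k·sd(d) on differences new − old. Two pairings are
supported: `replicate-index` (i-th replicate with i-th replicate within each
subject; all replicate pairs contribute) and `subject-means` (one difference
per subject). The multiplier defaults to 1.96 with k = 2 available — the
original convention; the bundled peak-flow reanalysis uses k = 2. The
coefficient of repeatability is 2 × sd of the difference between a method's
first two replicates; the default `zero-mean-sd` convention takes the sd
about zero (2·√(mean d²)), which assumes no systematic difference between
replicate occasions, and `sample-sd` uses the ordinary sample sd.

## Lidar pipeline

Geometry: beam angle β is measured from straight down in the scan plane;
x = r·sinβ, y = mount_height − r·cosβ. The mount height must be supplied
(sidecar config or argument) — it cannot be inferred from the scans.
Returns more than 5 cm below ground (default `below_ground_tol`) are
dropped; small negatives are clamped to 0.

Filters, in order: crop to |x| ≤ 0.762 m (30 in at exactly 0.0254 m/in,
isolating the rows under the scan line); drop the first and last
⌈0.15·n_scans⌉ scans (plot edges); iterative two-sided Grubbs test on the
height distribution at α = 0.01, critical value
G = ((n−1)/√n)·√(t²/(n−2+t²)) with t = t_{α/(2n), n−2}, removing the single
most extreme value per iteration until G ≤ G_crit. Constant data and n < 3
are left untouched. Height is then the 99th percentile of y with linear
interpolation between order statistics (the most common percentile
convention; recorded in provenance).

**Gap fraction.** Beams are binned by the zenith angle of the beam *line*
from vertical (min(|β|, 180°−|β|)), into the fixed bins
0–15–30–45–60–90°. A beam counts as a gap when the canopy did not
intercept it: no return at all, or a return at ground level
(y ≤ `ground_eps`, default 0.1 m). Counting ground hits as gaps is required
for a downward-looking scanner — a beam that reaches the soil passed
through the canopy, and without this rule the near-vertical bins of any
open canopy would read fully closed. Setting `ground_eps = 0` recovers a
strict no-return-only count. A bin with gap fraction exactly 0 is replaced
by ¼ of the next more skyward bin's value, resolved skyward-first so chains
of zeros propagate multiplicatively; a zero in the most skyward bin (no
skyward neighbor) uses the floor 1/(4·n_beams in the bin), i.e. a quarter
of the smallest observable nonzero fraction. Empty bins are marked and
excluded from the inversion.

**LAI.** Discretized Miller inversion over non-empty bins,
LAI = 2·Σ (−ln P_i)·cosθ̄_i·sinθ̄_i·Δθ_i with θ̄_i the bin midpoint and Δθ_i
the width in radians. For a Beer-law profile sampled at these five
midpoints the quadrature weights sum to Σ sinθ̄Δθ = 1.0073, i.e. an
intrinsic discretization error of +0.7 %.

## Synthetic generators

`simulate_repeated_measures` draws from the measurement model exactly;
mean-dependent spread is parameterized σ(μ) = a + c·μ, matching the
observed pattern of variance growing with stand height. All generators are
deterministic under a fixed seed (numpy `default_rng`).

`simulate_lidar_scene` ray-casts a horizontally uniform canopy slab between
`canopy_base` (default 0.2 m) and `canopy_top`, below a scanner at 4 m.
A downward beam at zenith θ is intercepted with probability
1 − exp(−k_ext·L/cosθ) (Beer–Lambert through the slab, k_ext default 0.5,
the spherical-leaf-angle G value); intercepted beams return at a
truncated-exponential depth along the in-slab path with the per-meter rate
k_ext·L/(slab thickness), which makes the depth distribution consistent
with the interception law; non-intercepted beams return from the ground
when it is within the 30 m range. Gaussian range noise (default 0.04 m,
the scanner's stated ±40 mm precision) is added to every return.

Design choices that matter for what the scene tests can show:

* **Zenith used for the interception draw** (`zenith_mode`). The default
  `bin-midpoint` draws each beam at the midpoint of its gap-fraction bin,
  so every bin's empirical gap fraction follows Beer's law at the midpoint
  up to binomial noise — the property the 5-bin inversion assumes. With
  `"exact"` (each beam at its own zenith) the wide 60–90° bin averages
  exp(−k·L/cosθ) over angles where the exponent varies enormously; the bin
  mean then differs from the midpoint value by far more than counting
  noise, and the coarse inversion is biased by roughly +7 % at L = 0.5 to
  −25 % at L = 5. That bias is a genuine limitation of five-bin gap-fraction
  inversion under dense angular sampling, not of this implementation; the
  midpoint mode isolates the inversion's own error from it.
* **Sector** defaults to ±82° because beams within ~8° of horizontal can
  reach neither the slab nor the ground inside the 30 m range from a 4 m
  mount (cosθ < mount_height/max_range) — they would register as permanent
  gaps carrying no canopy information.
* **n_scans = 600** so the most opaque bin at L = 5 (gap probability
  exp(−2.5/cos75°) ≈ 6·10⁻⁵) still receives ~10 expected gap beams — a
  Poisson design calculation, equivalent to combining the field protocol's
  five passes of ~120 scans each.
* Height-recovery scenes use a dense canopy (L = 5): a 99th-percentile
  height presumes the canopy top is well sampled; in a sparse canopy the
  quantile sits measurably below the physical top by construction.

What the scenes do **not** emulate: discrete plants and row structure, leaf
angle distributions other than spherical, multi-return pulses, wind motion,
mixed ground/vegetation returns near the base. Passing recovery tests
therefore show the algorithms invert their own physical model correctly at
field-realistic sampling densities — not that a field campaign would achieve
the same accuracy.

## Calibration and problem sizes

The distributional checks run at sizes chosen to keep Monte-Carlo error
well below the tolerances they assert: 10,000 replicates for the F-test
type-I error (binomial sd ≈ 0.22 % around 5 %), the chi-square CI coverage
and the LOA fresh-difference coverage (population limits approximated from
200,000 differences); 1,000 seeded runs of k = 200 subjects × 5 replicates
for bias-CI coverage; 10,000 draws for F-test power at df (4, 4) against
the closed-form oracle P(F > f_u/R) + P(F < f_l/R). The t/F/χ² tails and
the Grubbs critical values are verified to 1 × 10⁻⁸ against brute-force
numerical integration of hand-written log-densities (adaptive quadrature
plus root finding), independent of the library routines used in the
implementation.

## Known limitations

* Two-method designs only; no Deming regression or mean-dependent
  (regression-based) limits of agreement.
* The variance F-test assumes approximately normal residuals; heavy tails
  inflate its size.
* The gap-fraction inversion inherits the five-bin discretization and the
  ¼-replacement heuristic; both are faithful to the field procedure rather
  than optimal.
* The LAI-from-gap-fraction route assumes the extinction model's k_ext; a
  mismatched leaf angle distribution biases LAI proportionally.
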