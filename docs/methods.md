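# Methods

This note records the models, algorithmic conventions, numerical choices
and known limitations behind `lumiquant`. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Imaging stage

**Inputs.** An acquisition is a brightfield raster plus a co-registered
luminescence raster covering 1–5 mice. Two luminescence dialects are
supported. The *grayscale* dialect is a float32 TIFF whose pixels are
radiance (photons s⁻¹ cm⁻² sr⁻¹) — lossless and preferred. The
*pseudocolor* dialect is an 8-bit RGB overlay rendered through a named
color ramp between a min/max radiance scale; it is inverted on a log axis
(radiance spans orders of magnitude, so the scale is interpolated
logarithmically between the endpoints). Inversion places each colored
pixel at the center of the run of ramp entries indistinguishable at 8-bit
color resolution — the information-theoretic best for an 8-bit overlay —
giving a worst-case round-trip error of about 1.9 % over four decades
with the default `turbo` ramp. The classic `jet` ramp contains a
genuinely constant color stretch and cannot be inverted below ~9 % there;
it is supported but not the default. Near-gray pixels (channel spread
below 40 counts) are background and map to zero. The dialect is recorded
on every loaded image.

**Mouse isolation.** The body map is the union of thresholded
brightfield (default 0.2 on a 0–1 scale) and nonzero radiance, closed
with a radius-3 disk; connected components of at least 150 px are mice,
ordered left to right. Zero or more than five detections raises a QC
error so the frame is logged and excluded rather than silently guessed.

**Tail removal.** The mask's row-wise width profile is scanned upward
from the bottom: the maximal run of rows below the widest torso row whose
width is under 25 % of the torso width is the tail (the fraction is
configurable). Using the suffix-run rather than all thin rows protects
against mid-body width dips. Phantoms are built with a flat hindquarters
profile precisely so that no body row is tail-thin.

**Slant rejection.** A mouse is rejected when its mask's principal axis
(image second moments) deviates from vertical by strictly more than 10°
(configurable). The strict inequality means a mouse measured exactly at
the threshold is kept.

**Height normalization.** Each tail-free mouse is cropped to its mask,
isotropically resampled (bilinear, anti-aliased when downscaling) so the
mask spans exactly the target height (default 100 rows), and embedded
centered in a fixed-width frame (default 72 columns). A per-image
`pixel_area` factor tracks the area each pixel represents relative to the
raw acquisition, so total radiance `sum × pixel_area` is conserved
through resampling (measured ≤ 0.2 % on phantoms; the contract is 1 %).
Isotropic rather than vertical-only scaling preserves body proportions;
the original aspect ratios of the phantoms vary only through body height.

**Quantification.** Average radiance per pixel is the mean of radiance
over mask pixels (intersected with an optional ROI). Zero-luminescence
pixels inside the mask count as zeros — they are part of the average, not
excluded — and an empty intersection yields NaN. Whether the original
instrument software averages over mask pixels or the full crop is not
observable from outside; mask-pixel averaging is used throughout.

## Phase segmentation

Consecutive timepoints are compared once, in order: growth ends at the
timepoint immediately before the first strict drop below 75 % of the
previous value; decay then ends at the timepoint immediately before the
first increase of at least 3-fold (ties break toward relapse); all
remaining timepoints are relapse. Five classes result: G, GD, GDR, D, DR.
Two conventions deserve note:

* A "growth phase" of a single point (the 75 % rule fires at the very
  first step) is treated as no growth phase: the series starts in decay.
  The five-class scheme has no single-point-growth category, and cohort
  analyses dichotomize mice into "initially grew" vs "initially decayed".
* Values of exactly zero are clamped to a configurable detection floor
  (default 10³, a typical instrument background) before the ratio tests,
  since both thresholds and the log-domain fit require positivity.

Both rules are ratios, so segmentation is invariant under uniform
rescaling of the series — asserted as a property test.

## Piecewise kinetic model

Growth and relapse are logistic, `dT/dt = k T (1 − T/T∞)`; decay is
exponential relaxation toward a baseline, `dT/dt = −k_decay (T − T_B)`.
The closed forms are evaluated in the overflow-safe reciprocal form
`T(t) = 1/((1/T_start − 1/T∞) e^{−k(t−t₀)} + 1/T∞)` and agree with
direct numerical integration of the ODEs to better than 10⁻⁶ relative on
randomized parameters (acceptance suite, 1 000 parameter sets).

**Junction convention.** The model junction between decay and relapse is
the *last decay timepoint*: t_relapse is that day, T₁,relapse is the
decay curve evaluated there, and the relapse phase's data window starts
at that shared point. Likewise t_decay is the last growth timepoint and
the decay curve starts at the growth curve's value there. This makes the
piecewise curve exactly continuous at both junctions (checked to 10⁻¹²
relative). The `PhaseSegmentation.R_index` bookkeeping index, by
contrast, names the first timepoint *after* the 3-fold jump; the two
conventions differ by one deliberately — one indexes the detection event,
the other anchors the continuous model.

**Estimation.** Fitting is least squares on log₁₀ radiance (values span
~5 decades and residuals are reported in decades), per phase, with
t_decay/t_relapse fixed at the segmentation boundaries, bounded
trust-region optimization (`scipy.optimize.least_squares`) from five
seeded multi-starts, and junction values propagated forward. T∞ is
bounded to [max(values), 100 × max(values)] and estimated in the phase
where the plateau is actually visible: the growth phase of a treated
mouse rarely approaches carrying capacity, so a growth-estimated T∞ is
weakly identified, and anchoring the relapse phase to it biases the
relapse rate (≈2 % on noise-free data). Each phase therefore gets its own
T∞ estimate by default (`shared_tinf=True` restores sharing); for
trajectories with a relapse phase the reported T∞ is the relapse-phase
(plateau-informed) estimate. Two-point growth phases pin T∞ at the upper
bound — two points cannot constrain a plateau — making the fit
effectively exponential, and the fitted rate equals the log-slope.

After the sequential pass, a *joint polish* refits all free parameters in
one bounded least-squares pass over the full series (junction times still
fixed, continuity automatic). The sequential pass freezes each junction
value at the previous phase's estimate, so that estimate's noise leaks
into the next phase's rate; the joint pass lets every phase's data inform
the shared quantities. It is initialized at the sequential solution and
accepted only when the objective decreases, so noise-free recovery
(≤ 0.1 % on all three rates) and determinism are unaffected.

**MAP refit.** A rate is refit when its unpenalized estimate exceeds the
outlier cutoff (3 day⁻¹) or its phase has exactly two datapoints — the
regime where rate outliers concentrate. The refit minimizes
`Σ(log₁₀ residual/noise_sd)² + ((k − μ)/s)²` as a one-dimensional problem
in the rate, holding the other phase parameters at their fitted values;
`noise_sd` defaults to 0.15 decades (the measurement-noise scale assumed
throughout; the likelihood variance is not observable from a single
series and is configurable). The empirical priors are the mean and sample
standard deviation of the cohort's own fitted rates after removing values
above the cutoff; only k_growth and k_relapse are ever refit — the decay
rate population is bimodal and admits no reliable single Gaussian prior.
The refit moves the rate monotonically from the unpenalized estimate
toward the prior mean as the prior tightens (property-tested), but for a
two-point phase with widely spaced days the likelihood weight grows with
the day gap squared, so the MAP value of an extreme outlier is *not*
guaranteed to land below the cutoff for every spacing; under the
realistic cohort conditions used in the acceptance suite all refit rates
stay below 2 day⁻¹.

## Regional analysis

For every aligned image the radiance in each row (and, separately, each
column) is averaged, giving per-image axis profiles; PCA across images of
those profiles yields loading curves over the axis. Boundaries are the
loading curves' zero crossings — linearly interpolated to sub-pixel and
rounded — taken only where the stack's mean mask occupancy is at least
50 % (the body envelope), to avoid background crossings. Horizontal
boundaries come from selected row components, vertical from selected
column components; the default selections (row components 2–3, column
components 4–5) follow the convention established for large
heterogeneous cohorts and are configuration options, since component
ordering depends on the cohort's variance structure (the synthetic
cohorts here carry their contrast in the leading components). The grid
must contain exactly nine cells or demarcation fails loudly, listing the
crossings found — the construction is surfaced, never fudged. Anatomical
names are assigned by a configurable 3×3 template (snout top-center,
bmL/bmR bottom corners).

Note the phrase "averaging the rows of the average image" describes a
single image and cannot support a PCA; the per-image reading
(observations = images, features = positions) is the only self-consistent
one and is what is implemented.

Per region, the average radiance within cell ∩ mask is quantified per
day, floored and segmented exactly like the whole-body series; the
partition identity Σ_regions (regional mean × regional pixel count) =
whole-body mean × body pixel count holds exactly and is asserted.
Divergence is the fraction of mice whose regional class differs from
their whole-body class; the class-by-class residual-vs-identity table
gets 95 % intervals from a seeded 1 000-resample bootstrap over mice
(the band construction is a package choice), and cells whose interval
excludes zero are flagged. Region correlation is Pearson on log₁₀
radiance pooled across mice and days (dynamics span decades; Spearman
available), with floor-level values dropped pairwise.

## Synthetic study conditions

The generator inverts the fitted model. Defaults encode the study
conditions of a large (>1 000-mouse) leukemia cohort:

| quantity | default | why |
|---|---|---|
| class mixture G/GD/GDR/D/DR | .353/.058/.158/.097/.335 | observed five-class frequencies of the reference cohort |
| k_growth | N(0.84, 0.43²) day⁻¹, truncated to [0.05, 2] | empirical prior population |
| k_relapse | N(0.60, 0.32²) day⁻¹ truncated | empirical prior population |
| k_decay | ½N(0.35,0.10²)+½N(0.95,0.25²) | the decay-rate population is bimodal; mode values are this package's choice |
| T₀, T_B, T∞ | log-uniform 10⁴–10⁶, 10³·³–10⁴·⁵, 10⁸·⁷–10⁹·⁷ | five-decade dynamic range typical of luciferase imaging |
| noise | lognormal, σ = 0.15 decades | multiplicative measurement noise, additive on log₁₀ |
| imaging | every 3.5 days, 8–12 timepoints | twice-weekly imaging |
| change points | growth 2–4 points, decay 3–5 points | early CAR-T response, relapse weeks later |

Change points are rejection-sampled so the *noise-free* curve respects
the segmentation thresholds with margin (first decay step ≤ 0.6×, relapse
jump ≥ 3.2×, burden at decay onset ≤ half of carrying capacity), and the
noise vector is redrawn (seeded, deterministic) until the noisy series
segments to exactly the generative change points — the in-silico analog
of manually confirming automated classifications, and the condition under
which comparing fitted to generative rates is meaningful. Series end
early when the noise-free burden reaches 75 % of carrying capacity,
emulating sacrifice at tumor-burden endpoints; this also keeps
growth-phase data in the kinetically informative (pre-plateau) regime.

Phantom images are stadium-bodied masks with a head ellipse, flat
hindquarters, an optional thin angled tail, a textured brightfield layer,
and Gaussian foci at the centers of a 3×3 body grid, scaled so the
mask-mean radiance equals the trajectory value exactly. What the phantoms
do **not** emulate: anatomical realism, photon scattering and depth
attenuation, dorsal/ventral view differences, partial occlusions, or
luciferin kinetics. Passing tests therefore demonstrate the pipeline's
algorithmic correctness on well-posed inputs, not robustness to every
instrument artifact.

The aligned-stack generator used for region tests drives per-image
intensities through two zero-sum (+1, −2, +1) contrasts across the row
bands and column bands, so the leading row- and column-profile principal
components cross zero at the true boundaries; with identical Gaussian
foci the crossing sits within ~1 px of the band boundary. The cohort
generator's `region_factor_foci` option applies the same contrasts at the
focus-weight level.

## Numerical choices and degenerate inputs

* Detection floor 10³ (radiance units) everywhere a log is taken.
* Optimizer tolerances 10⁻¹⁴ (xtol/ftol/gtol); five seeded multi-starts;
  deterministic for a given seed. Rate bounds [0, 12] day⁻¹ for growth/
  relapse, [0, 20] for decay; T_B bounded below by the floor and above by
  the phase's data ceiling (and the junction value, when fixed).
* A phase with fewer than two points is skipped with a flag (possible
  only with user-supplied segmentations — threshold segmentation always
  yields ≥ 2 points per phase); a skipped decay anchors the relapse at
  the observed junction value.
* Residual summaries assign junction points to the earlier phase.
* Empty regions are floored and flagged; empty ROI intersections are NaN.
* `compute_priors` accepts a zero sample standard deviation (identical
  surviving rates); using such a prior for refitting is rejected at call
  time.

## Known limitations

* The decay rate is the hardest of the three to recover: with 3-point
  decay phases at 0.15-decade noise its median relative error is ~12 %
  even for an estimator given the true junction radiance (the acceptance
  suite measures ~11 % for the real pipeline, vs ~8 % for k_growth and
  ~5 % for k_relapse). Slow, baseline-distant decays at few timepoints
  are intrinsically weakly identified.
* Pseudocolor inversion is bounded by 8-bit color quantization (~1.9 %
  over four decades, proportionally more over wider scales) and cannot
  recover radiance below the scale minimum.
* Region demarcation presumes the cohort's profile variance carries
  anatomically structured contrasts; on cohorts without such structure it
  fails with diagnostics rather than inventing a grid.
* Exclusion rates for slanted images depend on the configurable angle
  threshold and cannot be guaranteed to match any particular instrument
  workflow.
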