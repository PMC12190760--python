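# lumiquant

Quantification, phase classification, piecewise kinetic modeling, and
per-anatomical-region analysis of bioluminescent tumor images from
preclinical immunotherapy experiments — with a synthetic phantom generator
so the whole pipeline can be validated end to end without instrument data.

## The problem

Preclinical CAR-T cell studies monitor luciferase-engineered tumors
(e.g. NALM6 B-cell leukemia) in immunodeficient NSG mice with an in-vivo
imaging system: each acquisition is a brightfield photograph plus a
radiance-calibrated luminescence raster covering 1–5 mice. Turning
thousands of such images into comparable tumor-burden trajectories — and
those trajectories into kinetic rates that can be compared across CAR
constructs and doses — is usually done by hand. `lumiquant` automates it:

1. **Imaging** — isolate each mouse, remove the tail, reject slanted
   animals, rescale every mouse to a common height so anatomy aligns
   across the cohort, and compute the average radiance per pixel
   (photons s⁻¹ cm⁻² sr⁻¹ px⁻¹) over the body mask or any region of
   interest. Both calibrated float-TIFF and pseudocolor-overlay
   luminescence dialects are read.
2. **Phases** — segment each radiance series into growth, decay and
   relapse by stepwise ratio thresholds (growth ends just before a drop
   below 75 % of the previous timepoint; decay ends just before a 3-fold
   increase), assigning one of five classes: G, GD, GDR, D, DR.
3. **Kinetics** — fit the piecewise model phase by phase on log₁₀
   radiance, and refit outlier rates at their Gaussian maximum a
   posteriori value under empirical cohort priors.
4. **Regions** — average the aligned stack's rows/columns into per-image
   profiles, run PCA across images, and use the loading curves'
   x-intercepts to demarcate nine anatomical regions (snout, lungs,
   liver, bmL/bmR, …); then classify every region's own trajectory,
   measure divergence from the whole-body class, and correlate regions.
5. **Simulate** — seeded synthetic trajectories, mouse phantoms, and full
   cohort directories with recorded ground truth.

## The model

Growth and relapse phases follow logistic growth; decay is exponential
relaxation toward a baseline burden:

    dT/dt = k T (1 − T/T∞)            (growth with rate k_growth,
                                       relapse with rate k_relapse)
    dT/dt = −k_decay (T − T_B)        (decay)

A full trajectory is parametrized by eight quantities — T₀, k_growth,
t_decay, k_decay, T_B, t_relapse, k_relapse, T∞ — plus the derived
radiance at relapse onset T₁,relapse (the decay curve evaluated at
t_relapse), which makes the piecewise curve continuous at both junctions.
t_decay and t_relapse are fixed at the segmentation's boundary days;
rates are in day⁻¹ and radiances in photons s⁻¹ cm⁻² sr⁻¹ per pixel.

Outlier rates (above 3 day⁻¹, or from two-point phases) are refit by
minimizing `Σ (log₁₀ residual / σ)² + ((k − μ)/s)²` under a Gaussian
prior (μ, s) computed from the cohort's own fitted rates after removing
outliers — defaults μ=0.84, s=0.43 day⁻¹ for k_growth and μ=0.60, s=0.32
day⁻¹ for k_relapse.

## Worked example

```python
import numpy as np
from lumiquant import (RadianceSeries, PriorSpec, segment_phases,
                       fit_trajectory, apply_refits)

days   = np.array([0.0, 3.5, 7.0, 10.5, 14.0, 17.5, 21.0])
values = np.array([1e5, 3e5, 9e5, 2e5, 1e5, 5e5, 2e6])
series = RadianceSeries("demo", days, values)

seg = segment_phases(series)
fit = fit_trajectory(series, seg, floor=1e3, seed=0)
fit = apply_refits(fit, {"k_growth": PriorSpec(0.84, 0.43, 3.0),
                         "k_relapse": PriorSpec(0.60, 0.32, 3.0)})
```

This prints (via `python examples/segment_and_fit.py`):

```
class GDR: growth ends at day 7, relapse starts at day 17.5
k_growth  = 0.331 /day   (initial tumor growth rate)
k_decay   = 0.553 /day   (clearance rate under treatment)
k_relapse = 0.475 /day   (regrowth rate at relapse)
T0 = 9.9e+04, T_B = 8.34e+04, T_inf = 6.96e+06
refit flags: {'k_growth': False, 'k_relapse': False}
log10 residuals: [-0.004  0.009 -0.005  0.     0.001 -0.002  0.002]
```

The radiance rose 9-fold over the first three timepoints (growth at
0.33 day⁻¹), fell under treatment (clearance at 0.55 day⁻¹ toward a
baseline of ~8×10⁴), then jumped ≥3-fold at day 17.5 and regrew at
0.48 day⁻¹ — class GDR. All residuals are within 0.01 decades, so no
rate triggered a prior-constrained refit.

More narrative scripts live in `examples/`:

* `examples/simulate_and_quantify.py` — write a synthetic cohort
  directory and run the imaging stage against its ground truth
  (max quantification error ≈ 2.6 %).
* `examples/regional_analysis.py` — end-to-end nine-region demarcation,
  per-region classification, divergence and correlation.

A thin CLI wraps the same pipeline for batch runs:

```sh
lumiquant simulate --out cohort/ --n-mice 20 --seed 1
lumiquant process  --input cohort/ --out results/
lumiquant fit      --input cohort/ --out results/
lumiquant regions  --input cohort/ --out results/ 
```

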