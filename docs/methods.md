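# Methods

## Model

Under constant laser irradiation the surface temperature of a small tissue
volume is treated as the step response of a first-order thermal system:

    T(t) = T∞ + (T0 − T∞) · exp(−t / τ),   t ≥ 0 (laser-on at t = 0)

with initial temperature `T0` (°C), steady-state temperature `T∞` (°C) and
thermal time constant `τ` (s), the time to cover 1 − e⁻¹ ≈ 63.2% of the span.
This lumps all heat transport into a single exponential mode; it is an
empirical kinetic description, not a bioheat (Pennes-type) PDE model, and is
appropriate exactly to the extent that observed heating curves are
single-exponential — which the fit diagnostics (R², RMSE) report per trace.

Two derived dosimetry metrics compare the gold-nanorod (GNR) injected arm
against saline-injected, laser-irradiated controls at the same wavelength,
both computed on unpaired group means:

* effective temperature enhancement
  `T̃enh = (T_GNR − T_saline) / T_saline · 100` (%), the percent excess of
  group-mean maximum temperature. It divides by a Celsius temperature, so it
  is anchored at the saline temperature scale rather than being a physical
  ratio; it is implemented exactly as defined and guarded by a
  `T_saline > 0` precondition.
* heating efficiency `HE = ΔT_GNR / ΔT_saline` (dimensionless), the ratio of
  group-mean temperature changes, invariant under a common temperature
  offset.

Published one-decimal HE tables are sometimes computed from unrounded group
means, so the ratio of the printed ΔT values can disagree with the printed
HE at the last decimal; `metrics.he_rounding_consistent` flags such rows
instead of matching them.

## Pipeline

1. **ROI extraction** (`roi`). One fixed circular ROI per tumor, 30 px
   diameter by default. Placement is determinized as the pixel attaining the
   global maximum temperature over all frames at/after laser-on (first in
   (frame, row, col) order on ties); the protocol's "encompassing the
   maximum temperature values" does not pin down a frame, and the
   spatiotemporal max is the reproducible reading. If the winner is nearer
   than one radius to an edge, the center is shifted minimally inward so the
   full circle fits — keeping the member-pixel count constant across
   animals rather than clipping the circle. Membership is by pixel-center
   Euclidean distance with inclusive boundary (709 px at diameter 30). Per
   frame the trace records the arithmetic mean and the population SD (a
   descriptive spread over a fixed pixel set, hence no n−1 correction).
2. **Kinetics fit** (`kinetics`). Nonlinear least squares on all samples
   with 0 ≤ t ≤ exposure (pre-exposure baseline excluded), via
   trust-region-reflective descent with the analytic Jacobian.
   Initialization: T0⁰ = first sample, T∞⁰ = mean of the last 5% of samples,
   τ⁰ = the 63.2%-crossing time by linear interpolation (fallback:
   exposure/3); deterministic restarts at 0.5×, 1×, 2× τ⁰ keep the best SSE.
   τ is bounded in (0, 10·exposure]. 95% CIs use the linearized covariance
   `s²(JᵀJ)⁻¹` with `s² = SSres/(n−3)` and the t quantile at n−3 df.
   R² = 1 − SSres/SStot; RMSE uses denominator n (a descriptive residual
   scale; the n−3 variant is a one-line change). Fits are unweighted by
   default because the per-frame SD measures spatial spread across the ROI,
   not the sampling error of the mean; `weighted=True` switches to 1/SD
   weights. Traces whose span is below 1 °C are declared degenerate rather
   than fitted. The normalized heating curve
   `T̃ = (T − Tmin)/(Tmax − Tmin)` uses the observed extrema over the
   exposure window (a robust 1st/99th-percentile option exists for spiky
   data).
3. **Metrics** (`metrics`). Per animal, Tmax is the maximum of the ROI-mean
   trace over the exposure — for monotone first-order heating this is the
   exposure endpoint, but the max is robust to end-of-trace dips — and
   ΔT = Tmax − T(0). Group summaries use sample SDs across animals.
4. **Statistics** (`group_stats`). Two-tailed pooled-variance Student
   t-tests (the named procedure; Welch available behind a flag) on Tmax and
   τ per wavelength, α = 0.05, no multiple-testing correction (none is part
   of the analysis being reproduced). The tumor-volume utility implements
   the modified-ellipsoid caliper formula V = L·W²/2.

## Synthetic data generator

The generator (`synth`) emulates the study design the analysis assumes:
8 groups (808/940/975/1064 nm × GNR/saline), n = 4 animals per group, 90 s
exposure sampled at 6 frames/s. Per animal it draws (T0, T∞, τ) from
group-level normal distributions truncated at physical bounds (τ > 1 s,
T∞ > T0; rejection sampling with a 1000-attempt cap — the published SD of
12.3 s at 940 nm saline admits nonphysical normal draws), evaluates the
first-order model, and adds iid Gaussian noise.

Group defaults are the published statistics: the four saline-arm time
constants and the 940 nm GNR value with their printed SDs; GNR τ at
808/1064 nm from the printed ≈33 s reduction relative to saline and at
975 nm from the printed ≈7 s reduction (SD of the saline arm reused, since
none is printed); T0 = printed Tmax − printed ΔT. Because the printed Tmax
is the 90-s endpoint of a curve still approaching its asymptote, the
steady-state default inverts the model at the endpoint,
`T∞ = (Tmax − T0·e^(−90/τ)) / (1 − e^(−90/τ))`, so simulated endpoint
temperatures match the printed Tmax in expectation. Values not published
anywhere — the 940 nm saline Tmax SD (3 °C), the cross-animal T0 SD
(1 °C), ambient (24 °C) — are tagged `assumed` in the per-group provenance
metadata and are plain config fields.

Noise: the camera model carries a per-pixel SD of 0.7 °C (default), chosen
so that first-order fits of simulated traces leave a mean RMSE near the
0.7 °C average residual that fits of the real traces reported. For
trace-level simulation this SD applies directly to the ROI-mean channel
(`roi_pixel_equivalent = 1` by default; larger values attenuate by √n for
studying averaging effects). Full-frame rendering uses an isotropic
Gaussian hotspot (σ = 12 px at the default 160×120 resolution; 640×480 is a
config option) on a rectangular body footprint over a 24 °C ambient
background, plus per-pixel noise and 0.01 °C quantization — the simplest
spatial model whose ROI mean is an affine function of the first-order curve
and therefore preserves τ exactly. Pre-exposure frames (default 5 s) carry
no heating term and negative times, so baseline handling is exercised.

What the generator does **not** emulate: animal motion and breathing
artifacts, spatially correlated camera noise and vignetting, emissivity
variation across skin, non-exponential late-time behavior from perfusion or
tissue phase change, and beam repositioning. Passing recovery tests
therefore show that the pipeline is correct for data that follow its
assumed model at the study's noise scale, not that the model captures every
feature of real thermographs.

## Determinism and seeding

One root seed expands to per-animal substreams via
`SeedSequence([seed, crc32("wavelength:injection:index")])`, so adding
animals or groups never perturbs existing draws. End-to-end runs are
byte-identical given the same config and seed; the run report embeds the
seed and package version and deliberately no wall-clock timestamp.

## Problem sizes

Default test and example runs use the study-scale design (32 animals,
541-sample traces) and 160×120 frames; replicated checks use 10–100 design
replicates and 300 single-trace replicates, sizes at which the ensemble
properties under test (τ ordering, CI coverage, rejection frequency) are
statistically resolvable on a desktop.

## Known limitations

* The first-order model has no cooling phase; laser-off decay is out of
  scope.
* CI construction is the linearized (Wald-type) interval; profile-likelihood
  intervals would be more faithful for strongly correlated (T∞, τ) at short
  exposures.
* `T̃enh` inherits the Celsius anchoring of its definition; comparisons
  across studies with different baselines should prefer HE.
* ROI placement assumes a still animal (anesthetized); there is no motion
  correction or tumor segmentation.
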