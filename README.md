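# pttherm

Thermal analysis of infrared thermography from plasmonic photothermal
therapy (PTT) experiments, for researchers quantifying laser-induced heating
of tumors with and without gold-nanorod (GNR) photosensitizers.

Given thermograph video stacks (multi-page TIFF, °C per pixel) or
pre-extracted temperature traces, the package:

* locates the hotspot region of interest (ROI, 30-pixel circle by default)
  and reduces each frame to the ROI mean ± SD;
* fits the first-order step response
  `T(t) = T∞ + (T0 − T∞)·exp(−t/τ)` to each heating curve, reporting the
  thermal time constant τ with 95% confidence intervals, R² and RMSE, plus
  the normalized heating curve `T̃ = (T − Tmin)/(Tmax − Tmin)`;
* computes PTT dosimetry metrics per wavelength: group Tmax and ΔT, the
  effective temperature enhancement
  `T̃enh = (T_GNR − T_saline)/T_saline · 100` and the heating efficiency
  `HE = ΔT_GNR / ΔT_saline`;
* compares GNR vs saline arms with two-tailed Student t-tests;
* simulates the whole 8-group study design (4 NIR wavelengths ×
  GNR/saline, n = 4, 6 frames/s, 90 s exposure) — traces or full
  thermograph stacks — so every stage is testable without real recordings.

See `docs/methods.md` for the model, the parameter provenance and the
generator's assumptions.

## Worked example

Run the full pipeline on a simulated study design:

```sh
pttherm run-all --simulate --seed 1 --outdir results
python analysis/03_fit_kinetics.py   # narrative drivers, same library
```

The fit stage prints:

```
fitted 32/32 traces
mean R² = 0.9945  RMSE mean 0.70 °C (range 0.66–0.72)

fitted time constants (s) by group:
                      mean   std
wavelength injection
808        GNR        35.2   1.4
           saline     68.6   1.7
940        GNR        39.6  13.8
           saline     53.7  18.9
975        GNR        30.5   6.0
           saline     39.6   3.4
1064       GNR        36.8   5.1
           saline     65.1   7.3
```

All 32 animals fit cleanly (mean R² > 0.99, residuals ≈ 0.7 °C — the
camera-noise scale), and in every wavelength the GNR arm heats faster
(smaller τ) than the saline controls, with the largest reductions at 808 and
1064 nm. The metrics stage then reports, from the printed group statistics
of the emulated study:

```
   808 nm  T~enh =  30.8%   HE = 1.77
   940 nm  T~enh =   7.8%   HE = 1.21
   975 nm  T~enh =   6.3%   HE = 1.10
  1064 nm  T~enh =  23.2%   HE = 1.54
```

i.e. nanorod injection raises the peak temperature by ~31% at 808 nm and
~23% at 1064 nm but under 10% at 940/975 nm, where endogenous tissue
absorption already heats the controls strongly.

The numbered scripts under `analysis/` run the same stages as a narrative:
`01_simulate` (design simulation), `02_extract_roi` (stack rendering → ROI
recovery), `03_fit_kinetics`, `04_metrics`, `05_group_stats`. A committed
YAML config for the full design is at `examples/run.yaml`.

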