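"""Synthetic thermograph generator emulating the in-vivo study design.

The study irradiated 32 subcutaneous mouse tumors in an 8-group design
(4 NIR wavelengths × {gold-nanorod injected, saline control}, n = 4/group)
for 90 s while recording surface temperature with an IR camera at 6 frames/s.
This module generates data with the statistical structure that design
implies: per-animal first-order heating parameters (T0, T_inf, tau) drawn
from group-level normal distributions (truncated at physical bounds), the
first-order step response as the forward model, and additive Gaussian camera
noise.

Group defaults are seeded from the published group statistics: time
constants per arm, and initial/steady-state temperatures back-computed from
the printed group-mean maximum temperature (Tmax, reached at the 90-s
endpoint of a monotone first-order curve) and temperature change ΔT.
Because the printed Tmax is the 90-s value and not the asymptote, the
steady-state default inverts the first-order model at t = 90 s:

    T_inf = (Tmax - T0 * exp(-90/tau)) / (1 - exp(-90/tau)),  T0 = Tmax - ΔT.

The spatial model for full frames (isotropic Gaussian hotspot on a
rectangular body footprint over ambient background) is the simplest shape
whose ROI mean still follows first-order kinetics; it is a rendering device,
not a tissue model.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pttherm.io import TemperatureTrace, ThermalFrameStack
from pttherm.kinetics import first_order

GNR = "GNR"
SALINE = "saline"

#: Published group statistics driving the defaults. Tmax/ΔT are the printed
#: group means ± SD; tau entries marked provenance "derived" come from the
#: printed reductions relative to the saline arm (≈33 s at 808/1064 nm,
#: ≈7 s at 975 nm), with the saline arm's SD reused. The 940 nm saline Tmax
#: SD and all T0 SDs are not published (provenance "assumed").
PUBLISHED_GROUP_STATS = {
    (808, GNR): dict(tmax=68.0, tmax_sd=2.0, dt=39.0, tau=34.8, tau_sd=1.8,
                     provenance={"tau": "derived", "tau_sd": "assumed", "tmax": "paper", "dt": "paper"}),
    (808, SALINE): dict(tmax=52.0, tmax_sd=1.0, dt=22.0, tau=67.8, tau_sd=1.8,
                        provenance={"tau": "paper", "tau_sd": "paper", "tmax": "paper", "dt": "paper"}),
    (940, GNR): dict(tmax=69.0, tmax_sd=3.0, dt=40.0, tau=35.4, tau_sd=9.8,
                     provenance={"tau": "paper", "tau_sd": "paper", "tmax": "paper", "dt": "paper"}),
    (940, SALINE): dict(tmax=64.0, tmax_sd=3.0, dt=33.0, tau=57.7, tau_sd=12.3,
                        provenance={"tau": "paper", "tau_sd": "paper", "tmax": "paper",
                                    "tmax_sd": "assumed", "dt": "paper"}),
    (975, GNR): dict(tmax=84.0, tmax_sd=9.0, dt=55.0, tau=31.3, tau_sd=5.1,
                     provenance={"tau": "derived", "tau_sd": "assumed", "tmax": "paper", "dt": "paper"}),
    (975, SALINE): dict(tmax=79.0, tmax_sd=3.0, dt=50.0, tau=38.3, tau_sd=5.1,
                        provenance={"tau": "paper", "tau_sd": "paper", "tmax": "paper", "dt": "paper"}),
    (1064, GNR): dict(tmax=69.0, tmax_sd=3.0, dt=40.0, tau=33.9, tau_sd=4.8,
                      provenance={"tau": "derived", "tau_sd": "assumed", "tmax": "paper", "dt": "paper"}),
    (1064, SALINE): dict(tmax=56.0, tmax_sd=1.0, dt=26.0, tau=66.9, tau_sd=4.8,
                         provenance={"tau": "paper", "tau_sd": "paper", "tmax": "paper", "dt": "paper"}),
}

DEFAULT_EXPOSURE_S = 90.0
DEFAULT_T0_SD = 1.0  # °C across animals; not published


@dataclass
class SimGroupParams:
    """Per-group distributions of the first-order heating parameters."""

    wavelength: int
    injection: str
    t0_mean: float
    t0_sd: float
    tinf_mean: float
    tinf_sd: float
    tau_mean: float
    tau_sd: float
    n_animals: int = 4
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.injection not in (GNR, SALINE):
            raise ValueError(f"injection must be {GNR!r} or {SALINE!r}, got {self.injection!r}")
        if self.tinf_mean <= self.t0_mean:
            raise ValueError("tinf_mean must exceed t0_mean (heating)")
        if self.tau_mean <= 0:
            raise ValueError("tau_mean must be positive")
        if min(self.t0_sd, self.tinf_sd, self.tau_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")

    @property
    def group(self) -> tuple[int, str]:
        return (self.wavelength, self.injection)


@dataclass
class CameraModel:
    """IR camera: frame rate, frame geometry and a simple noise model.

    Defaults follow a 6 fps radiometric camera with ±2 °C absolute accuracy;
    per-pixel noise SD defaults to 0.7 °C, the scale of the residuals that
    first-order fits leave on real ROI traces. Frames default to 160×120 for
    desk-scale work; the full 640×480 sensor is a config choice away.
    """

    frame_rate: float = 6.0
    width: int = 160
    height: int = 120
    noise_sd: float = 0.7
    bias: float = 0.0
    quantization_step: float = 0.01

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.noise_sd < 0 or self.quantization_step < 0:
            raise ValueError("noise_sd and quantization_step must be non-negative")


@dataclass
class SceneSpec:
    """Spatial layout of a rendered thermograph scene.

    ``body_temp=None`` uses the sampled per-animal T0 as the in-mask baseline
    so the hotspot-center profile reproduces the sampled heating curve
    exactly. The hotspot sigma default makes the ~0.8 cm beam span a
    plausible pixel extent at the reduced default resolution.
    """

    ambient_temp: float = 24.0
    body_temp: float | None = None
    hotspot_center: tuple[int, int] | None = None  # None → center of the body mask
    hotspot_sigma: float = 12.0
    body_mask: np.ndarray | None = None  # None → centered rectangle, 70% of each dim
    exposure_s: float = DEFAULT_EXPOSURE_S
    pre_exposure_s: float = 5.0

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")
        if self.pre_exposure_s < 0:
            raise ValueError("pre_exposure_s must be non-negative")


def tinf_from_tmax(tmax: float, t0: float, tau: float,
                   exposure_s: float = DEFAULT_EXPOSURE_S) -> float:
    """Steady-state temperature whose first-order curve passes through Tmax at the exposure end."""
    decay = np.exp(-exposure_s / tau)
    return (tmax - t0 * decay) / (1.0 - decay)


def default_paper_params(n_animals: int = 4) -> list[SimGroupParams]:
    """The 8-group study design (4 wavelengths × GNR/saline) at published statistics."""
    groups = []
    for (wl, inj), s in PUBLISHED_GROUP_STATS.items():
        t0 = s["tmax"] - s["dt"]
        tinf = tinf_from_tmax(s["tmax"], t0, s["tau"])
        groups.append(SimGroupParams(
            wavelength=wl, injection=inj,
            t0_mean=t0, t0_sd=DEFAULT_T0_SD,
            tinf_mean=float(tinf), tinf_sd=s["tmax_sd"],
            tau_mean=s["tau"], tau_sd=s["tau_sd"],
            n_animals=n_animals,
            metadata={
                "tmax_printed": s["tmax"], "tmax_sd_printed": s["tmax_sd"],
                "dt_printed": s["dt"], "provenance": dict(s["provenance"]),
            },
        ))
    return groups


MAX_RESAMPLE_ATTEMPTS = 1000


def sample_animal_params(params: SimGroupParams, rng: np.random.Generator) -> tuple[float, float, float]:
    """Draw one animal's (T0, T_inf, tau), truncated at physical bounds.

    Rejection sampling enforces tau > 1 s and T_inf > T0 (the published SDs,
    e.g. 12.3 s, admit nonphysical normal draws); after
    MAX_RESAMPLE_ATTEMPTS rejections an error is raised.
    """
    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        t0 = rng.normal(params.t0_mean, params.t0_sd)
        tinf = rng.normal(params.tinf_mean, params.tinf_sd)
        tau = rng.normal(params.tau_mean, params.tau_sd)
        if tau > 1.0 and tinf > t0:
            return float(t0), float(tinf), float(tau)
    raise RuntimeError(
        f"could not draw physical (T0, T_inf, tau) for group {params.group} "
        f"after {MAX_RESAMPLE_ATTEMPTS} attempts"
    )


def _exposure_times(exposure_s: float, frame_rate: float) -> np.ndarray:
    k = np.arange(int(np.floor(exposure_s * frame_rate)) + 1)
    return k / frame_rate


def simulate_trace(params: SimGroupParams, camera: CameraModel | None = None,
                   exposure_s: float = DEFAULT_EXPOSURE_S, seed=None,
                   roi_pixel_equivalent: int = 1, animal_id: str = "sim") -> TemperatureTrace:
    """Simulate one animal's ROI-mean temperature trace.

    Samples (T0, T_inf, tau) from the group distributions, evaluates the
    first-order step response at t = k / frame_rate over the exposure, and
    adds iid Gaussian noise of SD ``camera.noise_sd / sqrt(roi_pixel_equivalent)``
    to the mean channel. With the defaults (noise_sd 0.7 °C, equivalent
    count 1) the fitted residual scale matches the ~0.7 °C mean RMSE that
    first-order fits leave on real traces. The sampled ground truth is
    stored in ``trace.meta["truth"]``. Deterministic given the seed.
    """
    camera = camera or CameraModel()
    if exposure_s <= 0:
        raise ValueError("exposure_s must be positive")
    rng = np.random.default_rng(seed)
    t0, tinf, tau = sample_animal_params(params, rng)
    times = _exposure_times(exposure_s, camera.frame_rate)
    clean = first_order(times, t0, tinf, tau)
    noise_sd = camera.noise_sd / np.sqrt(roi_pixel_equivalent)
    temp = clean + camera.bias + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 \
        else clean + camera.bias
    return TemperatureTrace(
        times=times, temp_mean=temp,
        temp_sd=np.full_like(times, camera.noise_sd),
        animal_id=animal_id, group=params.group,
        meta={"truth": {"t0": t0, "tinf": tinf, "tau": tau},
              "noise_sd_mean_channel": float(noise_sd)},
    )


def _default_body_mask(camera: CameraModel) -> np.ndarray:
    mask = np.zeros((camera.height, camera.width), dtype=bool)
    r0, r1 = int(0.15 * camera.height), int(0.85 * camera.height)
    c0, c1 = int(0.15 * camera.width), int(0.85 * camera.width)
    mask[r0:r1, c0:c1] = True
    return mask


def simulate_stack(params: SimGroupParams, camera: CameraModel | None = None,
                   scene: SceneSpec | None = None, seed=None,
                   animal_id: str = "sim") -> ThermalFrameStack:
    """Render a full thermograph stack with a Gaussian hotspot over a body footprint.

    Outside the body mask every pixel sits at ambient; inside, the baseline
    (scene.body_temp, or the sampled T0 when None) carries a heating term
    (T(t) − T0) · exp(−r² / 2σ²) centered at the hotspot, plus Gaussian pixel
    noise and quantization. Pre-exposure frames (t < 0) carry no heating
    term. The hotspot-center pixel's temporal profile therefore follows the
    first-order model up to noise and quantization. Ground truth is stashed
    in a ``truth`` attribute on the returned stack.
    """
    camera = camera or CameraModel()
    scene = scene or SceneSpec()
    rng = np.random.default_rng(seed)
    t0, tinf, tau = sample_animal_params(params, rng)

    mask = scene.body_mask if scene.body_mask is not None else _default_body_mask(camera)
    if mask.shape != (camera.height, camera.width):
        raise ValueError(f"body_mask shape {mask.shape} does not match camera "
                         f"frame {(camera.height, camera.width)}")
    if scene.hotspot_center is not None:
        center = scene.hotspot_center
    else:
        rows, cols = np.nonzero(mask)
        center = (int(round(rows.mean())), int(round(cols.mean())))
    if not (0 <= center[0] < camera.height and 0 <= center[1] < camera.width
            and mask[center]):
        raise ValueError(f"hotspot center {center} lies outside the body mask")

    base = scene.body_temp if scene.body_temp is not None else t0
    # total frame count = floor(total duration * rate): pre frames at t < 0,
    # then exposure frames at t = k/rate for k = 0..floor(exposure*rate)-1
    n_pre = int(np.floor(scene.pre_exposure_s * camera.frame_rate))
    n_exp = int(np.floor(scene.exposure_s * camera.frame_rate))
    exp_times = np.arange(n_exp) / camera.frame_rate

    rr, cc = np.mgrid[0:camera.height, 0:camera.width]
    r2 = (rr - center[0]) ** 2.0 + (cc - center[1]) ** 2.0
    gauss = np.exp(-r2 / (2.0 * scene.hotspot_sigma ** 2))

    heating = first_order(exp_times, t0, tinf, tau) - t0  # 0 at laser-on
    amplitudes = np.concatenate([np.zeros(n_pre), heating])

    frames = np.where(mask, base, scene.ambient_temp)[None, :, :] \
        + amplitudes[:, None, None] * (gauss * mask)[None, :, :] + camera.bias
    if camera.noise_sd > 0:
        frames = frames + rng.normal(0.0, camera.noise_sd, size=frames.shape)
    if camera.quantization_step > 0:
        frames = np.round(frames / camera.quantization_step) * camera.quantization_step

    stack = ThermalFrameStack(
        frames=frames.astype(np.float64),
        frame_period_s=1.0 / camera.frame_rate,
        laser_on_index=n_pre,
        source_id=animal_id,
    )
    stack.truth = {"t0": t0, "tinf": tinf, "tau": tau, "hotspot_center": center,
                   "baseline": float(base)}
    return stack


def animal_seed(root_seed: int, wavelength: int, injection: str, index: int) -> np.random.SeedSequence:
    """Stable per-animal random substream: adding animals or groups never
    perturbs existing draws."""
    key = zlib.crc32(f"{wavelength}:{injection}:{index}".encode())
    return np.random.SeedSequence([int(root_seed), key])


def simulate_design(groups: list[SimGroupParams] | None = None,
                    camera: CameraModel | None = None,
                    exposure_s: float = DEFAULT_EXPOSURE_S,
                    seed: int = 0,
                    roi_pixel_equivalent: int = 1) -> tuple[list[TemperatureTrace], pd.DataFrame]:
    """Simulate traces for a whole design; returns (traces, ground-truth manifest)."""
    groups = groups if groups is not None else default_paper_params()
    camera = camera or CameraModel()
    traces, records = [], []
    for g in groups:
        for i in range(g.n_animals):
            aid = f"{g.wavelength}nm_{g.injection}_{i + 1:02d}"
            tr = simulate_trace(
                g, camera, exposure_s,
                seed=animal_seed(seed, g.wavelength, g.injection, i),
                roi_pixel_equivalent=roi_pixel_equivalent, animal_id=aid,
            )
            traces.append(tr)
            records.append({"animal_id": aid, "wavelength": g.wavelength,
                            "injection": g.injection, **tr.meta["truth"]})
    return traces, pd.DataFrame.from_records(records)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Write the simulated ground-truth parameters as JSON (for recovery tests)."""
    Path(path).write_text(json.dumps(manifest.to_dict(orient="records"), indent=1))
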