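"""Derived thermal statistics for photothermal-therapy dosimetry.

Per animal: maximum ROI-mean temperature (Tmax) over the laser exposure and
the temperature change ΔT = Tmax − T(0). Per wavelength, comparing the
nanorod-injected arm against the saline-irradiated controls:

* effective temperature enhancement, the percent excess of the GNR-group mean
  Tmax over the saline-group mean Tmax,

      T~enh = (Ti − TPBS,i) / TPBS,i · 100,

  where both temperatures are in °C — the formula is anchored at the Celsius
  saline temperature by construction (not an absolute scale), so it is only
  meaningful for TPBS > 0;

* heating efficiency, the dimensionless ratio of group-mean temperature
  changes HE = ΔT_GNR / ΔT_saline.

Group aggregation uses unpaired group means: animals are not paired across
injection arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pttherm.io import TemperatureTrace

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    """Mean ± SD of per-animal endpoints within one (wavelength, injection) group."""

    wavelength: int
    injection: str
    tmax_mean: float
    tmax_sd: float
    delta_t_mean: float
    delta_t_sd: float
    tau_mean: float
    tau_sd: float
    n: int


@dataclass
class EnhancementMetrics:
    """Per-wavelength GNR-vs-saline comparison (Table-2-style quantities)."""

    wavelength: int
    t_enh: float       # effective temperature enhancement, percent
    he: float          # heating efficiency, dimensionless
    t_gnr: float       # GNR group mean Tmax, °C
    t_pbs: float       # saline group mean Tmax, °C
    dt_gnr: float      # GNR group mean ΔT, °C
    dt_saline: float   # saline group mean ΔT, °C


def animal_thermal_summary(trace: TemperatureTrace,
                           exposure_s: float | None = None) -> tuple[float, float, float]:
    """Return (tmax, t_initial, delta_t) for one animal.

    tmax is the maximum ROI-mean temperature over t ∈ [0, exposure];
    t_initial the temperature at the sample nearest t = 0; ΔT their
    difference. The max (not the endpoint) is used so an end-of-trace dip
    does not understate the peak.
    """
    win = trace.window(0.0, exposure_s)
    if len(win) == 0:
        raise ValueError("no samples in the exposure window")
    tmax = float(win.temp_mean.max())
    t_initial = float(win.temp_mean[np.argmin(np.abs(win.times))])
    return tmax, t_initial, tmax - t_initial


def effective_temperature_enhancement(t_gnr: float, t_pbs: float) -> float:
    """Percent excess of the GNR-group mean Tmax over the saline-group mean Tmax."""
    if t_pbs <= 0:
        raise ValueError(
            f"saline mean Tmax must be positive (got {t_pbs} °C); the enhancement "
            "formula is anchored at the saline Celsius temperature"
        )
    return (t_gnr - t_pbs) / t_pbs * 100.0


def heating_efficiency(dt_gnr: float, dt_saline: float) -> float:
    """Ratio of GNR to saline group-mean temperature change at one wavelength."""
    if dt_saline <= 0:
        raise ValueError(f"saline ΔT must be positive (got {dt_saline} °C)")
    return dt_gnr / dt_saline


def he_rounding_consistent(dt_gnr: float, dt_saline: float, reported_he: float) -> bool:
    """Check whether a reported 1-decimal HE matches the ratio of the given ΔT values.

    Published tables sometimes compute HE from unrounded group means, so the
    ratio of the printed (rounded) ΔT values can disagree with the printed HE
    at the last decimal. This predicate flags such rows.
    """
    return round(heating_efficiency(dt_gnr, dt_saline), 1) == round(reported_he, 1)


def summarize_groups(per_animal: pd.DataFrame) -> tuple[list[GroupSummary], list[EnhancementMetrics]]:
    """Aggregate per-animal endpoints into group summaries and enhancement metrics.

    ``per_animal`` needs columns: animal_id, wavelength, injection, tmax,
    delta_t, tau (tau may be NaN for non-converged fits; it is excluded from
    the tau mean/SD). Enhancement metrics are emitted only for wavelengths
    present in both injection arms; missing arms are logged and skipped.
    SDs are sample SDs across animals (0 for single-animal groups, with a
    warning).
    """
    required = {"animal_id", "wavelength", "injection", "tmax", "delta_t", "tau"}
    missing = required - set(per_animal.columns)
    if missing:
        raise ValueError(f"per-animal table is missing columns {sorted(missing)}")

    summaries: list[GroupSummary] = []
    for (wl, inj), sub in per_animal.groupby(["wavelength", "injection"], sort=True):
        n = len(sub)
        if n == 1:
            logger.warning("group (%s nm, %s) has a single animal; SDs set to 0", wl, inj)
        def _sd(x: pd.Series) -> float:
            return float(x.std(ddof=1)) if len(x.dropna()) > 1 else 0.0
        tau = sub["tau"].dropna()
        summaries.append(GroupSummary(
            wavelength=int(wl), injection=str(inj),
            tmax_mean=float(sub["tmax"].mean()), tmax_sd=_sd(sub["tmax"]),
            delta_t_mean=float(sub["delta_t"].mean()), delta_t_sd=_sd(sub["delta_t"]),
            tau_mean=float(tau.mean()) if len(tau) else np.nan,
            tau_sd=_sd(tau), n=n,
        ))

    by_group = {(s.wavelength, s.injection): s for s in summaries}
    enhancements: list[EnhancementMetrics] = []
    for wl in sorted({s.wavelength for s in summaries}):
        gnr = by_group.get((wl, "GNR"))
        pbs = by_group.get((wl, "saline"))
        if gnr is None or pbs is None:
            logger.warning("wavelength %s nm lacks a %s arm; enhancement skipped",
                           wl, "GNR" if gnr is None else "saline")
            continue
        enhancements.append(EnhancementMetrics(
            wavelength=wl,
            t_enh=effective_temperature_enhancement(gnr.tmax_mean, pbs.tmax_mean),
            he=heating_efficiency(gnr.delta_t_mean, pbs.delta_t_mean),
            t_gnr=gnr.tmax_mean, t_pbs=pbs.tmax_mean,
            dt_gnr=gnr.delta_t_mean, dt_saline=pbs.delta_t_mean,
        ))
    return summaries, enhancements
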