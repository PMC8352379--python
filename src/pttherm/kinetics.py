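"""First-order step-response fitting of laser heating curves.

The tumor-surface temperature under constant laser irradiation is modeled as
the step response of a first-order system,

    T(t) = T_inf + (T0 - T_inf) * exp(-t / tau),

where T0 is the initial temperature, T_inf the steady-state temperature and
tau the thermal time constant (time to reach 1 - 1/e ≈ 63.2% of the span).
Estimation is (optionally weighted) nonlinear least squares with an analytic
Jacobian; 95% confidence intervals come from the linearized covariance of the
estimates. The module also computes the normalized heating curve

    T~(t) = (T(t) - Tmin) / (Tmax - Tmin),

used to compare heating kinetics across groups on a common [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from pttherm.io import TemperatureTrace

__all__ = [
    "FirstOrderFit",
    "NormalizedTrace",
    "FitOptions",
    "first_order",
    "fit_first_order",
    "normalized_temperature",
    "predict",
]


def first_order(t: np.ndarray, t0: float, tinf: float, tau: float) -> np.ndarray:
    """Evaluate the first-order step response at times t (s)."""
    return tinf + (t0 - tinf) * np.exp(-np.asarray(t, dtype=float) / tau)


@dataclass
class FitOptions:
    """Options controlling the first-order fit.

    span_floor_C: minimum observed temperature span; below it the trace is
        declared degenerate and no fit is attempted.
    exposure_s: end of the fit window. Only samples with 0 ≤ t ≤ exposure_s
        are fitted (pre-exposure baseline excluded). None fits all t ≥ 0.
    weighted: weight residuals by 1/temp_sd (per-frame spatial SD). Off by
        default: the per-frame SD describes spatial spread over the ROI, not
        the measurement error of the mean.
    """

    span_floor_C: float = 1.0
    exposure_s: float | None = None
    weighted: bool = False
    tau_restart_factors: tuple[float, ...] = (1.0, 0.5, 2.0)


@dataclass
class FirstOrderFit:
    """Estimated (T0, T_inf, tau) with 95% CIs and fit diagnostics."""

    t0_hat: float = np.nan
    tinf_hat: float = np.nan
    tau_hat: float = np.nan
    ci95: dict = field(default_factory=dict)  # param -> (low, high)
    r_squared: float = np.nan
    rmse: float = np.nan
    n_points: int = 0
    converged: bool = False
    reason: str = ""

    @property
    def sse(self) -> float:
        return self.rmse ** 2 * self.n_points if np.isfinite(self.rmse) else np.nan


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Spec'd initialization: endpoints for T0/T_inf, 63.2%-crossing for tau."""
    t0_0 = y[0]
    n_tail = max(1, int(round(0.05 * len(y))))
    tinf_0 = float(np.mean(y[-n_tail:]))
    target = t0_0 + (1.0 - np.exp(-1.0)) * (tinf_0 - t0_0)
    tau_0 = None
    if tinf_0 > t0_0:
        above = np.flatnonzero(y >= target)
        above = above[above > 0] if above.size and above[0] == 0 else above
        if above.size:
            k = above[0]
            y0, y1 = y[k - 1], y[k]
            if y1 != y0:  # linear interpolation to the crossing
                tau_0 = t[k - 1] + (target - y0) / (y1 - y0) * (t[k] - t[k - 1])
            else:
                tau_0 = t[k]
    if tau_0 is None or tau_0 <= 0:
        tau_0 = t[-1] / 3.0
    return float(t0_0), float(tinf_0), float(tau_0)


def _residuals_and_jac(t: np.ndarray, y: np.ndarray, w: np.ndarray):
    def residuals(p):
        t0, tinf, tau = p
        return (first_order(t, t0, tinf, tau) - y) * w

    def jac(p):
        t0, tinf, tau = p
        e = np.exp(-t / tau)
        J = np.empty((len(t), 3))
        J[:, 0] = e                                   # d/dT0
        J[:, 1] = 1.0 - e                             # d/dT_inf
        J[:, 2] = (t0 - tinf) * e * t / tau ** 2      # d/dtau
        return J * w[:, None]

    return residuals, jac


def fit_first_order(trace: TemperatureTrace, options: FitOptions | None = None) -> FirstOrderFit:
    """Fit the first-order step response to a temperature trace.

    Uses derivative-based least squares with deterministic restarts from
    scaled initial time constants; returns converged=False (never raises) for
    degenerate spans or optimizer failure.
    """
    opts = options or FitOptions()
    win = trace.window(0.0, opts.exposure_s)
    t, y = win.times, win.temp_mean
    n = len(t)
    if n < 5:
        return FirstOrderFit(n_points=n, converged=False, reason="fewer than 5 points with t >= 0")
    span = float(y.max() - y.min())
    if span < opts.span_floor_C:
        return FirstOrderFit(n_points=n, converged=False, reason="degenerate span")

    if opts.weighted:
        sd = np.where(win.temp_sd > 0, win.temp_sd, np.nanmax([win.temp_sd.max(), 1e-6]))
        w = 1.0 / sd
    else:
        w = np.ones(n)

    residuals, jac = _residuals_and_jac(t, y, w)
    t0_0, tinf_0, tau_0 = _initial_guess(t, y)
    tau_max = 10.0 * t[-1]
    lower = np.array([-np.inf, -np.inf, 1e-9])
    upper = np.array([np.inf, np.inf, tau_max])

    best = None
    for factor in opts.tau_restart_factors:
        x0 = np.array([t0_0, tinf_0, np.clip(tau_0 * factor, 1e-6, tau_max)])
        try:
            res = optimize.least_squares(
                residuals, x0, jac=jac, bounds=(lower, upper), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return FirstOrderFit(n_points=n, converged=False, reason="optimizer failed to converge")

    t0_hat, tinf_hat, tau_hat = best.x
    model = first_order(t, *best.x)
    resid = y - model
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(ss_res / n))

    # linearized covariance: cov = s^2 (J'J)^-1 with s^2 = SSres/(n - 3)
    ci95 = {}
    dof = n - 3
    if dof > 0:
        J = jac(best.x)
        try:
            cov = np.linalg.inv(J.T @ J) * (ss_res / dof)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            tq = stats.t.ppf(0.975, dof)
            for name, est, s in zip(("t0", "tinf", "tau"), best.x, se):
                ci95[name] = (float(est - tq * s), float(est + tq * s))
        except np.linalg.LinAlgError:
            pass

    return FirstOrderFit(
        t0_hat=float(t0_hat), tinf_hat=float(tinf_hat), tau_hat=float(tau_hat),
        ci95=ci95, r_squared=r_squared, rmse=rmse, n_points=n, converged=True,
    )


def predict(fit: FirstOrderFit, times: np.ndarray) -> np.ndarray:
    """Forward-evaluate a converged fit at the requested times."""
    if not fit.converged:
        raise ValueError(f"cannot predict from a non-converged fit ({fit.reason})")
    return first_order(np.asarray(times, dtype=float), fit.t0_hat, fit.tinf_hat, fit.tau_hat)


@dataclass
class NormalizedTrace:
    """Heating curve rescaled to [0, 1] by the observed extrema."""

    times: np.ndarray
    t_tilde: np.ndarray
    tmin: float
    tmax: float


def normalized_temperature(trace: TemperatureTrace, exposure_s: float | None = None,
                           robust: bool = False) -> NormalizedTrace:
    """Normalize a trace to T~ = (T - Tmin)/(Tmax - Tmin) over the exposure window.

    Tmin/Tmax are the observed extrema of the window (robust=True uses the
    1st/99th percentiles instead, for traces with spiky noise).
    """
    win = trace.window(0.0, exposure_s)
    if len(win) < 2:
        raise ValueError("need at least 2 points in the exposure window")
    y = win.temp_mean
    if robust:
        tmin, tmax = np.percentile(y, [1.0, 99.0])
    else:
        tmin, tmax = float(y.min()), float(y.max())
    if tmax <= tmin:
        raise ValueError("zero temperature span; cannot normalize")
    return NormalizedTrace(
        times=win.times,
        t_tilde=(y - tmin) / (tmax - tmin),
        tmin=float(tmin),
        tmax=float(tmax),
    )
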