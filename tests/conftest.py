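import numpy as np
import pytest

from pttherm.io import TemperatureTrace
from pttherm.kinetics import first_order
from pttherm.synth import CameraModel, SceneSpec, default_paper_params


@pytest.fixture
def paper_groups():
    """The 8-group study design at published statistics."""
    return default_paper_params()


@pytest.fixture
def quiet_camera():
    """Noise-free, unquantized camera for exact-value checks."""
    return CameraModel(noise_sd=0.0, quantization_step=0.0)


@pytest.fixture
def make_trace():
    """Factory for first-order traces, optionally with seeded Gaussian noise."""

    def _make(t0=30.0, tinf=70.0, tau=40.0, exposure_s=90.0, frame_rate=6.0,
              noise_sd=0.0, seed=0, **kwargs):
        t = np.arange(int(np.floor(exposure_s * frame_rate)) + 1) / frame_rate
        y = first_order(t, t0, tinf, tau)
        if noise_sd > 0:
            y = y + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
        return TemperatureTrace(t, y, np.zeros_like(t), **kwargs)

    return _make


def grid_search_oracle(times, temps, tau_lo=1.0, tau_hi=200.0, tau_step=0.01):
    """Separable brute-force fit of T(t) = a + b * exp(-t/tau).

    For each tau on a dense grid the conditionally-linear (a, b) subproblem
    is solved in closed form from the normal equations; returns the smallest
    SSE and its (t0, tinf, tau). Independent of the package's optimizer.
    """
    t = np.asarray(times, float)
    y = np.asarray(temps, float)
    taus = np.arange(tau_lo, tau_hi + tau_step / 2, tau_step)
    E = np.exp(-t[None, :] / taus[:, None])          # (K, n)
    n = len(t)
    Se = E.sum(axis=1)
    See = (E * E).sum(axis=1)
    Sy = y.sum()
    Syy = float(y @ y)
    Sey = E @ y
    det = n * See - Se ** 2
    b = (n * Sey - Se * Sy) / det
    a = (Sy - b * Se) / n
    sse = Syy + n * a ** 2 + b ** 2 * See + 2 * a * b * Se - 2 * a * Sy - 2 * b * Sey
    k = int(np.argmin(sse))
    tinf = a[k]
    t0 = a[k] + b[k]
    return float(sse[k]), (float(t0), float(tinf), float(taus[k]))
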