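"""Generative pooling simulations.

These build the pooled-model predictions constructively — by superposing
shifted, Gaussian-weighted scale-invariant inputs on a numerical grid — and
serve as independent checks of the closed forms in :mod:`poolsi.core`.

By default input positions sit on a deterministic grid spanning +/-4 pooling
SDs with Gaussian weights; passing a ``seed`` draws them at random from the
pooling Gaussian instead (Monte Carlo flavour, equal weights).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .core import si_ori_bandwidth, si_rf_width, si_sf_bandwidth
from .params import PoolingParams, ScaleInvarianceParams

__all__ = [
    "simulate_spatial_pooling",
    "simulate_phase_pooling",
    "simulate_spectral_pooling",
]

_DEF_SI = ScaleInvarianceParams()


def _input_positions(sigma_pool: float, n_inputs: int, seed=None):
    """Input centre offsets and weights for the pooling window."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    if sigma_pool == 0.0 or n_inputs == 1:
        return np.zeros(1), np.ones(1)
    if seed is not None:
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.0, sigma_pool, n_inputs)
        w = np.full(n_inputs, 1.0 / n_inputs)
    else:
        pos = np.linspace(-4 * sigma_pool, 4 * sigma_pool, n_inputs)
        w = np.exp(-0.5 * (pos / sigma_pool) ** 2)
        w /= w.sum()
    return pos, w


def _gaussian_profile_width(x: np.ndarray, y: np.ndarray) -> float:
    """1-sigma width of a nonnegative profile by least-squares Gaussian fit."""
    y = np.asarray(y, float)
    area = np.trapezoid(y, x)
    mu0 = np.trapezoid(x * y, x) / area
    sd0 = np.sqrt(max(np.trapezoid((x - mu0) ** 2 * y, x) / area, 1e-12))

    def g(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(g, x, y, p0=[y.max(), mu0, sd0], maxfev=5000)
    return abs(popt[2])


def simulate_spatial_pooling(
    f_o: float,
    pool: PoolingParams,
    si: ScaleInvarianceParams = _DEF_SI,
    n_inputs: int = 101,
    seed=None,
    step: float = 0.01,
) -> float:
    """Width (deg) of the superposed envelope of pooled SI Gabor energies.

    Shifted SI envelopes (Gaussians of width 1/(alpha*f_o)) are weighted by
    the retinotopic pooling Gaussian and summed; the fitted width of the
    output converges to sqrt(sigma_x,si^2 + sigma_hx^2) as the sampling is
    refined.
    """
    if step <= 0:
        raise ValueError("grid step must be positive")
    sx = float(si_rf_width(f_o, si))
    pos, w = _input_positions(pool.sigma_hx, n_inputs, seed)
    extent = 5.0 * (sx + pool.sigma_hx) + step
    x = np.arange(-extent, extent, step)
    envelope = (w[:, None] * np.exp(-0.5 * ((x[None, :] - pos[:, None]) / sx) ** 2)).sum(0)
    return _gaussian_profile_width(x, envelope)


def simulate_phase_pooling(
    f_o: float,
    pool: PoolingParams,
    phase_mode: str = "D",
    n_inputs: int = 201,
    seed=None,
    n_phase: int = 720,
) -> float:
    """F1/F0 of a cell summing half-wave-rectified, phase-shifted SI inputs.

    Each input is a simple cell whose response to a grating of phase ``phi``
    is the rectified cosine of the phase difference; input ``i`` at
    retinotopic offset ``x_i`` carries absolute phase ``2*pi*f_o*D*x_i``.
    ``phase_mode`` selects D: 'relative' -> 1, 'absolute' -> 0, 'D' -> pool.D.
    The resulting F1/F0 matches pi*exp(-(sigma_hx*2*pi*f_o*D)^2/2).
    """
    if f_o < 0:
        raise ValueError("f_o must be >= 0")
    D = {"relative": 1.0, "absolute": 0.0, "D": pool.D}[phase_mode]
    pos, w = _input_positions(pool.sigma_hx, n_inputs, seed)
    phases = 2.0 * np.pi * f_o * D * pos  # absolute phase of each input
    phi = np.linspace(0.0, 2.0 * np.pi, n_phase, endpoint=False)
    resp = (w[:, None] * np.maximum(np.cos(phi[None, :] - phases[:, None]), 0.0)).sum(0)
    f0 = resp.mean()
    # peak-to-peak amplitude of the fundamental component
    f1 = 2.0 * np.abs(np.mean(resp * np.exp(-1j * phi))) * 2.0
    return float(f1 / f0)


def simulate_spectral_pooling(
    f_o: float,
    pool: PoolingParams,
    si: ScaleInvarianceParams = _DEF_SI,
    n_inputs: int = 101,
    seed=None,
    step: float = 0.005,
) -> tuple[float, float]:
    """(SF bandwidth cyc/deg, orientation bandwidth deg) from 2D spectral pooling.

    SI spectral energy blobs (radial width sigma_f,si(f_o), tangential width
    sigma_f,si/A) are superposed under an isotropic 2D Gaussian pooling
    window of width sigma_hf centred at radius f_o. Because both the blob
    and the pooling window are axis-aligned Gaussians the superposition
    separates into independent radial and tangential 1D profiles, which are
    built on a fine grid and fit. The measured radial width and
    atan(tangential width / f_o) converge to the closed forms.
    """
    if f_o <= 0:
        raise ValueError("f_o must be > 0")
    s_rad = float(si_sf_bandwidth(f_o, si))
    s_tan = s_rad / si.aspect_ratio
    if pool.sigma_hf == 0.0:
        return s_rad, si_ori_bandwidth(si)

    widths = []
    for s_blob in (s_rad, s_tan):
        pos, w = _input_positions(pool.sigma_hf, n_inputs, seed)
        extent = 5.0 * (s_blob + pool.sigma_hf) + step
        x = np.arange(-extent, extent, step)
        profile = (
            w[:, None] * np.exp(-0.5 * ((x[None, :] - pos[:, None]) / s_blob) ** 2)
        ).sum(0)
        widths.append(_gaussian_profile_width(x, profile))
    sf_bw, tan_bw = widths
    ori_bw = float(np.degrees(np.arctan(tan_bw / f_o)))
    return float(sf_bw), ori_bw
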