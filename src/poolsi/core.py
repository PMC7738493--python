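"""Closed-form scale-invariance and pooled-scale-invariance predictions.

The scale-invariant (SI) Gabor family links every tuning parameter to the
preferred spatial frequency ``f_o`` (cyc/deg):

    sigma_x,si(f_o)  = 1 / (alpha * f_o)          RF width (deg)
    sigma_f,si(f_o)  = alpha * f_o / (2*pi)       linear SF bandwidth (cyc/deg)
    sigma_logf,si    = log2(1 + alpha/(2*pi))     log SF bandwidth (octaves)
    sigma_theta,si   = atan(alpha / (2*pi*A))     orientation bandwidth (deg)

Pooled scale invariance models the measured tuning of superficial V1 neurons
as a Gaussian-weighted integration over a population of SI inputs. Pooling
over retinotopy (window sigma_hx, deg) widens the RF envelope and, combined
with the absolute-phase progression rate D, attenuates phase selectivity;
isotropic pooling in the 2D spectral plane (window sigma_hf, cyc/deg) widens
SF bandwidth and, near the spectral origin, orientation bandwidth:

    sigma_x,p^2   = sigma_x,si^2(f_o) + sigma_hx^2
    F1/F0         = pi * exp(-(sigma_hx * 2*pi * f_o * D)^2 / 2)
    sigma_f,p^2   = sigma_f,si^2(f_o) + sigma_hf^2
    sigma_logf,p  = log2((f_o + sigma_f,p)/f_o)
    sigma_th,p    = atan(sqrt(sigma_f,si^2/A^2 + sigma_hf^2) / f_o)

All functions are vectorized over ``f_o``.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelPrediction, PoolingParams, ScaleInvarianceParams

__all__ = [
    "si_rf_width",
    "si_sf_bandwidth",
    "si_log_bandwidth",
    "si_ori_bandwidth",
    "pooled_rf_width",
    "pooled_f1f0",
    "pooled_sf_bandwidth",
    "pooled_log_bandwidth",
    "pooled_ori_bandwidth",
    "predict",
]

_DEF_SI = ScaleInvarianceParams()


def _check_fo(f_o, allow_zero: bool = False):
    f_o = np.asarray(f_o, dtype=float)
    bad = (f_o < 0) if allow_zero else (f_o <= 0)
    if np.any(bad):
        raise ValueError("preferred SF f_o must be positive")
    return f_o


def si_rf_width(f_o, params: ScaleInvarianceParams = _DEF_SI):
    """Scale-invariant RF width (deg): 1/(alpha*f_o)."""
    f_o = _check_fo(f_o)
    return 1.0 / (params.alpha * f_o)


def si_sf_bandwidth(f_o, params: ScaleInvarianceParams = _DEF_SI):
    """Scale-invariant linear SF bandwidth (cyc/deg): alpha*f_o/(2*pi).

    With alpha = pi this is f_o/2. Accepts f_o = 0 as a limiting case.
    """
    f_o = _check_fo(f_o, allow_zero=True)
    return params.alpha * f_o / (2.0 * np.pi)


def si_log_bandwidth(f_o, params: ScaleInvarianceParams = _DEF_SI):
    """Scale-invariant log SF bandwidth (octaves): log2(1 + alpha/(2*pi)).

    Constant in f_o; at alpha = pi it evaluates to log2(1.5) ~ 0.585 oct.
    """
    f_o = _check_fo(f_o)
    return np.broadcast_to(
        np.log2(1.0 + params.alpha / (2.0 * np.pi)), f_o.shape
    ).copy() if f_o.ndim else float(np.log2(1.0 + params.alpha / (2.0 * np.pi)))


def si_ori_bandwidth(params: ScaleInvarianceParams = _DEF_SI) -> float:
    """Scale-invariant orientation bandwidth (deg): atan(alpha/(2*pi*A)).

    Independent of f_o; ~14 deg at alpha = pi, A = 2.
    """
    return math.degrees(math.atan(params.alpha / (2.0 * np.pi * params.aspect_ratio)))


def pooled_rf_width(f_o, si: ScaleInvarianceParams = _DEF_SI,
                    pool: PoolingParams = PoolingParams()):
    """Pooled RF width (deg): sqrt(sigma_x,si^2 + sigma_hx^2).

    Convolution of the SI envelope with the retinotopic pooling window adds
    variances; decreasing in f_o with asymptote sigma_hx.
    """
    return np.hypot(si_rf_width(f_o, si), pool.sigma_hx)


def pooled_f1f0(f_o, pool: PoolingParams):
    """Phase selectivity F1/F0: pi * exp(-(sigma_hx*2*pi*f_o*D)^2/2).

    A Gaussian in f_o centred at zero with SD (sigma_hx*2*pi*D)^-1; equals pi
    (half-wave-rectified simple cell) at f_o = 0 or D = 0.
    """
    f_o = _check_fo(f_o, allow_zero=True)
    arg = pool.sigma_hx * 2.0 * np.pi * f_o * pool.D
    return np.pi * np.exp(-0.5 * arg**2)


def pooled_sf_bandwidth(f_o, si: ScaleInvarianceParams = _DEF_SI,
                        pool: PoolingParams = PoolingParams()):
    """Pooled linear SF bandwidth (cyc/deg): sqrt(sigma_f,si^2 + sigma_hf^2)."""
    _check_fo(f_o)
    return np.hypot(si_sf_bandwidth(f_o, si), pool.sigma_hf)


def pooled_log_bandwidth(f_o, si: ScaleInvarianceParams = _DEF_SI,
                         pool: PoolingParams = PoolingParams()):
    """Pooled log SF bandwidth (octaves): log2((f_o + sigma_f,p)/f_o).

    Strictly decreasing in f_o for sigma_hf > 0, converging to the constant
    SI value from above.
    """
    f_o = _check_fo(f_o)
    return np.log2((f_o + pooled_sf_bandwidth(f_o, si, pool)) / f_o)


def pooled_ori_bandwidth(f_o, si: ScaleInvarianceParams = _DEF_SI,
                         pool: PoolingParams = PoolingParams()):
    """Pooled orientation bandwidth (deg).

    atan(sqrt(sigma_f,si^2/A^2 + sigma_hf^2)/f_o): the numerator is the
    tangential (orientation-arc) width of the pooled spectral energy. Uses
    the sigma_hf fitted from SF bandwidth; no extra free parameter.
    """
    f_o = _check_fo(f_o)
    tangential = np.hypot(si_sf_bandwidth(f_o, si) / si.aspect_ratio, pool.sigma_hf)
    return np.degrees(np.arctan(tangential / f_o))


def f1f0_gaussian_sd(pool: PoolingParams) -> float:
    """SD (cyc/deg) of the F1/F0-vs-f_o Gaussian: (sigma_hx * 2*pi * D)^-1.

    With sigma_hx = 0.24 deg and D = 1 (constant relative phase) this is
    0.66 cyc/deg.
    """
    if pool.sigma_hx <= 0 or pool.D <= 0:
        raise ValueError("requires sigma_hx > 0 and D > 0")
    return 1.0 / (pool.sigma_hx * 2.0 * np.pi * pool.D)


def predict(f_o: float, si: ScaleInvarianceParams = _DEF_SI,
            pool: PoolingParams = PoolingParams()) -> ModelPrediction:
    """All pooled-model predictions for one preferred SF."""
    return ModelPrediction(
        f_o=float(f_o),
        rf_width=float(pooled_rf_width(f_o, si, pool)),
        sf_bw_linear=float(pooled_sf_bandwidth(f_o, si, pool)),
        sf_bw_log=float(pooled_log_bandwidth(f_o, si, pool)),
        ori_bw=float(pooled_ori_bandwidth(f_o, si, pool)),
        f1f0=float(pooled_f1f0(f_o, pool)),
    )
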