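"""Reduce response kernels to per-neuron tuning parameters.

The reduction follows the measurement conventions of the imaging analysis:
kernels are smoothed along time (Gaussian, sigma 50 ms) and sliced at the
peak-response frame; orientation tuning is a four-parameter Gaussian fit
after circularly centring the peak, with bandwidth taken as the half-width
at 61% of the amplitude (equal to the fitted sigma for a Gaussian to within
1%); SF tuning is a five-parameter difference-of-Gaussians on the linear SF
axis with the same 61% half-width rule; phase tuning is a fixed-period sine
fit giving F1 (peak-to-peak) over F0 (mean); bar kernels give the RF width
from a Gaussian fit to the line-weighting function at the optimal
orientation, ON/OFF subfield statistics, and the RF centre from a 2D
Gaussian fit to the filtered back-projection of the position responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.transform import iradon

from .synth.kernels import ResponseKernel

__all__ = [
    "NeuronTuning",
    "FitResult",
    "temporal_collapse",
    "fit_orientation",
    "fit_sf",
    "fit_phase",
    "fit_bar_rf",
    "correct_bar_width",
    "fit_neuron",
    "fit_population",
    "apply_exclusions",
]

HALFWIDTH_61 = np.sqrt(2.0 * np.log(1.0 / 0.61))  # = 0.9938..., 61% ~ 1 sigma


@dataclass
class FitResult:
    params: dict
    variance_explained: float
    curve_x: np.ndarray | None = None
    curve_y: np.ndarray | None = None
    ok: bool = True
    meta: dict = field(default_factory=dict)


@dataclass
class NeuronTuning:
    """Measured tuning of one neuron (Tables-style row)."""

    cell_id: int = -1
    f_o: float = np.nan            # cyc/deg
    sigma_x: float = np.nan        # deg, RF width (1 sigma)
    sigma_f: float = np.nan        # cyc/deg, linear SF bandwidth
    sigma_logf: float = np.nan     # octaves
    sigma_theta: float = np.nan    # deg, orientation bandwidth
    f1f0: float = np.nan
    onoff_separation: float = np.nan
    mu_on: float = np.nan
    mu_off: float = np.nan
    sigma_on: float = np.nan
    sigma_off: float = np.nan
    rf_x: float = np.nan
    rf_y: float = np.nan
    x_um: float = np.nan
    y_um: float = np.nan
    lowpass: bool = False
    ori_fit_ok: bool = False
    sf_fit_ok: bool = False
    rf_fit_ok: bool = False

    def as_row(self) -> dict:
        return asdict(self)


def _variance_explained(y, yhat) -> float:
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def temporal_collapse(kernel: ResponseKernel, smooth_sigma_s: float = 0.05):
    """Smooth along time (Gaussian, sigma 50 ms) and slice at the peak.

    Returns ``(condition_response, t_optimal)``; peak ties break to the
    earliest frame. An all-zero kernel is an error.
    """
    data = kernel.data
    if data.shape[-1] < 15:
        raise ValueError("kernel needs >= 15 time samples (1 s at 15 Hz)")
    if not np.any(data):
        raise ValueError("all-zero kernel")
    sig = smooth_sigma_s * kernel.fs
    data = np.nan_to_num(data)
    sm = (ndimage.gaussian_filter1d(data, sig, axis=-1, mode="nearest")
          if sig > 0 else data)
    mean_t = sm.reshape(-1, sm.shape[-1]).mean(axis=0)
    t_opt = int(np.argmax(mean_t))
    return sm[..., t_opt], kernel.t[t_opt]


def _gauss4(x, base, amp, mu, sd):
    return base + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _fit_gaussian_1d(x, y, sigma_bounds=None, circular_period=None) -> FitResult:
    """Four-parameter Gaussian fit with grid-search initialization.

    With ``circular_period`` the curve is circularly shifted to centre the
    peak before fitting and the centre is reported on the original axis.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    shift_val = 0.0
    if circular_period is not None:
        ipk = int(np.argmax(y))
        mid = len(x) // 2
        roll = mid - ipk
        y = np.roll(y, roll)
        shift_val = x[ipk] - x[mid]
    step = np.median(np.diff(x))
    span = x[-1] - x[0]
    lo, hi = sigma_bounds or (step / 2.0, span)
    best = None
    for mu0 in (x[np.argmax(y)],):
        for sd0 in np.geomspace(max(lo, step), hi, 4):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        _gauss4, x, y,
                        p0=[np.min(y), np.ptp(y), mu0, sd0],
                        bounds=([-np.inf, 0.0, x[0] - span, lo],
                                [np.inf, np.inf, x[-1] + span, hi]),
                        maxfev=5000,
                    )
            except RuntimeError:
                continue
            ve = _variance_explained(y, _gauss4(x, *popt))
            if best is None or ve > best[1]:
                best = (popt, ve)
    if best is None:
        return FitResult({}, 0.0, ok=False)
    popt, ve = best
    params = dict(zip(("base", "amp", "mu", "sd"), popt))
    params["mu"] = params["mu"] + shift_val
    if circular_period is not None:
        params["mu"] %= circular_period
    return FitResult(params, ve, curve_x=x, curve_y=_gauss4(x, *popt))


def _sf_weighted_profile(resp2d: np.ndarray, axis: int) -> np.ndarray:
    """1D tuning profile over ``axis`` of R(ori, sf).

    The profile over one axis is the weighted average over the other, with
    weights given by the mean response along the profile axis (negative
    weights, possible after Z-scoring, clipped to zero; renormalized to 1).
    """
    w = np.clip(resp2d.mean(axis=axis), 0.0, None)
    if w.sum() == 0:
        w = np.ones_like(w)
    w = w / w.sum()
    return resp2d @ w if axis == 0 else resp2d.T @ w


def fit_orientation(kernel: ResponseKernel, collapsed: np.ndarray | None = None) -> FitResult:
    """Orientation tuning curve fit; bandwidth via the 61% half-width rule.

    The 1D curve is the SF-weighted average of the phase-averaged response;
    sigma_theta equals the fitted Gaussian sigma except for very broad fits
    (sigma > 90 deg), where the numerical half-width of the fitted curve,
    capped at 90 deg, is reported instead.
    """
    if collapsed is None:
        collapsed, _ = temporal_collapse(kernel)
    resp = collapsed.mean(axis=2)  # average over phase -> (ori, sf)
    ori = np.asarray(kernel.axes["ori"], float)
    curve = _sf_weighted_profile(resp, axis=0)
    fr = _fit_gaussian_1d(ori, curve, circular_period=180.0)
    if not fr.ok:
        return fr
    sd = fr.params["sd"]
    if sd <= 90.0:
        sigma_theta = sd * HALFWIDTH_61
    else:
        sigma_theta = 90.0
    fr.params["sigma_theta"] = float(sigma_theta)
    fr.ok = fr.ok and fr.variance_explained > 0
    return fr


def _dog(f, a1, mu1, s1, a2, s2):
    return a1 * np.exp(-0.5 * ((f - mu1) / s1) ** 2) - a2 * np.exp(-0.5 * (f / s2) ** 2)


def fit_sf(kernel: ResponseKernel, collapsed: np.ndarray | None = None,
           n_dense: int = 2000) -> FitResult:
    """SF tuning via a five-parameter difference-of-Gaussians fit.

    f_o is the argmax of the fitted curve; the linear bandwidth is
    (f_hi - f_low)/2 at 61% of the peak, falling back to the lowest SF
    sampled when the curve has no low-side crossing. A fitted peak at the
    minimum SF flags the cell as low-pass.
    """
    if collapsed is None:
        collapsed, _ = temporal_collapse(kernel)
    resp = collapsed.mean(axis=2)
    sf = np.asarray(kernel.axes["sf"], float)
    curve = _sf_weighted_profile(resp, axis=1)

    span = sf[-1] - sf[0]
    best = None
    for mu0 in (sf[np.argmax(curve)], sf[len(sf) // 2]):
        for s0 in np.geomspace(sf[0] / 2, span, 4):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        _dog, sf, curve,
                        p0=[np.ptp(curve), mu0, s0, 0.0, span],
                        bounds=([0.0, 0.0, sf[0] / 4, 0.0, sf[0] / 4],
                                [np.inf, 2 * sf[-1], 4 * span, np.inf, 4 * span]),
                        maxfev=5000,
                    )
            except RuntimeError:
                continue
            ve = _variance_explained(curve, _dog(sf, *popt))
            if best is None or ve > best[1]:
                best = (popt, ve)
    if best is None:
        return FitResult({}, 0.0, ok=False)
    popt, ve = best

    dense = np.linspace(sf[0], sf[-1], n_dense)
    fit_dense = _dog(dense, *popt)
    ipk = int(np.argmax(fit_dense))
    f_o = float(dense[ipk])
    peak = fit_dense[ipk]
    lowpass = ipk == 0
    level = 0.61 * peak

    above = fit_dense >= level
    f_low = sf[0]
    for i in range(ipk, -1, -1):
        if not above[i]:
            f_low = dense[i]
            break
    f_hi = sf[-1]
    for i in range(ipk, n_dense):
        if not above[i]:
            f_hi = dense[i]
            break
    sigma_f = float((f_hi - f_low) / 2.0)

    params = dict(zip(("a1", "mu1", "s1", "a2", "s2"), popt))
    params.update(f_o=f_o, sigma_f=sigma_f, lowpass=bool(lowpass))
    return FitResult(params, ve, curve_x=dense, curve_y=fit_dense,
                     meta={"f_low": float(f_low), "f_hi": float(f_hi)})


def fit_phase(kernel: ResponseKernel, f_o: float, ori_opt: float,
              collapsed: np.ndarray | None = None) -> FitResult:
    """F1/F0 from a fixed-period sine fit at the optimal orientation and SF.

    F1 is the peak-to-peak amplitude of the fundamental (one cycle over
    360 deg of spatial phase), F0 the mean. Non-positive F0 is flagged and
    the ratio set to NaN (cell excluded from phase statistics).
    """
    if collapsed is None:
        collapsed, _ = temporal_collapse(kernel)
    ori = np.asarray(kernel.axes["ori"], float)
    sf = np.asarray(kernel.axes["sf"], float)
    ph = np.radians(np.asarray(kernel.axes["phase"], float))
    i_ori = int(np.argmin(np.abs((ori - ori_opt + 90) % 180 - 90)))
    i_sf = int(np.argmin(np.abs(sf - f_o)))
    r = collapsed[i_ori, i_sf, :]

    f0 = float(np.mean(r))
    a = 2.0 / len(r) * np.sum(r * np.cos(ph))
    b = 2.0 / len(r) * np.sum(r * np.sin(ph))
    amp = float(np.hypot(a, b))
    f1 = 2.0 * amp  # peak-to-peak of the fitted sine
    fit = f0 + a * np.cos(ph) + b * np.sin(ph)
    ve = _variance_explained(r, fit)
    if f0 <= 0:
        return FitResult({"F1": f1, "F0": f0, "f1f0": np.nan}, ve, ok=False,
                         meta={"reason": "non-positive F0"})
    return FitResult({"F1": f1, "F0": f0, "f1f0": f1 / f0}, ve,
                     curve_x=np.degrees(ph), curve_y=fit)


def _bin2(arr: np.ndarray, axis: int) -> np.ndarray:
    n = arr.shape[axis] // 2
    sl = [slice(None)] * arr.ndim
    sl[axis] = slice(0, 2 * n)
    arr = arr[tuple(sl)]
    shape = list(arr.shape)
    shape[axis : axis + 1] = [n, 2]
    return arr.reshape(shape).mean(axis=axis + 1)


def _gauss2d(coords, amp, x0, y0, sx, sy, rot, base):
    x, y = coords
    u = (x - x0) * np.cos(rot) + (y - y0) * np.sin(rot)
    v = -(x - x0) * np.sin(rot) + (y - y0) * np.cos(rot)
    return base + amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def fit_bar_rf(kernel: ResponseKernel, recon_step: float = 0.05) -> FitResult:
    """RF width, ON/OFF statistics and RF centre from a bar kernel.

    Orientation and position axes are 2x-binned before fitting. The width is
    the Gaussian sigma of the luminance-averaged line-weighting function at
    the optimal orientation; ON and OFF line-weighting functions are fit
    separately for the separation index |mu_ON - mu_OFF|/(sigma_ON +
    sigma_OFF); the RF centre comes from a 2D Gaussian fit to the filtered
    back-projection (inverse Radon, ramp filter) of the envelope responses,
    and rf_fit_ok requires that fit to explain >= 70% of the variance.
    """
    collapsed, _ = temporal_collapse(kernel)
    collapsed = _bin2(_bin2(collapsed, 0), 1)
    ori = _bin2(np.asarray(kernel.axes["ori"], float)[:, None], 0)[:, 0]
    pos = _bin2(np.asarray(kernel.axes["pos"], float)[:, None], 0)[:, 0]

    env = collapsed.mean(axis=2)          # average over luminance -> (ori, pos)
    i_opt = int(np.argmax(env.mean(axis=1)))

    lw = env[i_opt]
    fr_env = _fit_gaussian_1d(pos, lw)
    if not fr_env.ok:
        return FitResult({}, 0.0, ok=False)
    sigma_x = abs(fr_env.params["sd"])

    fr_on = _fit_gaussian_1d(pos, collapsed[i_opt, :, 0])
    fr_off = _fit_gaussian_1d(pos, collapsed[i_opt, :, 1])
    if fr_on.ok and fr_off.ok:
        mu_on, s_on = fr_on.params["mu"], abs(fr_on.params["sd"])
        mu_off, s_off = fr_off.params["mu"], abs(fr_off.params["sd"])
        sep = abs(mu_on - mu_off) / (s_on + s_off)
    else:
        mu_on = mu_off = s_on = s_off = sep = np.nan

    # RF centre from filtered back-projection of the (pos x ori) sinogram.
    # Projections are normalized to equal area first: orientation-tuned
    # amplitude modulation violates the Radon consistency conditions, but
    # the normalized line profiles are exactly the projections of the
    # (anisotropic Gaussian) RF envelope. The projection of the envelope at
    # bar orientation theta_b sits at detector angle theta_b + 90 deg in
    # the reconstruction convention used here.
    sino = np.clip(env, 0.0, None).T  # (detector, angle)
    area = sino.sum(axis=0)
    # floor the normalizer so orientations with little genuine response
    # (orthogonal to the preferred axis, mostly noise) are not blown up
    sino = sino / np.maximum(area, 0.25 * area.max())[None, :]
    step = np.median(np.diff(pos))
    n_det = sino.shape[0]
    recon = iradon(sino, theta=ori + 90.0, filter_name="ramp", circle=False,
                   output_size=n_det)
    half = (n_det - 1) / 2.0
    gy, gx = np.mgrid[0:n_det, 0:n_det]
    xs = (gx - half) * step
    ys = (half - gy) * step
    r = np.clip(recon, 0.0, None)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss2d, (xs.ravel(), ys.ravel()), r.ravel(),
                p0=[r.max(), xs.ravel()[np.argmax(r)], ys.ravel()[np.argmax(r)],
                    max(sigma_x, step), max(sigma_x, step), 0.0, 0.0],
                maxfev=10000,
            )
        ve2d = _variance_explained(r.ravel(), _gauss2d((xs.ravel(), ys.ravel()), *popt))
        rf_x, rf_y = float(popt[1]), float(popt[2])
    except RuntimeError:
        ve2d, rf_x, rf_y = 0.0, np.nan, np.nan

    params = {
        "sigma_x": float(sigma_x), "mu": float(fr_env.params["mu"]),
        "mu_on": float(mu_on), "mu_off": float(mu_off),
        "sigma_on": float(s_on), "sigma_off": float(s_off),
        "onoff_separation": float(sep),
        "rf_x": rf_x, "rf_y": rf_y,
        "ori_opt": float(ori[i_opt]),
    }
    ok = fr_env.variance_explained >= 0.0 and ve2d >= 0.70
    return FitResult(params, ve2d, ok=ok,
                     meta={"lw_ve": fr_env.variance_explained})


def correct_bar_width(sigma_measured: float, bar_width: float) -> float:
    """Deconvolve the finite bar width from a measured RF width.

    A bar of width w adds w^2/12 (boxcar variance) to the measured variance;
    the corrected width is sqrt(sigma^2 - w^2/12). If the measured width is
    smaller than the bar's own contribution, 0 is returned with a warning.
    """
    v = sigma_measured**2 - bar_width**2 / 12.0
    if v <= 0:
        warnings.warn("measured width below bar-width floor; returning 0")
        return 0.0
    return float(np.sqrt(v))


def fit_neuron(kernel_grat: ResponseKernel | None,
               kernel_bar: ResponseKernel | None,
               cell_id: int = -1, min_ve: float = 0.70,
               bar_width_correction: bool = False,
               bar_width: float = 0.2) -> NeuronTuning:
    """Full tuning reduction for one neuron from its kernels."""
    t = NeuronTuning(cell_id=cell_id)
    if kernel_grat is not None:
        collapsed, _ = temporal_collapse(kernel_grat)
        fo_fit = fit_orientation(kernel_grat, collapsed)
        fs_fit = fit_sf(kernel_grat, collapsed)
        t.ori_fit_ok = fo_fit.ok and fo_fit.variance_explained >= min_ve
        t.sf_fit_ok = fs_fit.ok and fs_fit.variance_explained >= min_ve
        if fo_fit.ok:
            t.sigma_theta = fo_fit.params["sigma_theta"]
        if fs_fit.ok:
            t.f_o = fs_fit.params["f_o"]
            t.sigma_f = fs_fit.params["sigma_f"]
            t.lowpass = fs_fit.params["lowpass"]
            if t.f_o > 0:
                t.sigma_logf = float(np.log2((t.f_o + t.sigma_f) / t.f_o))
        if fo_fit.ok and fs_fit.ok:
            ph = fit_phase(kernel_grat, t.f_o, fo_fit.params["mu"], collapsed)
            t.f1f0 = ph.params.get("f1f0", np.nan)
    if kernel_bar is not None:
        fb = fit_bar_rf(kernel_bar)
        t.rf_fit_ok = fb.ok
        if fb.params:
            sx = fb.params["sigma_x"]
            if bar_width_correction:
                sx = correct_bar_width(sx, bar_width)
            t.sigma_x = sx
            t.mu_on, t.mu_off = fb.params["mu_on"], fb.params["mu_off"]
            t.sigma_on, t.sigma_off = fb.params["sigma_on"], fb.params["sigma_off"]
            t.onoff_separation = fb.params["onoff_separation"]
            t.rf_x, t.rf_y = fb.params["rf_x"], fb.params["rf_y"]
    return t


def fit_population(grating_kernels, bar_kernels=None, cell_ids=None,
                   positions_um=None, **kwargs) -> pd.DataFrame:
    """Fit every neuron and return the tuning table (one row per cell)."""
    n = len(grating_kernels) if grating_kernels is not None else len(bar_kernels)
    rows = []
    for i in range(n):
        kg = grating_kernels[i] if grating_kernels is not None else None
        kb = bar_kernels[i] if bar_kernels is not None else None
        cid = cell_ids[i] if cell_ids is not None else i
        t = fit_neuron(kg, kb, cell_id=cid, **kwargs)
        if positions_um is not None:
            t.x_um, t.y_um = positions_um[i]
        rows.append(t.as_row())
    return pd.DataFrame(rows)


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the fit-quality and low-pass exclusion rules.

    Grating-based analyses require both the orientation and SF fits to pass;
    bar-based analyses require the RF-envelope fit; joint analyses intersect
    the two. Low-pass cells are excluded from statistics (kept in the table,
    flagged) . Returns the table with inclusion columns plus an audit log.
    """
    t = table.copy()
    t["grating_ok"] = t["ori_fit_ok"] & t["sf_fit_ok"] & ~t["lowpass"]
    t["bar_ok"] = t["rf_fit_ok"]
    t["joint_ok"] = t["grating_ok"] & t["bar_ok"]
    audit = {
        "n_total": int(len(t)),
        "n_excluded_grating": int((~(t["ori_fit_ok"] & t["sf_fit_ok"])).sum()),
        "n_excluded_bar": int((~t["rf_fit_ok"]).sum()),
        "n_lowpass": int(t["lowpass"].sum()),
        "n_grating_ok": int(t["grating_ok"].sum()),
        "n_bar_ok": int(t["bar_ok"].sum()),
        "n_joint_ok": int(t["joint_ok"].sum()),
    }
    return t, audit
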