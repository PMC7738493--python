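"""Estimate pooled-scale-invariance parameters from a tuning table.

The central object is :class:`PooledScaleInvarianceModel`, built from a
tuning table (one row per neuron: f_o, sigma_x, sigma_f, sigma_theta, F1/F0,
optional cortical positions and RF centres). ``fit()`` returns a
:class:`PooledScaleInvarianceResults` carrying the pooling-parameter
estimates, flexible-coefficient scale-invariance fits, leave-one-out
cross-validated model comparisons, the cortical magnification factor and
marginal statistics, with a ``summary()`` table.

Estimators
----------
The pooling widths are root-median estimators: sigma_hx^2 is the median of
the signed differences sigma_x^2 - (1/(alpha*f_o))^2 over included cells
(and analogously for sigma_hf in the SF domain). A non-positive median is an
explicit estimation failure — the pooled model presumes measured widths
exceed the scale-invariant prediction. D is fit by 1D least squares of the
phase-selectivity Gaussian with sigma_hx held at its previously constrained
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from .core import pooled_f1f0, si_rf_width, si_sf_bandwidth
from .params import PoolingParams, ScaleInvarianceParams

__all__ = [
    "EstimationError",
    "estimate_sigma_hx",
    "estimate_sigma_hf",
    "estimate_D",
    "fit_flexible_alpha",
    "loocv_compare",
    "estimate_magnification",
    "cortical_pooling_extent",
    "marginal_statistics",
    "variance_ratio_test",
    "PooledScaleInvarianceModel",
    "PooledScaleInvarianceResults",
]

_DEF_SI = ScaleInvarianceParams()


class EstimationError(RuntimeError):
    """Raised when an estimator's premises fail (e.g. non-positive median)."""


def _root_median(measured: np.ndarray, si_pred: np.ndarray, what: str) -> float:
    measured = np.asarray(measured, float)
    si_pred = np.asarray(si_pred, float)
    ok = np.isfinite(measured) & np.isfinite(si_pred)
    if ok.sum() < 3:
        raise EstimationError(f"need >= 3 cells to estimate {what}")
    med = float(np.median(measured[ok] ** 2 - si_pred[ok] ** 2))
    if med <= 0:
        raise EstimationError(
            f"non-positive median squared excess for {what}: "
            "population is consistent with plain scale invariance"
        )
    return float(np.sqrt(med))


def estimate_sigma_hx(table: pd.DataFrame,
                      si: ScaleInvarianceParams = _DEF_SI) -> float:
    """Spatial pooling width (deg): root-median of sigma_x^2 - sigma_x,si^2."""
    fo = table["f_o"].to_numpy(float)
    return _root_median(table["sigma_x"].to_numpy(float),
                        si_rf_width(fo, si), "sigma_hx")


def estimate_sigma_hf(table: pd.DataFrame,
                      si: ScaleInvarianceParams = _DEF_SI) -> float:
    """Spectral pooling width (cyc/deg): root-median in the SF domain."""
    fo = table["f_o"].to_numpy(float)
    return _root_median(table["sigma_f"].to_numpy(float),
                        si_sf_bandwidth(fo, si), "sigma_hf")


def estimate_D(table: pd.DataFrame, sigma_hx: float) -> float:
    """Phase-progression rate D in [0, 1] by least squares on F1/F0 vs f_o.

    sigma_hx must already be constrained (from the RF-width fit); only D is
    free here, mirroring the sequential fitting of the pooling model.
    """
    fo = table["f_o"].to_numpy(float)
    y = table["f1f0"].to_numpy(float)
    ok = np.isfinite(fo) & np.isfinite(y)
    if ok.sum() < 3:
        raise EstimationError("need >= 3 (f_o, F1/F0) pairs to estimate D")
    fo, y = fo[ok], y[ok]

    def mse(d):
        pool = PoolingParams(sigma_hx=sigma_hx, D=d)
        return float(np.mean((pooled_f1f0(fo, pool) - y) ** 2))

    res = minimize_scalar(mse, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def fit_flexible_alpha(table: pd.DataFrame, target: str = "rf_width") -> float:
    """Least-squares scaling coefficient of the scale-invariance line.

    Fit in log2 space: for ``rf_width`` the model is sigma_x = 1/(alpha*f_o)
    (alpha free); for ``sf_bandwidth`` it is sigma_f = alpha*f_o/(2*pi). The
    log-space least-squares solution is the geometric mean of the implied
    per-cell coefficients.
    """
    fo = table["f_o"].to_numpy(float)
    if target == "rf_width":
        y = table["sigma_x"].to_numpy(float)
        ok = np.isfinite(fo) & np.isfinite(y) & (y > 0)
        return float(2.0 ** (-np.mean(np.log2(y[ok] * fo[ok]))))
    if target == "sf_bandwidth":
        y = table["sigma_f"].to_numpy(float)
        ok = np.isfinite(fo) & np.isfinite(y) & (y > 0)
        return float(2.0 * np.pi * 2.0 ** np.mean(np.log2(y[ok] / fo[ok])))
    raise ValueError(f"unknown target {target!r}")


# ---------------------------------------------------------------------------
# leave-one-out cross-validation model comparison


def _predictor(model: str, target: str, si: ScaleInvarianceParams):
    """Return fit(train)->state and predict(state, fo)->width for a model."""
    col = "sigma_x" if target == "rf_width" else "sigma_f"
    si_fn = si_rf_width if target == "rf_width" else si_sf_bandwidth

    if model == "si":
        return (lambda train: None,
                lambda state, fo: si_fn(fo, si))
    if model == "si_flex":
        def fit(train):
            return fit_flexible_alpha(train, target)

        def predict(alpha, fo):
            p = ScaleInvarianceParams(alpha=alpha, aspect_ratio=si.aspect_ratio)
            return si_fn(fo, p)
        return fit, predict
    if model == "pooled":
        def fit(train):
            est = (estimate_sigma_hx if target == "rf_width"
                   else estimate_sigma_hf)
            return est(train, si)

        def predict(sig_h, fo):
            return np.hypot(si_fn(fo, si), sig_h)
        return fit, predict
    raise ValueError(f"unknown model {model!r}")


@dataclass
class LoocvComparison:
    target: str
    models: tuple[str, str]
    mse: dict
    mean_diff: float         # mean squared-log2-error difference (m1 - m2)
    t_stat: float
    p_value: float
    ci95: tuple[float, float]
    n: int
    errors: dict = field(repr=False, default_factory=dict)


def loocv_compare(table: pd.DataFrame, models: tuple[str, str] = ("si", "pooled"),
                  target: str = "rf_width", si: ScaleInvarianceParams = _DEF_SI,
                  test: str = "t") -> LoocvComparison:
    """Compare two models by leave-one-out cross-validated squared log2 error.

    For every cell the models are refit on the remaining cells, the left-out
    width is predicted, and the per-cell error is
    (log2 data - log2 prediction)^2. The paired difference of the two error
    distributions is tested with a paired t-test (or Wilcoxon signed-rank
    with ``test='wilcoxon'``) and summarized with a 95% CI of the mean.
    """
    col = "sigma_x" if target == "rf_width" else "sigma_f"
    sub = table[np.isfinite(table["f_o"]) & np.isfinite(table[col])]
    n = len(sub)
    if n < 10:
        import warnings
        warnings.warn(f"LOOCV with only {n} cells is unreliable")
    errs = {m: np.empty(n) for m in models}
    fo_all = sub["f_o"].to_numpy(float)
    y_all = sub[col].to_numpy(float)
    for m in models:
        fit, predict = _predictor(m, target, si)
        for i in range(n):
            train = sub.drop(sub.index[i])
            state = fit(train)
            pred = float(predict(state, fo_all[i]))
            errs[m][i] = (np.log2(y_all[i]) - np.log2(pred)) ** 2
    d = errs[models[0]] - errs[models[1]]
    if np.allclose(d, 0.0):
        t_stat, p = 0.0, 1.0
    elif test == "wilcoxon":
        w = stats.wilcoxon(errs[models[0]], errs[models[1]])
        t_stat, p = float(w.statistic), float(w.pvalue)
    else:
        tt = stats.ttest_rel(errs[models[0]], errs[models[1]])
        t_stat, p = float(tt.statistic), float(tt.pvalue)
    se = d.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return LoocvComparison(
        target=target, models=tuple(models),
        mse={m: float(errs[m].mean()) for m in models},
        mean_diff=float(d.mean()), t_stat=t_stat, p_value=p,
        ci95=(float(d.mean() - tcrit * se), float(d.mean() + tcrit * se)),
        n=n, errors=errs,
    )


# ---------------------------------------------------------------------------


def estimate_magnification(table: pd.DataFrame) -> float:
    """Cortical magnification (mm/deg) from all cell pairs.

    Zero-intercept line through the scatter of cortical separation (mm)
    versus RF separation (deg) over every unordered pair. The slope is fit
    with the RF separation — the measurement-noise-laden variable — as the
    response and then inverted; regressing the noisy axis on the clean one
    roughly halves the errors-in-variables attenuation that a direct
    mm-on-deg fit suffers from jittered RF centres.
    """
    need = ["x_um", "y_um", "rf_x", "rf_y"]
    sub = table.dropna(subset=need)
    if len(sub) < 2:
        raise ValueError("need at least 2 cells with positions and RF centres")
    cort = sub[["x_um", "y_um"]].to_numpy(float) / 1000.0  # mm
    rf = sub[["rf_x", "rf_y"]].to_numpy(float)             # deg
    d_mm = pdist(cort)
    d_deg = pdist(rf)
    return float(np.sum(d_mm**2) / np.sum(d_mm * d_deg))


def cortical_pooling_extent(sigma_hx: float, magnification: float) -> dict:
    """Lateral cortical integration extent: sigma_hx times magnification.

    Returns the 1-sigma and 2-sigma extents in mm.
    """
    one = sigma_hx * magnification
    return {"sigma_1_mm": float(one), "sigma_2_mm": float(2.0 * one)}


def marginal_statistics(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Mean, median, SD, mean-log2 and SD-log2 per tuning parameter."""
    if columns is None:
        columns = [c for c in ("f_o", "sigma_x", "sigma_f", "sigma_logf",
                               "sigma_theta", "f1f0", "onoff_separation")
                   if c in table.columns]
    out = {}
    for c in columns:
        v = table[c].to_numpy(float)
        v = v[np.isfinite(v)]
        pos = v[v > 0]
        out[c] = {
            "mean": v.mean() if v.size else np.nan,
            "median": np.median(v) if v.size else np.nan,
            "sd": v.std(ddof=1) if v.size > 1 else np.nan,
            "mean_log2": np.log2(pos).mean() if pos.size else np.nan,
            "sd_log2": np.log2(pos).std(ddof=1) if pos.size > 1 else np.nan,
        }
    return pd.DataFrame(out)


def variance_ratio_test(table: pd.DataFrame, col1: str, col2: str) -> dict:
    """Two-sided F-test comparing SD-log2 between two parameters."""
    a = np.log2(table[col1].to_numpy(float))
    b = np.log2(table[col2].to_numpy(float))
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2 or a.std() == 0 or b.std() == 0:
        return {"F": np.nan, "p": np.nan, "flag": "undefined (zero variance)"}
    f = a.var(ddof=1) / b.var(ddof=1)
    p = 2.0 * min(stats.f.cdf(f, a.size - 1, b.size - 1),
                  stats.f.sf(f, a.size - 1, b.size - 1))
    return {"F": float(f), "p": float(min(p, 1.0)), "flag": ""}


# ---------------------------------------------------------------------------
# model / results objects


class PooledScaleInvarianceModel:
    """Pooled-scale-invariance model of a measured tuning table.

    Parameters
    ----------
    data : DataFrame with at least ``f_o`` plus whichever measured columns
        are available (``sigma_x``, ``sigma_f``, ``sigma_theta``, ``f1f0``,
        cortical ``x_um``/``y_um`` and RF centres ``rf_x``/``rf_y``).
        Exclusion flags (``grating_ok`` etc., from
        :func:`poolsi.tuning.apply_exclusions`) are honoured when present;
        low-pass cells are never used in estimation.
    si : fixed scale-invariance parameters of the input population.
    groupby : optional column for per-ROI estimates; the headline estimates
        always pool all included cells.
    """

    def __init__(self, data: pd.DataFrame, si: ScaleInvarianceParams = _DEF_SI,
                 groupby: str | None = None):
        self.data = data.reset_index(drop=True)
        self.si = si
        self.groupby = groupby

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs):
        return cls(data, **kwargs)

    def _included(self, need_bar: bool = False) -> pd.DataFrame:
        t = self.data
        mask = np.ones(len(t), dtype=bool)
        if "lowpass" in t:
            mask &= ~t["lowpass"].fillna(False).to_numpy(bool)
        if "grating_ok" in t:
            mask &= t["grating_ok"].fillna(False).to_numpy(bool)
        if need_bar and "bar_ok" in t:
            mask &= t["bar_ok"].fillna(False).to_numpy(bool)
        return t[mask]

    def fit(self, loocv: bool = True) -> "PooledScaleInvarianceResults":
        inc_bar = self._included(need_bar=True)
        inc = self._included()

        def _try(fn, *a):
            try:
                return fn(*a)
            except (EstimationError, KeyError, ValueError):
                return np.nan

        sigma_hx = _try(estimate_sigma_hx, inc_bar, self.si) \
            if "sigma_x" in inc_bar else np.nan
        sigma_hf = _try(estimate_sigma_hf, inc, self.si) \
            if "sigma_f" in inc else np.nan
        D = _try(estimate_D, inc, sigma_hx) \
            if "f1f0" in inc and np.isfinite(sigma_hx) else np.nan

        alpha_flex = {}
        if "sigma_x" in inc_bar:
            alpha_flex["rf_width"] = _try(fit_flexible_alpha, inc_bar, "rf_width")
        if "sigma_f" in inc:
            alpha_flex["sf_bandwidth"] = _try(fit_flexible_alpha, inc, "sf_bandwidth")

        per_group = {}
        if self.groupby and self.groupby in self.data:
            for g, sub in self._included(need_bar=True).groupby(self.groupby):
                per_group[g] = {
                    "sigma_hx": _try(estimate_sigma_hx, sub, self.si),
                    "sigma_hf": _try(estimate_sigma_hf, sub, self.si),
                }

        loocv_results = {}
        if loocv:
            if "sigma_x" in inc_bar and len(inc_bar) >= 10:
                loocv_results["rf_width"] = {
                    "pooled_vs_si": loocv_compare(
                        inc_bar, ("si", "pooled"), "rf_width", self.si),
                    "pooled_vs_si_flex": loocv_compare(
                        inc_bar, ("si_flex", "pooled"), "rf_width", self.si),
                }
            if "sigma_f" in inc and len(inc) >= 10:
                loocv_results["sf_bandwidth"] = {
                    "pooled_vs_si": loocv_compare(
                        inc, ("si", "pooled"), "sf_bandwidth", self.si),
                    "pooled_vs_si_flex": loocv_compare(
                        inc, ("si_flex", "pooled"), "sf_bandwidth", self.si),
                }

        mag = np.nan
        if {"x_um", "y_um", "rf_x", "rf_y"} <= set(self.data.columns):
            mag = _try(estimate_magnification, self._included(need_bar=True))

        return PooledScaleInvarianceResults(
            model=self,
            pooling=PoolingParams(
                sigma_hx=0.0 if not np.isfinite(sigma_hx) else sigma_hx,
                sigma_hf=0.0 if not np.isfinite(sigma_hf) else sigma_hf,
                D=0.0 if not np.isfinite(D) else D,
            ),
            sigma_hx=sigma_hx, sigma_hf=sigma_hf, D=D,
            alpha_flexible=alpha_flex,
            per_group=per_group,
            loocv=loocv_results,
            magnification=mag,
            n_included=len(inc),
        )


@dataclass
class PooledScaleInvarianceResults:
    """Fit results: point estimates, model comparisons and diagnostics."""

    model: PooledScaleInvarianceModel
    pooling: PoolingParams
    sigma_hx: float
    sigma_hf: float
    D: float
    alpha_flexible: dict
    per_group: dict
    loocv: dict
    magnification: float
    n_included: int

    def cortical_extent(self) -> dict:
        return cortical_pooling_extent(self.sigma_hx, self.magnification)

    def marginals(self) -> pd.DataFrame:
        return marginal_statistics(self.model._included())

    def summary(self) -> str:
        lines = [
            "Pooled scale invariance fit",
            "=" * 44,
            f"cells included (grating)     {self.n_included}",
            f"sigma_h(x)  [deg]            {self.sigma_hx:.4g}",
            f"sigma_h(f)  [cyc/deg]        {self.sigma_hf:.4g}",
            f"D           [-]              {self.D:.4g}",
        ]
        for k, v in self.alpha_flexible.items():
            lines.append(f"alpha_flex ({k})       {v:.4g}")
        if np.isfinite(self.magnification):
            ext = self.cortical_extent()
            lines.append(f"magnification [mm/deg]       {self.magnification:.4g}")
            lines.append(f"cortical extent 1s/2s [mm]   "
                         f"{ext['sigma_1_mm']:.3g} / {ext['sigma_2_mm']:.3g}")
        for target, comps in self.loocv.items():
            for name, c in comps.items():
                lines.append(
                    f"LOOCV {target} {name}: dMSE={c.mean_diff:+.3g} "
                    f"p={c.p_value:.2g} CI95=({c.ci95[0]:.3g}, {c.ci95[1]:.3g})"
                )
        for g, est in self.per_group.items():
            lines.append(f"group {g}: sigma_hx={est['sigma_hx']:.3g} "
                         f"sigma_hf={est['sigma_hf']:.3g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "sigma_hx_deg": self.sigma_hx,
            "sigma_hf_cpd": self.sigma_hf,
            "D": self.D,
            "alpha_flexible": self.alpha_flexible,
            "magnification_mm_per_deg": self.magnification,
            "n_included": self.n_included,
            "loocv": {
                t: {n: {"mse": c.mse, "mean_diff": c.mean_diff,
                        "p": c.p_value, "ci95": c.ci95, "n": c.n}
                    for n, c in comps.items()}
                for t, comps in self.loocv.items()
            },
            "per_group": self.per_group,
        }
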