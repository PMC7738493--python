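"""Figure and table generation for a pipeline run directory."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import json

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import (
    pooled_f1f0,
    pooled_ori_bandwidth,
    pooled_rf_width,
    pooled_sf_bandwidth,
    si_ori_bandwidth,
    si_rf_width,
    si_sf_bandwidth,
)
from .fitting import marginal_statistics
from .params import PoolingParams, ScaleInvarianceParams

PANELS = [
    ("sigma_x", "RF width (deg)", "bar_ok"),
    ("sigma_f", "SF bandwidth (cyc/deg)", "grating_ok"),
    ("sigma_theta", "Ori bandwidth (deg)", "grating_ok"),
    ("f1f0", "F1/F0", "grating_ok"),
]


def _model_curves(param, fo, si, pool):
    if param == "sigma_x":
        return si_rf_width(fo, si), pooled_rf_width(fo, si, pool)
    if param == "sigma_f":
        return si_sf_bandwidth(fo, si), pooled_sf_bandwidth(fo, si, pool)
    if param == "sigma_theta":
        return np.full_like(fo, si_ori_bandwidth(si)), pooled_ori_bandwidth(fo, si, pool)
    if param == "f1f0":
        return np.full_like(fo, np.pi), pooled_f1f0(fo, pool)
    raise ValueError(param)


def render_report(run_dir) -> list[Path]:
    """Scatter-plus-model-curve panels, clustering profiles and stat tables.

    Reads tuning.csv / model_fit.json / clustering.csv from ``run_dir``;
    missing inputs are listed in the returned report log rather than fatal.
    """
    run_dir = Path(run_dir)
    written, missing = [], []

    tpath = run_dir / "tuning.csv"
    mpath = run_dir / "model_fit.json"
    if not tpath.exists() or not mpath.exists():
        missing += [p.name for p in (tpath, mpath) if not p.exists()]
        (run_dir / "report_log.txt").write_text(
            "missing inputs: " + ", ".join(missing))
        return written
    table = pd.read_csv(tpath)
    fit = json.loads(mpath.read_text())
    si = ScaleInvarianceParams()
    pool = PoolingParams(
        sigma_hx=fit["sigma_hx_deg"] if np.isfinite(fit["sigma_hx_deg"]) else 0.0,
        sigma_hf=fit["sigma_hf_cpd"] if np.isfinite(fit["sigma_hf_cpd"]) else 0.0,
        D=fit["D"] if np.isfinite(fit["D"]) else 0.0,
    )

    fo_grid = np.geomspace(0.25, 8.0, 200)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (param, label, okcol) in zip(axes.ravel(), PANELS):
        ok = table[okcol].astype(bool) & ~table["lowpass"].astype(bool)
        ax.scatter(table.loc[ok, "f_o"], table.loc[ok, param], s=10,
                   c="0.3", alpha=0.6, label="cells")
        si_curve, pooled_curve = _model_curves(param, fo_grid, si, pool)
        ax.plot(fo_grid, si_curve, "b-", label="scale invariance")
        ax.plot(fo_grid, pooled_curve, "g-", label="pooled SI")
        ax.set_xscale("log", base=2)
        if param != "f1f0":
            ax.set_yscale("log", base=2)
        ax.set_xlabel("preferred SF (cyc/deg)")
        ax.set_ylabel(label)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    p = run_dir / "fig_scatter_models.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    cpath = run_dir / "clustering.csv"
    if cpath.exists():
        prof = pd.read_csv(cpath)
        fig, ax = plt.subplots(figsize=(6, 4))
        for param, sub in prof.groupby("parameter"):
            centers = (sub["bin_lo_um"] + sub["bin_hi_um"]) / 2
            ax.plot(centers, sub["statistic"], "-o", ms=3, label=param)
        ax.axhline(0, color="0.7", lw=0.8)
        ax.set_xlabel("cortical distance (um)")
        ax.set_ylabel("pairwise correlation")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = run_dir / "fig_clustering.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        missing.append(cpath.name)

    marg = marginal_statistics(table[
        table.get("grating_ok", pd.Series(True, index=table.index)).astype(bool)
    ])
    p = run_dir / "table_marginals.csv"
    marg.to_csv(p)
    written.append(p)

    (run_dir / "report_log.txt").write_text(
        "written: " + ", ".join(w.name for w in written)
        + ("\nmissing inputs: " + ", ".join(missing) if missing else ""))
    return written
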