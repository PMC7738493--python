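"""Neuron populations whose ground-truth tuning obeys pooled scale invariance.

Each sampled neuron inherits its preferred SF, orientation and retinotopic RF
centre from the cortical sheet; its remaining tuning (RF width, SF bandwidth,
orientation bandwidth, F1/F0) is computed from f_o via the pooled model. The
"measured-parameter targets" — what a noiseless measurement of the neuron
should return — carry multiplicative log-normal scatter on widths (SD in
log2 units) and additive truncated-Gaussian noise on F1/F0, since the model
is a population-level description rather than a per-cell identity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from ..core import (
    pooled_f1f0,
    pooled_log_bandwidth,
    pooled_ori_bandwidth,
    pooled_rf_width,
    pooled_sf_bandwidth,
)
from ..params import PoolingParams, ScaleInvarianceParams
from .sheet import CorticalSheet


@dataclass
class NeuronGroundTruth:
    """Ground truth for one synthetic neuron.

    ``*_true`` fields satisfy the pooled-model equations exactly given the
    generator's PoolingParams; the unsuffixed tuning fields are the scattered
    measurement targets. Positions in um (cortex) and deg (visual field).
    """

    cell_id: int
    x_um: float
    y_um: float
    rf_x: float
    rf_y: float
    f_o: float
    ori: float
    phase_abs: float
    sigma_x_true: float
    sigma_f_true: float
    sigma_logf_true: float
    sigma_theta_true: float
    f1f0_true: float
    sigma_x: float
    sigma_f: float
    sigma_theta: float
    f1f0: float
    onoff_separation: float
    amplitude: float


def sample_population(
    sheet: CorticalSheet,
    pooling: PoolingParams,
    n_cells: int = 200,
    scatter: float = 0.2,
    f1f0_noise: float = 0.15,
    rf_jitter: float = 0.05,
    si: ScaleInvarianceParams = ScaleInvarianceParams(),
    seed: int | None = 0,
) -> list[NeuronGroundTruth]:
    """Sample neurons from a cortical sheet under pooled scale invariance.

    Parameters
    ----------
    scatter : SD of the multiplicative log-normal scatter applied to width
        targets, in log2 units (0 disables it).
    f1f0_noise : SD of additive Gaussian noise on the F1/F0 target, clipped
        to [0, pi].
    rf_jitter : total radial SD (deg) of isotropic Gaussian jitter applied
        to RF centres on top of the retinotopic prediction.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = sheet.shape
    rows = rng.integers(0, h, n_cells)
    cols = rng.integers(0, w, n_cells)

    f_o = sheet.fo_map[rows, cols]
    sx_true = pooled_rf_width(f_o, si, pooling)
    sf_true = pooled_sf_bandwidth(f_o, si, pooling)
    slogf_true = pooled_log_bandwidth(f_o, si, pooling)
    sth_true = pooled_ori_bandwidth(f_o, si, pooling)
    f1f0_true = pooled_f1f0(f_o, pooling)

    sx = sx_true * 2.0 ** rng.normal(0.0, scatter, n_cells)
    sf = sf_true * 2.0 ** rng.normal(0.0, scatter, n_cells)
    sth = sth_true * 2.0 ** rng.normal(0.0, scatter, n_cells)
    f1f0 = np.clip(f1f0_true + rng.normal(0.0, f1f0_noise, n_cells), 0.0, np.pi)

    jit = rng.normal(0.0, rf_jitter / np.sqrt(2.0), (n_cells, 2))
    rf_x = sheet.retinotopy_x[rows, cols] + jit[:, 0]
    rf_y = sheet.retinotopy_y[rows, cols] + jit[:, 1]

    # ON-OFF separation scales with phase selectivity: simple cells have
    # displaced subfields, complex cells overlapping ones.
    onoff = 0.5 * f1f0_true / np.pi
    amp = 2.0 ** rng.normal(0.0, 0.3, n_cells)

    return [
        NeuronGroundTruth(
            cell_id=i,
            x_um=float(cols[i] * sheet.pixel_size),
            y_um=float(rows[i] * sheet.pixel_size),
            rf_x=float(rf_x[i]),
            rf_y=float(rf_y[i]),
            f_o=float(f_o[i]),
            ori=float(sheet.ori_map[rows[i], cols[i]]),
            phase_abs=float(sheet.phase_map[rows[i], cols[i]]),
            sigma_x_true=float(sx_true[i]),
            sigma_f_true=float(sf_true[i]),
            sigma_logf_true=float(slogf_true[i]),
            sigma_theta_true=float(sth_true[i]),
            f1f0_true=float(f1f0_true[i]),
            sigma_x=float(sx[i]),
            sigma_f=float(sf[i]),
            sigma_theta=float(sth[i]),
            f1f0=float(f1f0[i]),
            onoff_separation=float(onoff[i]),
            amplitude=float(amp[i]),
        )
        for i in range(n_cells)
    ]


def population_frame(population: list[NeuronGroundTruth]) -> pd.DataFrame:
    """Ground-truth manifest as a DataFrame (one row per neuron)."""
    return pd.DataFrame([asdict(n) for n in population])
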