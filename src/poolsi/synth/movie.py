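"""Synthetic imaging sessions and calcium movies.

``simulate_session`` plays a stimulus ensemble as a random rapid sequence
(one condition per update interval, organized in blocks separated by gray
gaps) and synthesizes each neuron's clean fluorescence trace by convolving
its condition responses with the calcium impulse response.
``render_movie`` paints those traces as Gaussian puncta on a pixel grid and
adds shared sinusoidal breathing/heartbeat artifacts, white noise and an
optional frame-wise lateral drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import (
    bar_condition_response,
    calcium_impulse_response,
    grating_condition_response,
)
from .population import NeuronGroundTruth
from .stimuli import StimulusEnsemble


@dataclass
class CalciumMovie:
    """Synthetic movie plus its ground truth."""

    frames: np.ndarray                 # (T, H, W) float32
    fs: float
    pixel_size_um: float
    masks: np.ndarray                  # (H, W) int labels, 0 = background
    positions_um: np.ndarray           # (n_cells, 2) (x, y)
    traces: np.ndarray                 # (n_cells, T) clean input traces
    drift: np.ndarray                  # (T, 2) applied (row, col) shifts, px
    artifact_freqs: tuple = ()

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def simulate_session(
    population: list[NeuronGroundTruth],
    ensemble: StimulusEnsemble,
    duration_s: float = 120.0,
    fs: float = 15.0,
    block_s: float = 30.0,
    gap_s: float = 5.0,
    trace_noise: float = 0.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a randomized stimulus session.

    Returns ``(traces, stim_log)`` where ``traces`` is (n_cells, T) and the
    log has one row per presentation: onset_frame, block, flat condition id
    and the per-axis condition values.
    """
    rng = np.random.default_rng(seed)
    frames_per_update = max(1, int(round(ensemble.update_ms / 1000.0 * fs)))
    n_frames = int(round(duration_s * fs))
    block_frames = int(round(block_s * fs))
    gap_frames = int(round(gap_s * fs))

    shape = ensemble.shape
    n_cond = ensemble.n_conditions
    resp_fn = (grating_condition_response if ensemble.kind == "grating"
               else bar_condition_response)
    responses = np.stack(
        [resp_fn(n, ensemble).reshape(-1) for n in population]
    )  # (n_cells, n_cond)

    onsets, conds, blocks = [], [], []
    frame = 0
    while frame + frames_per_update <= n_frames:
        in_block = frame % (block_frames + gap_frames) < block_frames
        if in_block:
            onsets.append(frame)
            conds.append(rng.integers(0, n_cond))
            blocks.append(frame // (block_frames + gap_frames))
        frame += frames_per_update

    onsets = np.asarray(onsets)
    conds = np.asarray(conds)
    drive = np.zeros((len(population), n_frames))
    drive[:, onsets] = responses[:, conds]
    h = calcium_impulse_response(fs=fs)
    traces = np.apply_along_axis(lambda d: np.convolve(d, h)[:n_frames], 1, drive)
    if trace_noise > 0:
        traces = traces + rng.normal(0.0, trace_noise * responses.max(), traces.shape)

    idx = np.unravel_index(conds, shape)
    log = pd.DataFrame({"onset_frame": onsets, "block": blocks, "condition": conds})
    for name, ax_idx in zip(ensemble.axes, idx):
        log[name] = np.asarray(ensemble.axes[name])[ax_idx]
    log.attrs["kind"] = ensemble.kind
    log.attrs["fs"] = fs
    return traces, log


def render_movie(
    positions_um: np.ndarray,
    traces: np.ndarray,
    shape: tuple[int, int] = (64, 64),
    pixel_size_um: float = 2.0,
    fs: float = 15.0,
    punctum_sigma_um: float = 3.0,
    baseline: float = 1.0,
    punctum_baseline: float = 0.5,
    artifact_freqs: tuple = (0.4, 1.5),
    artifact_amp: float = 0.0,
    noise_sd: float = 0.0,
    drift: np.ndarray | None = None,
    seed: int | None = 0,
) -> CalciumMovie:
    """Render per-cell traces into a calcium movie.

    ``positions_um`` are (x, y) cell-body positions; ``drift`` is an optional
    (T, 2) integer (row, col) shift trajectory applied to each frame. The
    artifacts are shared additive sinusoids at the given frequencies (Hz).
    """
    positions_um = np.atleast_2d(np.asarray(positions_um, float))
    traces = np.atleast_2d(np.asarray(traces, float))
    n_cells, n_frames = traces.shape
    h, w = shape
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    sig_px = punctum_sigma_um / pixel_size_um
    puncta = np.zeros((n_cells, h, w))
    masks = np.zeros((h, w), dtype=int)
    for i, (px, py) in enumerate(positions_um):
        cx, cy = px / pixel_size_um, py / pixel_size_um
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        puncta[i] = np.exp(-0.5 * r2 / sig_px**2)
        masks[r2 <= (2.0 * sig_px) ** 2] = i + 1

    t = np.arange(n_frames) / fs
    art = np.zeros(n_frames)
    for f in artifact_freqs:
        if artifact_amp > 0:
            art += artifact_amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    frames = np.einsum("ct,chw->thw", traces + punctum_baseline, puncta)
    frames += baseline + art[:, None, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)

    if drift is None:
        drift = np.zeros((n_frames, 2), dtype=int)
    else:
        drift = np.asarray(drift, dtype=int)
        for k in range(n_frames):
            if drift[k, 0] or drift[k, 1]:
                frames[k] = np.roll(frames[k], (drift[k, 0], drift[k, 1]), axis=(0, 1))

    return CalciumMovie(
        frames=frames.astype(np.float32),
        fs=fs,
        pixel_size_um=pixel_size_um,
        masks=masks,
        positions_um=positions_um,
        traces=traces,
        drift=drift,
        artifact_freqs=tuple(artifact_freqs),
    )


def apply_fluorescence_nonlinearity(trace: np.ndarray, exponent: float) -> np.ndarray:
    """Static accelerating indicator nonlinearity: pointwise power law.

    ``exponent`` = 1 is the identity; larger exponents narrow tuning curves
    (a Gaussian raised to power n has width sigma/sqrt(n)). Negative inputs
    with a non-integer exponent are rejected.
    """
    if exponent < 1:
        raise ValueError("exponent must be >= 1 (accelerating nonlinearity)")
    trace = np.asarray(trace, dtype=float)
    if np.any(trace < 0) and not float(exponent).is_integer():
        raise ValueError("negative trace values require an integer exponent")
    return np.power(trace, exponent)
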