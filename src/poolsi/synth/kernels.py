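"""Stimulus-triggered response kernels of synthetic neurons.

The condition response is built from the neuron's (scattered) tuning targets:
an axial Gaussian in orientation, a Gaussian in linear SF, and a phase tuning
curve that is a mixture of a half-wave-rectified cosine (F1/F0 = pi) and a
flat component, weighted so the mixture's F1/F0 equals the target. Bar
responses are line-weighting Gaussians (projections of the 2D RF envelope)
smeared by the finite bar width. The temporal profile is a double-exponential
calcium impulse response sampled at the imaging frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .population import NeuronGroundTruth
from .stimuli import StimulusEnsemble


@dataclass
class ResponseKernel:
    """Stimulus-triggered average response R(condition..., t).

    ``data`` has the ensemble's condition axes followed by time; ``axes``
    maps axis names to values and ``t`` holds the post-onset times (s).
    """

    kind: str
    data: np.ndarray
    axes: dict
    t: np.ndarray
    fs: float = 15.0
    meta: dict = field(default_factory=dict)

    def collapse(self, func=np.mean, axis_name: str | None = None):
        names = list(self.axes)
        idx = names.index(axis_name)
        return func(self.data, axis=idx)


def calcium_impulse_response(
    fs: float = 15.0, rise_s: float = 0.05, decay_s: float = 0.4,
    duration_s: float = 1.0,
) -> np.ndarray:
    """Double-exponential calcium impulse response, peak-normalized."""
    t = np.arange(int(round(duration_s * fs))) / fs
    h = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return h / h.max()


def _axial_diff(a, b):
    """Smallest difference between axial angles in degrees, in [-90, 90]."""
    d = (np.asarray(a) - np.asarray(b) + 90.0) % 180.0 - 90.0
    return d


def phase_tuning(phase_deg, phase_pref_deg, f1f0):
    """Phase tuning with mean 1 and the requested F1/F0.

    Mixture r = w * pi * [cos]_+ + (1 - w), with w = f1f0/pi, so the
    fundamental peak-to-peak over mean equals f1f0 exactly.
    """
    w = np.clip(f1f0 / np.pi, 0.0, 1.0)
    rect = np.maximum(np.cos(np.radians(phase_deg - phase_pref_deg)), 0.0)
    return w * np.pi * rect + (1.0 - w)


def grating_condition_response(neuron: NeuronGroundTruth,
                               ensemble: StimulusEnsemble) -> np.ndarray:
    """Noiseless response amplitude over (ori, sf, phase)."""
    ori, sf, ph = (ensemble.axes[k] for k in ("ori", "sf", "phase"))
    g_ori = np.exp(-0.5 * (_axial_diff(ori, neuron.ori) / neuron.sigma_theta) ** 2)
    g_sf = np.exp(-0.5 * ((sf - neuron.f_o) / neuron.sigma_f) ** 2)
    g_ph = phase_tuning(ph, neuron.phase_abs, neuron.f1f0)
    return neuron.amplitude * g_ori[:, None, None] * g_sf[None, :, None] * g_ph[None, None, :]


def _smeared_gaussian(pos, mu, sigma, bar_width):
    """Gaussian line-weighting profile convolved with a boxcar bar profile."""
    if bar_width <= 0:
        return np.exp(-0.5 * ((pos - mu) / sigma) ** 2)
    lo = (pos - mu - bar_width / 2) / sigma
    hi = (pos - mu + bar_width / 2) / sigma
    prof = ndtr(hi) - ndtr(lo)
    peak = 2 * ndtr(bar_width / 2 / sigma) - 1.0
    return prof / peak


def bar_condition_response(neuron: NeuronGroundTruth,
                           ensemble: StimulusEnsemble) -> np.ndarray:
    """Noiseless response amplitude over (ori, pos, lum).

    The line-weighting width at bar orientation theta_b is the projection of
    the 2D RF envelope (width sigma_x, length A*sigma_x) onto the bar-normal
    axis; ON and OFF profiles are displaced along that axis according to the
    neuron's ON-OFF separation index.
    """
    ori, pos, lum = (ensemble.axes[k] for k in ("ori", "pos", "lum"))
    aspect = 2.0
    d = np.radians(_axial_diff(ori, neuron.ori))
    sig_proj = neuron.sigma_x * np.sqrt(np.cos(d) ** 2 + (aspect * np.sin(d)) ** 2)
    g_ori = np.exp(-0.5 * (_axial_diff(ori, neuron.ori) / neuron.sigma_theta) ** 2)

    # projection of the RF centre onto each bar-normal axis
    normal = np.radians(ori + 90.0)
    c = neuron.rf_x * np.cos(normal) + neuron.rf_y * np.sin(normal)

    delta = neuron.onoff_separation * 2.0 * neuron.sigma_x  # ON-OFF displacement
    out = np.empty((len(ori), len(pos), len(lum)))
    for j, l in enumerate(lum):
        mu = c + (delta / 2.0 if l > 0 else -delta / 2.0) * np.cos(d)
        for i in range(len(ori)):
            out[i, :, j] = g_ori[i] * _smeared_gaussian(
                pos, mu[i], sig_proj[i], ensemble.bar_width
            )
    return neuron.amplitude * out


def _with_time(resp: np.ndarray, axes: dict, kind: str, noise: float,
               rng: np.random.Generator, fs: float, meta: dict) -> ResponseKernel:
    h = calcium_impulse_response(fs=fs)
    data = resp[..., None] * h
    if noise > 0:
        data = data + rng.normal(0.0, noise * data.max(), data.shape)
    t = np.arange(len(h)) / fs
    return ResponseKernel(kind=kind, data=data, axes=axes, t=t, fs=fs, meta=meta)


def simulate_grating_kernel(
    neuron: NeuronGroundTruth, ensemble: StimulusEnsemble,
    noise: float = 0.1, seed: int | None = 0, fs: float = 15.0,
) -> ResponseKernel:
    """R_grat(ori, sf, phase, t) for one neuron. ``noise`` is the additive
    Gaussian SD as a fraction of the peak noiseless response."""
    if ensemble.kind != "grating":
        raise ValueError("ensemble must be a grating ensemble")
    rng = np.random.default_rng(seed)
    resp = grating_condition_response(neuron, ensemble)
    return _with_time(resp, dict(ensemble.axes), "grating", noise, rng, fs,
                      {"cell_id": neuron.cell_id})


def simulate_bar_kernel(
    neuron: NeuronGroundTruth, ensemble: StimulusEnsemble,
    noise: float = 0.1, seed: int | None = 0, fs: float = 15.0,
) -> ResponseKernel:
    """R_bar(ori, pos, lum, t) for one neuron."""
    if ensemble.kind != "bar":
        raise ValueError("ensemble must be a bar ensemble")
    rng = np.random.default_rng(seed)
    resp = bar_condition_response(neuron, ensemble)
    return _with_time(resp, dict(ensemble.axes), "bar", noise, rng, fs,
                      {"cell_id": neuron.cell_id})
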