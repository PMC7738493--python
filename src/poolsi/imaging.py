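"""From calcium movies to per-cell stimulus-triggered response kernels.

Stages: rigid frame alignment, cell detection via the local cross-correlation
image, trace extraction, double-notch filtering of breathing/heartbeat
artifacts, within-trial Z-scoring, and stimulus-triggered averaging.

The local cross-correlation image scores each pixel by the summed product of
its time course with the DoG-weighted time course of its neighbourhood:

    LocalX(x, y) = sum_t F(x,y,t) * [F(.,.,t) conv DoG](x, y)

with an integral-normalized centre Gaussian (sigma ~ cell body, 3 um) minus
an integral-normalized surround Gaussian (sigma 20 um, the neuropil). Pixel
time courses are mean-subtracted first, making the score a correlation
rather than a raw product sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from skimage.segmentation import flood

from .synth.kernels import ResponseKernel

__all__ = [
    "rigid_align",
    "local_crosscorr_image",
    "segment_cells",
    "extract_traces",
    "notch_filter_trace",
    "zscore_trial",
    "stimulus_triggered_average",
    "LocalXImage",
    "CellROI",
]


@dataclass
class LocalXImage:
    values: np.ndarray
    pixel_size_um: float
    center_sigma_um: float = 3.0
    surround_sigma_um: float = 20.0


@dataclass
class CellROI:
    label: int
    pixels: np.ndarray            # (n, 2) (row, col)
    centroid_um: tuple
    trace: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def rigid_align(frames: np.ndarray, reference: np.ndarray | None = None,
                upsample: int = 1):
    """Rigid (translation-only) alignment of each frame to a reference.

    Uses the frame/reference cross-correlation peak; integer-pixel by
    default, subpixel with ``upsample`` > 1. Returns the aligned movie and
    the (T, 2) shift trajectory that was removed.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("movie must be a (T, H, W) stack with >= 2 frames")
    if reference is None:
        reference = frames.mean(axis=0)
    aligned = np.empty_like(frames)
    shifts = np.zeros((frames.shape[0], 2))
    h, w = reference.shape
    if upsample == 1:
        ref_f = np.fft.rfft2(reference - reference.mean())
        for k, frame in enumerate(frames):
            xc = np.fft.irfft2(ref_f * np.conj(np.fft.rfft2(frame - frame.mean())),
                               s=(h, w))
            r, c = np.unravel_index(np.argmax(xc), xc.shape)
            shift = (r - h if r > h // 2 else r, c - w if c > w // 2 else c)
            shifts[k] = shift
            aligned[k] = np.roll(frame, shift, axis=(0, 1))
    else:
        for k, frame in enumerate(frames):
            shift, _, _ = phase_cross_correlation(
                reference, frame, upsample_factor=upsample, normalization=None
            )
            shifts[k] = shift
            aligned[k] = ndimage.shift(frame, shift, order=1, mode="nearest")
    return aligned, shifts


def _normalized_gaussian_kernel(sigma_px: float, radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    g = np.exp(-0.5 * (x**2 + y**2) / sigma_px**2)
    return g / g.sum()


def dog_kernel(pixel_size_um: float, center_sigma_um: float = 3.0,
               surround_sigma_um: float = 20.0) -> np.ndarray:
    """Centre-minus-surround DoG, each Gaussian integral-normalized."""
    sc = center_sigma_um / pixel_size_um
    ss = surround_sigma_um / pixel_size_um
    radius = int(np.ceil(3 * ss))
    return (_normalized_gaussian_kernel(sc, radius)
            - _normalized_gaussian_kernel(ss, radius))


def local_crosscorr_image(frames: np.ndarray, pixel_size_um: float,
                          center_sigma_um: float = 3.0,
                          surround_sigma_um: float = 20.0) -> LocalXImage:
    """Local cross-correlation image of an aligned movie."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("movie must be a (T, H, W) stack with >= 2 frames")
    mean_img = frames.mean(axis=0)
    kern = dog_kernel(pixel_size_um, center_sigma_um, surround_sigma_um)
    from scipy.signal import fftconvolve

    acc = np.zeros(frames.shape[1:])
    chunk = max(1, int(2**22 // max(frames[0].size, 1)))  # modest working set
    for k0 in range(0, frames.shape[0], chunk):
        f = frames[k0 : k0 + chunk] - mean_img
        conv = fftconvolve(f, kern[None, :, :], mode="same", axes=(1, 2))
        acc += (f * conv).sum(axis=0)
    return LocalXImage(acc, pixel_size_um, center_sigma_um, surround_sigma_um)


def segment_cells(localx: LocalXImage, detect_z: float = 4.0,
                  local_threshold: float = 0.5,
                  min_area_um2: float = 9.0, max_area_um2: float = 400.0,
                  min_separation_um: float = 6.0) -> list[CellROI]:
    """Deterministic stand-in for manual point-and-click cell selection.

    Local maxima of LocalX exceeding ``detect_z`` robust SDs above the median
    seed region growing; each ROI is the connected region around its seed
    above ``local_threshold`` of the seed value (the local-threshold rule),
    claimed in seed-strength order so ROIs never overlap.
    """
    img = localx.values
    if not np.all(np.isfinite(img)):
        raise ValueError("LocalX image contains non-finite values")
    med = np.median(img)
    mad = np.median(np.abs(img - med)) * 1.4826
    if mad == 0:
        return []
    thr = med + detect_z * mad
    min_dist = max(1, int(round(min_separation_um / localx.pixel_size_um)))
    peaks = peak_local_max(img, min_distance=min_dist, threshold_abs=thr)
    order = np.argsort(img[peaks[:, 0], peaks[:, 1]])[::-1] if len(peaks) else []

    px_area = localx.pixel_size_um**2
    claimed = np.zeros(img.shape, dtype=bool)
    rois = []
    for label, oi in enumerate(order, start=1):
        r, c = peaks[oi]
        if claimed[r, c]:
            continue
        seed_val = img[r, c]
        region = flood(img, (int(r), int(c)),
                       tolerance=seed_val * (1 - local_threshold))
        region &= img >= local_threshold * seed_val
        region &= ~claimed
        lab, _ = ndimage.label(region)
        region = lab == lab[r, c]
        area = region.sum() * px_area
        if area < min_area_um2 or area > max_area_um2:
            continue
        claimed |= region
        pix = np.argwhere(region)
        cy, cx = pix.mean(axis=0)
        rois.append(CellROI(
            label=label, pixels=pix,
            centroid_um=(cx * localx.pixel_size_um, cy * localx.pixel_size_um),
        ))
    return rois


def rois_from_labels(labels: np.ndarray, pixel_size_um: float) -> list[CellROI]:
    """Build ROIs from a labelled mask image (mask-import path).

    Preserves a manual-selection workflow: labels produced by any external
    tool (0 = background) become CellROIs usable by extract_traces.
    """
    rois = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        pix = np.argwhere(labels == lab)
        cy, cx = pix.mean(axis=0)
        rois.append(CellROI(label=int(lab), pixels=pix,
                            centroid_um=(cx * pixel_size_um, cy * pixel_size_um)))
    return rois


def extract_traces(frames: np.ndarray, rois: list[CellROI]) -> np.ndarray:
    """Mean trace over each ROI's pixels; also stored on the ROIs."""
    traces = np.empty((len(rois), frames.shape[0]))
    for i, roi in enumerate(rois):
        traces[i] = frames[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
        roi.trace = traces[i]
    return traces


def notch_filter_trace(trace: np.ndarray, fs: float = 15.0,
                       search_band: tuple[float, float] = (0.2, 3.0),
                       n_notches: int = 2, z_thresh: float = 3.0,
                       notch_halfwidth_bins: int = 2) -> np.ndarray:
    """Remove up to two resonant spectral peaks (breathing, heartbeat).

    Peaks inside ``search_band`` whose amplitude exceeds the local median
    noise floor by ``z_thresh`` robust SDs are excised by zero-phase spectral
    interpolation (complex rFFT bins replaced by the linear interpolation of
    the flanking amplitudes with the original phase discarded toward zero).
    A trace with no qualifying peak is returned unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 64:
        raise ValueError("trace must have at least 64 samples")
    if not 0 < search_band[0] < search_band[1] <= fs / 2:
        raise ValueError("search band must lie inside (0, Nyquist]")

    # detect resonant peaks on a segment-averaged (Welch) log-spectrum: a
    # candidate must exceed the local median floor by z_thresh robust SDs
    # and stand at least 6 dB above it (sinusoidal artifact lines do both;
    # broadband noise fluctuations do neither)
    from scipy.signal import welch

    nperseg = max(64, trace.size // 8)
    f_w, pxx = welch(trace, fs=fs, nperseg=nperseg)
    logp = np.log(np.maximum(pxx, 1e-300))
    win = max(9, int(round(1.0 / (f_w[1] - f_w[0]))) | 1)
    floor = ndimage.median_filter(logp, size=win, mode="nearest")
    resid = logp - floor
    sd = max((np.percentile(resid, 84) - np.percentile(resid, 16)) / 2.0, 1e-12)
    z = resid / sd
    in_band = (f_w >= search_band[0]) & (f_w <= search_band[1])
    cand = np.where(in_band & (z > z_thresh) & (resid > np.log(4.0)))[0]
    if cand.size == 0:
        return trace.copy()
    cand = cand[np.argsort(z[cand])[::-1]]
    peak_freqs: list[float] = []
    min_sep = 2 * (f_w[1] - f_w[0])
    for idx in cand:
        if len(peak_freqs) >= n_notches:
            break
        if any(abs(f_w[idx] - pf) <= 2 * min_sep for pf in peak_freqs):
            continue
        peak_freqs.append(float(f_w[idx]))

    # excise the detected lines from the full-resolution spectrum
    spec = np.fft.rfft(trace)
    freqs = np.fft.rfftfreq(trace.size, d=1.0 / fs)
    amp = np.abs(spec)
    df = freqs[1] - freqs[0]
    half = max(notch_halfwidth_bins, int(np.ceil((f_w[1] - f_w[0]) / df)))
    out = spec.copy()
    for pf in peak_freqs:
        idx = int(np.argmin(np.abs(freqs - pf)))
        start = max(idx - half, 1)
        idx = start + int(np.argmax(amp[start : idx + half + 1]))
        lo = max(idx - half, 1)
        hi = min(idx + half, len(spec) - 1)
        a0 = amp[max(lo - 1, 0)]
        a1 = amp[min(hi + 1, len(spec) - 1)]
        for k in range(lo, hi + 1):
            frac = (k - (lo - 1)) / (hi + 2 - lo)
            target = a0 + frac * (a1 - a0)
            out[k] = target * np.exp(1j * np.angle(out[k]))
    return np.fft.irfft(out, n=trace.size)


def zscore_trial(trace: np.ndarray) -> np.ndarray:
    """Z-score one trial's trace; a zero-variance trace raises ValueError
    (the cell is flagged and excluded upstream)."""
    trace = np.asarray(trace, dtype=float)
    sd = trace.std()
    if sd == 0:
        raise ValueError("zero-variance trace: cell excluded")
    return (trace - trace.mean()) / sd


def stimulus_triggered_average(
    traces: np.ndarray, stim_log: pd.DataFrame, axes: dict,
    fs: float = 15.0, window_s: float = 1.0,
) -> list[ResponseKernel]:
    """Stimulus-triggered average response per condition, 1 s post-onset.

    ``axes`` maps condition axis names (columns of ``stim_log``) to their
    value arrays; returns one kernel per row of ``traces``. Conditions never
    shown are flagged in kernel.meta['missing'] and left as NaN.
    """
    traces = np.atleast_2d(traces)
    n_t = int(round(window_s * fs))
    shape = tuple(len(v) for v in axes.values())
    names = list(axes)

    cond_idx = np.zeros(len(stim_log), dtype=int)
    for name in names:
        vals = np.asarray(axes[name], dtype=float)
        col = stim_log[name].to_numpy(dtype=float)
        idx = np.abs(col[:, None] - vals[None, :]).argmin(axis=1)
        cond_idx = cond_idx * len(vals) + idx

    onsets = stim_log["onset_frame"].to_numpy()
    valid = onsets + n_t <= traces.shape[1]
    onsets, cond_idx = onsets[valid], cond_idx[valid]

    n_cond = int(np.prod(shape))
    counts = np.bincount(cond_idx, minlength=n_cond)
    kernels = []
    t = np.arange(n_t) / fs
    for trace in traces:
        acc = np.zeros((n_cond, n_t))
        seg = trace[onsets[:, None] + np.arange(n_t)[None, :]]
        np.add.at(acc, cond_idx, seg)
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = acc / counts[:, None]
        kernels.append(ResponseKernel(
            kind=stim_log.attrs.get("kind", "grating"),
            data=avg.reshape(shape + (n_t,)),
            axes={k: np.asarray(v) for k, v in axes.items()},
            t=t, fs=fs,
            meta={"counts": counts.reshape(shape),
                  "missing": int((counts == 0).sum())},
        ))
    return kernels
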