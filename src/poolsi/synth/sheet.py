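"""Ground-truth cortical sheets: periodic preferred-SF map, pinwheel
orientation map, linear retinotopy and an absolute-phase map.

Map synthesis uses band-pass-filtered Gaussian noise (real for the SF map,
complex for the orientation map, whose half-angle produces pinwheels); the
band centre sets the dominant spatial period. The marginal log2(f_o)
statistics are imposed exactly by standardizing the filtered field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CorticalSheet:
    """Ground-truth functional maps on a square-pixel grid.

    fo_map is in cyc/deg, ori_map in degrees (axial, [0, 180)), retinotopy in
    degrees of visual field, phase_map in degrees, pixel_size in um,
    magnification in mm/deg.
    """

    pixel_size: float
    fo_map: np.ndarray
    ori_map: np.ndarray
    retinotopy_x: np.ndarray
    retinotopy_y: np.ndarray
    phase_map: np.ndarray
    magnification: float
    period_um: float = 750.0
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fo_map.shape

    @property
    def extent_mm(self) -> tuple[float, float]:
        h, w = self.shape
        return h * self.pixel_size / 1000.0, w * self.pixel_size / 1000.0


def _bandpass_noise(shape, pixel_size_um, period_um, rng, complex_field=False,
                    rel_bandwidth=0.25):
    """White noise filtered with an annular Gaussian band in 2D frequency."""
    noise = rng.standard_normal(shape)
    if complex_field:
        noise = noise + 1j * rng.standard_normal(shape)
    ky = np.fft.fftfreq(shape[0], d=pixel_size_um)
    kx = np.fft.fftfreq(shape[1], d=pixel_size_um)
    kr = np.hypot(ky[:, None], kx[None, :])
    k0 = 1.0 / period_um
    band = np.exp(-0.5 * ((kr - k0) / (rel_bandwidth * k0)) ** 2)
    filt = np.fft.ifft2(np.fft.fft2(noise) * band)
    return filt if complex_field else filt.real


def make_cortical_sheet(
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 10.0,
    period_um: float = 750.0,
    fo_mean_log2: float = 0.95,
    fo_sd_log2: float = 0.64,
    magnification: float = 2.0,
    D: float = 0.54,
    seed: int | None = 0,
) -> CorticalSheet:
    """Synthesize a ground-truth cortical sheet.

    Defaults follow the measured marginals of the imaged populations:
    log-normal preferred SF with mean-log2 0.95 and SD-log2 0.64, SF-map
    spatial period ~750 um, and 2.0 mm of cortex per degree of visual field.

    Parameters
    ----------
    shape : grid size in pixels; must be at least 64 x 64.
    D : absolute-phase progression rate used for the phase map (the phase
        advances at ``D * 360 * f_o`` degrees per degree of retinotopy).
    """
    if min(shape) < 64:
        raise ValueError("sheet grid must be at least 64x64 pixels")
    if period_um <= 0 or magnification <= 0 or pixel_size_um <= 0:
        raise ValueError("period, magnification and pixel size must be positive")
    if period_um < 2 * pixel_size_um or period_um > max(shape) * pixel_size_um:
        raise ValueError("SF-map period inconsistent with grid extent/resolution")
    rng = np.random.default_rng(seed)

    z = _bandpass_noise(shape, pixel_size_um, period_um, rng)
    z = (z - z.mean()) / z.std()
    fo_map = 2.0 ** (fo_mean_log2 + fo_sd_log2 * z)

    c = _bandpass_noise(shape, pixel_size_um, period_um, rng, complex_field=True)
    ori_map = (np.degrees(np.angle(c)) / 2.0) % 180.0

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    x_mm = xx * pixel_size_um / 1000.0
    y_mm = yy * pixel_size_um / 1000.0
    retinotopy_x = x_mm / magnification
    retinotopy_y = y_mm / magnification

    phase_map = (360.0 * D * fo_map * retinotopy_x) % 360.0

    return CorticalSheet(
        pixel_size=pixel_size_um,
        fo_map=fo_map,
        ori_map=ori_map,
        retinotopy_x=retinotopy_x,
        retinotopy_y=retinotopy_y,
        phase_map=phase_map,
        magnification=magnification,
        period_um=period_um,
        meta={
            "fo_mean_log2": fo_mean_log2,
            "fo_sd_log2": fo_sd_log2,
            "D": D,
            "seed": seed,
        },
    )


def radial_autocorrelation(img: np.ndarray, pixel_size_um: float):
    """Radially averaged spatial autocorrelation of a map.

    Returns (lag_um, acf) with acf normalized to 1 at zero lag. Used to check
    the dominant period of the synthesized SF map.
    """
    z = img - img.mean()
    f = np.fft.fft2(z)
    acf2 = np.fft.ifft2(f * np.conj(f)).real
    acf2 = np.fft.fftshift(acf2) / acf2.max()
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - h // 2, xx - w // 2)
    rbin = np.round(r).astype(int)
    nmax = min(h, w) // 2
    acf = np.bincount(rbin.ravel(), weights=acf2.ravel())[:nmax]
    counts = np.bincount(rbin.ravel())[:nmax]
    return np.arange(nmax) * pixel_size_um, acf / counts
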