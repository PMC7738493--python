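"""Stimulus ensembles: the 224-condition random grating set and the random
bar set used to probe spectral and spatial RFs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StimulusEnsemble:
    """Enumeration of stimulus conditions plus presentation timing.

    ``axes`` maps axis name -> value array; ``kind`` is 'grating' or 'bar'.
    Grating condition order is (ori, sf, phase); bar order (ori, pos, lum).
    """

    kind: str
    axes: dict = field(default_factory=dict)
    update_ms: float = 133.0
    aperture_deg: float = 3.0
    bar_width: float = 0.0
    bar_length: float = 0.0

    @property
    def n_conditions(self) -> int:
        n = 1
        for v in self.axes.values():
            n *= len(v)
        return n

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.axes.values())


def grating_ensemble(
    n_ori: int = 8,
    sf_range: tuple[float, float] = (0.25, 8.0),
    n_sf: int = 7,
    n_phase: int = 4,
    update_ms: float = 133.0,
    aperture_deg: float = 3.0,
) -> StimulusEnsemble:
    """Random flashed-grating ensemble: 8 orientations (delta 22.5 deg),
    7 log-spaced SFs from 0.25 to 8 cyc/deg, 4 phases (delta 90 deg) —
    224 conditions, updated every 133 ms at max contrast."""
    axes = {
        "ori": np.arange(n_ori) * (180.0 / n_ori),
        "sf": np.geomspace(sf_range[0], sf_range[1], n_sf),
        "phase": np.arange(n_phase) * (360.0 / n_phase),
    }
    return StimulusEnsemble(kind="grating", axes=axes, update_ms=update_ms,
                            aperture_deg=aperture_deg)


def bar_ensemble(
    ori_step: float = 10.0,
    pos_step: float = 0.1,
    pos_extent: float = 1.5,
    bar_width: float = 0.2,
    bar_length: float = 3.0,
    update_ms: float = 133.0,
) -> StimulusEnsemble:
    """Random bar ensemble: 0.2 deg wide bars, positions every 0.1 deg,
    orientations every 10 deg, bright and dark luminances."""
    n_pos = int(round(2 * pos_extent / pos_step)) + 1
    axes = {
        "ori": np.arange(0.0, 180.0, ori_step),
        "pos": np.linspace(-pos_extent, pos_extent, n_pos),
        "lum": np.array([1.0, -1.0]),  # bright, dark
    }
    return StimulusEnsemble(kind="bar", axes=axes, update_ms=update_ms,
                            bar_width=bar_width, bar_length=bar_length)
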