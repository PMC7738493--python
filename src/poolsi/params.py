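"""Parameter containers for the scale-invariance and pooling models.

Angles are stored and returned in degrees at every public interface; internal
trigonometry uses radians. Spatial frequencies are in cycles per degree of
visual angle (cyc/deg), spatial widths in degrees of visual angle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path


@dataclass(frozen=True)
class ScaleInvarianceParams:
    """Parameters of the scale-invariant Gabor family.

    Attributes
    ----------
    alpha : float
        Dimensionless scaling coefficient linking RF width to preferred SF,
        ``sigma_x = 1/(alpha * f_o)``. The default ``pi`` corresponds to
        2-3 ON/OFF subfields per envelope, the classic V1 simple-cell value.
    aspect_ratio : float
        RF length/width ratio ``A`` (length measured along the preferred
        orientation). Default 2.0.
    """

    alpha: float = math.pi
    aspect_ratio: float = 2.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.aspect_ratio > 0:
            raise ValueError(f"aspect_ratio must be > 0, got {self.aspect_ratio}")


@dataclass(frozen=True)
class PoolingParams:
    """Free parameters of the pooled-scale-invariance model.

    Attributes
    ----------
    sigma_hx : float
        Width (1 SD, degrees of visual angle) of the Gaussian window that
        pools scale-invariant inputs over retinotopy.
    sigma_hf : float
        Width (1 SD, cyc/deg) of the isotropic Gaussian pooling window in the
        2D spectral (Fourier) plane.
    D : float
        Dimensionless rate of absolute-phase progression within the pooling
        window, in [0, 1]. ``D = 1`` is constant relative phase (carrier
        rides with the envelope); ``D = 0`` is constant absolute phase.
    """

    sigma_hx: float = 0.0
    sigma_hf: float = 0.0
    D: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_hx < 0:
            raise ValueError(f"sigma_hx must be >= 0, got {self.sigma_hx}")
        if self.sigma_hf < 0:
            raise ValueError(f"sigma_hf must be >= 0, got {self.sigma_hf}")
        if not 0.0 <= self.D <= 1.0:
            raise ValueError(f"D must be in [0, 1], got {self.D}")


@dataclass
class ModelPrediction:
    """Per-neuron tuning predicted from its preferred SF.

    All widths are 1-sigma. ``f1f0`` lies in (0, pi].
    """

    f_o: float
    rf_width: float          # deg
    sf_bw_linear: float      # cyc/deg
    sf_bw_log: float         # octaves
    ori_bw: float            # deg
    f1f0: float              # dimensionless


def save_params(
    path: str | Path,
    si: ScaleInvarianceParams,
    pool: PoolingParams,
) -> None:
    """Serialize model parameters to a JSON document."""
    doc = {
        "alpha": si.alpha,
        "aspect_ratio_A": si.aspect_ratio,
        "sigma_hx_deg": pool.sigma_hx,
        "sigma_hf_cpd": pool.sigma_hf,
        "D": pool.D,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_params(path: str | Path) -> tuple[ScaleInvarianceParams, PoolingParams]:
    """Load model parameters from the JSON document written by save_params."""
    doc = json.loads(Path(path).read_text())
    si = ScaleInvarianceParams(alpha=doc["alpha"], aspect_ratio=doc["aspect_ratio_A"])
    pool = PoolingParams(
        sigma_hx=doc["sigma_hx_deg"], sigma_hf=doc["sigma_hf_cpd"], D=doc["D"]
    )
    return si, pool


def params_to_dict(si: ScaleInvarianceParams, pool: PoolingParams) -> dict:
    return {**asdict(si), **asdict(pool)}
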