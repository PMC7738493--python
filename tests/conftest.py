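import numpy as np
import pytest

from poolsi.params import PoolingParams, ScaleInvarianceParams
from poolsi.synth import (
    NeuronGroundTruth,
    bar_ensemble,
    grating_ensemble,
    make_cortical_sheet,
    sample_population,
)

STUDY_POOL = PoolingParams(sigma_hx=0.24, sigma_hf=0.85, D=0.54)


@pytest.fixture(scope="session")
def si_params():
    return ScaleInvarianceParams()


@pytest.fixture(scope="session")
def study_pool():
    return STUDY_POOL


@pytest.fixture(scope="session")
def small_sheet():
    return make_cortical_sheet(shape=(64, 64), pixel_size_um=12.0, seed=7)


@pytest.fixture(scope="session")
def population(small_sheet):
    return sample_population(small_sheet, STUDY_POOL, n_cells=50, seed=3)


@pytest.fixture(scope="session")
def grat_ens():
    return grating_ensemble()


@pytest.fixture(scope="session")
def bar_ens():
    return bar_ensemble(pos_extent=1.5)


def make_neuron(
    f_o=2.0, sigma_x=0.3, sigma_f=1.0, sigma_theta=25.0, f1f0=1.0,
    ori=40.0, phase=0.0, rf_x=0.0, rf_y=0.0, onoff=0.0, amplitude=1.0,
    cell_id=0,
):
    """Hand-built neuron with explicit measurement targets."""
    return NeuronGroundTruth(
        cell_id=cell_id, x_um=0.0, y_um=0.0, rf_x=rf_x, rf_y=rf_y,
        f_o=f_o, ori=ori, phase_abs=phase,
        sigma_x_true=sigma_x, sigma_f_true=sigma_f,
        sigma_logf_true=float(np.log2((f_o + sigma_f) / f_o)),
        sigma_theta_true=sigma_theta, f1f0_true=f1f0,
        sigma_x=sigma_x, sigma_f=sigma_f, sigma_theta=sigma_theta,
        f1f0=f1f0, onoff_separation=onoff, amplitude=amplitude,
    )
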