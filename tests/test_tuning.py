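"""Tuning-curve reduction: fits, bandwidth rules, exclusions, recovery."""

import numpy as np
import pandas as pd
import pytest

from poolsi.synth import (
    bar_ensemble,
    grating_ensemble,
    population_frame,
    sample_population,
    simulate_bar_kernel,
    simulate_grating_kernel,
)
from poolsi.synth.kernels import ResponseKernel, calcium_impulse_response
from poolsi.tuning import (
    HALFWIDTH_61,
    apply_exclusions,
    correct_bar_width,
    fit_bar_rf,
    fit_neuron,
    fit_orientation,
    fit_phase,
    fit_population,
    fit_sf,
    temporal_collapse,
)

from conftest import STUDY_POOL, make_neuron


def _grating_kernel(neuron, noise=0.0, seed=0):
    return simulate_grating_kernel(neuron, grating_ensemble(), noise=noise,
                                   seed=seed)


class TestTemporalCollapse:
    def test_delta_in_time_slices_at_that_frame(self):
        data = np.zeros((4, 3, 2, 15))
        data[..., 7] = 1.0
        k = ResponseKernel("grating", data, {"ori": np.arange(4),
                                             "sf": np.arange(3),
                                             "phase": np.arange(2)},
                           t=np.arange(15) / 15.0)
        sliced, t_opt = temporal_collapse(k, smooth_sigma_s=0.0)
        assert t_opt == pytest.approx(7 / 15.0)
        assert np.allclose(sliced, 1.0)

    def test_constant_kernel_breaks_tie_to_earliest(self):
        data = np.ones((2, 2, 2, 15))
        k = ResponseKernel("grating", data, {"ori": np.arange(2),
                                             "sf": np.arange(2),
                                             "phase": np.arange(2)},
                           t=np.arange(15) / 15.0)
        _, t_opt = temporal_collapse(k)
        assert t_opt == 0.0

    def test_all_zero_kernel_rejected(self):
        data = np.zeros((2, 2, 2, 15))
        k = ResponseKernel("grating", data, {"ori": np.arange(2),
                                             "sf": np.arange(2),
                                             "phase": np.arange(2)},
                           t=np.arange(15) / 15.0)
        with pytest.raises(ValueError):
            temporal_collapse(k)

    def test_smoothing_attenuates_white_noise_peak(self):
        rng = np.random.default_rng(0)
        wins = 0
        for s in range(20):
            data = rng.standard_normal((2, 2, 2, 30))
            k = ResponseKernel("grating", data, {"ori": np.arange(2),
                                                 "sf": np.arange(2),
                                                 "phase": np.arange(2)},
                               t=np.arange(30) / 15.0)
            smoothed, _ = temporal_collapse(k)
            raw = data.max()
            wins += smoothed.max() < raw
        assert wins >= 18


class TestOrientationFit:
    def test_sixty_one_percent_halfwidth_is_one_sigma(self):
        # exp(-x^2/2s^2) = 0.61 at x = s*sqrt(2 ln(1/0.61)) ~ 0.994 s
        assert HALFWIDTH_61 == pytest.approx(np.sqrt(2 * np.log(1 / 0.61)))
        assert HALFWIDTH_61 == pytest.approx(1.0, abs=0.01)

    def test_noiseless_gaussian_recovered_within_one_percent(self):
        dense = grating_ensemble(n_ori=36)
        n = make_neuron(sigma_theta=20.0, ori=60.0)
        k = simulate_grating_kernel(n, dense, noise=0.0)
        fr = fit_orientation(k)
        assert fr.params["sigma_theta"] == pytest.approx(20.0, rel=0.01)
        assert fr.variance_explained == pytest.approx(1.0, abs=1e-5)

    def test_peak_near_axis_wrap_handled(self):
        dense = grating_ensemble(n_ori=36)
        n = make_neuron(sigma_theta=18.0, ori=3.0)
        k = simulate_grating_kernel(n, dense, noise=0.0)
        fr = fit_orientation(k)
        assert fr.params["sigma_theta"] == pytest.approx(18.0, rel=0.05)


class TestSfFit:
    def test_noiseless_gaussian_recovered(self):
        n = make_neuron(f_o=2.0, sigma_f=0.8)
        fr = fit_sf(_grating_kernel(n))
        assert fr.params["f_o"] == pytest.approx(2.0, rel=0.02)
        assert fr.params["sigma_f"] == pytest.approx(0.8, rel=0.03)
        assert not fr.params["lowpass"]

    def test_monotone_decreasing_tuning_is_lowpass(self):
        sf = np.geomspace(0.25, 8, 7)
        data = np.exp(-sf / 2)[None, :, None, None] * np.ones((8, 7, 4, 15))
        k = ResponseKernel("grating", data,
                           {"ori": np.arange(8) * 22.5, "sf": sf,
                            "phase": np.arange(4) * 90.0},
                           t=np.arange(15) / 15.0)
        fr = fit_sf(k)
        assert fr.params["lowpass"]

    def test_missing_low_cutoff_falls_back_to_min_sf(self):
        # broad curve peaked at 1 cyc/deg that never drops below 61% on the
        # low side within the sampled range
        sf = np.geomspace(0.25, 8, 7)
        curve = np.exp(-0.5 * ((sf - 1.0) / 4.0) ** 2)
        data = curve[None, :, None, None] * np.ones((8, 7, 4, 15))
        k = ResponseKernel("grating", data,
                           {"ori": np.arange(8) * 22.5, "sf": sf,
                            "phase": np.arange(4) * 90.0},
                           t=np.arange(15) / 15.0)
        fr = fit_sf(k)
        assert fr.meta["f_low"] == pytest.approx(0.25)


class TestPhaseFit:
    def _phase_kernel(self, responses):
        data = np.asarray(responses, float)[None, None, :, None] * np.ones(
            (1, 1, 4, 15))
        return ResponseKernel("grating", data,
                              {"ori": np.array([0.0]), "sf": np.array([2.0]),
                               "phase": np.arange(4) * 90.0},
                              t=np.arange(15) / 15.0)

    def test_four_point_example(self):
        fr = fit_phase(self._phase_kernel([2.0, 1.0, 0.0, 1.0]), 2.0, 0.0)
        assert fr.params["F1"] == pytest.approx(2.0)
        assert fr.params["F0"] == pytest.approx(1.0)
        assert fr.params["f1f0"] == pytest.approx(2.0)

    def test_constant_response_is_complex_cell(self):
        fr = fit_phase(self._phase_kernel([1.0, 1.0, 1.0, 1.0]), 2.0, 0.0)
        assert fr.params["f1f0"] == pytest.approx(0.0, abs=1e-12)

    def test_rectified_sinusoid_near_pi(self):
        # 4-point sampling of [cos]_+ biases F1/F0 above pi (up to 4/pi
        # when the peak aligns with a sample); assert the known range
        for offset in (0.0, 22.5, 45.0):
            r = np.maximum(np.cos(np.radians(np.arange(4) * 90.0 - offset)), 0)
            fr = fit_phase(self._phase_kernel(r), 2.0, 0.0)
            assert 2.7 <= fr.params["f1f0"] <= 4.05

    def test_amplitude_invariance(self):
        a = fit_phase(self._phase_kernel([2.0, 1.0, 0.0, 1.0]), 2.0, 0.0)
        b = fit_phase(self._phase_kernel([20.0, 10.0, 0.0, 10.0]), 2.0, 0.0)
        assert a.params["f1f0"] == pytest.approx(b.params["f1f0"])

    def test_nonpositive_f0_flagged(self):
        fr = fit_phase(self._phase_kernel([-1.0, -1.0, -1.0, -1.0]), 2.0, 0.0)
        assert not fr.ok and np.isnan(fr.params["f1f0"])


class TestBarFit:
    def test_noiseless_width_and_center(self):
        n = make_neuron(sigma_x=0.3, ori=30.0, rf_x=0.4, rf_y=-0.3, onoff=0.2)
        k = simulate_bar_kernel(n, bar_ensemble(pos_extent=1.5), noise=0.0)
        fr = fit_bar_rf(k)
        assert fr.ok
        # measured width includes bar (0.2 deg) and 2x-binning smear, plus a
        # percent-level widening from averaging neighbouring orientations
        expected = np.sqrt(0.3**2 + 0.2**2 / 12 + 0.2**2 / 12)
        assert fr.params["sigma_x"] == pytest.approx(expected, rel=0.05)
        assert fr.params["rf_x"] == pytest.approx(0.4, abs=0.12)
        assert fr.params["rf_y"] == pytest.approx(-0.3, abs=0.12)

    def test_identical_on_off_gives_zero_separation(self):
        n = make_neuron(sigma_x=0.3, ori=0.0, onoff=0.0)
        k = simulate_bar_kernel(n, bar_ensemble(pos_extent=1.5), noise=0.0)
        fr = fit_bar_rf(k)
        assert fr.params["onoff_separation"] == pytest.approx(0.0, abs=1e-6)

    def test_separation_index_formula(self):
        # mu_ON = +0.2, mu_OFF = -0.2, sigma = 0.2 each -> separation 1.0
        pos = np.linspace(-1.5, 1.5, 31)
        on = np.exp(-0.5 * ((pos - 0.2) / 0.2) ** 2)
        off = np.exp(-0.5 * ((pos + 0.2) / 0.2) ** 2)
        data = np.zeros((18, 31, 2, 15))
        data[0, :, 0, :] = on[:, None]
        data[0, :, 1, :] = off[:, None]
        k = ResponseKernel("bar", data,
                           {"ori": np.arange(0.0, 180.0, 10.0), "pos": pos,
                            "lum": np.array([1.0, -1.0])},
                           t=np.arange(15) / 15.0)
        fr = fit_bar_rf(k)
        sep = abs(fr.params["mu_on"] - fr.params["mu_off"]) / (
            fr.params["sigma_on"] + fr.params["sigma_off"])
        assert sep == pytest.approx(1.0, rel=0.1)


class TestBarWidthCorrection:
    def test_zero_width_is_identity(self):
        assert correct_bar_width(0.3, 0.0) == pytest.approx(0.3)

    def test_boxcar_variance_subtraction(self):
        assert correct_bar_width(0.3, 0.2) == pytest.approx(
            np.sqrt(0.09 - 0.04 / 12))
        # ~2% shrink: the finite bar has minimal impact on the width scale
        assert correct_bar_width(0.3, 0.2) / 0.3 > 0.97

    def test_undercut_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert correct_bar_width(0.05, 0.2) == 0.0

    def test_generator_round_trip(self):
        n = make_neuron(sigma_x=0.3, ori=0.0)
        k0 = simulate_bar_kernel(n, bar_ensemble(bar_width=0.0, pos_extent=1.5),
                                 noise=0.0)
        k2 = simulate_bar_kernel(n, bar_ensemble(bar_width=0.2, pos_extent=1.5),
                                 noise=0.0)
        w0 = fit_bar_rf(k0).params["sigma_x"]
        w2 = correct_bar_width(fit_bar_rf(k2).params["sigma_x"], 0.2)
        assert w2 == pytest.approx(w0, rel=0.01)


class TestExclusions:
    def _table(self, n, ori_ok=True, sf_ok=True, rf_ok=True, lowpass=False):
        return pd.DataFrame({
            "cell_id": np.arange(n),
            "ori_fit_ok": [ori_ok] * n,
            "sf_fit_ok": [sf_ok] * n,
            "rf_fit_ok": [rf_ok] * n,
            "lowpass": [lowpass] * n,
        })

    def test_perfect_fits_no_exclusions(self):
        t, audit = apply_exclusions(self._table(10))
        assert audit["n_grating_ok"] == 10
        assert audit["n_joint_ok"] == 10

    def test_joint_yield_is_intersection(self):
        t = pd.concat([
            self._table(5),
            self._table(3, rf_ok=False),
            self._table(4, sf_ok=False),
        ], ignore_index=True)
        t, audit = apply_exclusions(t)
        assert audit["n_joint_ok"] == 5
        assert audit["n_joint_ok"] <= min(audit["n_grating_ok"],
                                          audit["n_bar_ok"])

    def test_junk_cells_counted(self, small_sheet):
        pop = sample_population(small_sheet, STUDY_POOL, n_cells=18, seed=0)
        kg = [simulate_grating_kernel(n, grating_ensemble(), noise=0.05,
                                      seed=i) for i, n in enumerate(pop)]
        # inject pure-noise kernels: they cannot reach 70% variance explained
        rng = np.random.default_rng(1)
        for i in range(2):
            kg[i].data = rng.standard_normal(kg[i].data.shape)
        table = fit_population(kg)
        table, audit = apply_exclusions(table)
        assert audit["n_excluded_grating"] >= 2
        assert not table.loc[0, "grating_ok"] and not table.loc[1, "grating_ok"]


class TestParameterRecovery:
    def test_median_relative_error_below_ten_percent(self, small_sheet):
        pop = sample_population(small_sheet, STUDY_POOL, n_cells=60,
                                scatter=0.2, seed=9)
        truth = population_frame(pop)
        gens = grating_ensemble()
        extent = float(np.abs(truth[["rf_x", "rf_y"]].to_numpy()).max()) + 1.0
        bens = bar_ensemble(pos_extent=np.ceil(extent * 10) / 10)
        kg = [simulate_grating_kernel(n, gens, noise=0.1, seed=100 + i)
              for i, n in enumerate(pop)]
        kb = [simulate_bar_kernel(n, bens, noise=0.1, seed=500 + i)
              for i, n in enumerate(pop)]
        table = fit_population(kg, kb)
        table, _ = apply_exclusions(table)

        def med_err(col, truth_col, mask):
            e = np.abs(table.loc[mask, col] - truth.loc[mask, truth_col]) \
                / truth.loc[mask, truth_col]
            return np.median(e)

        g = table["grating_ok"].to_numpy(bool)
        b = table["bar_ok"].to_numpy(bool)
        assert g.sum() > 30 and b.sum() > 30
        assert med_err("f_o", "f_o", g) < 0.10
        assert med_err("sigma_f", "sigma_f", g) < 0.10
        assert med_err("sigma_theta", "sigma_theta", g) < 0.10
        assert med_err("sigma_x", "sigma_x", b) < 0.10
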