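"""Imaging pipeline: alignment, cell detection, filtering, triggered averages."""

import numpy as np
import pandas as pd
import pytest

from poolsi import imaging
from poolsi.imaging import (
    local_crosscorr_image,
    notch_filter_trace,
    rigid_align,
    segment_cells,
    stimulus_triggered_average,
    zscore_trial,
)
from poolsi.synth import render_movie


def _punctum_movie(n_cells=20, shape=(128, 128), n_frames=240, noise=0.05,
                   seed=0, drift=None):
    rng = np.random.default_rng(seed)
    margin = 12
    pos = np.column_stack([
        rng.uniform(margin, shape[1] - margin, n_cells),
        rng.uniform(margin, shape[0] - margin, n_cells),
    ]) * 2.0  # um at 2 um/px
    traces = np.clip(rng.normal(0.5, 0.4, (n_cells, n_frames)), 0, None)
    return render_movie(pos, traces, shape=shape, pixel_size_um=2.0,
                        artifact_amp=0.0, noise_sd=noise, drift=drift,
                        seed=seed + 1)


class TestRigidAlign:
    def test_zero_drift_gives_zero_shifts(self):
        mov = _punctum_movie(n_cells=5, shape=(48, 48), n_frames=30, noise=0.02)
        _, shifts = rigid_align(mov.frames)
        assert np.abs(shifts).max() <= 1

    def test_known_drift_recovered_within_one_pixel(self):
        n_frames = 40
        rng = np.random.default_rng(3)
        drift = rng.integers(-3, 4, (n_frames, 2))
        mov = _punctum_movie(n_cells=8, shape=(64, 64), n_frames=n_frames,
                             noise=0.02, drift=drift)
        _, shifts = rigid_align(mov.frames)
        # recovered shift should undo the applied drift
        err = shifts + drift
        err -= np.round(err.mean(axis=0))  # common offset is unidentifiable
        assert np.abs(err).max() <= 1

    def test_alignment_is_idempotent(self):
        drift = np.tile([[2, -1]], (30, 1))
        drift[::2] = 0
        mov = _punctum_movie(n_cells=6, shape=(48, 48), n_frames=30,
                             noise=0.01, drift=drift)
        once, _ = rigid_align(mov.frames)
        twice, shifts2 = rigid_align(once)
        assert np.abs(shifts2).max() == 0
        assert np.array_equal(once, twice)

    def test_rejects_too_short_movies(self):
        with pytest.raises(ValueError):
            rigid_align(np.zeros((1, 8, 8)))


class TestLocalCrossCorr:
    def test_white_noise_movie_scores_near_zero(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((200, 40, 40))
        lx = local_crosscorr_image(frames, pixel_size_um=10.0)
        z = (lx.values - np.median(lx.values)) / (
            np.median(np.abs(lx.values - np.median(lx.values))) * 1.4826
        )
        assert np.abs(z).max() < 6.0  # no structure anywhere near cell-like

    def test_single_punctum_is_brightest_at_punctum(self):
        mov = _punctum_movie(n_cells=1, shape=(48, 48), n_frames=120, noise=0.05,
                             seed=4)
        lx = local_crosscorr_image(mov.frames, pixel_size_um=2.0)
        peak = np.unravel_index(np.argmax(lx.values), lx.values.shape)
        true_px = mov.positions_um[0][::-1] / 2.0  # (row, col)
        assert np.hypot(*(np.array(peak) - true_px)) <= 2.0

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(1)
        frames = rng.standard_normal((12, 24, 24))
        lx = local_crosscorr_image(frames, pixel_size_um=10.0)
        f = frames - frames.mean(axis=0, keepdims=True)
        kern = imaging.dog_kernel(10.0)
        rad = kern.shape[0] // 2
        # naive per-pixel loop on the interior (kernel fully inside)
        for y in range(rad, 24 - rad):
            for x in range(rad, 24 - rad):
                acc = 0.0
                for t in range(12):
                    patch = f[t, y - rad : y + rad + 1, x - rad : x + rad + 1]
                    acc += f[t, y, x] * np.sum(patch * kern[::-1, ::-1])
                assert acc == pytest.approx(lx.values[y, x], rel=1e-9, abs=1e-9)


class TestSegmentation:
    def test_recovers_planted_puncta(self):
        mov = _punctum_movie(n_cells=20, noise=0.05, seed=6)
        lx = local_crosscorr_image(mov.frames, pixel_size_um=2.0)
        rois = segment_cells(lx)
        matched = 0
        for true_xy in mov.positions_um:
            d = [np.hypot(r.centroid_um[0] - true_xy[0],
                          r.centroid_um[1] - true_xy[1]) for r in rois]
            if d and min(d) <= 3.0:
                matched += 1
        assert matched >= 18

    def test_flat_image_yields_no_rois(self):
        lx = imaging.LocalXImage(np.zeros((64, 64)), 2.0)
        assert segment_cells(lx) == []

    def test_rois_do_not_overlap(self):
        mov = _punctum_movie(n_cells=15, noise=0.05, seed=8)
        lx = local_crosscorr_image(mov.frames, pixel_size_um=2.0)
        rois = segment_cells(lx)
        seen = set()
        for r in rois:
            pix = set(map(tuple, r.pixels))
            assert not pix & seen
            seen |= pix


class TestNotchFilter:
    def test_white_noise_unchanged(self):
        rng = np.random.default_rng(0)
        tr = rng.standard_normal(600)
        out = notch_filter_trace(tr, fs=15.0)
        assert np.allclose(out, tr)

    def test_attenuates_artifacts_spares_broadband(self):
        rng = np.random.default_rng(1)
        n = 1800
        t = np.arange(n) / 15.0
        signal = rng.standard_normal(n)
        artifacts = 3.0 * np.sin(2 * np.pi * 0.4 * t) + 3.0 * np.sin(2 * np.pi * 1.5 * t)
        out = notch_filter_trace(signal + artifacts, fs=15.0)
        spec_in = np.abs(np.fft.rfft(signal + artifacts))
        spec_out = np.abs(np.fft.rfft(out))
        freqs = np.fft.rfftfreq(n, 1 / 15.0)
        for f0 in (0.4, 1.5):
            i = np.argmin(np.abs(freqs - f0))
            atten_db = 20 * np.log10(spec_in[i] / spec_out[i])
            assert atten_db >= 20.0
        # broadband loss < 1 dB outside the notches
        away = (np.abs(freqs - 0.4) > 0.1) & (np.abs(freqs - 1.5) > 0.1) & (freqs > 0)
        loss_db = 20 * np.log10(
            np.linalg.norm(spec_in[away]) / np.linalg.norm(spec_out[away])
        )
        assert abs(loss_db) < 1.0

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        t = np.arange(900) / 15.0
        tr = rng.standard_normal(900) + 2.5 * np.sin(2 * np.pi * 1.1 * t)
        once = notch_filter_trace(tr, fs=15.0)
        twice = notch_filter_trace(once, fs=15.0)
        assert np.allclose(once, twice, atol=1e-6 * np.abs(once).max())

    def test_band_validation(self):
        with pytest.raises(ValueError):
            notch_filter_trace(np.zeros(128), fs=15.0, search_band=(0.2, 10.0))
        with pytest.raises(ValueError):
            notch_filter_trace(np.zeros(32), fs=15.0)


class TestZScore:
    def test_constant_trace_flags_exclusion(self):
        with pytest.raises(ValueError):
            zscore_trial(np.ones(100))

    def test_affine_invariance_and_moments(self):
        rng = np.random.default_rng(0)
        tr = rng.standard_normal(200)
        z1 = zscore_trial(tr)
        z2 = zscore_trial(3.5 * tr - 7.0)
        assert np.allclose(z1, z2)
        assert z1.mean() == pytest.approx(0.0, abs=1e-12)
        assert z1.std() == pytest.approx(1.0, rel=1e-12)


class TestTriggeredAverage:
    def _delta_setup(self):
        axes = {"cond": np.array([0.0, 1.0, 2.0])}
        log = pd.DataFrame({
            "onset_frame": [0, 20, 40, 60],
            "cond": [1.0, 0.0, 1.0, 2.0],
        })
        log.attrs["kind"] = "grating"
        return axes, log

    def test_delta_stimulus_indicator(self):
        axes, log = self._delta_setup()
        trace = np.zeros(80)
        for f, c in zip(log["onset_frame"], log["cond"]):
            if c == 1.0:
                trace[f : f + 15] = 1.0
        [k] = stimulus_triggered_average(trace[None, :], log, axes)
        assert np.allclose(k.data[1], 1.0)
        assert np.allclose(k.data[0], 0.0) and np.allclose(k.data[2], 0.0)

    def test_matches_bruteforce_event_loop(self):
        rng = np.random.default_rng(0)
        axes = {"a": np.array([0.0, 1.0]), "b": np.array([0.0, 1.0, 2.0])}
        onsets = np.arange(0, 400, 4)
        log = pd.DataFrame({
            "onset_frame": onsets,
            "a": rng.choice([0.0, 1.0], len(onsets)),
            "b": rng.choice([0.0, 1.0, 2.0], len(onsets)),
        })
        trace = rng.standard_normal(420)
        [k] = stimulus_triggered_average(trace[None, :], log, axes)
        n_t = k.data.shape[-1]
        for ia, av in enumerate(axes["a"]):
            for ib, bv in enumerate(axes["b"]):
                segs = [trace[o : o + n_t]
                        for o, a, b in zip(log["onset_frame"], log["a"], log["b"])
                        if a == av and b == bv and o + n_t <= len(trace)]
                if segs:
                    assert np.allclose(k.data[ia, ib], np.mean(segs, axis=0))
                else:
                    assert np.all(np.isnan(k.data[ia, ib]))

    def test_kernel_se_scales_with_trial_count(self):
        # doubling the number of presentations should shrink the kernel SE
        # by ~sqrt(2) (checked as halving of variance within +/-20 %)
        rng = np.random.default_rng(42)
        axes = {"c": np.array([0.0])}
        errs = {40: [], 80: []}
        for n_trials in errs:
            for _ in range(50):
                onsets = np.arange(n_trials) * 16
                log = pd.DataFrame({"onset_frame": onsets,
                                    "c": np.zeros(n_trials)})
                trace = rng.standard_normal(onsets[-1] + 20)
                [k] = stimulus_triggered_average(trace[None, :], log, axes)
                errs[n_trials].append(k.data.mean())
        se_ratio = np.std(errs[40]) / np.std(errs[80])
        assert se_ratio == pytest.approx(np.sqrt(2.0), rel=0.20)

    def test_never_shown_condition_flagged(self):
        axes, log = self._delta_setup()
        log = log[log["cond"] != 2.0]
        [k] = stimulus_triggered_average(np.zeros((1, 80)), log, axes)
        assert k.meta["missing"] == 1
        assert np.all(np.isnan(k.data[2]))


class TestEndToEnd:
    def test_extracted_kernels_match_generator_truth(self, grat_ens):
        # movie -> align -> detect -> notch/zscore -> STA must recover the
        # generator's noiseless kernels (correlation > 0.9 at default SNR)
        from conftest import make_neuron
        from poolsi.synth import simulate_session
        from poolsi.synth.kernels import grating_condition_response
        from poolsi.tuning import temporal_collapse

        neurons = [
            make_neuron(f_o=1.0, ori=30.0, f1f0=2.5, sigma_theta=20.0,
                        sigma_f=0.6, cell_id=0),
            make_neuron(f_o=3.0, ori=120.0, f1f0=0.3, sigma_theta=35.0,
                        sigma_f=1.6, cell_id=1),
        ]
        traces, log = simulate_session(neurons, grat_ens, duration_s=1200.0,
                                       block_s=40.0, gap_s=4.0, seed=0)
        pos = np.array([[30.0, 30.0], [80.0, 70.0]])
        mov = render_movie(pos, traces, shape=(56, 56), pixel_size_um=2.0,
                           artifact_freqs=(0.4, 1.5), artifact_amp=0.3,
                           noise_sd=0.05, seed=1)
        aligned, _ = rigid_align(mov.frames)
        lx = local_crosscorr_image(aligned, 2.0)
        rois = segment_cells(lx)
        assert len(rois) >= 2
        raw = imaging.extract_traces(aligned, rois)
        proc = np.stack([
            zscore_trial(notch_filter_trace(tr, fs=15.0)) for tr in raw
        ])
        kernels = stimulus_triggered_average(proc, log, grat_ens.axes)
        # match ROIs to ground-truth cells by position
        for n, p in zip(neurons, pos):
            d = [np.hypot(r.centroid_um[0] - p[0], r.centroid_um[1] - p[1])
                 for r in rois]
            k = kernels[int(np.argmin(d))]
            truth = grating_condition_response(n, grat_ens)
            meas, _ = temporal_collapse(k)
            r = np.corrcoef(meas.ravel(), truth.ravel())[0, 1]
            assert r > 0.9
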