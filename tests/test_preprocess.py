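"""EEG epoch container and cleaning operations."""

import warnings

import numpy as np
import pytest

from cppddm.epochs import EEGEpochArray, make_montage
from cppddm.preprocess import (
    censor_transients,
    dc_median_correct,
    drop_bad_trials,
    epoch_response_locked,
    flag_outlier_electrodes,
    interpolate_electrodes,
    preprocess_pipeline,
    regress_out_eog,
    rereference_and_baseline,
)


def make_epochs(data, fs=500.0, t0=-600.0):
    n_el = data.shape[1]
    _, neighbours = make_montage(n_el)
    time = t0 + 1000.0 / fs * np.arange(data.shape[2])
    return EEGEpochArray(
        data=data,
        time_ms=time,
        channel_names=[f"E{i}" for i in range(n_el)],
        neighbours=neighbours,
        sample_rate=fs,
    )


@pytest.fixture()
def gaussian_epochs():
    rng = np.random.default_rng(0)
    return make_epochs(rng.normal(size=(20, 16, 100)))


class TestContainer:
    def test_time_axis_validation(self):
        _, neighbours = make_montage(4)
        time = np.arange(10) * 2.0  # 2 ms steps = 500 Hz, not 250
        with pytest.raises(ValueError, match="sample_rate"):
            EEGEpochArray(np.zeros((2, 4, 10)), time, list("abcd"), neighbours, 250.0)

    def test_neighbour_symmetry_enforced(self):
        data = np.zeros((2, 4, 10))
        time = np.arange(10) * 2.0
        with pytest.raises(ValueError, match="symmetric"):
            EEGEpochArray(data, time, list("abcd"), [[1], [], [], []], 500.0)

    def test_hdf5_roundtrip(self, gaussian_epochs, tmp_path):
        p = tmp_path / "ep.h5"
        gaussian_epochs.to_hdf5(p)
        back = EEGEpochArray.from_hdf5(p)
        np.testing.assert_array_equal(back.data, gaussian_epochs.data)
        np.testing.assert_array_equal(back.time_ms, gaussian_epochs.time_ms)
        assert back.neighbours == gaussian_epochs.neighbours
        assert back.channel_names == gaussian_epochs.channel_names

    def test_montage_degrees(self):
        _, neighbours = make_montage(64)
        degrees = [len(n) for n in neighbours]
        assert min(degrees) >= 4
        for e, nbrs in enumerate(neighbours):
            for n in nbrs:
                assert e in neighbours[n]


class TestDCAndOutliers:
    def test_constant_channel_zeroed(self):
        data = np.full((3, 16, 50), 7.0)
        out = dc_median_correct(make_epochs(data))
        np.testing.assert_allclose(out.data, 0.0)

    def test_median_zero_and_translation_invariance(self, gaussian_epochs):
        out = dc_median_correct(gaussian_epochs)
        np.testing.assert_allclose(np.nanmedian(out.data, axis=2), 0.0, atol=1e-12)
        shifted = make_epochs(gaussian_epochs.data + 100.0)
        out2 = dc_median_correct(shifted)
        np.testing.assert_allclose(out2.data, out.data, atol=1e-9)

    def test_homogeneous_data_rarely_flagged(self):
        """With a 2.5% tail, >= 15% exceedance per electrode is rare."""
        n_flagged = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ep = make_epochs(rng.normal(size=(10, 16, 100)))
            n_flagged += int(flag_outlier_electrodes(ep).sum())
        assert n_flagged / (20 * 16) < 0.01

    def test_scaled_electrode_flagged(self, gaussian_epochs):
        data = gaussian_epochs.data.copy()
        data[:, 5, :] *= 50
        mask = flag_outlier_electrodes(make_epochs(data))
        assert mask[5]
        assert mask.sum() == 1

    def test_pct_100_flags_nothing(self, gaussian_epochs):
        assert not flag_outlier_electrodes(gaussian_epochs, pct=100).any()


class TestInterpolation:
    def test_fixed_point(self, gaussian_epochs):
        """An electrode already equal to its neighbour mean is unchanged."""
        data = gaussian_epochs.data.copy()
        nbrs = gaussian_epochs.neighbours[3]
        data[:, 3, :] = data[:, nbrs, :].mean(axis=1)
        ep = make_epochs(data)
        mask = np.zeros(16, dtype=bool)
        mask[3] = True
        out = interpolate_electrodes(ep, mask)
        np.testing.assert_allclose(out.data[:, 3, :], data[:, 3, :], atol=1e-12)

    def test_constant_neighbours(self, gaussian_epochs):
        data = gaussian_epochs.data.copy()
        nbrs = gaussian_epochs.neighbours[0]
        data[:, nbrs, :] = 3.0
        mask = np.zeros(16, dtype=bool)
        mask[0] = True
        out = interpolate_electrodes(make_epochs(data), mask)
        np.testing.assert_allclose(out.data[:, 0, :], 3.0)

    def test_matches_bruteforce_neighbour_mean(self, gaussian_epochs):
        mask = np.zeros(16, dtype=bool)
        mask[[2, 9]] = True
        out = interpolate_electrodes(gaussian_epochs, mask)
        for e in (2, 9):
            good = [n for n in gaussian_epochs.neighbours[e] if not mask[n]]
            expected = gaussian_epochs.data[:, good, :].mean(axis=1)
            np.testing.assert_allclose(out.data[:, e, :], expected)


class TestEOG:
    def test_perfect_fit_residual_zero(self, gaussian_epochs):
        rng = np.random.default_rng(1)
        heog = rng.normal(size=(20, 100))
        veog = rng.normal(size=(20, 100))
        data = gaussian_epochs.data.copy()
        data[:, 4, :] = 0.5 * heog
        out = regress_out_eog(make_epochs(data), heog, veog)
        np.testing.assert_allclose(out.data[:, 4, :], 0.0, atol=1e-10)

    def test_residual_uncorrelated_with_eog(self, gaussian_epochs):
        rng = np.random.default_rng(2)
        heog = rng.normal(size=(20, 100))
        veog = rng.normal(size=(20, 100))
        data = gaussian_epochs.data + 0.3 * heog[:, None, :] - 0.2 * veog[:, None, :]
        out = regress_out_eog(make_epochs(data), heog, veog)
        for e in range(0, 16, 5):
            resid = out.data[:, e, :].ravel()
            for trace in (heog.ravel(), veog.ravel()):
                r = np.corrcoef(resid, trace)[0, 1]
                assert abs(r) < 1e-10

    def test_collinear_eog_warns(self, gaussian_epochs):
        rng = np.random.default_rng(3)
        heog = rng.normal(size=(20, 100))
        with pytest.warns(UserWarning, match="collinear"):
            regress_out_eog(gaussian_epochs, heog, 2.0 * heog)


class TestTransientsAndReference:
    def test_single_spike_censored(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(5, 16, 200))
        sd = data[:, 7, :].std()
        data[2, 7, 50] = 10 * sd
        out = censor_transients(make_epochs(data))
        assert np.isnan(out.data[2, 7, 50])
        assert np.isnan(out.data).sum() <= 3  # other extreme draws at most

    def test_infinite_threshold_is_identity(self, gaussian_epochs):
        out = censor_transients(gaussian_epochs, k_sd=float("inf"))
        np.testing.assert_array_equal(out.data, gaussian_epochs.data)

    def test_constant_trace_untouched(self):
        data = np.full((3, 16, 50), 2.5)
        out = censor_transients(make_epochs(data))
        assert not np.isnan(out.data).any()

    def test_reference_and_baseline_postconditions(self, gaussian_epochs):
        out = rereference_and_baseline(gaussian_epochs)
        np.testing.assert_allclose(np.nanmean(out.data, axis=1), 0.0, atol=1e-10)
        sel = (out.time_ms >= out.time_ms[0]) & (out.time_ms <= out.time_ms[0] + 100)
        np.testing.assert_allclose(
            np.nanmean(out.data[:, :, sel], axis=2), 0.0, atol=1e-10
        )

    def test_idempotent(self, gaussian_epochs):
        once = rereference_and_baseline(gaussian_epochs)
        twice = rereference_and_baseline(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)


class TestTrialRejection:
    @pytest.mark.parametrize("n_bad,kept", [(19, False), (18, True)])
    def test_threshold(self, n_bad, kept):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(4, 128, 50))
        data[1, :n_bad, :] = np.nan
        out, report = drop_bad_trials(make_epochs(data))
        assert (1 in out.trial_index) == kept
        assert report.loc[1, "n_bad_electrodes"] == n_bad

    def test_clean_data_untouched(self, gaussian_epochs):
        out, report = drop_bad_trials(gaussian_epochs)
        assert out.n_trials == gaussian_epochs.n_trials
        assert report["kept"].all()


class TestResponseLocking:
    def test_window_arithmetic_at_500hz(self):
        """rt = 1.0 s: 400-sample window starting 300 samples after
        stimulus onset, time axis -600..+198 ms at 2 ms steps."""
        data = np.zeros((1, 4, 1000))
        ep = make_epochs(data, t0=0.0)
        out = epoch_response_locked(ep, [1.0])
        assert out.n_samples == 400
        assert out.time_ms[0] == -600.0 and out.time_ms[-1] == 198.0
        # sample at t=-600ms corresponds to stimulus sample 500-300=200
        data2 = data.copy()
        data2[0, :, 200] = 9.0
        out2 = epoch_response_locked(make_epochs(data2, t0=0.0), [1.0])
        assert out2.data[0, 0, 0] == 9.0

    def test_short_rt_dropped(self):
        data = np.zeros((2, 4, 1000))
        ep = make_epochs(data, t0=0.0)
        with pytest.warns(UserWarning, match="dropped"):
            out = epoch_response_locked(ep, [0.3, 1.0])
        assert out.n_trials == 1
        assert list(out.trial_index) == [1]

    def test_ramp_stays_aligned_across_rts(self):
        """A ramp peaking at the response lands at t = 0 for any RT."""
        fs = 500.0
        n = 1500
        rts = [0.9, 1.3, 1.9]
        data = np.zeros((3, 4, n))
        for i, rt in enumerate(rts):
            resp = int(rt * fs)
            ramp = np.maximum(0, 1 - np.abs(np.arange(n) - resp) / 100)
            data[i] = ramp[None, :]
        out = epoch_response_locked(make_epochs(data, t0=0.0), rts)
        i0 = int(np.argmin(np.abs(out.time_ms)))
        for i in range(3):
            assert int(np.argmax(out.data[i, 0])) == i0


class TestFullPipeline:
    def test_trial_identity_preserved_and_missing_monotone(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(12, 16, 120))
        data[3, 4, 10] = 500.0  # transient
        ep = make_epochs(data)
        out, report = preprocess_pipeline(ep)
        assert set(out.trial_index).issubset(set(ep.trial_index))
        assert np.isnan(out.data).sum() >= np.isnan(ep.data).sum()

    def test_identity_up_to_reference_on_clean_data(self):
        """Artefact-free data pass through unchanged except for the
        re-referencing/baselining affine step."""
        # deterministic equal-amplitude oscillations: no 4-SD transients
        # and every electrode has the same 2.5% exceedance of the pooled
        # amplitude percentile, so nothing is ever flagged
        t = np.arange(80) / 80.0
        phases = np.linspace(0, np.pi, 16, endpoint=False)
        trial_shift = np.linspace(0, 1, 6)
        data = np.sin(
            2 * np.pi * (3 * t[None, None, :] + phases[None, :, None] + trial_shift[:, None, None])
        )
        ep = make_epochs(data)
        out, _ = preprocess_pipeline(ep)
        manual = rereference_and_baseline(dc_median_correct(ep))
        assert out.n_trials == 6
        np.testing.assert_allclose(out.data, manual.data, atol=1e-9)
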