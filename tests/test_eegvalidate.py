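"""Preprocessing, blink projection, epoching, rejection, features, stats."""

import warnings

import numpy as np
import pytest
from scipy import signal

from neurosync import eegvalidate as ev
from neurosync.eegsynth import (CHANNELS, SFREQ, DeviceProfile, EffectSpec,
                                Recording, TaskProtocol, inject_artifacts,
                                synth_task_recording)


def make_recording(data, events=(), lost=None):
    data = np.asarray(data, dtype=float)
    return Recording(data=data, sfreq=SFREQ, ch_names=CHANNELS,
                     events=list(events),
                     lost_mask=(np.zeros(data.shape[1], dtype=bool)
                                if lost is None else lost))


def make_epochs(data, labels=None, times=None, lost=None):
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_t = data.shape
    return ev.EpochSet(
        data=data,
        times=(np.arange(n_t) / SFREQ if times is None else times),
        labels=(np.array(["a"] * n_tr) if labels is None
                else np.asarray(labels)),
        sfreq=SFREQ, ch_names=CHANNELS[:n_ch],
        lost=(np.zeros((n_tr, n_t), dtype=bool) if lost is None else lost))


class TestPreprocess:
    def test_common_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(7, 5000))
        shifted = base + 10.0  # +10 µV on every channel
        out_a = ev.preprocess(make_recording(base))
        out_b = ev.preprocess(make_recording(shifted))
        np.testing.assert_allclose(out_a.data, out_b.data, atol=1e-9)

    def test_stopband_and_passband_response(self):
        t = np.arange(int(20 * SFREQ)) / SFREQ
        x50 = np.tile(np.sin(2 * np.pi * 50.0 * t), (7, 1))
        x10 = np.tile(np.sin(2 * np.pi * 10.0 * t), (7, 1))
        mid = slice(int(2 * SFREQ), int(18 * SFREQ))
        out50 = ev.preprocess(make_recording(x50), band=(1, 30), mode="bci")
        out10 = ev.preprocess(make_recording(x10), band=(1, 30), mode="bci")
        rms_in = np.sqrt(np.mean(x50[0, mid] ** 2))
        rms50 = np.sqrt(np.mean(out50.data[0, mid] ** 2))
        rms10 = np.sqrt(np.mean(out10.data[0, mid] ** 2))
        assert 20 * np.log10(rms_in / rms50) >= 40.0
        assert rms10 == pytest.approx(np.sqrt(0.5), rel=0.05)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ev.preprocess(make_recording(np.zeros((7, 100))), band=(1, 300))


class TestBlinkProject:
    def contaminated(self, seed=0):
        spec = EffectSpec(loss_rate=0.0, amp_artifact_rate_hz=0.0)
        clean = synth_task_recording(TaskProtocol.eyes(), spec,
                                     DeviceProfile.lab_grade(), seed)
        dirty, log = inject_artifacts(clean, spec, seed=seed + 1)
        return clean, dirty, [e for e in log if e["kind"] == "blink"]

    def test_blink_variance_reduced(self):
        clean, dirty, blinks = self.contaminated()
        out = ev.blink_project(dirty)
        fpz = dirty.ch_names.index("Fpz")
        before = after = 0.0
        for e in blinks:
            seg = slice(e["start"], e["start"] + e["length"])
            before += dirty.data[fpz, seg].var()
            after += out.data[fpz, seg].var()
        assert after <= 0.2 * before

    def test_alpha_power_preserved(self):
        clean, dirty, _ = self.contaminated()
        out = ev.blink_project(dirty)
        oz = dirty.ch_names.index("Oz")

        def alpha(x):
            f, p = signal.welch(x, fs=SFREQ, nperseg=2000)
            return p[(f >= 8) & (f <= 12)].sum()

        # compare on the task portion, away from blink-dominated samples
        sel = slice(int(60 * SFREQ), None)
        assert abs(alpha(out.data[oz, sel]) - alpha(clean.data[oz, sel])) \
            <= 0.1 * alpha(clean.data[oz, sel])

    def test_no_blinks_returns_unchanged_with_warning(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.normal(size=(7, 10000)))
        with pytest.warns(UserWarning, match="no blinks"):
            out = ev.blink_project(rec)
        np.testing.assert_array_equal(out.data, rec.data)


class TestExtractEpochs:
    def test_eyes_window_counts_and_length(self):
        rec = synth_task_recording(TaskProtocol.eyes(), EffectSpec(),
                                   DeviceProfile.lab_grade(), 0)
        epochs = ev.extract_epochs(rec, "eyes")
        assert epochs.n_trials == 20
        assert epochs.data.shape[2] == int(4.5 * SFREQ)

    def test_ssvep_three_overlapping_epochs_per_trial(self):
        rec = synth_task_recording(TaskProtocol.ssvep(), EffectSpec(),
                                   DeviceProfile.lab_grade(), 0)
        epochs = ev.extract_epochs(rec, "ssvep")
        assert epochs.n_trials == 6 * 3
        assert epochs.data.shape[2] == int(5.0 * SFREQ)

    def test_motor_windows(self):
        rec = synth_task_recording(TaskProtocol.motor(), EffectSpec(),
                                   DeviceProfile.lab_grade(), 0)
        epochs = ev.extract_epochs(rec, "motor")
        assert (epochs.labels == "move").sum() == 25
        assert (epochs.labels == "rest").sum() == 25
        assert epochs.data.shape[2] == int(4.0 * SFREQ)

    def test_oddball_baseline_correction_exact_on_flat_signal(self):
        n = int(10 * SFREQ)
        rec = make_recording(np.full((7, n), 5.0),
                             events=[(5.0, "target")])
        epochs = ev.extract_epochs(rec, "oddball")
        assert np.allclose(epochs.data, 0.0)
        assert epochs.times[0] == pytest.approx(-0.2)

    def test_marker_outside_recording_skipped(self):
        rec = make_recording(np.zeros((7, int(2 * SFREQ))),
                             events=[(1.0, "target"), (100.0, "target")])
        with pytest.warns(UserWarning, match="outside"):
            epochs = ev.extract_epochs(rec, "oddball")
        assert epochs.n_trials == 1

    def test_bci_mode_window_and_baseline(self):
        n = int(10 * SFREQ)
        rng = np.random.default_rng(0)
        rec = make_recording(rng.normal(size=(7, n)),
                             events=[(5.0, "target")])
        epochs = ev.extract_epochs(rec, "bci", mode="bci")
        assert epochs.times[0] == pytest.approx(0.0)
        assert epochs.data.shape[2] == int(0.7 * SFREQ)
        first100 = epochs.times < 0.100
        assert np.allclose(epochs.data[:, :, first100].mean(axis=2), 0.0,
                           atol=1e-9)


class TestRejectionRules:
    def test_loss_rule_boundary_20_vs_21(self):
        data = np.zeros((2, 7, 1000))
        lost = np.zeros((2, 1000), dtype=bool)
        lost[0, 100:121] = True  # 21 consecutive -> rejected
        lost[1, 100:120] = True  # exactly 20 -> kept
        epochs = make_epochs(data, lost=lost)
        epochs, counts = ev.reject_epochs(epochs)
        assert epochs.rejected[0] and epochs.reject_reason[0] == "loss"
        assert not epochs.rejected[1]

    def test_amplitude_rule_boundary_40_vs_60(self):
        t = np.arange(1000) / SFREQ
        data = np.zeros((2, 7, 1000))
        data[0, 0] = 60.0 * np.sin(2 * np.pi * 5 * t)
        data[1, 0] = 40.0 * np.sin(2 * np.pi * 5 * t)
        epochs = make_epochs(data)
        epochs, _ = ev.reject_epochs(epochs)
        assert epochs.rejected[0] and epochs.reject_reason[0] == "amplitude"
        assert not epochs.rejected[1]

    def test_bci_amplitude_bound_is_100(self):
        t = np.arange(1000) / SFREQ
        data = np.zeros((2, 7, 1000))
        data[0, 0] = 90.0 * np.sin(2 * np.pi * 5 * t)
        data[1, 0] = 110.0 * np.sin(2 * np.pi * 5 * t)
        epochs = make_epochs(data)
        epochs, _ = ev.reject_epochs(epochs, mode="bci")
        assert not epochs.rejected[0]
        assert epochs.rejected[1]

    def test_linear_rule_ramp_vs_noise(self):
        rng = np.random.default_rng(0)
        data = np.zeros((2, 7, 1000))
        data[0] = np.linspace(-40, 40, 1000)[None, :]  # r^2 == 1
        data[1] = rng.normal(0, 5, size=(7, 1000))     # r^2 ~ 0
        epochs = make_epochs(data)
        epochs, _ = ev.reject_epochs(epochs)
        assert epochs.rejected[0] and epochs.reject_reason[0] == "linear"
        assert not epochs.rejected[1]

    def test_constant_channel_defines_r2_zero(self):
        data = np.full((1, 7, 1000), 3.0)
        assert not ev.rule_linear(data[0], np.zeros(1000, dtype=bool), SFREQ)

    def test_psd_rule_triggers_on_extreme_high_band_power(self):
        t = np.arange(2250) / SFREQ
        hot = np.tile(8000.0 * np.sin(2 * np.pi * 25.0 * t), (7, 1))
        quiet = np.tile(10.0 * np.sin(2 * np.pi * 25.0 * t), (7, 1))
        nomask = np.zeros(2250, dtype=bool)
        assert ev.rule_psd(hot, nomask, SFREQ)
        assert not ev.rule_psd(quiet, nomask, SFREQ)

    def test_first_triggering_rule_recorded(self):
        t = np.arange(1000) / SFREQ
        data = np.zeros((1, 7, 1000))
        data[0, 0] = 80.0 * np.sin(2 * np.pi * 5 * t)  # amplitude-violating
        lost = np.zeros((1, 1000), dtype=bool)
        lost[0, :30] = True                            # and loss-violating
        epochs = make_epochs(data, lost=lost)
        epochs, counts = ev.reject_epochs(epochs)
        assert epochs.reject_reason[0] == "loss"
        assert counts["loss"] == 1 and counts["amplitude"] == 0


class TestPsdFeatures:
    def test_welch_peak_bin_exactly_at_10hz(self):
        t = np.arange(2500) / SFREQ
        data = np.tile(np.sin(2 * np.pi * 10.0 * t), (1, 7, 1)) * 5.0
        epochs = make_epochs(data)
        freqs, psd = ev.psd_features(epochs, "welch")
        assert freqs[np.argmax(psd[0, 0])] == 10.0
        assert np.diff(freqs)[0] == pytest.approx(0.1)

    def test_multitaper_flat_for_white_noise(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(100, 1, 2500))
        epochs = make_epochs(data)
        freqs, psd = ev.psd_features(epochs, "multitaper")
        mean_db = 10 * np.log10(psd.mean(axis=0)[0])
        sel = (freqs >= 5) & (freqs <= 25)
        assert mean_db[sel].max() - mean_db[sel].min() < 2.0

    def test_quadratic_amplitude_scaling(self):
        t = np.arange(2500) / SFREQ
        base = np.sin(2 * np.pi * 10.0 * t)
        epochs = make_epochs(np.stack([np.tile(base, (7, 1)),
                                       np.tile(2 * base, (7, 1))]))
        freqs, psd = ev.psd_features(epochs, "welch")
        k = np.argmax(psd[0, 0])
        assert psd[1, 0, k] == pytest.approx(4 * psd[0, 0, k], rel=1e-6)

    def test_short_epoch_rejected_for_welch(self):
        epochs = make_epochs(np.zeros((1, 7, 1000)))
        with pytest.raises(ValueError, match="Welch"):
            ev.psd_features(epochs, "welch")


class TestErspMorlet:
    def make_stationary(self, n_trials=50, amp_post=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(8 * SFREQ)
        times = -6.0 + np.arange(n) / SFREQ
        data = rng.normal(size=(n_trials, 1, n))
        if amp_post != 1.0:
            data[:, :, times >= 0] *= amp_post
        return make_epochs(data, times=times)

    def test_stationary_signal_gives_zero_db(self):
        epochs = self.make_stationary()
        freqs, times, ersp = ev.ersp_morlet(epochs)
        post = ersp[:, :, (times >= 0.5) & (times <= 1.5)]
        assert np.abs(post.mean()) < 0.5

    def test_power_doubling_gives_plus_3db(self):
        epochs = self.make_stationary(amp_post=np.sqrt(2.0))
        freqs, times, ersp = ev.ersp_morlet(epochs)
        post = ersp[:, 5:25, (times >= 0.5) & (times <= 1.5)]
        assert post.mean() == pytest.approx(3.01, abs=0.5)

    def test_erd_fraction_half_gives_minus_3db(self):
        epochs = self.make_stationary(amp_post=np.sqrt(0.5))
        freqs, times, ersp = ev.ersp_morlet(epochs)
        post = ersp[:, 9:20, (times >= 0.5) & (times <= 1.5)]
        assert post.mean() == pytest.approx(-3.01, abs=0.5)

    def test_baseline_outside_epoch_raises(self):
        epochs = make_epochs(np.zeros((2, 1, 1000)))
        with pytest.raises(ValueError, match="baseline"):
            ev.ersp_morlet(epochs, baseline_window=(-6.0, 0.0))


class TestErpAverage:
    def test_identical_trials_average_is_any_trial(self):
        trial = np.random.default_rng(0).normal(size=(7, 350))
        epochs = make_epochs(np.tile(trial, (5, 1, 1)))
        out = ev.erp_average(epochs)
        np.testing.assert_allclose(out["a"]["mean"], trial)

    def test_noise_average_shrinks_with_sqrt_n(self):
        rng = np.random.default_rng(3)
        sd = 10.0
        epochs = make_epochs(rng.normal(0, sd, size=(1000, 1, 50)))
        avg = ev.erp_average(epochs)["a"]["mean"]
        assert np.abs(avg).mean() < 3 * sd / np.sqrt(1000)
        assert np.abs(avg).max() < 5 * sd / np.sqrt(1000)

    def test_p300_latency_within_window(self):
        rec = synth_task_recording(TaskProtocol.oddball(), EffectSpec(),
                                   DeviceProfile.lab_grade(), 2)
        rec = ev.preprocess(rec)
        epochs = ev.extract_epochs(rec, "oddball")
        out = ev.erp_average(epochs, peak_window=(0.25, 0.55))
        cz = epochs.channel_index("Cz")
        lat_ms = out["target"]["peak_latency"][cz] * 1e3
        assert 250 <= lat_ms <= 400

    def test_empty_condition_raises(self):
        epochs = make_epochs(np.zeros((2, 7, 100)))
        epochs.rejected[:] = True
        with pytest.raises(ValueError):
            ev.erp_average(epochs)


class TestCompareConditions:
    def test_identical_inputs_nothing_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 12))
        for method in ("bonferroni", "cluster"):
            res = ev.compare_conditions(a, a, method, n_perm=200)
            assert not res.significant.any()

    def test_single_shifted_bin_survives_bonferroni(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2))
        a[:, 1] += 10.0
        res = ev.compare_conditions(a, b, "bonferroni")
        assert res.significant[1] and not res.significant[0]

    def test_cluster_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        n, m = 8, 6
        a = rng.normal(size=(n, m))
        b = rng.normal(size=(n, m))
        a[:, 2:5] += 1.2
        res = ev.compare_conditions(a, b, "cluster", n_perm=1000)
        assert res.clusters

        # independent oracle: explicit enumeration of all 2^8 sign patterns
        from scipy import stats as st

        d = a - b
        thr = st.t.ppf(0.975, df=n - 1)

        def clusters_of(x):
            tt = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(n))
            found = []
            for sign in (1, -1):
                run = None
                for i in range(m):
                    if sign * tt[i] > thr:
                        run = (i if run is None else run)
                    elif run is not None:
                        found.append(tt[run:i].sum())
                        run = None
                if run is not None:
                    found.append(tt[run:m].sum())
            return found

        null_max = []
        for code in range(2 ** n):
            signs = np.array([1 if code >> k & 1 else -1 for k in range(n)])
            masses = [abs(c) for c in clusters_of(d * signs[:, None])]
            null_max.append(max(masses) if masses else 0.0)
        null_max = np.array(null_max)
        for cl in res.clusters:
            expected = np.mean(null_max >= abs(cl["mass"]))
            assert cl["p"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            ev.compare_conditions(np.zeros((1, 3)), np.zeros((5, 3)))


class TestPowerCurve:
    def test_null_effect_proportion_near_alpha(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(60, 1, 1))
        b = rng.normal(size=(60, 1, 1))
        curve = ev.power_curve(a, b, lambda tr: float(tr[0, 0]),
                               [5, 10, 20], n_perm=500, seed=0)
        bound = 3 * np.sqrt(0.05 * 0.95 / 500)
        # subsample draws overlap heavily, so allow twice the iid bound
        assert np.all(np.abs(curve.proportion - 0.05) < 2 * bound + 0.02)

    def test_large_effect_monotone_and_small_n80(self):
        rng = np.random.default_rng(5)
        a = rng.normal(2.0, 1.0, size=(40, 1, 1))
        b = rng.normal(0.0, 1.0, size=(40, 1, 1))
        curve = ev.power_curve(a, b, lambda tr: float(tr[0, 0]),
                               range(2, 21), n_perm=500, seed=1)
        from scipy import stats as st

        rho = st.spearmanr(curve.n_grid, curve.proportion).statistic
        assert rho > 0.9
        assert curve.n80 is not None and curve.n80 <= 10

    def test_null_rarely_reports_n80(self):
        rng = np.random.default_rng(6)
        hits = 0
        for seed in range(20):
            a = rng.normal(size=(60, 1, 1))
            b = rng.normal(size=(60, 1, 1))
            curve = ev.power_curve(a, b, lambda tr: float(tr[0, 0]),
                                   [5, 10, 20, 40], n_perm=200, seed=seed)
            hits += curve.n80 is not None
        assert hits <= 1

    def test_oversized_grid_truncated_with_warning(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 1, 1))
        with pytest.warns(UserWarning, match="truncated"):
            curve = ev.power_curve(a, a, lambda tr: float(tr[0, 0]),
                                   [5, 50], n_perm=50, seed=0)
        assert list(curve.n_grid) == [5]
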