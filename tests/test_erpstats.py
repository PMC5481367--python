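from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sstats

from pedalerp.erpstats import (
    Erp,
    ErpPermutationTest,
    PermutationSpec,
    average,
    count_peaks,
    dominant_frequency,
    peak_amplitude,
    permutation_test,
)
from pedalerp.exceptions import ConfigurationError, DataError, EmptyInputError
from pedalerp.preprocessing import rereference_segments
from pedalerp.simulate import synthesize_noise_epochs

FS = 250.0


def make_erp(x, fs=FS, t0=int(2 * FS)):
    """Single-channel Erp on Pz from a 1-D waveform."""
    return Erp(data=np.atleast_2d(np.asarray(x, dtype=float)), n_trials=1,
               condition="foot_exec", lock="stimulus", reference="common_average",
               sampling_rate=fs, channel_labels=["Pz"], t0_sample=t0)


def erp_from_window(wave_6s):
    """Embed a 6 s task waveform into an 8 s epoch (2 s pre-lock)."""
    x = np.zeros(int(8 * FS))
    x[int(2 * FS):int(8 * FS)] = wave_6s
    return make_erp(x)


class TestAverage:
    def test_identical_segments_average_to_themselves(self, stim_segments):
        one_cond = stim_segments
        erp = average(one_cond, "rest")
        segs = one_cond.by_condition("rest")
        manual = np.mean([s.data for s in segs], axis=0)
        assert np.allclose(erp.data, manual)
        assert erp.n_trials == len(segs)

    def test_opposite_segments_cancel(self, stim_segments):
        mirrored = stim_segments.copy()
        segs = mirrored.by_condition("rest")[:2]
        segs[1].data = -segs[0].data
        mirrored.segments = segs
        erp = average(mirrored, "rest")
        assert np.allclose(erp.data, 0.0)

    def test_empty_condition_raises(self, emg_segments):
        with pytest.raises(EmptyInputError):
            average(emg_segments, "rest")

    def test_responder_erp_dominated_by_1hz(self, foot_rest_emg_segments):
        erp = average(rereference_segments(foot_rest_emg_segments,
                                           "common_average"), "foot_exec")
        assert dominant_frequency(erp, "Pz") == pytest.approx(1.0, abs=1 / 6)
        assert count_peaks(erp, "Pz") == 6


class TestPeakCount:
    def test_six_cycle_component_gives_six(self):
        t = np.arange(int(6 * FS)) / FS
        wave = 50 * np.sin(2 * np.pi * 1.0 * t) * np.exp(-0.1 * t)
        assert count_peaks(erp_from_window(wave), "Pz") == 6

    def test_flat_erp_gives_zero(self):
        assert count_peaks(erp_from_window(np.zeros(int(6 * FS))), "Pz") == 0

    def test_single_half_cycle_pulse_gives_one(self):
        wave = np.zeros(int(6 * FS))
        wave[:int(FS)] = 40 * np.sin(2 * np.pi * 0.5 * np.arange(int(FS)) / FS)
        assert count_peaks(erp_from_window(wave), "Pz") == 1

    def test_missing_channel_raises(self):
        with pytest.raises(DataError):
            count_peaks(erp_from_window(np.zeros(1500)), "Oz")


class TestDominantFrequency:
    @pytest.mark.parametrize("freq", [1.0, 2.0])
    def test_pure_sinusoid_within_one_bin(self, freq):
        t = np.arange(int(6 * FS)) / FS
        erp = erp_from_window(30 * np.sin(2 * np.pi * freq * t))
        assert dominant_frequency(erp, "Pz") == pytest.approx(freq, abs=1 / 6)

    def test_window_too_short_rejected(self):
        erp = erp_from_window(np.ones(int(6 * FS)))
        with pytest.raises(ConfigurationError):
            dominant_frequency(erp, "Pz", window=(0.0, 1.0))


class TestPeakAmplitude:
    def test_zero_erp(self):
        assert peak_amplitude(erp_from_window(np.zeros(int(6 * FS))), "Pz") == 0.0

    def test_signed_extremum(self):
        wave = np.zeros(int(6 * FS))
        wave[100] = 30.0
        wave[200] = -80.0
        assert peak_amplitude(erp_from_window(wave), "Pz") == -80.0

    def test_decay_profile_first_window_peak_largest(self, foot_rest_emg_segments):
        erp = average(rereference_segments(foot_rest_emg_segments,
                                           "common_average"), "foot_exec")
        first = abs(peak_amplitude(erp, "Pz", window=(0.0, 1.0)))
        last = abs(peak_amplitude(erp, "Pz", window=(5.0, 6.0)))
        assert first >= last


def brute_force_cluster_p(x1, x2, cf_alpha=0.05):
    """Independent oracle: enumerate every partition with scipy's t-test."""
    n1 = x1.shape[0]
    X = np.vstack([x1 - x1.mean(axis=1, keepdims=True),
                   x2 - x2.mean(axis=1, keepdims=True)])
    n = X.shape[0]
    tc = sstats.t.ppf(1 - cf_alpha / 2, n - 2)

    def max_mass(a, b):
        t = sstats.ttest_ind(a, b, axis=0).statistic
        best, run = 0.0, 0.0
        prev = 0
        for v in t:
            s = 1 if v > tc else (-1 if v < -tc else 0)
            if s == 0 or s != prev:
                run = 0.0
            if s != 0:
                run += v
                best = max(best, abs(run))
            prev = s
        return best

    obs = max_mass(X[:n1], X[n1:])
    null = [max_mass(X[list(sel)], X[[i for i in range(n) if i not in sel]])
            for sel in combinations(range(n), n1)]
    return np.mean([m >= obs for m in null]), obs


class TestPermutationTest:
    def _effect_groups(self, n1=4, n2=4, amp=10.0, seed=5, t_len=200):
        rng = np.random.default_rng(seed)
        t = np.arange(t_len) / FS
        bump = amp * np.exp(-((t - 0.4) ** 2) / 0.01)
        x1 = rng.standard_normal((n1, t_len)) * 3 + bump
        x2 = rng.standard_normal((n2, t_len)) * 3
        return x1, x2

    def test_exact_enumeration_matches_independent_oracle(self):
        x1, x2 = self._effect_groups()
        res = permutation_test(x1, x2, spec=PermutationSpec(n_partitions=2000),
                               sampling_rate=FS)
        assert res.exact and res.n_partitions_used == 70
        p_oracle, _ = brute_force_cluster_p(x1, x2)
        assert res.min_p == pytest.approx(p_oracle, abs=1e-12)

    def test_monte_carlo_within_002_of_exact_at_4v4(self):
        x1, x2 = self._effect_groups()
        exact = permutation_test(x1, x2, spec=PermutationSpec(n_partitions=2000),
                                 sampling_rate=FS)
        mc = permutation_test(
            x1, x2, sampling_rate=FS, seed=99,
            spec=PermutationSpec(n_partitions=2000, force_monte_carlo=True))
        assert not mc.exact
        assert mc.min_p == pytest.approx(exact.min_p, abs=0.02)

    def test_trial_order_does_not_change_observed_track(self):
        x1, x2 = self._effect_groups(n1=6, n2=6)
        res = permutation_test(x1, x2, sampling_rate=FS, seed=1)
        rng = np.random.default_rng(2)
        res_shuffled = permutation_test(x1[rng.permutation(6)],
                                        x2[rng.permutation(6)],
                                        sampling_rate=FS, seed=1)
        assert np.allclose(res.observed, res_shuffled.observed)

    def test_mean_correction_invariance(self):
        x1, x2 = self._effect_groups(n1=6, n2=6)
        spec = PermutationSpec(n_partitions=300)
        a = permutation_test(x1, x2, spec=spec, sampling_rate=FS, seed=7)
        b = permutation_test(x1 + 500.0, x2, spec=spec, sampling_rate=FS, seed=7)
        # exact in exact arithmetic; float round-off can shift ties slightly
        assert np.allclose(a.observed, b.observed)
        assert np.allclose(a.to_frame()["p_value"], b.to_frame()["p_value"],
                           atol=0.02)

    def test_seeded_reproducibility(self):
        x1, x2 = self._effect_groups(n1=15, n2=15)
        spec = PermutationSpec(n_partitions=400)
        a = permutation_test(x1, x2, spec=spec, sampling_rate=FS, seed=11)
        b = permutation_test(x1, x2, spec=spec, sampling_rate=FS, seed=11)
        assert a.to_frame().equals(b.to_frame())

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DataError):
            permutation_test(np.zeros((3, 100)), np.zeros((3, 90)),
                             sampling_rate=FS)

    def test_too_few_trials_rejected(self):
        with pytest.raises(EmptyInputError):
            permutation_test(np.zeros((1, 100)), np.zeros((5, 100)),
                             sampling_rate=FS)

    def test_responder_foot_exec_significant_at_pz(self, foot_rest_spec,
                                                   clean_responder_profile):
        from pedalerp.preprocessing import (apply_filters, baseline_correct,
                                            detect_emg_onsets, segment)
        from pedalerp.simulate import synthesize_recording

        rec = synthesize_recording(foot_rest_spec, clean_responder_profile, 61)
        filt = apply_filters(rec)
        filt.events = sorted(filt.events + detect_emg_onsets(filt))
        segs = rereference_segments(
            baseline_correct(segment(filt, "stimulus")), "common_average")
        res = ErpPermutationTest(segs, segs, condition="foot_exec",
                                 spec=PermutationSpec(n_partitions=500)).fit(8)
        sig = res.significant_intervals
        assert sig, "responder foot execution should differ from rest"
        assert any(0.0 < a < 6.0 for a, _ in sig)
        assert "significant" in res.summary()

    def test_power_monotone_in_component_amplitude(self, foot_rest_spec):
        """Detection rate never decreases with oscillation amplitude."""
        from pedalerp.preprocessing import (apply_filters, baseline_correct,
                                            segment)
        from pedalerp.simulate import SubjectProfile, synthesize_recording

        rates = []
        for amp in (0.0, 25.0, 90.0):
            hits = 0
            for seed in (1, 2, 3):
                prof = SubjectProfile(
                    label=f"amp{amp}", oscillation_amplitude_uV=amp,
                    trial_response_probability=1.0, blink_rate=0.0,
                    eye_movement_rate=0.0, bad_channel_episode_rate=0.0)
                rec = synthesize_recording(foot_rest_spec, prof, seed)
                segs = rereference_segments(
                    baseline_correct(segment(apply_filters(rec), "stimulus")),
                    "common_average")
                res = ErpPermutationTest(
                    segs, segs, condition="foot_exec",
                    spec=PermutationSpec(n_partitions=200)).fit(seed)
                hits += bool(res.significant_intervals)
            rates.append(hits / 3)
        assert rates == sorted(rates)
        assert rates[0] <= 1 / 3 and rates[-1] == 1.0

    def test_null_noise_rarely_significant(self):
        """Small-scale calibration: false-positive fraction near alpha."""
        rej = 0
        n_rep = 60
        seeds = np.random.SeedSequence(77).generate_state(3 * n_rep) % (2 ** 31)
        for i in range(n_rep):
            g1 = synthesize_noise_epochs(12, 500, FS, 12.0, int(seeds[3 * i]))
            g2 = synthesize_noise_epochs(12, 500, FS, 12.0, int(seeds[3 * i + 1]))
            res = permutation_test(g1, g2, sampling_rate=FS,
                                   spec=PermutationSpec(n_partitions=200),
                                   seed=int(seeds[3 * i + 2]))
            rej += bool(res.significant_intervals)
        assert rej / n_rep <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_pointwise_correction_variant(self):
        x1, x2 = self._effect_groups(n1=10, n2=10, amp=15.0)
        res = permutation_test(
            x1, x2, sampling_rate=FS, seed=3,
            spec=PermutationSpec(n_partitions=400, correction="pointwise"))
        assert res.significant_intervals

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            PermutationSpec(n_partitions=0)
        with pytest.raises(ConfigurationError):
            PermutationSpec(alpha=1.5)
        with pytest.raises(ConfigurationError):
            PermutationSpec(statistic="median_diff")
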