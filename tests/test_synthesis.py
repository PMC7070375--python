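"""Generator: timing statistics, ground-truth consistency, reproducibility."""

import numpy as np
import pytest

from heartsounds import (
    ConfigurationError,
    DegenerateInputError,
    SynthConfig,
    generate_ecg,
    generate_pcg,
    hilbert_envelope,
    inject_artifacts,
    systole_empirical,
)

from conftest import make_recording


class TestGeneratePcg:
    def test_systole_follows_empirical_formula(self):
        # at 60 bpm the empirical systole is 371.64 ms; the generated mean
        # must agree within the jitter-driven standard error
        cfg = SynthConfig(duration=20.0, heart_rate=60.0, noise_sd=0.0,
                          split_probability=0.0, s3_probability=0.0, seed=7)
        _, truth = generate_pcg(cfg)
        assert 19 <= truth.n_cycles <= 20
        expected = systole_empirical(60.0)
        tol = 3.0 * cfg.hr_jitter_sd / np.sqrt(truth.n_cycles)
        assert abs(truth.true_sys_lengths.mean() - expected) < max(tol, 5.0)

    @pytest.mark.parametrize("hr", [50.0, 80.0, 120.0])
    def test_s1_spacing_matches_heart_rate(self, hr):
        (_, truth), _ = make_recording(hr=hr, duration=30.0, seed=3)
        spacing_ms = np.diff(truth.s1_onsets).mean() * 1000.0
        assert spacing_ms == pytest.approx(60000.0 / hr, rel=0.02)

    def test_ground_truth_consistency(self):
        (_, truth), cfg = make_recording(hr=70.0, seed=5)
        # events inside the recording, S1/S2 strictly alternating
        for arr in (truth.s1_peak_times, truth.s2_peak_times, truth.r_peak_times):
            assert np.all((arr >= 0) & (arr <= cfg.duration))
        merged = np.sort(np.concatenate([truth.s1_peak_times, truth.s2_peak_times]))
        interleaved = np.empty_like(merged)
        interleaved[0::2] = truth.s1_peak_times
        interleaved[1::2] = truth.s2_peak_times
        assert np.array_equal(merged, interleaved)
        # R-peaks coincide with S1 onsets, sys+dia spans the full cycle
        np.testing.assert_array_equal(truth.r_peak_times, truth.s1_onsets)
        cycles = np.diff(truth.s1_peak_times) * 1000.0
        np.testing.assert_allclose(
            truth.true_sys_lengths[:-1] + truth.true_dia_lengths[:-1], cycles,
            atol=1e-9,
        )

    def test_amplitude_ratio_scales_envelope_peaks(self):
        cfg = SynthConfig(duration=15.0, heart_rate=60.0, amp_ratio_s1_s2=2.0,
                          amp_jitter_sd=0.0, noise_sd=0.0, seed=2)
        pcg, truth = generate_pcg(cfg)
        env = hilbert_envelope(pcg)
        t = env.times
        s1_amp = [env.values[np.argmin(np.abs(t - p))] for p in truth.s1_peak_times]
        s2_amp = [env.values[np.argmin(np.abs(t - p))] for p in truth.s2_peak_times]
        assert np.mean(s1_amp) / np.mean(s2_amp) == pytest.approx(2.0, rel=0.05)

    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(duration=10.0, seed=42, noise_sd=0.1,
                          split_probability=0.3, s3_probability=0.3)
        p1, t1 = generate_pcg(cfg)
        p2, t2 = generate_pcg(cfg)
        assert np.array_equal(p1.samples, p2.samples)
        assert np.array_equal(t1.s1_peak_times, t2.s1_peak_times)
        assert np.array_equal(t1.extra_event_times, t2.extra_event_times)
        p3, _ = generate_pcg(SynthConfig(duration=10.0, seed=43, noise_sd=0.1))
        assert not np.array_equal(p1.samples, p3.samples)

    def test_duration_too_short_raises(self):
        with pytest.raises(DegenerateInputError):
            generate_pcg(SynthConfig(duration=0.5, heart_rate=40.0))

    @pytest.mark.parametrize("bad", [
        dict(heart_rate=30.0),
        dict(split_probability=1.5),
        dict(s1_center_freq=500.0),
        dict(noise_sd=-0.1),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SynthConfig(**bad)


class TestGenerateEcg:
    def test_spike_maxima_at_r_peaks(self):
        (_, truth), cfg = make_recording(hr=60.0, duration=12.0, seed=1)
        ecg = generate_ecg(truth, cfg)
        for r in truth.r_peak_times:
            lo = int((r - 0.05) * ecg.sampling_rate)
            hi = int((r + 0.05) * ecg.sampling_rate)
            peak_idx = lo + np.argmax(ecg.samples[lo:hi])
            assert abs(peak_idx / ecg.sampling_rate - r) <= 1.0 / ecg.sampling_rate

    def test_empty_truth_gives_flat_signal(self):
        from heartsounds.synthesis import GroundTruth

        empty = GroundTruth(*[np.empty(0)] * 8)
        ecg = generate_ecg(empty, SynthConfig(duration=2.0))
        assert np.all(ecg.samples == 0)

    def test_known_r_times_index_arithmetic(self):
        from heartsounds.synthesis import GroundTruth

        truth = GroundTruth(
            s1_onsets=[1.0, 2.0], s1_peak_times=[1.05, 2.05],
            s2_onsets=[1.3, 2.3], s2_peak_times=[1.35, 2.35],
            extra_event_times=[], r_peak_times=[1.0, 2.0],
            true_sys_lengths=[300, 300], true_dia_lengths=[700, 700],
        )
        ecg = generate_ecg(truth, SynthConfig(duration=3.0, sampling_rate_ecg=500.0))
        assert abs(int(np.argmax(ecg.samples[:750])) - 500) <= 1
        assert abs(int(750 + np.argmax(ecg.samples[750:])) - 1000) <= 1


class TestInjectArtifacts:
    def test_split_s2_creates_two_sub_bursts(self):
        (pcg, truth), cfg = make_recording(hr=60.0, duration=10.0, seed=4,
                                           amp_jitter_sd=0.0)
        out, truth2 = inject_artifacts(pcg, truth, "split_s2", cfg,
                                       cycle_index=2, gap_ms=60.0)
        np.testing.assert_array_equal(truth2.s2_peak_times, truth.s2_peak_times)
        env = hilbert_envelope(out)
        s2 = truth.s2_peak_times[2]
        window = (env.times > s2 + 0.02) & (env.times < s2 + 0.1)
        base = hilbert_envelope(pcg)
        # energy appears after the original S2 where the echo burst sits
        assert env.values[window].max() > 2 * base.values[window].max()

    def test_s3_adds_envelope_peak_in_diastole(self):
        from heartsounds.peaks import local_maxima, apply_threshold

        (pcg, truth), cfg = make_recording(hr=60.0, duration=10.0, seed=4)
        out, truth2 = inject_artifacts(pcg, truth, "s3", cfg, cycle_index=1)
        assert truth2.extra_event_times.size == truth.extra_event_times.size + 1
        env0, env1 = hilbert_envelope(pcg), hilbert_envelope(out)
        n0 = len(apply_threshold(local_maxima(env0), env0, 1.0))
        n1 = len(apply_threshold(local_maxima(env1), env1, 1.0))
        assert n1 == n0 + 1

    def test_zero_noise_is_identity(self):
        (pcg, truth), cfg = make_recording(hr=60.0, duration=8.0, seed=4)
        out, _ = inject_artifacts(pcg, truth, "white_noise", cfg, sd=0.0)
        np.testing.assert_array_equal(out.samples, pcg.samples)

    def test_unknown_kind_raises(self):
        (pcg, truth), cfg = make_recording(hr=60.0, duration=8.0, seed=4)
        with pytest.raises(ConfigurationError):
            inject_artifacts(pcg, truth, "murmur", cfg)
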