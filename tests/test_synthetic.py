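"""Generator contracts: pulse construction, burst placement, warped audio,
image stacks, determinism."""

import numpy as np
import pytest
from scipy import stats

from nasemg.datatypes import AudioSignal
from nasemg.synthetic import (
    Event,
    MRIGeometry,
    PiecewiseLinearWarp,
    ScenarioConfig,
    burst_windows,
    make_base_audio,
    make_emg,
    make_mri_stack,
    make_scenario,
    make_velum_curve,
    make_warped_audio,
    nasal_intervals,
)


class TestVelumCurve:
    def test_empty_schedule_is_constant_zero(self):
        c = make_velum_curve([], fps=14.0, duration=2.0)
        assert c.values.size == 28
        assert np.all(c.values == 0.0)

    def test_single_pulse_support_and_peak(self):
        ev = [Event(onset_time=1.0, kind="nasal", open_duration=0.5)]
        c = make_velum_curve(ev, fps=14.0, duration=3.0)
        t = c.times
        inside = (t > 1.0) & (t < 1.5)
        assert np.all(c.values[~inside & ((t < 1.0) | (t >= 1.5))] == 0.0)
        assert c.values.max() == pytest.approx(
            0.5 * (1 - np.cos(2 * np.pi * (t[np.argmax(c.values)] - 1.0) / 0.5))
        )
        assert c.values.max() > 0.95

    def test_overlapping_pulses_merge_by_pointwise_max(self):
        evs = [
            Event(onset_time=1.0, kind="nasal", open_duration=0.5),
            Event(onset_time=1.4, kind="nasal", open_duration=0.5),
        ]
        fps, dur = 50.0, 3.0
        c = make_velum_curve(evs, fps=fps, duration=dur)
        # enumeration oracle: evaluate both pulses sample by sample
        expected_positive = 0
        for k in range(int(dur * fps)):
            t = k / fps
            v = 0.0
            for o in (1.0, 1.4):
                if o <= t < o + 0.5:
                    v = max(v, 0.5 * (1 - np.cos(2 * np.pi * (t - o) / 0.5)))
            expected_positive += v > 0
        assert np.count_nonzero(c.values > 0) == expected_positive

    def test_oral_events_contribute_nothing(self):
        c = make_velum_curve(
            [Event(onset_time=0.5, kind="oral", open_duration=0.5)], 14.0, 2.0
        )
        assert np.all(c.values == 0.0)

    def test_event_outside_duration_errors(self):
        with pytest.raises(ValueError):
            make_velum_curve(
                [Event(onset_time=1.8, kind="nasal", open_duration=0.5)], 14.0, 2.0
            )


class TestEMG:
    def _curve_and_intervals(self, dur=3.0, rate=600.0):
        sched = [Event(onset_time=1.0, kind="nasal", open_duration=0.8)]
        return make_velum_curve(sched, rate, dur), nasal_intervals(sched)

    def test_zero_snr_is_pure_noise(self):
        """Without bursts, RMS inside lead windows matches silence within
        5% over repeated seeded draws."""
        curve, ivs = self._curve_and_intervals()
        in_win, out_win = [], []
        for seed in range(100):
            cfg = ScenarioConfig(burst_snr=0.0, n_channels=1, seed=seed,
                                 crosstalk=[[1.0]])
            rec = make_emg(curve, ivs, cfg)
            t = np.arange(rec.n_samples) / rec.rate
            lead = (t >= 0.9) & (t < 1.0)
            silence = t < 0.8
            in_win.append(np.sqrt(np.mean(rec.channels[0][lead] ** 2)))
            out_win.append(np.sqrt(np.mean(rec.channels[0][silence] ** 2)))
        assert abs(np.mean(in_win) - np.mean(out_win)) / np.mean(out_win) < 0.05

    def test_burst_raises_rms_in_envelope_window(self):
        """At burst SNR 4 the envelope window (which opens burst_lead
        before the nasal onset) carries clearly elevated RMS."""
        curve, ivs = self._curve_and_intervals()
        for seed in range(20):
            cfg = ScenarioConfig(burst_snr=4.0, n_channels=1, seed=seed,
                                 crosstalk=[[1.0]], bursts_at_closing=False)
            rec = make_emg(curve, ivs, cfg)
            t = np.arange(rec.n_samples) / rec.rate
            (w0, w1), = burst_windows(ivs, cfg)
            assert w0 == pytest.approx(ivs[0][0] - cfg.burst_lead)
            win = (t >= w0) & (t < w1)
            silence = t < w0 - 0.05
            r_in = np.sqrt(np.mean(rec.channels[0][win] ** 2))
            r_out = np.sqrt(np.mean(rec.channels[0][silence] ** 2))
            assert r_in > 2.0 * r_out

    def test_same_seed_bit_identical(self):
        curve, ivs = self._curve_and_intervals()
        cfg = ScenarioConfig(seed=5)
        a = make_emg(curve, ivs, cfg)
        b = make_emg(curve, ivs, cfg)
        np.testing.assert_array_equal(a.channels, b.channels)

    def test_negative_snr_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(burst_snr=-1.0)

    def test_burst_envelope_onset_at_lead(self):
        cfg = ScenarioConfig()
        wins = burst_windows([(2.0, 2.8)], cfg)
        assert wins[0][0] == pytest.approx(2.0 - cfg.burst_lead)


class TestWarpedAudio:
    def test_identity_warp_correlates_at_zero_lag(self):
        base = make_base_audio([Event(0.2, "nasal", 0.4)], 1.0)
        mri, emg, w = make_warped_audio(base, None)
        a = mri.samples[:: 2]  # 16 kHz -> 8 kHz naive decimation
        n = min(a.size, emg.samples.size)
        xc = np.correlate(a[:n], emg.samples[:n], "full")
        assert abs(int(np.argmax(xc)) - (n - 1)) <= 1

    def test_affine_warp_scales_duration(self):
        base = make_base_audio([Event(0.2, "nasal", 0.4)], 1.0)
        mri, _, _ = make_warped_audio(base, ("affine", 1.1))
        assert mri.samples.size == pytest.approx(1.1 * 16000, abs=1)

    def test_true_warp_hits_knots_exactly(self):
        base = make_base_audio([Event(0.2, "nasal", 0.4)], 2.0)
        knots = [[0.0, 0.0], [0.8, 0.9], [2.0, 2.1]]
        _, _, w = make_warped_audio(base, knots)
        # true_warp maps MRI time back to EMG time
        for u, t in knots:
            assert w(t) == pytest.approx(u, abs=1e-12)

    def test_non_monotone_warp_rejected(self):
        base = make_base_audio([Event(0.2, "nasal", 0.4)], 1.0)
        with pytest.raises(ValueError):
            make_warped_audio(base, [[0.0, 0.0], [1.0, 0.5], [2.0, 0.4]])

    def test_empty_base_rejected(self):
        with pytest.raises(ValueError):
            make_warped_audio(AudioSignal(np.array([]), 16000.0), None)


class TestMRIStack:
    def test_constant_zero_curve_gives_min_area(self):
        from nasemg.datatypes import VelumCurve

        v = VelumCurve(values=np.zeros(10), rate=14.0)
        geom = MRIGeometry(noise_sd=0.0)
        seq, areas = make_mri_stack(v, geom)
        dark = (seq.frames < 0.5).reshape(10, -1).sum(axis=1)
        assert np.all(areas == geom.min_area)
        np.testing.assert_array_equal(dark, areas)

    def test_full_aperture_attains_max_area(self):
        from nasemg.datatypes import VelumCurve

        v = VelumCurve(values=np.array([0.0, 1.0, 0.0]), rate=14.0)
        geom = MRIGeometry(noise_sd=0.0)
        seq, areas = make_mri_stack(v, geom)
        assert areas[1] == geom.max_area
        assert (seq.frames[1] < 0.5).sum() == geom.max_area

    def test_stack_length_matches_recorded_sequence(self):
        """A 75-image sequence at 14 frames/s, the acquisition format."""
        from nasemg.datatypes import VelumCurve

        v = VelumCurve(values=np.linspace(0, 1, 75), rate=14.0)
        seq, _ = make_mri_stack(v)
        assert seq.n_frames == 75

    def test_area_rank_correlates_perfectly_with_curve(self):
        from nasemg.datatypes import VelumCurve

        rng = np.random.default_rng(1)
        # distinct aperture levels far enough apart to map to distinct areas
        v = VelumCurve(values=rng.permutation(np.linspace(0, 1, 40)), rate=14.0)
        _, areas = make_mri_stack(v, MRIGeometry(noise_sd=0.0))
        rho = stats.spearmanr(areas, v.values).statistic
        assert rho == pytest.approx(1.0)


class TestScenario:
    def test_determinism_bit_identical(self):
        cfg = ScenarioConfig(n_utterances=3, seed=11)
        a, b = make_scenario(cfg), make_scenario(cfg)
        np.testing.assert_array_equal(a.emg.channels, b.emg.channels)
        np.testing.assert_array_equal(a.mri.frames, b.mri.frames)
        np.testing.assert_array_equal(a.audio_mri.samples, b.audio_mri.samples)
        np.testing.assert_array_equal(a.true_velum.values, b.true_velum.values)

    def test_invariants(self, scenario8):
        s = scenario8
        ivs = s.true_nasal_intervals
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
        assert s.emg.duration >= ivs[-1][1]
        assert abs(s.audio_emg.duration - s.emg.duration) <= 1.0 / s.audio_emg.rate
        assert 0.0 <= s.true_velum.values.min() <= s.true_velum.values.max() <= 1.0
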