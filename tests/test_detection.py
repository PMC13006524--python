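import dataclasses

import numpy as np
import pytest

import larvaforce as lf
from larvaforce.detection import (
    Bout,
    ForceWave,
    PeakParams,
    delimit_wave,
    find_extrema,
    group_bouts,
    match_to_behavior,
    prominence_of,
    segment_waves,
)
from larvaforce.io import BACKWARD, FORWARD, BehaviorEvent, BehaviorTrack, ForceTrace
from larvaforce.pipeline import noiseless_params
from oracles import brute_force_peaks


def make_trace(values, dt=0.01):
    return ForceTrace(0.0, dt, np.asarray(values, float))


def wave(start, peak, end, peak_val=20.0, direction="unmatched"):
    return ForceWave(
        peak_time=peak, peak_value=peak_val, start_time=start, start_value=5.0,
        end_time=end, end_value=5.0, prominence=10.0, direction=direction,
    )


class TestProminence:
    def test_isolated_triangular_peak(self):
        v = [0, 0, 5, 10, 5, 0, 0]
        assert prominence_of(make_trace(v), 3) == pytest.approx(10.0)

    def test_twin_peaks_minor_prominence_from_saddle(self):
        # peaks 10 and 8 with a saddle at 4: minor peak prominence = 8 - 4
        v = [0, 10, 4, 8, 0]
        trace = make_trace(v + [0, 0])
        assert prominence_of(trace, 3) == pytest.approx(4.0)
        i, p = brute_force_peaks(trace.values, 0.01, 0.1, 0.01)[1]
        assert (i, p) == (3, pytest.approx(4.0))

    def test_non_maximum_rejected(self):
        with pytest.raises(lf.InputError):
            prominence_of(make_trace([0, 1, 2, 3, 4, 5, 6]), 3)


class TestFindExtrema:
    @staticmethod
    def bumpy(rng, n):
        raw = np.cumsum(rng.standard_normal(n))
        return np.convolve(raw, np.ones(5) / 5, mode="same") + rng.standard_normal(n) * 0.01

    def test_injected_peaks_recovered(self):
        dt = 0.05
        t = np.arange(0, 60, dt)
        v = np.zeros_like(t)
        truth = [5.0, 15.0, 25.0, 35.0, 45.0]
        for tc in truth:
            v += 10.0 * np.exp(-0.5 * ((t - tc) / 0.8) ** 2)
        found = find_extrema(make_trace(v, dt), PeakParams())
        assert len(found) == 5
        for (i, prom), tc in zip(found, truth):
            assert abs(i * dt - tc) <= dt
            assert prom >= 5.0

    def test_close_peaks_merged_keeping_higher(self):
        dt = 0.05
        t = np.arange(0, 30, dt)
        v = 10.0 * np.exp(-0.5 * ((t - 10) / 0.5) ** 2)
        v += 11.0 * np.exp(-0.5 * ((t - 12) / 0.5) ** 2)  # 2 s apart < 3 s
        found = find_extrema(make_trace(v, dt), PeakParams())
        assert len(found) == 1
        assert abs(found[0][0] * dt - 12.0) <= 2 * dt  # the higher one

    def test_subthreshold_amplitude_ignored(self):
        dt = 0.05
        t = np.arange(0, 30, dt)
        v = 4.0 * np.exp(-0.5 * ((t - 15) / 1.0) ** 2)  # 4 mN < 5 mN
        assert find_extrema(make_trace(v, dt), PeakParams()) == []

    def test_monotone_ramp_has_no_peaks(self):
        assert find_extrema(make_trace(np.linspace(0, 50, 2000)), PeakParams()) == []

    def test_short_trace_empty_with_warning(self, caplog):
        v = [0, 10, 0, 10, 0]
        with caplog.at_level("WARNING"):
            out = find_extrema(make_trace(v, 0.01), PeakParams(min_distance_s=3.0))
        assert out == []
        assert "shorter" in caplog.text

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(100, 1500))
            dt = 0.02
            v = self.bumpy(rng, n)
            params = PeakParams(
                min_prominence=float(rng.uniform(0.5, 4.0)),
                min_distance_s=float(rng.uniform(0.1, 1.0)),
            )
            got = find_extrema(make_trace(v, dt), params)
            want = brute_force_peaks(v, dt, params.min_prominence, params.min_distance_s)
            assert [i for i, _ in got] == [i for i, _ in want]
            assert np.allclose([p for _, p in got], [p for _, p in want])

    def test_trough_peak_duality(self):
        rng = np.random.default_rng(3)
        v = self.bumpy(rng, 800)
        trace = make_trace(v, 0.02)
        neg = make_trace(-v, 0.02)
        params = PeakParams(min_prominence=1.0, min_distance_s=0.2)
        troughs = find_extrema(trace, params, "troughs")
        peaks_of_neg = find_extrema(neg, params, "peaks")
        assert troughs == peaks_of_neg

    def test_raising_prominence_never_adds_peaks(self):
        rng = np.random.default_rng(5)
        v = self.bumpy(rng, 1000)
        trace = make_trace(v, 0.02)
        prev = None
        for prom in (0.5, 1.0, 2.0, 4.0):
            found = {i for i, _ in find_extrema(trace, PeakParams(min_prominence=prom, min_distance_s=0.2))}
            if prev is not None:
                assert found <= prev
            prev = found


class TestDelimitation:
    def test_end_near_analytic_flattening_point(self):
        # closed-form profile: the slope of the relaxation falls below
        # 0.5 mN/s at s* = tau * ln(rate0 / 0.5); detected end must agree
        # within the slope-estimation span
        from larvaforce.synthetic import synthesize_wave_profile

        dt, duration, peak, net = 0.01, 4.0, 12.0, 3.0
        seg = synthesize_wave_profile(FORWARD, peak, net, duration, dt)
        baseline = np.full(800, 0.0)
        v = np.concatenate([baseline, seg, np.full(800, net)])
        trace = make_trace(v, dt)
        peak_idx = 800 + int(np.argmax(seg))
        t0, t1, trunc = delimit_wave(trace, peak_idx)
        t_rise = 0.6 * duration
        tau = (duration - t_rise) / 4.0
        s_end = (duration - dt - t_rise) / tau
        rate0 = (peak - net) / (tau * (1 - np.exp(-s_end)))
        s_star = tau * np.log(rate0 / 0.5)
        t_flat = 800 * dt + t_rise + s_star
        assert not trunc
        assert t1 == pytest.approx(t_flat, abs=0.6)

    def test_short_flat_shoulder_does_not_end_wave(self):
        # 0.4 s of flat slope (< 0.5 s dwell) then renewed rise: the end
        # must fall after the shoulder, not on it
        dt = 0.01
        up1 = np.linspace(0, 20, 200)
        down = np.linspace(20, 10, 100)
        shoulder = np.full(40, 10.0)  # 0.4 s
        up2 = np.linspace(10, 30, 200)
        tail = np.full(300, 30.0)
        v = np.concatenate([np.zeros(100), up1, down, shoulder, up2, tail])
        trace = make_trace(v, dt)
        peak_idx = 100 + 199
        shoulder_end_t = (100 + 200 + 100 + 40) * dt
        _, t1, _ = delimit_wave(trace, peak_idx)
        assert t1 > shoulder_end_t

    def test_constant_trace_yields_no_waves(self):
        assert segment_waves(make_trace(np.full(3000, 25.0))) == []

    def test_noiseless_trial_recovery(self, noiseless_trial):
        waves = segment_waves(noiseless_trial.force_trace)
        truth = noiseless_trial.truth_waves
        assert len(waves) == len(truth)
        for w, tw in zip(waves, truth):
            assert abs(w.peak_time - tw.peak_s) <= 0.5

    def test_noise_does_not_change_wave_count(self, noiseless_trial):
        p = dataclasses.replace(noiseless_params(), noise_sd=0.5)
        noisy = lf.simulate_trial(p, lf.CleftGeometry(baseline_force=25.0), seed=11)
        waves = segment_waves(noisy.force_trace)
        assert len(waves) == len(noiseless_trial.truth_waves)

    def test_adjacent_periods_overlap_under_ten_percent(self):
        p = lf.LarvaParams(inter_wave_delay_mean=2.0, inter_wave_delay_sd=0.3, noise_sd=0.0)
        trial = lf.simulate_trial(p, lf.CleftGeometry(baseline_force=50.0), seed=4)
        waves = segment_waves(trial.force_trace)
        for a, b in zip(waves, waves[1:]):
            overlap = a.end_time - b.start_time
            shorter = min(a.period, b.period)
            assert overlap < 0.10 * shorter or overlap <= 0


class TestMatching:
    def test_exact_span_match(self):
        track = BehaviorTrack((BehaviorEvent(0, FORWARD, 10.0, 14.0),))
        out = match_to_behavior([wave(10.0, 12.0, 14.0)], track)
        assert out[0].direction == FORWARD
        assert out[0].matched_behavior_wave_id == 0

    def test_no_overlap_unmatched(self):
        track = BehaviorTrack((BehaviorEvent(0, FORWARD, 40.0, 44.0),))
        out = match_to_behavior([wave(10.0, 12.0, 14.0)], track)
        assert out[0].direction == "unmatched"

    def test_majority_overlap_wins(self):
        # force wave overlapping forward 60% and backward 20% -> forward
        track = BehaviorTrack(
            (
                BehaviorEvent(0, FORWARD, 10.0, 16.0),
                BehaviorEvent(1, BACKWARD, 18.0, 20.0),
            )
        )
        out = match_to_behavior([wave(10.0, 13.0, 20.0)], track, tolerance_s=0.0)
        assert out[0].direction == FORWARD

    def test_each_event_matches_at_most_one_wave(self):
        track = BehaviorTrack((BehaviorEvent(0, FORWARD, 10.0, 14.0),))
        waves = [wave(10.0, 12.0, 14.0), wave(10.5, 12.5, 14.5)]
        out = match_to_behavior(waves, track)
        assert [w.direction for w in out].count(FORWARD) == 1
        # greatest overlap wins; tie broken to the earlier wave
        assert out[0].direction == FORWARD


class TestBouts:
    def test_gap_rule_splits_bouts(self):
        ws = [
            wave(0.0, 2.0, 4.0, direction=FORWARD),
            wave(9.0, 11.0, 13.0, direction=FORWARD),  # gap 5 s
            wave(53.0, 55.0, 57.0, direction=FORWARD),  # gap 40 s
        ]
        bouts = group_bouts(ws)
        assert [len(b) for b in bouts] == [2, 1]

    def test_direction_change_splits_bouts(self):
        ws = [
            wave(0.0, 2.0, 4.0, direction=FORWARD),
            wave(9.0, 11.0, 13.0, direction=BACKWARD),
            wave(18.0, 20.0, 22.0, direction=FORWARD),
        ]
        assert [len(b) for b in group_bouts(ws)] == [1, 1, 1]

    def test_unmatched_wave_breaks_bouts(self):
        ws = [
            wave(0.0, 2.0, 4.0, direction=FORWARD),
            wave(9.0, 11.0, 13.0),  # unmatched
            wave(18.0, 20.0, 22.0, direction=FORWARD),
        ]
        bouts = group_bouts(ws)
        assert [len(b) for b in bouts] == [1, 1]
        assert all(w.direction == FORWARD for b in bouts for w in b.waves)

    def test_empty_input(self):
        assert group_bouts([]) == []
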