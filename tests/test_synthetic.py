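import numpy as np
import pytest

import larvaforce as lf
from larvaforce.io import BACKWARD, FORWARD
from larvaforce.pipeline import noiseless_params
from larvaforce.synthetic import (
    RAMP_DURATION,
    force_from_position,
    sample_behavior_sequence,
    simulate_trial,
    synthesize_wave_profile,
)


class TestForceField:
    def test_flat_coverslip_returns_baseline(self):
        geo = lf.CleftGeometry(tilt_deg=0.0, baseline_force=25.0)
        p = lf.LarvaParams()
        for x in (0.0, 5.0, 20.0):
            assert force_from_position(geo, p, x) == 25.0

    def test_linear_evaluation_one_mm_advance(self):
        geo = lf.CleftGeometry(baseline_force=25.0, force_gradient=5.0, start_distance=10.0)
        p = lf.LarvaParams()
        assert force_from_position(geo, p, 9.0) == pytest.approx(30.0)

    def test_clamped_at_zero_far_from_slit(self):
        geo = lf.CleftGeometry(baseline_force=25.0, force_gradient=5.0, start_distance=10.0)
        assert force_from_position(geo, lf.LarvaParams(), 20.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(lf.InputError):
            force_from_position(lf.CleftGeometry(), lf.LarvaParams(), -1.0)

    def test_monotone_nonincreasing_in_distance(self):
        geo = lf.CleftGeometry(baseline_force=50.0)
        p = lf.LarvaParams()
        xs = np.linspace(0, 25, 60)
        fs = [force_from_position(geo, p, x) for x in xs]
        assert all(a >= b for a, b in zip(fs, fs[1:]))


class TestWaveProfile:
    def test_zero_peak_delta_gives_zero_segment(self):
        seg = synthesize_wave_profile(FORWARD, 0.0, 0.0, 2.0, 0.01)
        assert np.allclose(seg, 0.0)

    @pytest.mark.parametrize(
        "direction,net", [(FORWARD, 3.0), (BACKWARD, -7.0)]
    )
    def test_final_sample_equals_net_increment(self, direction, net):
        seg = synthesize_wave_profile(direction, 12.0, net, 3.5, 0.01)
        assert seg[-1] == pytest.approx(net)
        assert np.max(np.abs(seg)) >= abs(net)

    def test_rise_peak_relaxation_shape(self):
        seg = synthesize_wave_profile(FORWARD, 10.0, 3.0, 4.0, 0.01)
        peak = int(np.argmax(seg))
        assert seg[peak] == pytest.approx(10.0, abs=0.05)
        assert 0 < peak < seg.size - 1  # interior peak, partial relaxation

    def test_invalid_inputs_rejected(self):
        with pytest.raises(lf.InputError):
            synthesize_wave_profile(FORWARD, 10.0, 3.0, -1.0, 0.01)
        with pytest.raises(lf.InputError):
            synthesize_wave_profile(FORWARD, 10.0, 3.0, 0.005, 0.01)
        with pytest.raises(lf.InputError):
            synthesize_wave_profile(FORWARD, 2.0, 3.0, 2.0, 0.01)  # peak < net


class TestBehaviorSequence:
    def test_degenerate_policies(self):
        rng = np.random.default_rng(0)
        all_f = sample_behavior_sequence(lf.LocomotionPolicy(1.0, 0.0), 5, rng)
        assert all_f == [FORWARD] * 5
        all_b = sample_behavior_sequence(lf.LocomotionPolicy(0.0, 0.0), 5, rng)
        assert all_b == [BACKWARD] * 5

    def test_seeded_reproducibility(self):
        pol = lf.LocomotionPolicy(0.5, 0.2)
        a = sample_behavior_sequence(pol, 50, np.random.default_rng(42))
        b = sample_behavior_sequence(pol, 50, np.random.default_rng(42))
        assert a == b


class TestSimulateTrial:
    def test_no_waves_constant_after_ramp(self):
        p = noiseless_params(policy=lf.LocomotionPolicy(0.0, 1.0))
        trial = simulate_trial(p, lf.CleftGeometry(baseline_force=25.0), 30.0, 100.0, 0)
        post = trial.force_trace.slice(RAMP_DURATION, 30.0)
        assert np.allclose(post, 25.0)
        assert len(trial.truth_waves) == 0

    def test_post_wave_plateau_carries_net_increment(self, noiseless_trial):
        trace = noiseless_trial.force_trace
        for w in noiseless_trial.truth_waves[:-1]:
            # plateau just after the wave = plateau before + net increment
            t_probe = w.end_s + 0.3
            assert trace.value_at(t_probe) == pytest.approx(
                w.plateau_before_mN + w.net_delta_mN, abs=0.05
            )

    def test_early_termination_below_engagement_force(self):
        p = lf.LarvaParams(
            backward_increment_mean=-30.0, backward_increment_sd=0.0,
            policy=lf.LocomotionPolicy(0.0, 0.0),
        )
        trial = simulate_trial(p, lf.CleftGeometry(baseline_force=25.0), 120.0, 100.0, 1)
        assert trial.terminated_early
        assert trial.force_trace.duration < 120.0

    def test_bit_reproducible(self):
        p = lf.LarvaParams(noise_sd=0.5)
        a = simulate_trial(p, lf.CleftGeometry(), 60.0, 100.0, 9)
        b = simulate_trial(p, lf.CleftGeometry(), 60.0, 100.0, 9)
        assert np.array_equal(a.force_trace.values, b.force_trace.values)
        assert a.truth_waves == b.truth_waves

    def test_truth_waves_disjoint_within_span(self, noisy_trial):
        waves = noisy_trial.truth_waves
        for a, b in zip(waves, waves[1:]):
            assert a.end_s <= b.start_s
        assert waves[0].start_s >= RAMP_DURATION
        assert waves[-1].end_s <= noisy_trial.force_trace.end_time

    def test_behavior_track_mirrors_truth(self, noisy_trial):
        evs = noisy_trial.behavior.events
        assert len(evs) == len(noisy_trial.truth_waves)
        for ev, tw in zip(evs, noisy_trial.truth_waves):
            assert ev.direction == tw.direction
            assert ev.start_s == pytest.approx(tw.start_s)

    def test_monotone_peaks_per_direction_noiseless(self, noiseless_trial):
        # positive force gradient + zero noise: consecutive same-direction
        # peak forces are strictly monotone (increasing fwd, decreasing bwd)
        waves = noiseless_trial.truth_waves
        for a, b in zip(waves, waves[1:]):
            if a.direction == b.direction == FORWARD:
                assert b.peak_mN > a.peak_mN
            if a.direction == b.direction == BACKWARD:
                assert b.peak_mN < a.peak_mN

    def test_duration_must_exceed_ramp(self):
        with pytest.raises(lf.InputError):
            simulate_trial(lf.LarvaParams(), lf.CleftGeometry(), 4.0, 100.0, 0)


class TestGeneratorSelfConsistency:
    def test_forward_increment_mean_recovered(self):
        # Monte-Carlo: >= 200 forward waves, sample mean of injected net
        # increments within 3 standard errors of the configured mean
        p = lf.LarvaParams(policy=lf.LocomotionPolicy(1.0, 0.0))
        nets = []
        seed = 0
        while len(nets) < 200:
            trial = simulate_trial(p, lf.CleftGeometry(baseline_force=25.0), 120.0, 50.0, seed)
            nets.extend(w.net_delta_mN for w in trial.truth_waves if w.direction == FORWARD)
            seed += 1
        nets = np.array(nets[:250])
        se = nets.std(ddof=1) / np.sqrt(nets.size)
        assert abs(nets.mean() - p.forward_increment_mean) <= 3 * se
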