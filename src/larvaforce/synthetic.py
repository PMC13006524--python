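"""Synthetic virtual-larva trials: force traces with ground-truth waves.

A third-instar larva confined in a tilted cleft between a coverslip and
a force platform pushes against the confinement.  Each forward
peristaltic wave advances the animal into the narrowing wedge and
leaves the resting force a few mN higher (~+3 mN); each backward wave
retreats and leaves it lower (~-7 mN).  Superimposed on that staircase,
every wave produces a transient force excursion: a smooth rise to a
peak followed by partial relaxation to the new resting level.

This module generates seeded trials with that structure — compression
ramp, wave profiles, inter-wave plateaus, Gaussian sensor noise — plus
the matching behaviour annotations and the ground-truth wave records
the detection and metrics modules are benchmarked against.  The
locomotion policy (what the animal decides to do next) is a simulator
stand-in: real larvae are not modelled, only the statistical structure
their recordings exhibit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InputError
from .io import BACKWARD, FORWARD, RAMP_DURATION, BehaviorEvent, BehaviorTrack, ForceTrace

PAUSE = "pause"

#: trial termination rule: mechanical engagement is lost below this force (mN)
MIN_ENGAGEMENT_FORCE = 5.0


@dataclass(frozen=True)
class LocomotionPolicy:
    """Per-wave decision rule of the virtual larva.

    Each scheduled wave slot is forward with probability ``p_forward``,
    a pause (no wave) with ``p_pause``, otherwise backward.
    ``reward_sensitivity`` is the logit gain by which a drop in
    commanded force immediately after a wave increases the probability
    of repeating that wave's direction (0 disables learning).  This is
    an explicit model assumption of the simulator, not a claim about
    larval neurobiology.
    """

    p_forward: float = 0.6
    p_pause: float = 0.1
    reward_sensitivity: float = 0.0

    def __post_init__(self):
        for name in ("p_forward", "p_pause"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {p}")
        if self.p_forward + self.p_pause > 1.0 + 1e-12:
            raise InputError("p_forward + p_pause must not exceed 1")
        if self.reward_sensitivity < 0:
            raise InputError("reward_sensitivity must be >= 0")


@dataclass(frozen=True)
class LarvaParams:
    """Mechanical and behavioural parameters of the virtual larva.

    Forces in mN, times in s, distances in mm.  The per-wave net force
    increments default to the empirical means (+3 mN per forward wave,
    -7 mN per backward wave); ``elastic_coefficient_k`` converts force
    extrema into elastic energy and has no literature default — it is a
    required property of the preparation.
    """

    elastic_coefficient_k: float = 100.0  # mN/mm
    advance_per_forward_wave: float = 0.6  # mm
    retreat_per_backward_wave: float = 1.4  # mm
    forward_wave_duration_mean: float = 4.0
    forward_wave_duration_sd: float = 0.5
    backward_wave_duration_mean: float = 3.0
    backward_wave_duration_sd: float = 0.4
    inter_wave_delay_mean: float = 6.0
    inter_wave_delay_sd: float = 1.5
    forward_increment_mean: float = 3.0
    forward_increment_sd: float = 1.0
    backward_increment_mean: float = -7.0
    backward_increment_sd: float = 1.5
    peak_excursion_mean: float = 12.0  # transient rise above pre-wave plateau
    peak_excursion_sd: float = 1.0
    noise_sd: float = 0.0
    policy: LocomotionPolicy = field(default_factory=LocomotionPolicy)

    def __post_init__(self):
        if self.elastic_coefficient_k <= 0:
            raise InputError("elastic_coefficient_k must be > 0")
        for name in (
            "forward_wave_duration_mean",
            "backward_wave_duration_mean",
            "inter_wave_delay_mean",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        for name in ("advance_per_forward_wave", "retreat_per_backward_wave"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")

    def wave_duration_moments(self, direction: str) -> tuple[float, float]:
        if direction == FORWARD:
            return self.forward_wave_duration_mean, self.forward_wave_duration_sd
        return self.backward_wave_duration_mean, self.backward_wave_duration_sd

    def increment_moments(self, direction: str) -> tuple[float, float]:
        if direction == FORWARD:
            return self.forward_increment_mean, self.forward_increment_sd
        return self.backward_increment_mean, self.backward_increment_sd


@dataclass(frozen=True)
class CleftGeometry:
    """Tilted-cleft force field.

    The coverslip tilts by ``tilt_deg`` towards the slit, so the
    confinement force falls linearly with distance ``x`` from the slit.
    When ``force_gradient`` is not given it derives from the tilt and
    the body's elastic coefficient as ``k * tan(tilt)``: advancing 1 mm
    into the wedge deepens the compression by ``tan(tilt)`` mm.
    ``start_distance`` is the larva's initial distance from the slit,
    where the force equals ``baseline_force``.
    """

    tilt_deg: float = 3.0
    baseline_force: float = 25.0
    force_gradient: float | None = None  # mN/mm; derived from tilt if None
    start_distance: float = 10.0  # mm from the slit at trial start
    slit_position: float = 0.0

    def __post_init__(self):
        if self.baseline_force < 0:
            raise InputError("baseline_force must be >= 0")
        if self.force_gradient is not None and self.force_gradient < 0:
            raise InputError("force_gradient must be >= 0")
        if self.start_distance < 0:
            raise InputError("start_distance must be >= 0")

    def gradient(self, params: LarvaParams) -> float:
        if self.force_gradient is not None:
            return self.force_gradient
        if self.tilt_deg == 0:
            return 0.0
        return params.elastic_coefficient_k * math.tan(math.radians(self.tilt_deg))


@dataclass(frozen=True)
class TruthWave:
    """Ground-truth record for one injected wave."""

    wave_id: int
    direction: str
    start_s: float
    end_s: float
    peak_s: float
    peak_mN: float
    net_delta_mN: float
    plateau_before_mN: float


@dataclass(frozen=True)
class SimulatedTrial:
    force_trace: ForceTrace
    behavior: BehaviorTrack
    truth_waves: tuple[TruthWave, ...]
    seed: int
    params: LarvaParams
    geometry: CleftGeometry
    terminated_early: bool = False


def force_from_position(geometry: CleftGeometry, params: LarvaParams, x: float) -> float:
    """Confinement force (mN) at distance ``x`` (mm) from the slit.

    Linear in position: ``baseline_force`` at the starting distance,
    rising by the gradient per mm of advance towards the slit, clamped
    at zero (the coverslip cannot pull).
    """
    if x < 0:
        raise InputError(f"distance from slit must be >= 0, got {x}")
    g = geometry.gradient(params)
    f = geometry.baseline_force + g * (geometry.start_distance - x)
    return max(f, 0.0)


def synthesize_wave_profile(
    direction: str,
    peak_delta: float,
    net_delta: float,
    duration: float,
    dt: float,
    rise_fraction: float = 0.6,
) -> np.ndarray:
    """Force increment of one wave, relative to the pre-wave plateau.

    Raised-cosine rise from 0 to ``peak_delta`` over the first
    ``rise_fraction`` of the wave, then exponential relaxation to
    ``net_delta`` (the lasting per-wave force change), renormalised so
    the final sample equals ``net_delta`` exactly.  The peak excursion
    must dominate the net offset (``peak_delta >= max(net_delta, 0)``).
    """
    if duration <= 0:
        raise InputError(f"duration must be > 0, got {duration}")
    if dt <= 0 or dt >= duration:
        raise InputError("need duration > dt > 0")
    if direction not in (FORWARD, BACKWARD):
        raise InputError(f"unknown direction {direction!r}")
    if peak_delta < max(net_delta, 0.0) - 1e-12:
        raise InputError(
            f"peak excursion {peak_delta} must be >= max(net offset {net_delta}, 0)"
        )
    n = max(int(round(duration / dt)), 2)
    t = np.arange(n) * dt
    t_rise = rise_fraction * duration
    seg = np.empty(n)
    rising = t <= t_rise
    seg[rising] = peak_delta * 0.5 * (1.0 - np.cos(np.pi * t[rising] / t_rise))
    # relaxation: normalised exponential decay, exactly 1 at the peak
    # and 0 at the wave end so the last sample hits net_delta
    tau = (duration - t_rise) / 4.0
    s = (t[~rising] - t_rise) / tau
    s_end = (t[-1] - t_rise) / tau
    decay = (np.exp(-s) - np.exp(-s_end)) / (1.0 - np.exp(-s_end))
    seg[~rising] = net_delta + (peak_delta - net_delta) * decay
    seg[-1] = net_delta
    return seg


def sample_behavior_sequence(
    policy: LocomotionPolicy, n_waves: int, rng: np.random.Generator
) -> list[str]:
    """Draw ``n_waves`` wave-slot outcomes (forward / backward / pause)."""
    if n_waves < 0:
        raise InputError("n_waves must be >= 0")
    u = rng.random(n_waves)
    out = []
    for ui in u:
        if ui < policy.p_forward:
            out.append(FORWARD)
        elif ui < policy.p_forward + policy.p_pause:
            out.append(PAUSE)
        else:
            out.append(BACKWARD)
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float | None = None,
    hi: float | None = None, max_tries: int = 100,
) -> float:
    """Normal draw rejected outside [lo, hi]; falls back to clipping."""
    if sd == 0:
        x = mean
    else:
        x = mean + sd * rng.standard_normal()
        tries = 0
        while ((lo is not None and x < lo) or (hi is not None and x > hi)) and tries < max_tries:
            x = mean + sd * rng.standard_normal()
            tries += 1
    if lo is not None:
        x = max(x, lo)
    if hi is not None:
        x = min(x, hi)
    return x


def simulate_trial(
    params: LarvaParams,
    geometry: CleftGeometry,
    duration_s: float = 120.0,
    sample_rate_hz: float = 100.0,
    seed: int = 0,
) -> SimulatedTrial:
    """Simulate one measurement trial of the cleft paradigm.

    The trace starts with a linear compression ramp reaching the
    baseline force in 5 s.  Wave slots are then drawn from the
    locomotion policy; each non-pause slot injects a wave profile whose
    net offset is a truncated-normal per-wave increment, preceded by a
    truncated-normal inter-wave delay.  The trial is truncated (and
    flagged) as soon as the resting force drops below 5 mN — loss of
    mechanical engagement.

    All randomness flows from one ``numpy`` Generator seeded with
    ``seed``; draw order is fixed (per slot: direction, delay, duration,
    peak excursion, net increment), so trials are bit-reproducible.
    """
    if duration_s <= RAMP_DURATION:
        raise InputError(f"duration_s must exceed the {RAMP_DURATION} s ramp")
    if sample_rate_hz <= 0:
        raise InputError("sample_rate_hz must be > 0")

    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    n_total = int(round(duration_s / dt)) + 1
    times = dt * np.arange(n_total)
    force = np.empty(n_total)

    baseline = force_from_position(geometry, params, geometry.start_distance)
    gradient = geometry.gradient(params)

    # 5 s linear compression ramp from 0 to baseline
    ramp_mask = times <= RAMP_DURATION
    force[ramp_mask] = baseline * times[ramp_mask] / RAMP_DURATION
    force[~ramp_mask] = baseline

    plateau = baseline
    x = geometry.start_distance
    t_cursor = RAMP_DURATION
    truth: list[TruthWave] = []
    events: list[BehaviorEvent] = []
    terminated_early = False
    wave_id = 0
    end_index = n_total  # exclusive cut point on early termination

    while True:
        direction = sample_behavior_sequence(params.policy, 1, rng)[0]
        delay = _truncated_normal(
            rng, params.inter_wave_delay_mean, params.inter_wave_delay_sd, lo=0.5
        )
        if direction == PAUSE:
            t_cursor += delay
            if t_cursor >= duration_s:
                break
            continue
        dur_mean, dur_sd = params.wave_duration_moments(direction)
        duration_w = _truncated_normal(rng, dur_mean, dur_sd, lo=max(4 * dt, 0.5))
        inc_mean, inc_sd = params.increment_moments(direction)
        peak_delta = _truncated_normal(
            rng, params.peak_excursion_mean, params.peak_excursion_sd, lo=0.0
        )
        # net increment truncated so the resting force stays >= 0
        net = _truncated_normal(rng, inc_mean, inc_sd, lo=-plateau)
        peak_delta = max(peak_delta, net, 0.0)

        t_start = t_cursor + delay
        t_end = t_start + duration_w
        if t_end > duration_s:
            break  # wave does not fit; no silent truncation of waves

        i0 = int(round(t_start / dt))
        seg = synthesize_wave_profile(direction, peak_delta, net, duration_w, dt)
        i1 = min(i0 + seg.size, n_total)
        force[i0:i1] = plateau + seg[: i1 - i0]
        force[i1:] = plateau + net

        peak_rel = float(np.argmax(seg)) * dt
        truth.append(
            TruthWave(
                wave_id=wave_id,
                direction=direction,
                start_s=t_start,
                end_s=t_end,
                peak_s=t_start + peak_rel,
                peak_mN=plateau + peak_delta,
                net_delta_mN=net,
                plateau_before_mN=plateau,
            )
        )
        events.append(BehaviorEvent(wave_id, direction, t_start, t_end))
        wave_id += 1
        plateau += net
        if gradient > 0:
            x += -net / gradient  # forward (net>0) moves towards the slit
            x = max(x, 0.0)
        t_cursor = t_end

        if plateau < MIN_ENGAGEMENT_FORCE:
            terminated_early = True
            end_index = min(int(round((t_end + 1.0) / dt)) + 1, n_total)
            break

    if params.noise_sd > 0:
        force = force + params.noise_sd * rng.standard_normal(n_total)

    force = force[:end_index]
    trace = ForceTrace(
        start_time=0.0,
        sample_interval=dt,
        values=force,
        meta={
            "source": "synthetic",
            "units": "mN",
            "baseline_force": baseline,
            "seed": seed,
        },
    )
    return SimulatedTrial(
        force_trace=trace,
        behavior=BehaviorTrack(tuple(events)),
        truth_waves=tuple(truth),
        seed=seed,
        params=params,
        geometry=geometry,
        terminated_early=terminated_early,
    )


def trial_to_files(trial: SimulatedTrial, directory, stem: str = "trial") -> dict:
    """Write a trial as force CSV + behaviour CSV + truth CSV + JSON sidecar.

    Returns the mapping of role -> path written.
    """
    import json
    from pathlib import Path

    import pandas as pd

    from .io import write_behavior_csv, write_force_csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "force": directory / f"{stem}_force.csv",
        "behavior": directory / f"{stem}_behavior.csv",
        "truth": directory / f"{stem}_truth.csv",
        "sidecar": directory / f"{stem}_params.json",
    }
    write_force_csv(trial.force_trace, paths["force"])
    write_behavior_csv(trial.behavior, paths["behavior"])
    pd.DataFrame([asdict(w) for w in trial.truth_waves]).to_csv(
        paths["truth"], index=False, float_format="%.12g"
    )
    sidecar = {
        "seed": trial.seed,
        "terminated_early": trial.terminated_early,
        "params": asdict(trial.params),
        "geometry": asdict(trial.geometry),
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths
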