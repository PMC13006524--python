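"""Closed-loop operant force-feedback training, simulated in silico.

Protocol: a larva starts under a commanded confinement force of 100 mN.
In pro-forward mode every forward peristaltic wave triggers a 20 mN
decrease of the commanded force (reward) and every backward wave a
20 mN increase (punishment); pro-backward mode mirrors the rule; naive
mode applies no feedback.  A session runs until the commanded force
reaches 0 mN (or a safety time cap).  The whole session is repeated
(two sessions by default, each restarting from the initial force), the
larva is excluded if it shows no peristaltic activity or — in
pro-forward training — a run of >= 5 consecutive backward waves amid
the rising pressure, and surviving larvae get a single 120 s test
session at 25 mN in which forward and backward waves are counted.

The controller (feedback step, termination, test protocol) is modelled
exactly; the larva's *learning rule* is a simulator assumption: a drop
in commanded force immediately after a wave nudges the policy's
forward-vs-backward logit towards that wave's direction, with gain
``reward_sensitivity`` (see :mod:`larvaforce.synthetic`).  Commanded
force changes settle linearly over the controller's 0.2 s response
time; waves arriving mid-transition see the instantaneous value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError
from .io import BACKWARD, FORWARD
from .synthetic import PAUSE, LarvaParams, LocomotionPolicy, _truncated_normal

PRO_FORWARD = "pro_forward"
PRO_BACKWARD = "pro_backward"
NAIVE = "naive"
MODES = (PRO_FORWARD, PRO_BACKWARD, NAIVE)

REACHED_ZERO = "reached_zero"
MAX_TIME = "max_time"

#: logit bound for the learned forward-vs-backward preference
LOGIT_BOUND = 4.0


@dataclass(frozen=True)
class TrainingConfig:
    mode: str = PRO_FORWARD
    initial_force: float = 100.0  # mN
    step: float = 20.0  # mN per wave
    sessions: int = 2
    controller_refresh_hz: float = 5.0
    controller_settle_s: float = 0.2
    test_force: float = 25.0  # mN
    test_duration_s: float = 120.0
    max_session_s: float = 600.0  # safety cap for non-terminating sessions

    def __post_init__(self):
        if self.mode not in MODES:
            raise InputError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.step <= 0:
            raise InputError("step must be > 0")
        if self.initial_force < 0:
            raise InputError("initial_force must be >= 0")
        if self.sessions < 1:
            raise InputError("sessions must be >= 1")


@dataclass(frozen=True)
class WaveFeedback:
    time_s: float
    direction: str
    commanded_before: float
    commanded_after: float


@dataclass(frozen=True)
class TrainingLog:
    records: tuple[WaveFeedback, ...]
    termination: str  # REACHED_ZERO or MAX_TIME
    session_index: int = 0

    @property
    def n_waves(self) -> int:
        return len(self.records)

    def directions(self) -> list[str]:
        return [r.direction for r in self.records]


@dataclass
class VirtualLarva:
    """Policy-carrying agent for training and test sessions.

    The learned state is the forward-vs-backward preference logit; the
    pause probability is fixed.  ``policy`` exposes the current
    probabilities; learning persists across sessions.
    """

    params: LarvaParams
    _logit: float = field(init=False)
    _p_pause: float = field(init=False)

    def __post_init__(self):
        pol = self.params.policy
        p_f, p_b = pol.p_forward, max(1.0 - pol.p_forward - pol.p_pause, 0.0)
        if p_f <= 0:
            self._logit = -LOGIT_BOUND
        elif p_b <= 0:
            self._logit = LOGIT_BOUND
        else:
            self._logit = math.log(p_f / p_b)
        self._p_pause = pol.p_pause

    @property
    def policy(self) -> LocomotionPolicy:
        p_active = 1.0 - self._p_pause
        p_f = p_active / (1.0 + math.exp(-self._logit))
        return LocomotionPolicy(
            p_forward=p_f,
            p_pause=self._p_pause,
            reward_sensitivity=self.params.policy.reward_sensitivity,
        )

    def draw_wave(self, rng: np.random.Generator) -> tuple[str, float, float]:
        """One wave slot: (direction, preceding delay s, wave duration s)."""
        pol = self.policy
        u = rng.random()
        delay = _truncated_normal(
            rng, self.params.inter_wave_delay_mean, self.params.inter_wave_delay_sd, lo=0.5
        )
        if u < pol.p_forward:
            direction = FORWARD
        elif u < pol.p_forward + pol.p_pause:
            return PAUSE, delay, 0.0
        else:
            direction = BACKWARD
        mean, sd = self.params.wave_duration_moments(direction)
        duration = _truncated_normal(rng, mean, sd, lo=0.5)
        return direction, delay, duration

    def reinforce(self, direction: str, force_delta: float) -> None:
        """Bounded logit update after a wave.

        A commanded-force *drop* (force_delta < 0) reinforces the wave's
        direction with gain ``reward_sensitivity``; increases leave the
        policy unchanged (the minimal reward-only mechanism).
        """
        s = self.params.policy.reward_sensitivity
        if s == 0 or force_delta >= 0 or direction == PAUSE:
            return
        nudge = s if direction == FORWARD else -s
        self._logit = min(max(self._logit + nudge, -LOGIT_BOUND), LOGIT_BOUND)


class ScriptedLarva(VirtualLarva):
    """A larva that replays a fixed wave sequence (for protocol checks).

    ``sequence`` entries are directions (forward/backward/pause); when
    exhausted the larva pauses forever.  Delays and durations are fixed
    at the policy means, so session timelines are fully deterministic.
    """

    def __init__(self, params: LarvaParams, sequence):
        super().__init__(params)
        self._script = list(sequence)
        self._cursor = 0

    def draw_wave(self, rng: np.random.Generator) -> tuple[str, float, float]:
        if self._cursor >= len(self._script):
            return PAUSE, self.params.inter_wave_delay_mean, 0.0
        direction = self._script[self._cursor]
        self._cursor += 1
        delay = self.params.inter_wave_delay_mean
        if direction == PAUSE:
            return PAUSE, delay, 0.0
        duration = self.params.wave_duration_moments(direction)[0]
        return direction, delay, duration


def apply_feedback(commanded: float, wave_direction: str, mode: str, step: float) -> float:
    """Commanded force after one wave under the training rule (clamped at 0)."""
    if commanded < 0:
        raise InputError("commanded force must be >= 0")
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}")
    if wave_direction not in (FORWARD, BACKWARD):
        raise InputError(f"unknown wave direction {wave_direction!r}")
    if mode == NAIVE:
        return commanded
    reward_dir = FORWARD if mode == PRO_FORWARD else BACKWARD
    delta = -step if wave_direction == reward_dir else step
    return max(commanded + delta, 0.0)


def run_training_session(
    larva: VirtualLarva,
    config: TrainingConfig,
    rng: np.random.Generator,
    session_index: int = 0,
) -> TrainingLog:
    """One feedback session: waves drive the commanded force to 0 mN.

    The commanded force settles linearly over ``controller_settle_s``
    after each wave; since wave slots are separated by at least the
    minimum inter-wave delay (0.5 s), every wave sees the settled value.
    Policy updates (reward learning) persist on the larva.
    """
    commanded = config.initial_force
    t = 0.0
    records: list[WaveFeedback] = []
    termination = MAX_TIME
    while t < config.max_session_s:
        direction, delay, duration = larva.draw_wave(rng)
        t += delay + duration
        if t >= config.max_session_s:
            break
        if direction == PAUSE:
            continue
        before = commanded
        commanded = apply_feedback(commanded, direction, config.mode, config.step)
        records.append(WaveFeedback(t, direction, before, commanded))
        larva.reinforce(direction, commanded - before)
        if commanded <= 0:
            termination = REACHED_ZERO
            break
    return TrainingLog(tuple(records), termination, session_index)


def check_exclusion(log_or_logs, mode: str) -> tuple[bool, str | None]:
    """Apply the training exclusion rules to one or more session logs.

    Pro-forward training excludes a larva that produced a run of >= 5
    consecutive backward waves with no intervening forward wave while
    each backward wave was driving the commanded force up, or that
    showed no peristaltic activity at all.  Pro-backward training
    excludes only inactivity.  Naive larvae are never excluded.
    Returns ``(excluded, rule_fired)``.
    """
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}")
    logs = log_or_logs if isinstance(log_or_logs, (list, tuple)) else [log_or_logs]
    if mode == NAIVE:
        return False, None
    n_waves = sum(log.n_waves for log in logs)
    if n_waves == 0:
        return True, "no_peristaltic_activity"
    if mode == PRO_FORWARD:
        for log in logs:
            run = 0
            for rec in log.records:
                if rec.direction == BACKWARD and rec.commanded_after >= rec.commanded_before:
                    run += 1
                    if run >= 5:
                        return True, "consecutive_backward_waves"
                elif rec.direction == FORWARD:
                    run = 0
    return False, None


def run_test_session(
    larva: VirtualLarva, config: TrainingConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Post-training test: count forward/backward waves in 120 s at 25 mN.

    The platform is locked (no feedback), so the policy does not change;
    wave slots are drawn until the test window is exhausted.
    """
    t = 0.0
    n_f = n_b = 0
    while True:
        direction, delay, duration = larva.draw_wave(rng)
        t += delay + duration
        if t >= config.test_duration_s:
            break
        if direction == FORWARD:
            n_f += 1
        elif direction == BACKWARD:
            n_b += 1
    return n_f, n_b


def train_and_test_one(
    params: LarvaParams, config: TrainingConfig, rng: np.random.Generator
) -> dict:
    """Full protocol for one larva: sessions, exclusion check, test."""
    larva = VirtualLarva(params)
    logs = []
    if config.mode != NAIVE:
        for s in range(config.sessions):
            logs.append(run_training_session(larva, config, rng, session_index=s))
    excluded, rule = check_exclusion(logs, config.mode) if logs else (False, None)
    if excluded:
        return {"excluded": True, "exclusion_rule": rule,
                "n_forward": None, "n_backward": None, "logs": logs}
    n_f, n_b = run_test_session(larva, config, rng)
    return {"excluded": False, "exclusion_rule": None,
            "n_forward": n_f, "n_backward": n_b, "logs": logs}


def run_experiment(
    params: LarvaParams,
    modes: tuple[str, ...] = (NAIVE, PRO_FORWARD, PRO_BACKWARD),
    n_per_group: int = 10,
    seed: int = 0,
    config: TrainingConfig | None = None,
    replacement_cap: int = 5,
) -> pd.DataFrame:
    """Simulate the grouped training experiment.

    Each group gets ``n_per_group`` larvae; a larva excluded during
    training is replaced by a fresh one (new seed) up to
    ``replacement_cap`` extra attempts per slot, mirroring a fixed
    group size with animal exclusion.  Returns one row per tested larva
    (group, seed, wave counts); aggregate with
    :func:`summarize_experiment`.
    """
    if n_per_group < 0:
        raise InputError("n_per_group must be >= 0")
    base = config or TrainingConfig()
    root = np.random.default_rng(seed)
    rows = []
    for mode in modes:
        cfg = replace(base, mode=mode)
        for i in range(n_per_group):
            for attempt in range(replacement_cap + 1):
                sub_seed = int(root.integers(0, 2**31 - 1))
                res = train_and_test_one(params, cfg, np.random.default_rng(sub_seed))
                if not res["excluded"]:
                    break
            rows.append(
                {
                    "group": mode,
                    "larva": i,
                    "seed": sub_seed,
                    "attempts": attempt + 1,
                    "excluded": res["excluded"],
                    "n_forward": res["n_forward"],
                    "n_backward": res["n_backward"],
                }
            )
    return pd.DataFrame(rows)


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Group means and SDs of the test-session wave counts."""
    ok = table[~table["excluded"]]
    return (
        ok.groupby("group")[["n_forward", "n_backward"]]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
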