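"""Point-biserial coupling between locomotor state and counteracting force.

Locomotion is coded per sample as 1 (forward peristalsis), 0 (static)
or -1 (backward peristalsis).  For each active state the coupling with
the (baseline-subtracted) force signal is the point-biserial
correlation

    r_pb = ((M1 - M0) / S) * sqrt(n1 * n0 / n^2)

where M1 and M0 are the mean force during the active and static
samples, S is the standard deviation of force pooled over the included
samples (population normalisation, divide by n), and n1, n0, n are the
sample counts (n = n1 + n0).  Samples carrying the *other* active code
are excluded from the comparison, so each r_pb is a clean two-group
statistic; with this normalisation r_pb is exactly the Pearson
correlation between force and the 0/1 activity indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io import BACKWARD, FORWARD, BehaviorTrack, ForceTrace, align

#: length of the pre-compression reference interval (s)
BASELINE_WINDOW = 5.0


@dataclass(frozen=True)
class StateCoupling:
    """r_pb for one active state plus its components."""

    r_pb: float  # NaN when undefined
    m_active: float
    m_static: float
    s_pooled: float
    n_active: int
    n_static: int
    n_total: int
    defined: bool


@dataclass(frozen=True)
class CouplingResult:
    forward: StateCoupling
    backward: StateCoupling
    clock_offset_s: float = 0.0

    @property
    def r_pb_forward(self) -> float:
        return self.forward.r_pb

    @property
    def r_pb_backward(self) -> float:
        return self.backward.r_pb


def encode_states(track: BehaviorTrack, times: np.ndarray) -> np.ndarray:
    """Per-sample state codes {1, 0, -1} from a behaviour track."""
    return track.state_at(times)


def subtract_baseline(trace: ForceTrace) -> ForceTrace:
    """Subtract the mean of the initial 5 s pre-compression reference.

    Idempotent: the re-centred first 5 s has zero mean, so applying the
    subtraction again changes nothing.
    """
    if trace.duration < BASELINE_WINDOW:
        raise InputError(
            f"trace spans {trace.duration:.3g} s < {BASELINE_WINDOW} s baseline window"
        )
    n = int(round(BASELINE_WINDOW / trace.sample_interval)) + 1
    ref = float(np.mean(trace.values[:n]))
    return ForceTrace(
        trace.start_time, trace.sample_interval, trace.values - ref,
        {**trace.meta, "baseline_subtracted_mN": ref},
    )


def point_biserial(
    force: np.ndarray, codes: np.ndarray, active_state: str
) -> StateCoupling:
    """Point-biserial correlation of force with one locomotor state.

    ``active_state`` selects which code counts as active (``forward`` ->
    1, ``backward`` -> -1); samples carrying the opposite active code
    are excluded.  Undefined results (no active samples, no static
    samples, or zero pooled SD) come back flagged with r_pb = NaN rather
    than raising, since a trial without one of the states is a valid
    observation.
    """
    if active_state not in (FORWARD, BACKWARD):
        raise InputError(f"active_state must be forward/backward, got {active_state!r}")
    force = np.asarray(force, dtype=float)
    codes = np.asarray(codes)
    if force.shape != codes.shape:
        raise InputError("force and codes must have equal length")
    active_code = 1 if active_state == FORWARD else -1
    include = (codes == active_code) | (codes == 0)
    f = force[include]
    active = codes[include] == active_code
    n1 = int(active.sum())
    n0 = int(f.size - n1)
    n = n1 + n0
    if n1 == 0 or n0 == 0:
        return StateCoupling(math.nan, math.nan, math.nan, math.nan, n1, n0, n, False)
    m1 = float(f[active].mean())
    m0 = float(f[~active].mean())
    s = float(f.std())  # population SD over the included samples
    if s == 0:
        return StateCoupling(math.nan, m1, m0, s, n1, n0, n, False)
    r = ((m1 - m0) / s) * math.sqrt(n1 * n0 / n**2)
    return StateCoupling(r, m1, m0, s, n1, n0, n, True)


def coupling_analysis(
    trace: ForceTrace, track: BehaviorTrack, tolerance_s: float = 0.5
) -> CouplingResult:
    """Full behaviour-force coupling pipeline for one trial.

    align (clock-offset correction + truncation at the last valid index
    of both series) -> baseline subtraction -> state coding ->
    point-biserial r for the forward (1 vs 0) and backward (-1 vs 0)
    states.
    """
    centred = subtract_baseline(trace)
    force, codes, _times, offset = align(centred, track, tolerance_s)
    return CouplingResult(
        forward=point_biserial(force, codes, FORWARD),
        backward=point_biserial(force, codes, BACKWARD),
        clock_offset_s=offset,
    )
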