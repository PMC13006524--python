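"""Force-trace and behaviour-track containers, CSV round-tripping,
resampling and clock alignment.

The measured signal is the vertical force (mN) a confined larva exerts
on a sensor platform, sampled uniformly in time.  Behaviour arrives as
an event table of peristaltic waves, each labelled forward or backward,
from which a per-sample locomotor state code in {1 forward, 0 static,
-1 backward} is derived.

Time is trial-relative seconds with t = 0 at the onset of the
compression ramp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, InputError

log = logging.getLogger(__name__)

#: direction labels used throughout the package
FORWARD = "forward"
BACKWARD = "backward"

#: numeric state codes
STATE_CODE = {FORWARD: 1, BACKWARD: -1}

#: maximum per-sample timestamp jitter tolerated when reading CSV (s)
TIME_JITTER_TOL = 1e-6

#: duration of the compression ramp that opens every trial (s);
#: trial-relative time puts t = 0 at ramp onset
RAMP_DURATION = 5.0


@dataclass(frozen=True)
class ForceTrace:
    """A uniformly sampled vertical-force time series.

    Parameters
    ----------
    start_time : float
        Time of the first sample (s).
    sample_interval : float
        Spacing between samples (s); must be positive.
    values : numpy.ndarray
        Force samples in mN, at least two of them, all finite.
    meta : dict
        Free-form provenance (source path, units, baseline force, seed).
    """

    start_time: float
    sample_interval: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.sample_interval <= 0:
            raise InputError(f"sample_interval must be > 0, got {self.sample_interval}")
        if vals.ndim != 1 or vals.size < 2:
            raise InputError("a force trace needs at least 2 samples")
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise FormatError(f"non-finite force value at sample {bad}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.sample_interval

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.sample_interval * np.arange(self.values.size)

    @property
    def end_time(self) -> float:
        return self.start_time + self.sample_interval * (self.values.size - 1)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t``, clipped to the trace."""
        i = int(round((t - self.start_time) / self.sample_interval))
        return min(max(i, 0), self.values.size - 1)

    def value_at(self, t: float) -> float:
        return float(self.values[self.index_of(t)])

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples with times in [t0, t1] (inclusive)."""
        i0 = int(np.ceil((t0 - self.start_time) / self.sample_interval - 1e-9))
        i1 = int(np.floor((t1 - self.start_time) / self.sample_interval + 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.values.size - 1)
        return self.values[i0 : i1 + 1]


@dataclass(frozen=True)
class BehaviorEvent:
    wave_id: int
    direction: str  # FORWARD or BACKWARD
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.direction not in (FORWARD, BACKWARD):
            raise InputError(f"unknown direction {self.direction!r}")
        if not self.end_s > self.start_s:
            raise InputError(
                f"event {self.wave_id}: end ({self.end_s}) must exceed start ({self.start_s})"
            )


@dataclass(frozen=True)
class BehaviorTrack:
    """Per-wave behaviour annotations and the derived state function.

    Events of one track must not overlap; the locomotor state is 1
    inside forward events, -1 inside backward events and 0 elsewhere.
    """

    events: tuple[BehaviorEvent, ...]

    def __post_init__(self):
        evs = tuple(sorted(self.events, key=lambda e: e.start_s))
        object.__setattr__(self, "events", evs)
        for a, b in zip(evs, evs[1:]):
            if b.start_s < a.end_s - 1e-12:
                raise FormatError(
                    f"behaviour events {a.wave_id} and {b.wave_id} overlap "
                    f"([{a.start_s}, {a.end_s}] vs [{b.start_s}, {b.end_s}])"
                )

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """State code {1, 0, -1} for each query time.

        Membership is half-open [start, end): a sample exactly at an
        event's end belongs to the following static period.
        """
        t = np.asarray(times, dtype=float)
        codes = np.zeros(t.shape, dtype=int)
        for ev in self.events:
            codes[(t >= ev.start_s) & (t < ev.end_s)] = STATE_CODE[ev.direction]
        return codes

    def shifted(self, offset_s: float) -> "BehaviorTrack":
        return BehaviorTrack(
            tuple(
                replace(e, start_s=e.start_s + offset_s, end_s=e.end_s + offset_s)
                for e in self.events
            )
        )

    @property
    def end_time(self) -> float:
        return max((e.end_s for e in self.events), default=0.0)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

FORCE_COLUMNS = ("time_s", "force_mN")
EVENT_COLUMNS = ("wave_id", "direction", "start_s", "end_s")

#: short direction codes used in CSV files
_DIR_TO_CODE = {FORWARD: "F", BACKWARD: "B"}
_CODE_TO_DIR = {"F": FORWARD, "B": BACKWARD}


def read_force_csv(path) -> ForceTrace:
    """Read a two-column ``time_s, force_mN`` CSV into a :class:`ForceTrace`.

    Timestamps must be strictly increasing and uniform to within 1 µs of
    jitter; violations raise :class:`FormatError` naming the offending
    row.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in FORCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples, got {len(df)}")
    t = df["time_s"].to_numpy(dtype=float)
    f = df["force_mN"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise FormatError(f"{path}: non-finite time at row {int(np.flatnonzero(~np.isfinite(t))[0])}")
    if not np.all(np.isfinite(f)):
        raise FormatError(f"{path}: NaN/inf force at row {int(np.flatnonzero(~np.isfinite(f))[0])}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise FormatError(f"{path}: non-monotone time at row {row}")
    dt0 = float(np.median(dt))
    jitter = np.abs(dt - dt0)
    if np.any(jitter > TIME_JITTER_TOL):
        row = int(np.argmax(jitter)) + 1
        raise FormatError(
            f"{path}: non-uniform sampling at row {row} "
            f"(interval {dt[row-1]:.9g} s vs median {dt0:.9g} s)"
        )
    return ForceTrace(start_time=float(t[0]), sample_interval=dt0, values=f,
                      meta={"source": str(path), "units": "mN"})


def write_force_csv(trace: ForceTrace, path) -> None:
    """Write a trace as ``time_s, force_mN`` with full float precision."""
    df = pd.DataFrame({"time_s": trace.times, "force_mN": trace.values})
    df.to_csv(path, index=False, float_format="%.12g")


def read_behavior_csv(path) -> BehaviorTrack:
    """Read a behaviour event table (``wave_id, direction, start_s, end_s``)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    events = []
    for i, row in df.iterrows():
        code = str(row["direction"]).strip()
        if code not in _CODE_TO_DIR:
            raise FormatError(f"{path}: unknown direction {code!r} at row {i}")
        events.append(
            BehaviorEvent(
                wave_id=int(row["wave_id"]),
                direction=_CODE_TO_DIR[code],
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
            )
        )
    return BehaviorTrack(tuple(events))


def write_behavior_csv(track: BehaviorTrack, path) -> None:
    df = pd.DataFrame(
        {
            "wave_id": [e.wave_id for e in track.events],
            "direction": [_DIR_TO_CODE[e.direction] for e in track.events],
            "start_s": [e.start_s for e in track.events],
            "end_s": [e.end_s for e in track.events],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Resampling and alignment
# ---------------------------------------------------------------------------

def resample(trace: ForceTrace, new_rate_hz: float) -> ForceTrace:
    """Linearly interpolate a trace onto a uniform grid at ``new_rate_hz``.

    The first sample is preserved exactly; the grid covers the original
    time span.  A constant trace maps to a constant trace.
    """
    if new_rate_hz <= 0:
        raise InputError(f"new_rate_hz must be > 0, got {new_rate_hz}")
    dt = 1.0 / new_rate_hz
    n = int(np.floor(trace.duration / dt + 1e-9)) + 1
    if n < 2:
        raise InputError(
            f"rate {new_rate_hz} Hz yields {n} sample(s) over {trace.duration:.3g} s"
        )
    new_t = trace.start_time + dt * np.arange(n)
    new_v = np.interp(new_t, trace.times, trace.values)
    return ForceTrace(trace.start_time, dt, new_v, dict(trace.meta))


def estimate_clock_offset(
    trace: ForceTrace,
    track: BehaviorTrack,
    search_s: float = 5.0,
) -> float:
    """Estimate the track-minus-trace clock offset by cross-correlation.

    Peristaltic waves coincide with episodes of rapid force change, so
    the wave-state indicator (|state| as a 0/1 series) is
    cross-correlated against a matching 0/1 force-activity series —
    samples where the smoothed slope magnitude exceeds the settling
    threshold.  Both series are boxcars over near-identical intervals,
    so the correlation peaks at the true lag without shape bias.  The
    maximising lag, searched over +-``search_s``, is the additive
    correction (in seconds) that brings the track onto the trace's
    clock.
    """
    from ._signal import SLOPE_THRESHOLD, smoothed, smoothed_slope

    dt = trace.sample_interval
    times = trace.times
    slope = smoothed_slope(smoothed(trace.values, dt), dt)
    activity_force = (np.abs(slope) > SLOPE_THRESHOLD).astype(float)
    activity_force[times <= trace.start_time + RAMP_DURATION] = 0.0  # ramp is not behaviour

    indicator = (track.state_at(times) != 0).astype(float)
    if indicator.sum() == 0 or activity_force.sum() == 0:
        return 0.0
    activity_force = activity_force - activity_force.mean()
    indicator = indicator - indicator.mean()

    max_lag = int(round(search_s / dt))
    lags = np.arange(-max_lag, max_lag + 1)
    # full cross-correlation, restricted to the searched lags
    full = np.correlate(activity_force, indicator, mode="full")
    centre = indicator.size - 1
    keep = (centre + lags >= 0) & (centre + lags < full.size)
    lags = lags[keep]
    scores = full[centre + lags]
    best = lags[int(np.argmax(scores))]
    # best > 0: force activity lags the annotated waves, so the track's
    # clock runs early; adding best*dt to the track corrects it.
    return float(best * dt)


def align(
    trace: ForceTrace,
    track: BehaviorTrack,
    tolerance_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Bring a force trace and behaviour track onto one clock.

    A global offset between the two clocks is estimated by
    cross-correlation and corrected by shifting the track, provided the
    detected offset does not exceed ``tolerance_s`` (the synchronisation
    error budget); larger offsets raise :class:`AlignmentError`.  Both
    series are truncated at the last valid index of either dataset.

    Estimated offsets below the estimator's resolution (half the
    boundary-smoothing window) snap to zero, which makes ``align``
    idempotent: re-aligning an already-aligned pair changes nothing.

    Returns ``(force, state_codes, times, applied_offset_s)``.
    """
    if track.events and (
        track.end_time <= trace.start_time
        or min(e.start_s for e in track.events) >= trace.end_time
    ):
        raise AlignmentError("trace and track have no overlapping time support")

    from ._signal import SMOOTH_WINDOW

    offset = estimate_clock_offset(trace, track, search_s=max(5.0, 2 * tolerance_s))
    if abs(offset) > tolerance_s + trace.sample_interval / 2:
        raise AlignmentError(
            f"detected clock offset {offset:.3f} s exceeds tolerance {tolerance_s} s"
        )
    if abs(offset) <= 0.5 * SMOOTH_WINDOW:
        offset = 0.0
    shifted = track.shifted(offset)

    # truncate at the last valid index of both datasets
    t_last = min(trace.end_time, shifted.end_time) if shifted.events else trace.end_time
    n = trace.index_of(t_last) + 1
    times = trace.times[:n]
    force = trace.values[:n]
    codes = shifted.state_at(times)
    return force, codes, times, offset
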