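"""Segmentation of a force trace into peristaltic force waves.

Detection follows the classic findpeaks recipe: local maxima filtered
by topographic prominence (default minimum 5 mN), with close-by
candidates (closer than 3 s) merged keeping the highest.  Each retained
peak is delimited into a wave period — the start is the local minimum
nearest before the peak (falling back to the first minimum after the
previous peak), the end is where the smoothed slope magnitude stays
below 0.5 mN/s for at least 0.5 s — and adjacent periods are trimmed so
they overlap by less than 10% of the shorter one.  Detected force waves
are then matched to annotated behaviour waves by temporal overlap and
grouped into bouts of consecutive same-direction waves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import InputError
from ._signal import SLOPE_SPAN, SLOPE_THRESHOLD, SMOOTH_WINDOW, noise_scale, smoothed, smoothed_slope
from .io import RAMP_DURATION, BehaviorTrack, ForceTrace

log = logging.getLogger(__name__)

UNMATCHED = "unmatched"

#: wave-end rule: |slope| must stay below SLOPE_THRESHOLD for this long (s)
SLOPE_DWELL = 0.5
#: maximum tolerated overlap between adjacent wave periods, as a
#: fraction of the shorter period
MAX_OVERLAP_FRACTION = 0.10


@dataclass(frozen=True)
class PeakParams:
    """findpeaks-style detection parameters (all strictly positive)."""

    window_s: float = 5.0
    min_prominence: float = 5.0  # mN
    min_distance_s: float = 3.0

    def __post_init__(self):
        for name in ("window_s", "min_prominence", "min_distance_s"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")


@dataclass(frozen=True)
class ForceWave:
    """One detected force wave and its linkage to behaviour."""

    peak_time: float
    peak_value: float
    start_time: float
    start_value: float
    end_time: float
    end_value: float
    prominence: float
    direction: str = UNMATCHED
    matched_behavior_wave_id: int | None = None
    truncated: bool = False  # delimited against a trace boundary

    @property
    def period(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class Bout:
    """A maximal run of same-direction waves with gaps under 30 s."""

    bout_id: int
    direction: str
    waves: tuple[ForceWave, ...]

    def __len__(self) -> int:
        return len(self.waves)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def prominence_of(trace: ForceTrace, peak_index: int) -> float:
    """Topographic prominence of the local maximum at ``peak_index``.

    Height of the peak above the higher of its two key saddles: on each
    side, walk outward to the nearest strictly higher sample (the trace
    boundary counts as higher ground) and take the minimum along the
    way; the prominence is the peak value minus the larger of the two
    side minima.
    """
    v = trace.values
    i = peak_index
    if i <= 0 or i >= v.size - 1 or not (v[i - 1] < v[i] and v[i] > v[i + 1]):
        raise InputError(f"index {peak_index} is not a strict local maximum")
    (prom,), _, _ = sps.peak_prominences(v, np.array([i]))
    return float(prom)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    v = values
    return np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1


def _retain_by_distance(
    indices: np.ndarray, heights: np.ndarray, min_distance_samples: int
) -> np.ndarray:
    """Greedy min-distance retention, highest candidates first.

    Candidates are visited in decreasing height (earlier index first on
    ties); one is kept only if every already-kept extremum is at least
    ``min_distance_samples`` away.  This mirrors findpeaks' ``merge or
    ignore overly close peaks while retaining the highest one``.
    """
    order = np.lexsort((indices, -heights))
    kept: list[int] = []
    for j in order:
        i = indices[j]
        if all(abs(i - k) >= min_distance_samples for k in kept):
            kept.append(int(i))
    return np.array(sorted(kept), dtype=int)


def find_extrema(
    trace: ForceTrace, params: PeakParams, polarity: str = "peaks"
) -> list[tuple[int, float]]:
    """Detect prominent peaks (or troughs) of a force trace.

    Returns ``[(sample_index, prominence), ...]`` ordered by time.  All
    reported extrema have prominence >= ``min_prominence`` and are at
    least ``min_distance_s`` apart; where candidates crowd closer, the
    highest (peaks) / lowest (troughs) wins.  Troughs are the peaks of
    the negated trace.

    The sliding analysis window of ``window_s`` (advanced by half a
    window, duplicates merged by index) bounds per-window cost; a peak's
    prominence is always evaluated on the full trace so window placement
    cannot change the result.
    """
    if polarity not in ("peaks", "troughs"):
        raise InputError(f"polarity must be 'peaks' or 'troughs', got {polarity!r}")
    values = trace.values if polarity == "peaks" else -trace.values
    dt = trace.sample_interval
    if trace.duration < params.min_distance_s:
        log.warning(
            "trace of %.3g s is shorter than min_distance_s=%.3g s; no extrema reported",
            trace.duration, params.min_distance_s,
        )
        return []

    # sliding windows (half-window hop) gather candidate local maxima;
    # the union over windows is exactly the set of global local maxima
    win = max(int(round(params.window_s / dt)), 3)
    hop = max(win // 2, 1)
    candidates: set[int] = set()
    for lo in range(0, max(values.size - 2, 1), hop):
        chunk = values[lo : lo + win + 2]
        if chunk.size < 3:
            break
        candidates.update((lo + _local_maxima(chunk)).tolist())
        if lo + win + 2 >= values.size:
            break
    if not candidates:
        return []
    idx = np.array(sorted(candidates), dtype=int)
    # keep only strict global local maxima (window edges can truncate)
    keep = (idx > 0) & (idx < values.size - 1)
    idx = idx[keep]
    idx = idx[(values[idx] > values[idx - 1]) & (values[idx] > values[idx + 1])]
    if idx.size == 0:
        return []

    proms = sps.peak_prominences(values, idx)[0]
    ok = proms >= params.min_prominence
    idx, proms = idx[ok], proms[ok]
    if idx.size == 0:
        return []

    min_dist = int(round(params.min_distance_s / dt))
    kept = _retain_by_distance(idx, values[idx], min_dist)
    prom_by_idx = dict(zip(idx.tolist(), proms.tolist()))
    return [(int(i), float(prom_by_idx[i])) for i in kept]


# ---------------------------------------------------------------------------
# Wave delimitation
# ---------------------------------------------------------------------------



def _wave_start(
    smooth: np.ndarray, eps: float, peak_idx: int, prev_peak_idx: int | None
) -> tuple[int, bool]:
    """Start of the wave period: index and a boundary-truncation flag.

    The start is the trough between the previous peak (or the trace
    start) and the current peak, read noise-robustly: the last sample of
    the inter-peak region whose smoothed value stays within ``eps`` of
    the region minimum.  On a flat inter-wave plateau this is the
    sample just before the rise — the last local minimum preceding the
    peak, which is also the later of the two candidate minima.
    """
    lo = 0 if prev_peak_idx is None else prev_peak_idx
    region = smooth[lo : peak_idx + 1]
    near_min = np.flatnonzero(region <= region.min() + eps)
    return lo + int(near_min[-1]), False




def _wave_end(
    smooth: np.ndarray, dt: float, peak_idx: int, next_peak_idx: int | None
) -> tuple[int, bool]:
    """End of the wave period: earliest post-peak time from which the
    smoothed slope magnitude stays below 0.5 mN/s for >= 0.5 s.

    The instantaneous zero-slope crossing at the peak itself cannot
    qualify because the dwell requirement demands sustained quiet.
    """
    hi = smooth.size - 1 if next_peak_idx is None else next_peak_idx
    slope = smoothed_slope(smooth, dt)
    quiet = (np.abs(slope) < SLOPE_THRESHOLD).astype(int)
    dwell = max(int(round(SLOPE_DWELL / dt)), 1)
    if quiet.size >= dwell:
        runs = np.convolve(quiet, np.ones(dwell, dtype=int), mode="valid")
        starts = np.flatnonzero(runs == dwell)
        starts = starts[(starts > peak_idx) & (starts + dwell - 1 <= hi)]
        if starts.size:
            return int(starts[0]), False
    return hi, True  # never settled before the next peak / boundary


def delimit_wave(
    trace: ForceTrace,
    peak_index: int,
    prev_peak_index: int | None = None,
    next_peak_index: int | None = None,
) -> tuple[float, float, bool]:
    """Delimit one wave period around a detected peak.

    Returns ``(start_time, end_time, truncated)``; boundaries are
    computed on a 0.2 s moving-average smoothing of the trace so that
    sensor noise does not dominate the trough and slope rules.
    """
    smooth = smoothed(trace.values, trace.sample_interval)
    eps = 3.0 * noise_scale(trace.values) / np.sqrt(
        max(int(round(SMOOTH_WINDOW / trace.sample_interval)), 1)
    )
    if prev_peak_index is None:
        ramp_idx = trace.index_of(trace.start_time + RAMP_DURATION + SMOOTH_WINDOW)
        prev_peak_index = ramp_idx if ramp_idx < peak_index else None
    s_idx, s_trunc = _wave_start(smooth, eps, peak_index, prev_peak_index)
    e_idx, e_trunc = _wave_end(smooth, trace.sample_interval, peak_index, next_peak_index)
    t0 = trace.times[s_idx]
    t1 = trace.times[e_idx]
    return float(t0), float(t1), bool(s_trunc or e_trunc)


def _trim_overlaps(waves: list[ForceWave]) -> list[ForceWave]:
    """Enforce the <10%-of-shorter-period overlap rule on adjacent waves.

    Where two periods overlap by 10% or more, the earlier wave's end is
    pulled back to the later wave's start (zero overlap), never past its
    own peak.
    """
    out = list(waves)
    for i in range(len(out) - 1):
        a, b = out[i], out[i + 1]
        overlap = a.end_time - b.start_time
        if overlap <= 0:
            continue
        shorter = min(a.period, b.period)
        if shorter > 0 and overlap / shorter >= MAX_OVERLAP_FRACTION:
            new_end = max(b.start_time, a.peak_time + 1e-9)
            out[i] = replace(a, end_time=new_end)
    return out


def segment_waves(trace: ForceTrace, params: PeakParams | None = None) -> list[ForceWave]:
    """Segment a force trace into force waves, ordered by peak time."""
    params = params or PeakParams()
    extrema = find_extrema(trace, params, "peaks")
    waves: list[ForceWave] = []
    indices = [i for i, _ in extrema]
    if not extrema:
        return waves
    dt = trace.sample_interval
    smooth = smoothed(trace.values, dt)
    eps = 3.0 * noise_scale(trace.values) / np.sqrt(
        max(int(round(SMOOTH_WINDOW / dt)), 1)
    )
    ramp_idx = trace.index_of(trace.start_time + RAMP_DURATION + SMOOTH_WINDOW)
    for j, (i, prom) in enumerate(extrema):
        prev_i = indices[j - 1] if j > 0 else (ramp_idx if ramp_idx < i else None)
        next_i = indices[j + 1] if j + 1 < len(indices) else None
        s_idx, s_trunc = _wave_start(smooth, eps, i, prev_i)
        e_idx, e_trunc = _wave_end(smooth, dt, i, next_i)
        t0, t1, trunc = float(trace.times[s_idx]), float(trace.times[e_idx]), bool(s_trunc or e_trunc)
        waves.append(
            ForceWave(
                peak_time=float(trace.times[i]),
                peak_value=float(trace.values[i]),
                start_time=t0,
                start_value=trace.value_at(t0),
                end_time=t1,
                end_value=trace.value_at(t1),
                prominence=prom,
                truncated=trunc,
            )
        )
    return _trim_overlaps(waves)


# ---------------------------------------------------------------------------
# Behaviour matching and bout grouping
# ---------------------------------------------------------------------------

def match_to_behavior(
    waves: list[ForceWave],
    track: BehaviorTrack,
    tolerance_s: float = 0.5,
) -> list[ForceWave]:
    """Assign each force wave the behaviour wave it most overlaps.

    A force wave (widened by the +-``tolerance_s`` synchronisation
    slack) is matched to the behaviour event with the greatest temporal
    overlap, provided that overlap covers at least half of the force
    wave's period; otherwise it stays unmatched.  Each behaviour event
    matches at most one force wave — greatest overlap wins, the earlier
    wave on ties.
    """
    pairs: list[tuple[float, float, int, int]] = []  # (-overlap, peak_time, wave#, event#)
    for wi, w in enumerate(waves):
        lo, hi = w.start_time - tolerance_s, w.end_time + tolerance_s
        need = 0.5 * w.period
        for ei, ev in enumerate(track.events):
            ov = min(hi, ev.end_s) - max(lo, ev.start_s)
            if ov > 0 and ov >= need:
                pairs.append((-ov, w.peak_time, wi, ei))
    pairs.sort()
    out = [replace(w, direction=UNMATCHED, matched_behavior_wave_id=None) for w in waves]
    used_waves: set[int] = set()
    used_events: set[int] = set()
    for _, _, wi, ei in pairs:
        if wi in used_waves or ei in used_events:
            continue
        ev = track.events[ei]
        out[wi] = replace(out[wi], direction=ev.direction,
                          matched_behavior_wave_id=ev.wave_id)
        used_waves.add(wi)
        used_events.add(ei)
    return out


def group_bouts(waves: list[ForceWave], max_gap_s: float = 30.0) -> list[Bout]:
    """Group matched waves into bouts of consecutive same-direction waves.

    Waves are consecutive only if they share a direction and the
    inter-wave gap (end of the previous wave to start of the next) is
    under ``max_gap_s``.  Unmatched waves break bouts and belong to
    none.
    """
    ordered = sorted(waves, key=lambda w: w.peak_time)
    bouts: list[Bout] = []
    current: list[ForceWave] = []

    def flush():
        if current:
            bouts.append(Bout(len(bouts), current[0].direction, tuple(current)))
            current.clear()

    for w in ordered:
        if w.direction == UNMATCHED:
            flush()
            continue
        if current and (
            w.direction != current[-1].direction
            or (w.start_time - current[-1].end_time) >= max_gap_s
        ):
            flush()
        current.append(w)
    flush()
    return bouts
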