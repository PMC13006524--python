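"""The six per-wave force parameters, elastic work, and wave-index
rescaling within bouts of consecutive peristaltic waves.

For each force wave in a bout the package reports:

1. ``delta_peak_prev`` — peak force change versus the previous wave of
   the bout (mN; undefined for a bout's first wave);
2. ``delta_peak_bout`` — peak force change versus the bout's first wave
   (mN);
3. ``amplitude`` — peak value minus end value of the wave (mN);
4. ``duration`` — wave period, start to end (s);
5. ``inter_wave_delay`` — end of the previous wave to start of this one
   (s; undefined for a bout's first wave);
6. ``work`` — elastic energy of the wave, (f_max^2 - f_min^2) / (2 k),
   in mN·mm = µJ, where f_max / f_min are the extreme trace values
   within the wave's period and k the elastic coefficient of the body
   (mN/mm).

To compare bouts of different absolute force levels, each parameter
series is rescaled against its first wave:
``P_re[n] = (Para[n] - Para[1]) / |Para[1]|``, so the first wave maps
to 0 and later values measure relative change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detection import Bout
from .errors import InputError
from .io import BACKWARD, FORWARD, ForceTrace

#: sentinel for parameters that are undefined rather than zero
UNDEFINED = float("nan")


@dataclass(frozen=True)
class WaveMetrics:
    bout_id: int
    wave_index: int  # 1-based index within the bout
    direction: str
    delta_peak_prev: float  # mN, NaN for the first wave
    delta_peak_bout: float  # mN
    amplitude: float  # mN
    duration: float  # s
    inter_wave_delay: float  # s, NaN for the first wave
    work: float  # µJ (mN·mm)


@dataclass(frozen=True)
class RescaledSeries:
    """Per-wave rescaled parameter values within one bout."""

    values: tuple[float, ...]
    reference: float  # Para[1]
    defined: bool  # False when Para[1] == 0


def wave_work(f_max: float, f_min: float, k: float) -> float:
    """Elastic work of a force wave, ``(f_max^2 - f_min^2) / (2 k)``.

    Equals the integral of force over displacement along the
    linear-elastic loading path f = k·x between the wave's force
    extremes; forces in mN and k in mN/mm give µJ.
    """
    if k <= 0:
        raise InputError(f"elastic coefficient k must be > 0, got {k}")
    if f_min < 0 or f_max < f_min:
        raise InputError(f"need f_max >= f_min >= 0, got f_max={f_max}, f_min={f_min}")
    return (f_max**2 - f_min**2) / (2.0 * k)


def compute_metrics(bout: Bout, trace: ForceTrace, k: float) -> list[WaveMetrics]:
    """The six parameters for every wave of a bout.

    ``f_max``/``f_min`` for the work estimate are the extreme trace
    values within each wave's own period (a trace value marginally below
    zero from sensor noise is clamped to zero).  For a singleton bout
    the inter-wave parameters are NaN — absent, not zero.
    """
    if k <= 0:
        raise InputError("k must be > 0")
    out: list[WaveMetrics] = []
    first_peak = bout.waves[0].peak_value if bout.waves else UNDEFINED
    for i, w in enumerate(bout.waves):
        seg = trace.slice(w.start_time, w.end_time)
        f_max = float(np.max(seg)) if seg.size else w.peak_value
        f_min = max(float(np.min(seg)) if seg.size else w.end_value, 0.0)
        f_max = max(f_max, f_min)
        prev = bout.waves[i - 1] if i > 0 else None
        out.append(
            WaveMetrics(
                bout_id=bout.bout_id,
                wave_index=i + 1,
                direction=w.direction,
                delta_peak_prev=(w.peak_value - prev.peak_value) if prev else UNDEFINED,
                delta_peak_bout=w.peak_value - first_peak,
                amplitude=w.peak_value - w.end_value,
                duration=w.period,
                inter_wave_delay=(w.start_time - prev.end_time) if prev else UNDEFINED,
                work=wave_work(f_max, f_min, k),
            )
        )
    return out


def rescale_series(values) -> RescaledSeries:
    """Rescale a per-wave parameter series against its first wave.

    ``P_re[n] = (Para[n] - Para[1]) / |Para[1]|``; the result is flagged
    undefined when the first wave's value is zero (or NaN).
    """
    vals = [float(v) for v in values]
    if not vals:
        raise InputError("need at least one wave")
    ref = vals[0]
    if ref == 0 or math.isnan(ref):
        return RescaledSeries(tuple(UNDEFINED for _ in vals), ref, defined=False)
    return RescaledSeries(tuple((v - ref) / abs(ref) for v in vals), ref, defined=True)


def direction_effect_fractions(
    metrics: list[WaveMetrics],
) -> tuple[float, float]:
    """Fractions of waves whose peak change matches their direction.

    Returns ``(forward_fraction, backward_fraction)``: among waves with
    a defined ``delta_peak_prev``, the share of forward waves that
    increased the peak force (delta > 0) and of backward waves that
    decreased it (delta < 0).  Ties (delta == 0) count against the
    direction-consistent share.  A direction with no eligible wave
    yields NaN.
    """
    fwd = [m.delta_peak_prev for m in metrics
           if m.direction == FORWARD and not math.isnan(m.delta_peak_prev)]
    bwd = [m.delta_peak_prev for m in metrics
           if m.direction == BACKWARD and not math.isnan(m.delta_peak_prev)]
    f_frac = sum(d > 0 for d in fwd) / len(fwd) if fwd else UNDEFINED
    b_frac = sum(d < 0 for d in bwd) / len(bwd) if bwd else UNDEFINED
    return f_frac, b_frac


def metrics_table(bouts: list[Bout], trace: ForceTrace, k: float):
    """All metrics of a trial as a tidy :class:`pandas.DataFrame`.

    One row per wave with the six parameters plus the rescaled
    peak-change, amplitude, duration, delay and work series of its bout.
    """
    import pandas as pd
    from dataclasses import asdict

    rows = []
    for bout in bouts:
        ms = compute_metrics(bout, trace, k)
        rescaled = {
            "rescaled_amplitude": rescale_series([m.amplitude for m in ms]),
            "rescaled_duration": rescale_series([m.duration for m in ms]),
            "rescaled_work": rescale_series([m.work for m in ms]),
        }
        for i, m in enumerate(ms):
            row = asdict(m)
            for name, rs in rescaled.items():
                row[name] = rs.values[i] if rs.defined else UNDEFINED
            rows.append(row)
    return pd.DataFrame(rows)
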