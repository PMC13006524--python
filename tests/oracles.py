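"""Independent reference implementations used as test oracles.

These deliberately avoid the library's code paths: prominence by a
quadratic definition walk, work by numerical integration, the
point-biserial statistic via numpy's Pearson correlation.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(values, dt, min_prominence, min_distance_s):
    """O(n^2) peak enumerator straight from the definitions.

    Strict local maxima; prominence = peak minus the higher of the two
    side minima, each taken walking to the nearest strictly higher
    sample (trace boundary = higher ground); then greedy min-distance
    retention, highest first, earlier index on ties.
    Returns sorted [(index, prominence), ...].
    """
    v = list(values)
    n = len(v)
    cands = []
    for i in range(1, n - 1):
        if not (v[i - 1] < v[i] > v[i + 1]):
            continue
        side_mins = []
        for step in (-1, 1):
            run_min = v[i]
            j = i + step
            while 0 <= j < n and v[j] <= v[i]:
                run_min = min(run_min, v[j])
                j += step
            side_mins.append(run_min)
        prom = v[i] - max(side_mins)
        if prom >= min_prominence:
            cands.append((i, prom))
    min_dist = int(round(min_distance_s / dt))
    kept = []
    for i, prom in sorted(cands, key=lambda c: (-values[c[0]], c[0])):
        if all(abs(i - k) >= min_dist for k, _ in kept):
            kept.append((i, prom))
    return sorted(kept)


def work_by_integration(f_max, f_min, k, n_steps=100_000):
    """Trapezoidal integral of f dx along the linear-elastic path f = k x."""
    x = np.linspace(f_min / k, f_max / k, n_steps + 1)
    return float(np.trapezoid(k * x, x))


def pearson_with_indicator(force, indicator):
    """Pearson correlation of force with a 0/1 indicator (numpy oracle)."""
    return float(np.corrcoef(np.asarray(force, float), np.asarray(indicator, float))[0, 1])


def random_bumpy_trace(rng, n, dt):
    """A random trace with realistic mixed structure for detector tests."""
    raw = np.cumsum(rng.standard_normal(n)) * rng.uniform(0.2, 2.0)
    k = int(rng.integers(1, 20))
    v = np.convolve(raw, np.ones(k) / k, mode="same")
    return v + rng.standard_normal(n) * 0.01
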