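"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-implement the analysis rules as plain
Python loops, independent of the vectorised library code they check.
"""

from __future__ import annotations

import numpy as np
import pytest


def crossing_scan_oracle(x, fs, threshold_sd=7.0, dead_time=1e-3, polarity="both"):
    """Direct sample-by-sample threshold scan with dead-time collapse.

    An exceeding sample within ``dead_time`` of the previous exceeding
    sample extends the current event; otherwise it starts a new one.
    """
    mu = float(np.mean(x))
    sd = float(np.std(x))
    if sd == 0.0:
        return []
    thr = threshold_sd * sd
    dead_n = int(round(dead_time * fs))
    out: list[float] = []
    last_exceed = None
    for i, v in enumerate(x):
        dev = v - mu
        hit = abs(dev) > thr if polarity == "both" else dev < -thr
        if hit:
            if last_exceed is None or i - last_exceed > dead_n:
                out.append(i / fs)
            last_exceed = i
    return out


def burst_oracle(hist, flags, electrode_order, active_set,
                 threshold_sd=5.0, min_participation=0.20, bin_s=0.05):
    """Independent mark/prune/merge re-implementation, bin by bin.

    Returns a list of (start_s, end_s, n_spikes, electrode frozenset).
    """
    hist = list(hist)
    n = len(hist)
    mean = sum(hist) / n
    sd = (sum((c - mean) ** 2 for c in hist) / n) ** 0.5
    active_cols = [j for j, e in enumerate(electrode_order) if e in active_set]
    marked = []
    for i in range(n):
        m = hist[i] > mean + threshold_sd * sd
        if m and active_cols:
            firing = sum(1 for j in active_cols if flags[i][j])
            if firing < min_participation * len(active_cols):
                m = False
        elif not active_cols:
            m = False
        marked.append(m)
    bursts = []
    i = 0
    while i < n:
        if marked[i]:
            j = i
            while j + 1 < n and marked[j + 1]:
                j += 1
            members = frozenset(
                electrode_order[c]
                for c in range(len(electrode_order))
                if any(flags[b][c] for b in range(i, j + 1))
            )
            bursts.append(
                (i * bin_s, (j + 1) * bin_s, sum(hist[i:j + 1]), members)
            )
            i = j + 1
        else:
            i += 1
    return bursts


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def spaced_times(rng, n, duration, min_gap=0.01, t_max_frac=0.99):
    """n random times in [0, duration*t_max_frac) separated by >= min_gap."""
    hi = duration * t_max_frac
    grid = np.linspace(0.0, hi - min_gap, n, endpoint=False)
    jitter = rng.uniform(0, (hi / n - min_gap) * 0.9, size=n)
    return np.sort(grid + jitter)
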