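"""Whole-network activity measures, network-burst detection, maturity staging.

Network bursts are detected from the population firing-rate histogram:
spike counts in 50 ms bins across all electrodes; bins whose count
strictly exceeds the mean bin count plus 5 SDs (mean and SD over all bins
of the recording, empty bins included) are candidate burst bins; candidate
bins in which fewer than 20% of the recording's active electrodes fire are
pruned; runs of consecutive surviving bins merge into single bursts.

Cultures are staged by age: young (15–35 DIV), middle-aged (42–56 DIV),
old (63–70 DIV); ages outside those ranges — including the gaps between
them — are left unstaged.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import Burst, BurstSet, NetworkActivitySummary, SpikeTrainSet

__all__ = [
    "network_firing_rate",
    "active_electrodes",
    "bin_spike_counts",
    "detect_network_bursts",
    "burst_spike_fraction",
    "classify_stage",
    "exclude_low_activity",
    "summarize_network",
]

log = logging.getLogger(__name__)

STAGE_RANGES = {"young": (15, 35), "middle_aged": (42, 56), "old": (63, 70)}


def network_firing_rate(trains: SpikeTrainSet) -> float:
    """Total spikes across all electrodes divided by recording length (Hz)."""
    return trains.n_spikes / trains.duration


def active_electrodes(trains: SpikeTrainSet, min_rate_hz: float = 0.1) -> set[str]:
    """Electrodes whose individual firing rate is >= ``min_rate_hz``."""
    if min_rate_hz < 0:
        raise ValueError(f"min_rate_hz must be >= 0, got {min_rate_hz}")
    return {
        eid
        for eid, t in trains.trains.items()
        if t.size / trains.duration >= min_rate_hz
    }


def bin_spike_counts(
    trains: SpikeTrainSet, bin_s: float = 0.05
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Population firing-rate histogram and per-electrode activity flags.

    Bins are half-open ``[i*bin_s, (i+1)*bin_s)``; a spike at exactly the
    recording end falls in the last bin.  Returns ``(histogram, flags,
    electrode_order)`` where ``histogram[i]`` is the total spike count in
    bin ``i`` and ``flags[i, j]`` marks electrode ``electrode_order[j]``
    firing at least one spike in bin ``i``.  The histogram sums to the
    total spike count.
    """
    if bin_s <= 0:
        raise ValueError(f"bin_s must be > 0, got {bin_s}")
    n_bins = max(1, int(np.ceil(trains.duration / bin_s - 1e-9)))
    order = trains.electrode_ids
    flags = np.zeros((n_bins, len(order)), dtype=bool)
    hist = np.zeros(n_bins, dtype=np.int64)
    for j, eid in enumerate(order):
        t = trains.trains[eid]
        if t.size == 0:
            continue
        idx = np.minimum((t / bin_s).astype(np.int64), n_bins - 1)
        np.add.at(hist, idx, 1)
        flags[idx, j] = True
    return hist, flags, order


def detect_network_bursts(
    histogram: np.ndarray,
    flags: np.ndarray,
    electrode_order: list[str],
    active_set: set[str],
    *,
    threshold_sd: float = 5.0,
    min_participation: float = 0.20,
    bin_s: float = 0.05,
) -> BurstSet:
    """Mark, prune and merge histogram bins into network bursts.

    Step 1 marks bins with count strictly greater than ``mean + threshold_sd
    * SD`` of the histogram (so a constant histogram yields no bursts).
    Step 2 unmarks bins where fewer than ``min_participation`` of the
    ``active_set`` electrodes fire ("fewer than" is strict: exactly the
    fraction survives).  Step 3 merges runs of consecutive marked bins;
    burst boundaries snap to bin edges, per-burst spike counts and the
    union of participating electrodes come from the merged bins.

    With an empty ``active_set`` every candidate bin is pruned and an empty
    set is returned with a logged warning.
    """
    histogram = np.asarray(histogram)
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (histogram.size, len(electrode_order)):
        raise ValueError("flags shape must be (n_bins, n_electrodes)")
    mean = float(np.mean(histogram))
    sd = float(np.std(histogram))
    marked = histogram > mean + threshold_sd * sd

    active_cols = [j for j, eid in enumerate(electrode_order) if eid in active_set]
    if not active_cols:
        if marked.any():
            log.warning("empty active set: all %d candidate bins pruned", int(marked.sum()))
        marked = np.zeros_like(marked)
    else:
        n_active_in_bin = flags[:, active_cols].sum(axis=1)
        marked &= n_active_in_bin >= min_participation * len(active_cols)

    bursts: list[Burst] = []
    i = 0
    n = marked.size
    while i < n:
        if not marked[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and marked[j + 1]:
            j += 1
        bins = slice(i, j + 1)
        members = frozenset(
            electrode_order[c] for c in np.flatnonzero(flags[bins].any(axis=0))
        )
        bursts.append(
            Burst(
                start_s=i * bin_s,
                end_s=(j + 1) * bin_s,
                n_spikes=int(histogram[bins].sum()),
                electrodes=members,
            )
        )
        i = j + 1
    return BurstSet(
        bursts=bursts,
        bin_s=bin_s,
        threshold_sd=threshold_sd,
        min_participation=min_participation,
    )


def burst_spike_fraction(trains: SpikeTrainSet, bursts: BurstSet) -> float:
    """Fraction of all recorded spikes falling inside detected bursts.

    Zero when there are no spikes or no bursts; always in [0, 1].
    """
    total = trains.n_spikes
    if total == 0 or len(bursts) == 0:
        return 0.0
    starts = np.array([b.start_s for b in bursts])
    ends = np.array([b.end_s for b in bursts])
    inside = 0
    for t in trains.trains.values():
        if t.size == 0:
            continue
        # spike in [start, end) of some burst
        k = np.searchsorted(starts, t, side="right") - 1
        valid = k >= 0
        inside += int(np.count_nonzero(valid & (t < ends[np.maximum(k, 0)])))
    return inside / total


def classify_stage(div: int) -> str:
    """Maturity stage for a culture age in days in vitro.

    Ages in the gaps between stage ranges (36–41, 57–62) and outside
    15–70 are ``"unstaged"``.
    """
    if div < 0:
        raise ValueError(f"div must be >= 0, got {div}")
    for stage, (lo, hi) in STAGE_RANGES.items():
        if lo <= div <= hi:
            return stage
    return "unstaged"


def exclude_low_activity(
    summary: NetworkActivitySummary, min_rate_hz: float = 0.05
) -> bool:
    """True when a recording shows too little activity to analyse further.

    The rule is a strict ``<``: a recording at exactly the threshold is
    retained.
    """
    return summary.firing_rate_hz < min_rate_hz


def summarize_network(
    trains: SpikeTrainSet,
    *,
    bin_s: float = 0.05,
    threshold_sd: float = 5.0,
    min_participation: float = 0.20,
    active_min_rate_hz: float = 0.1,
) -> tuple[NetworkActivitySummary, BurstSet]:
    """Run the full network-activity analysis for one recording."""
    active = active_electrodes(trains, active_min_rate_hz)
    hist, flags, order = bin_spike_counts(trains, bin_s)
    bursts = detect_network_bursts(
        hist,
        flags,
        order,
        active,
        threshold_sd=threshold_sd,
        min_participation=min_participation,
        bin_s=bin_s,
    )
    summary = NetworkActivitySummary(
        firing_rate_hz=network_firing_rate(trains),
        burst_fraction=burst_spike_fraction(trains, bursts),
        n_active_electrodes=len(active),
        div=trains.div,
        stage=classify_stage(trains.div) if trains.div is not None else "unstaged",
    )
    return summary, bursts
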