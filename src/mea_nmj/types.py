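"""Core in-memory containers shared by every analysis stage.

All times are seconds as floats; all interval conventions are half-open
``[start, end)`` unless a docstring says otherwise; one time origin per
recording (t = 0 at recording start) and per assay window (t = 0 at
window start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RawRecording",
    "SpikeTrainSet",
    "Burst",
    "BurstSet",
    "BurstSpec",
    "ContractionWindow",
    "ContractionSeries",
    "GroundTruth",
    "NetworkActivitySummary",
    "AssayResult",
]


@dataclass
class RawRecording:
    """Multichannel extracellular voltage recording.

    Parameters
    ----------
    electrode_ids
        Electrode labels, one per channel.
    fs
        Sampling frequency in Hz.
    samples
        Array of shape ``(n_electrodes, n_samples)`` in microvolts.
    """

    electrode_ids: list[str]
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (electrodes x samples) array")
        if len(self.electrode_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.electrode_ids)} electrode ids but "
                f"{self.samples.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike timestamps for one recording.

    ``trains`` maps electrode id to a sorted 1-D array of spike times in
    seconds.  ``div`` (days in vitro) is optional culture-age metadata used
    for maturity staging.  ``threshold_sd`` records the detection
    multiplier that produced the trains, when known.
    """

    trains: dict[str, np.ndarray]
    duration: float
    fs: float | None = None
    div: int | None = None
    threshold_sd: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        clean: dict[str, np.ndarray] = {}
        for eid, t in self.trains.items():
            t = np.asarray(t, dtype=np.float64).ravel()
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(
                    f"electrode {eid!r}: spike times outside [0, {self.duration}]"
                )
            if t.size and np.any(np.diff(t) < 0):
                t = np.sort(t)
            clean[eid] = t
        self.trains = clean

    @property
    def electrode_ids(self) -> list[str]:
        return list(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))


@dataclass(frozen=True)
class Burst:
    """One detected network burst, snapped to histogram bin edges."""

    start_s: float
    end_s: float
    n_spikes: int
    electrodes: frozenset[str]


@dataclass
class BurstSet:
    """Ordered, non-overlapping network bursts plus the detection settings."""

    bursts: list[Burst]
    bin_s: float = 0.05
    threshold_sd: float = 5.0
    min_participation: float = 0.20

    def __post_init__(self) -> None:
        for a, b in zip(self.bursts, self.bursts[1:]):
            if b.start_s < a.end_s:
                raise ValueError("bursts overlap or are unordered")

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    @property
    def total_burst_time(self) -> float:
        return float(sum(b.end_s - b.start_s for b in self.bursts))


@dataclass(frozen=True)
class BurstSpec:
    """Specification of one planted synchronized burst epoch.

    ``rate_multiplier`` scales the background rate for participating
    electrodes inside the epoch; ``participation`` is the fraction of
    electrodes recruited (drawn afresh per epoch).
    """

    start_s: float
    duration_s: float
    rate_multiplier: float
    participation: float

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.rate_multiplier < 1:
            raise ValueError(
                f"rate_multiplier must be >= 1, got {self.rate_multiplier}"
            )
        if not 0 < self.participation <= 1:
            raise ValueError(
                f"participation must be in (0, 1], got {self.participation}"
            )

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class ContractionWindow:
    """One observation window of a myotube contraction series.

    Event times are seconds relative to the window start; ``partial``
    optionally flags partial contractions, tallied separately from full
    contractions downstream.
    """

    duration_s: float
    times: np.ndarray
    partial: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"window duration must be > 0, got {self.duration_s}")
        t = np.asarray(self.times, dtype=np.float64).ravel()
        if t.size and np.any(np.diff(t) < 0):
            t = np.sort(t)
        if t.size and (t.min() < 0 or t.max() >= self.duration_s):
            raise ValueError("event time outside its window")
        self.times = t
        if self.partial is not None:
            p = np.asarray(self.partial, dtype=bool).ravel()
            if p.size != t.size:
                raise ValueError("partial flags must match event count")
            self.partial = p


@dataclass
class ContractionSeries:
    """Contraction event times for one myotube, by named window."""

    myotube_id: str
    windows: dict[str, ContractionWindow]
    group: str = "treated"  # treated | sham

    def window(self, name: str) -> ContractionWindow:
        try:
            return self.windows[name]
        except KeyError:
            raise KeyError(
                f"myotube {self.myotube_id!r} has no window {name!r}; "
                f"available: {sorted(self.windows)}"
            ) from None


@dataclass
class GroundTruth:
    """Planted truth emitted by the generators, for recovery scoring."""

    seed: int
    true_spike_times: Mapping[str, np.ndarray] | None = None
    true_burst_epochs: Sequence[tuple[float, float, frozenset[str]]] = field(
        default_factory=list
    )
    true_rates: dict[str, float] = field(default_factory=dict)


@dataclass
class NetworkActivitySummary:
    """Whole-network activity measures for one recording."""

    firing_rate_hz: float
    burst_fraction: float
    n_active_electrodes: int
    div: int | None = None
    stage: str = "unstaged"

    def __post_init__(self) -> None:
        if self.firing_rate_hz < 0:
            raise ValueError("firing_rate_hz must be >= 0")
        if not 0 <= self.burst_fraction <= 1:
            raise ValueError("burst_fraction must be in [0, 1]")


@dataclass
class AssayResult:
    """Outcome of the contraction blockade assay for one myotube."""

    myotube_id: str
    group: str
    pre_count: int
    post_count: int
    percent_reduction: float
    response_class: str
    binned_pre: np.ndarray
    binned_post: np.ndarray
    pre_partial_count: int = 0
    post_partial_count: int = 0
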