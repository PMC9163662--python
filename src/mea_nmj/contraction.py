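"""Myotube contraction quantification for the α-bungarotoxin blockade assay.

α-bungarotoxin irreversibly blocks postsynaptic nicotinic acetylcholine
receptors, so contractions driven through a functional neuromuscular
junction should stop after treatment while sham-treated myotubes keep
contracting.  The assay takes an event list per myotube (pre/post named
observation windows), applies the selection rule used to pick myotubes
the day before the experiment, counts contractions in 10-min windows,
bins them into 30-s intervals, and classifies the response.

Partial contractions, when flagged in the input, are tallied separately
and never merged into full-contraction counts.
"""

from __future__ import annotations

import numpy as np

from .types import AssayResult, ContractionSeries

__all__ = [
    "passes_selection",
    "count_window",
    "count_partial",
    "bin_contractions",
    "percent_reduction",
    "classify_response",
    "run_assay",
]


def _full_times(series: ContractionSeries, window_name: str) -> np.ndarray:
    w = series.window(window_name)
    if w.partial is None:
        return w.times
    return w.times[~w.partial]


def passes_selection(
    series: ContractionSeries,
    window_name: str = "pre",
    obs_minutes: int = 5,
) -> bool:
    """Selection rule: more than 1 contraction/min over ``obs_minutes``,
    with at least 1 contraction in each minute.

    "More than 1 per minute" is a strict mean (> ``obs_minutes`` events in
    total); both clauses must hold.  Raises ``ValueError`` when the window
    is shorter than ``obs_minutes``.
    """
    w = series.window(window_name)
    if w.duration_s < obs_minutes * 60:
        raise ValueError(
            f"window {window_name!r} ({w.duration_s} s) is shorter than the "
            f"{obs_minutes}-min observation required by the selection rule"
        )
    t = _full_times(series, window_name)
    t = t[t < obs_minutes * 60]
    per_minute = np.histogram(t, bins=obs_minutes, range=(0, obs_minutes * 60))[0]
    return t.size > obs_minutes and bool((per_minute >= 1).all())


def count_window(
    series: ContractionSeries, window_name: str, length_s: float = 600.0
) -> int:
    """Number of full contractions in ``[0, length_s)`` of the window."""
    t = _full_times(series, window_name)
    return int(np.count_nonzero(t < length_s))


def count_partial(
    series: ContractionSeries, window_name: str, length_s: float = 600.0
) -> int:
    """Separate tally of flagged partial contractions in ``[0, length_s)``."""
    w = series.window(window_name)
    if w.partial is None:
        return 0
    t = w.times[w.partial]
    return int(np.count_nonzero(t < length_s))


def bin_contractions(
    series: ContractionSeries,
    window_name: str,
    bin_s: float = 30.0,
    length_s: float | None = None,
) -> np.ndarray:
    """Full-contraction counts per half-open ``bin_s`` interval.

    The vector covers ``[0, length_s)`` (default: the window duration) and
    sums to :func:`count_window` over the same span.
    """
    if bin_s <= 0:
        raise ValueError(f"bin_s must be > 0, got {bin_s}")
    w = series.window(window_name)
    span = w.duration_s if length_s is None else length_s
    n_bins = int(np.ceil(span / bin_s - 1e-9))
    t = _full_times(series, window_name)
    t = t[t < span]
    idx = np.minimum((t / bin_s).astype(np.int64), n_bins - 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    np.add.at(counts, idx, 1)
    return counts


def percent_reduction(pre_count: int, post_count: int) -> float:
    """Percent reduction of contraction count, ``100 * (1 - post/pre)``.

    Negative when activity increases; requires ``pre_count > 0``.
    """
    if pre_count <= 0:
        raise ValueError(
            f"percent reduction undefined for pre_count={pre_count}; "
            "needs at least one pre-treatment contraction"
        )
    return 100.0 * (1.0 - post_count / pre_count)


def classify_response(
    pre_count: int,
    post_count: int,
    *,
    abolish_requires_zero: bool = True,
    change_tol: float = 10.0,
) -> str:
    """Classify a myotube's response to treatment.

    ``abolished`` requires a post count of exactly zero (when
    ``abolish_requires_zero``); otherwise the percent reduction is compared
    with ``change_tol`` (percent): ``reduced`` above it, ``increased``
    below its negative, ``unchanged`` in between.
    """
    if post_count == 0 and abolish_requires_zero:
        return "abolished"
    r = percent_reduction(pre_count, post_count)
    if r == 100.0:
        return "abolished"
    if r > change_tol:
        return "reduced"
    if r < -change_tol:
        return "increased"
    return "unchanged"


def run_assay(
    series: ContractionSeries,
    *,
    window_length_s: float = 600.0,
    bin_s: float = 30.0,
    change_tol: float = 10.0,
) -> AssayResult:
    """Full per-myotube assay: counts, binned time courses, classification."""
    pre = count_window(series, "pre", window_length_s)
    post = count_window(series, "post", window_length_s)
    return AssayResult(
        myotube_id=series.myotube_id,
        group=series.group,
        pre_count=pre,
        post_count=post,
        percent_reduction=percent_reduction(pre, post),
        response_class=classify_response(pre, post, change_tol=change_tol),
        binned_pre=bin_contractions(series, "pre", bin_s, window_length_s),
        binned_post=bin_contractions(series, "post", bin_s, window_length_s),
        pre_partial_count=count_partial(series, "pre", window_length_s),
        post_partial_count=count_partial(series, "post", window_length_s),
    )
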