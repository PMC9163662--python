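"""Synthetic-data generators with known ground truth.

Three generators emulate the data the analysis pipeline consumes:

* :func:`gen_raw_recording` — Gaussian-noise extracellular traces with a
  biphasic spike waveform embedded at scheduled times (for testing the
  filter + threshold detector);
* :func:`gen_spike_trains` — multi-electrode Poisson spike trains with
  planted synchronized burst epochs (for testing network-burst detection);
* :func:`gen_contraction_series` — Poisson-like myotube contraction event
  series whose rate changes after an intervention (for testing the
  blockade assay).

Every generator is a pure function of its parameters and an integer seed,
and emits a :class:`~mea_nmj.types.GroundTruth` describing exactly what it
planted.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .types import (
    BurstSpec,
    ContractionSeries,
    ContractionWindow,
    GroundTruth,
    RawRecording,
    SpikeTrainSet,
)

__all__ = [
    "biphasic_waveform",
    "gen_raw_recording",
    "gen_spike_trains",
    "gen_contraction_series",
    "default_electrode_ids",
]


def default_electrode_ids(n: int = 60) -> list[str]:
    """Electrode labels ``E01 .. En`` for an n-electrode array."""
    width = max(2, len(str(n)))
    return [f"E{i + 1:0{width}d}" for i in range(n)]


def biphasic_waveform(
    fs: float, amplitude_uv: float = 50.0, total_ms: float = 1.5
) -> np.ndarray:
    """Canonical biphasic (negative-then-positive) spike template.

    One full sine cycle of ``total_ms`` duration whose negative phase
    leads, scaled so the negative peak reaches ``-amplitude_uv``.  The
    shape mimics a typical extracellular action potential; its energy sits
    near ``1 / total_ms`` kHz, well inside a 300–3,000 Hz passband.
    """
    n = max(2, int(round(total_ms * 1e-3 * fs)))
    t = np.arange(n) / n
    w = -np.sin(2 * np.pi * t)
    return amplitude_uv * w / np.max(np.abs(w))


def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    """Homogeneous Poisson event times on [t0, t1) via count + sorted uniforms."""
    span = t1 - t0
    if rate_hz <= 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * span)
    return t0 + np.sort(rng.uniform(0.0, span, size=n))


def gen_raw_recording(
    spike_schedule: Mapping[str, Sequence[float]],
    waveform: np.ndarray | None = None,
    *,
    amplitude_uv: float = 50.0,
    noise_sd: float = 5.0,
    fs: float = 10_000.0,
    duration: float = 240.0,
    seed: int = 0,
) -> tuple[RawRecording, GroundTruth]:
    """Generate noisy multichannel traces with spikes planted at known times.

    Parameters
    ----------
    spike_schedule
        Map electrode id -> iterable of spike times in seconds.  Each time
        marks where the waveform template *starts*.
    waveform
        Template samples in microvolts; defaults to
        :func:`biphasic_waveform` at ``amplitude_uv``.
    noise_sd
        Standard deviation of the i.i.d. Gaussian background noise (µV).
    seed
        Identical seed and arguments give bit-identical output.

    Returns
    -------
    (RawRecording, GroundTruth)
        The ground truth echoes the schedule (sorted) per electrode.

    Raises
    ------
    ValueError
        If a scheduled time falls outside ``[0, duration)`` (the message
        names the electrode and the offending time), or the waveform is
        longer than the recording.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if waveform is None:
        waveform = biphasic_waveform(fs, amplitude_uv)
    waveform = np.asarray(waveform, dtype=np.float64).ravel()
    n_samples = int(round(fs * duration))
    if waveform.size >= n_samples:
        raise ValueError(
            f"waveform ({waveform.size} samples) must be shorter than the "
            f"recording ({n_samples} samples)"
        )

    electrode_ids = list(spike_schedule)
    truth: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    samples = (
        rng.normal(0.0, noise_sd, size=(len(electrode_ids), n_samples))
        if noise_sd > 0
        else np.zeros((len(electrode_ids), n_samples))
    )
    for row, eid in enumerate(electrode_ids):
        times = np.sort(np.asarray(list(spike_schedule[eid]), dtype=np.float64))
        for t in times:
            if not 0 <= t < duration:
                raise ValueError(
                    f"electrode {eid!r}: scheduled spike at {t} s is outside "
                    f"[0, {duration}) s"
                )
            i0 = int(round(t * fs))
            i1 = min(i0 + waveform.size, n_samples)
            samples[row, i0:i1] += waveform[: i1 - i0]
        truth[eid] = times

    rec = RawRecording(electrode_ids=electrode_ids, fs=fs, samples=samples)
    gt = GroundTruth(
        seed=seed,
        true_spike_times=truth,
        true_rates={"noise_sd_uv": noise_sd, "amplitude_uv": amplitude_uv},
    )
    return rec, gt


def gen_spike_trains(
    n_electrodes: int,
    background_rate: float,
    bursts: Sequence[BurstSpec] = (),
    *,
    duration: float = 240.0,
    seed: int = 0,
    electrode_ids: Sequence[str] | None = None,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Poisson spike trains with planted synchronized network-burst epochs.

    Each electrode fires as a homogeneous Poisson process at
    ``background_rate`` Hz.  Inside each :class:`BurstSpec` epoch a freshly
    drawn ``participation`` fraction of electrodes fires at
    ``background_rate * rate_multiplier`` instead (implemented by
    superposing an extra Poisson process at rate ``background_rate *
    (rate_multiplier - 1)`` over the epoch, which is exactly the target
    inhomogeneous Poisson process).

    Raises
    ------
    ValueError
        If burst epochs overlap or extend outside ``[0, duration]``, or
        ``background_rate`` is negative.
    """
    if background_rate < 0:
        raise ValueError(f"background_rate must be >= 0, got {background_rate}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    ordered = sorted(bursts, key=lambda b: b.start_s)
    for spec in ordered:
        if spec.end_s > duration:
            raise ValueError(
                f"burst epoch [{spec.start_s}, {spec.end_s}) extends past "
                f"duration {duration} s"
            )
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s:
            raise ValueError(
                f"burst epochs overlap: [{a.start_s}, {a.end_s}) and "
                f"[{b.start_s}, {b.end_s})"
            )

    ids = list(electrode_ids) if electrode_ids is not None else default_electrode_ids(n_electrodes)
    if len(ids) != n_electrodes:
        raise ValueError("electrode_ids length must equal n_electrodes")

    rng = np.random.default_rng(seed)
    trains: dict[str, list[np.ndarray]] = {
        eid: [_poisson_times(rng, background_rate, 0.0, duration)] for eid in ids
    }
    epochs: list[tuple[float, float, frozenset[str]]] = []
    for spec in ordered:
        k = max(1, int(round(spec.participation * n_electrodes)))
        members = frozenset(rng.choice(ids, size=k, replace=False).tolist())
        extra_rate = background_rate * (spec.rate_multiplier - 1.0)
        for eid in ids:
            if eid in members:
                trains[eid].append(
                    _poisson_times(rng, extra_rate, spec.start_s, spec.end_s)
                )
        epochs.append((spec.start_s, spec.end_s, members))

    merged = {eid: np.sort(np.concatenate(parts)) for eid, parts in trains.items()}
    sts = SpikeTrainSet(trains=merged, duration=duration)
    gt = GroundTruth(
        seed=seed,
        true_burst_epochs=epochs,
        true_rates={"background_rate_hz": background_rate},
    )
    return sts, gt


def _thin_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Drop events closer than ``refractory`` to the previous *kept* event."""
    if refractory <= 0 or times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def gen_contraction_series(
    rate_pre: float,
    rate_post: float,
    *,
    pre_window: float = 600.0,
    post_window: float = 600.0,
    refractory: float = 1.0,
    seed: int = 0,
    myotube_id: str = "M1",
    group: str = "treated",
) -> tuple[ContractionSeries, GroundTruth]:
    """Contraction event series with a rate change after an intervention.

    Rates are in events per *minute* (the unit the assay reports).  Events
    are homogeneous Poisson within each window, thinned by a refractory
    period: a myotube cannot re-contract instantaneously, so events closer
    than ``refractory`` seconds to the previous kept event are dropped.

    Raises
    ------
    ValueError
        For negative rates, windows or refractory.
    """
    if rate_pre < 0 or rate_post < 0:
        raise ValueError("rates must be >= 0")
    if pre_window <= 0 or post_window <= 0:
        raise ValueError("window durations must be positive")
    if refractory < 0:
        raise ValueError(f"refractory must be >= 0, got {refractory}")

    rng = np.random.default_rng(seed)
    pre = _thin_refractory(_poisson_times(rng, rate_pre / 60.0, 0.0, pre_window), refractory)
    post = _thin_refractory(_poisson_times(rng, rate_post / 60.0, 0.0, post_window), refractory)
    series = ContractionSeries(
        myotube_id=myotube_id,
        windows={
            "pre": ContractionWindow(duration_s=pre_window, times=pre),
            "post": ContractionWindow(duration_s=post_window, times=post),
        },
        group=group,
    )
    gt = GroundTruth(
        seed=seed,
        true_rates={
            "rate_pre_per_min": rate_pre,
            "rate_post_per_min": rate_post,
            "refractory_s": refractory,
        },
    )
    return series, gt
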