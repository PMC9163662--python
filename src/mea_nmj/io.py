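"""File readers and writers for recordings, spike trains and event series.

Formats:

* raw recordings — HDF5 with datasets ``/signal`` (float32, electrodes x
  samples), ``/fs`` (scalar Hz) and ``/electrode_ids``; tiny fixtures may
  instead use a wide CSV whose first column is ``time_s`` and remaining
  columns are one electrode each;
* spike trains — CSV with columns ``electrode_id, time_s``;
* contraction series — CSV with columns ``myotube_id, time_s, condition``
  plus optional ``group`` and ``partial`` columns;
* ground truth and settings — sidecar JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    ContractionSeries,
    ContractionWindow,
    GroundTruth,
    RawRecording,
    SpikeTrainSet,
)

__all__ = [
    "write_raw",
    "read_raw",
    "write_spikes",
    "read_spikes",
    "write_events",
    "read_events",
    "write_ground_truth",
    "write_json",
]

log = logging.getLogger(__name__)


# -- raw recordings ---------------------------------------------------------

def write_raw(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording to HDF5 (``.h5``/``.hdf5``) or wide CSV."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=rec.samples.astype(np.float32))
            f.create_dataset("fs", data=float(rec.fs))
            f.create_dataset(
                "electrode_ids",
                data=np.array(rec.electrode_ids, dtype=h5py.string_dtype()),
            )
    else:
        t = np.arange(rec.n_samples) / rec.fs
        df = pd.DataFrame({"time_s": t})
        for eid, row in zip(rec.electrode_ids, rec.samples):
            df[eid] = row
        df.to_csv(path, index=False)
    return path


def read_raw(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_raw`.

    Raises ``ValueError`` naming the missing dataset or offending channel
    on malformed input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "fs" not in f:
                raise ValueError(f"{path}: missing /fs dataset")
            if "signal" not in f:
                raise ValueError(f"{path}: missing /signal dataset")
            fs = float(f["fs"][()])
            signal = np.asarray(f["signal"], dtype=np.float64)
            if "electrode_ids" in f:
                ids = [
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["electrode_ids"][()]
                ]
            else:
                ids = [f"E{i + 1:02d}" for i in range(signal.shape[0])]
        if signal.ndim != 2 or len(ids) != signal.shape[0]:
            raise ValueError(
                f"{path}: /signal shape {signal.shape} does not match "
                f"{len(ids)} electrode ids"
            )
        rec = RawRecording(electrode_ids=ids, fs=fs, samples=signal)
    else:
        df = pd.read_csv(path)
        if df.columns[0] != "time_s":
            raise ValueError(f"{path}: first CSV column must be time_s")
        na_cols = [c for c in df.columns[1:] if df[c].isna().any()]
        if na_cols:
            raise ValueError(
                f"{path}: channel {na_cols[0]!r} has missing samples "
                "(unequal channel lengths?)"
            )
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"{path}: need at least 2 samples to infer fs")
        fs = 1.0 / float(np.median(np.diff(t)))
        ids = [str(c) for c in df.columns[1:]]
        rec = RawRecording(
            electrode_ids=ids, fs=fs, samples=df[df.columns[1:]].to_numpy().T
        )
    log.info("read %s: %d electrodes at %g Hz, %.3f s", path, rec.n_electrodes, rec.fs, rec.duration)
    return rec


# -- spike trains -----------------------------------------------------------

def write_spikes(sts: SpikeTrainSet, path: str | Path, settings: dict | None = None) -> Path:
    """Write spike trains as CSV (electrode_id, time_s); optional settings
    sidecar JSON next to it."""
    path = Path(path)
    rows = [
        (eid, t)
        for eid in sts.electrode_ids
        for t in sts.trains[eid]
    ]
    df = pd.DataFrame(rows, columns=["electrode_id", "time_s"])
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "duration_s": sts.duration,
        "fs_hz": sts.fs,
        "div": sts.div,
        "threshold_sd": sts.threshold_sd,
        "electrode_ids": sts.electrode_ids,
    }
    if settings:
        meta["settings"] = settings
    write_json(meta, path.with_suffix(path.suffix + ".json"))
    return path


def read_spikes(
    path: str | Path,
    duration: float | None = None,
    div: int | None = None,
) -> SpikeTrainSet:
    """Read a spike-train CSV; the sidecar JSON supplies metadata when present.

    Unsorted rows are sorted with a warning; duplicate (electrode, time)
    rows are dropped with a logged count; negative times are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"electrode_id", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    if (df["time_s"] < 0).any():
        bad = df.loc[df["time_s"] < 0, "time_s"].iloc[0]
        raise ValueError(f"{path}: negative spike time {bad}")

    meta_path = path.with_suffix(path.suffix + ".json")
    fs = None
    electrode_ids = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        duration = duration if duration is not None else meta.get("duration_s")
        div = div if div is not None else meta.get("div")
        fs = meta.get("fs_hz")
        electrode_ids = meta.get("electrode_ids")

    n0 = len(df)
    df = df.drop_duplicates(subset=["electrode_id", "time_s"])
    if len(df) < n0:
        log.info("%s: dropped %d duplicate rows", path, n0 - len(df))
    if not df["time_s"].is_monotonic_increasing:
        log.warning("%s: unsorted spike times; sorting", path)

    if duration is None:
        duration = float(df["time_s"].max()) if len(df) else 1.0
    trains = {
        str(eid): np.sort(g["time_s"].to_numpy(dtype=np.float64))
        for eid, g in df.groupby("electrode_id", sort=True)
    }
    for eid in electrode_ids or []:
        trains.setdefault(str(eid), np.empty(0))
    return SpikeTrainSet(trains=trains, duration=float(duration), fs=fs, div=div)


# -- contraction series -----------------------------------------------------

def write_events(series_list: list[ContractionSeries] | ContractionSeries, path: str | Path) -> Path:
    """Write contraction series as CSV (myotube_id, time_s, condition,
    group, partial).  A sidecar JSON records window durations."""
    if isinstance(series_list, ContractionSeries):
        series_list = [series_list]
    path = Path(path)
    rows = []
    meta: dict[str, dict] = {}
    for s in series_list:
        meta[s.myotube_id] = {
            "group": s.group,
            "windows": {name: w.duration_s for name, w in s.windows.items()},
        }
        for name, w in s.windows.items():
            partial = w.partial if w.partial is not None else np.zeros(w.times.size, bool)
            for t, p in zip(w.times, partial):
                rows.append((s.myotube_id, t, name, s.group, int(p)))
    pd.DataFrame(
        rows, columns=["myotube_id", "time_s", "condition", "group", "partial"]
    ).to_csv(path, index=False, float_format="%.6f")
    write_json(meta, path.with_suffix(path.suffix + ".json"))
    return path


def read_events(
    path: str | Path, window_durations: dict[str, float] | None = None
) -> list[ContractionSeries]:
    """Read contraction series from CSV written by :func:`write_events`.

    ``window_durations`` overrides the sidecar JSON (and is required when
    no sidecar exists).  Negative times are rejected; unsorted input is
    sorted with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"myotube_id", "time_s", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    if len(df) and (df["time_s"] < 0).any():
        raise ValueError(f"{path}: negative event time")
    if len(df) and not df["time_s"].is_monotonic_increasing:
        log.warning("%s: unsorted event times; sorting", path)

    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    out: list[ContractionSeries] = []
    myotube_ids = list(dict.fromkeys(df["myotube_id"].astype(str))) or list(meta)
    for mid in myotube_ids:
        sub = df[df["myotube_id"].astype(str) == mid]
        m = meta.get(mid, {})
        durations = dict(m.get("windows", {}))
        if window_durations:
            durations.update(window_durations)
        if not durations:
            raise ValueError(
                f"{path}: no window durations for myotube {mid!r}; pass "
                "window_durations or provide the sidecar JSON"
            )
        windows = {}
        for name, dur in durations.items():
            wsub = sub[sub["condition"] == name]
            times = np.sort(wsub["time_s"].to_numpy(dtype=np.float64))
            partial = None
            if "partial" in wsub.columns and len(wsub):
                partial = (
                    wsub.sort_values("time_s")["partial"].to_numpy().astype(bool)
                )
            windows[name] = ContractionWindow(duration_s=float(dur), times=times, partial=partial)
        group = m.get("group")
        if group is None and "group" in sub.columns and len(sub):
            group = str(sub["group"].iloc[0])
        out.append(ContractionSeries(myotube_id=mid, windows=windows, group=group or "treated"))
    return out


# -- sidecars ---------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")
    return path


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Ground truth as sidecar JSON for recovery scoring."""
    data = {
        "seed": gt.seed,
        "true_rates": gt.true_rates,
        "true_burst_epochs": [
            {"start_s": s, "end_s": e, "electrodes": sorted(m)}
            for s, e, m in gt.true_burst_epochs
        ],
    }
    if gt.true_spike_times is not None:
        data["true_spike_times"] = {k: v for k, v in gt.true_spike_times.items()}
    return write_json(data, path)
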