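"""Pipeline configuration with validated, reproducible defaults.

The defaults are the analysis settings of the reference protocol: 300–
3,000 Hz 4th-order Butterworth bandpass, 7 SD detection threshold, 50 ms
burst-histogram bins with a mean + 5 SD threshold and 20% participation
pruning, 10-min assay windows with 30-s intervals.  Unknown keys and
out-of-range values are rejected with a message naming the parameter.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


def _check(name: str, value, lo=None, hi=None, strict_lo=False):
    if lo is not None and (value <= lo if strict_lo else value < lo):
        op = ">" if strict_lo else ">="
        raise ValueError(f"config parameter {name}={value} out of range (must be {op} {lo})")
    if hi is not None and value > hi:
        raise ValueError(f"config parameter {name}={value} out of range (must be <= {hi})")


@dataclass
class PipelineConfig:
    """All tunables of the simulate → detect → analyze → assay pipeline."""

    # filter + detection
    filter_order: int = 4
    filter_low_hz: float = 300.0
    filter_high_hz: float = 3_000.0
    zero_phase: bool = True
    detect_threshold_sd: float = 7.0
    detect_dead_time_s: float = 1e-3
    detect_polarity: str = "both"
    # burst analysis
    burst_bin_s: float = 0.05
    burst_threshold_sd: float = 5.0
    burst_min_participation: float = 0.20
    active_min_rate_hz: float = 0.1
    exclude_min_rate_hz: float = 0.05
    # assay
    assay_window_s: float = 600.0
    assay_bin_s: float = 30.0
    assay_change_tol_pct: float = 10.0
    # simulation (used when no input files are given)
    sim_n_electrodes: int = 60
    sim_duration_s: float = 240.0
    sim_fs_hz: float = 10_000.0
    sim_noise_sd_uv: float = 5.0
    sim_amplitude_uv: float = 50.0
    sim_background_rate_hz: float = 2.0
    sim_rate_pre_per_min: float = 12.4
    sim_rate_post_per_min: float = 1.1
    seed: int = 0
    # metadata / paths
    div: int | None = None
    raw_path: str | None = None
    spikes_path: str | None = None
    events_path: str | None = None
    out_dir: str = "out"

    def __post_init__(self) -> None:
        _check("filter_order", self.filter_order, lo=1)
        _check("filter_low_hz", self.filter_low_hz, lo=0, strict_lo=True)
        if self.filter_high_hz <= self.filter_low_hz:
            raise ValueError(
                "config parameter filter_high_hz must exceed filter_low_hz "
                f"({self.filter_high_hz} <= {self.filter_low_hz})"
            )
        _check("detect_threshold_sd", self.detect_threshold_sd, lo=0, strict_lo=True)
        _check("detect_dead_time_s", self.detect_dead_time_s, lo=0)
        if self.detect_polarity not in ("both", "negative"):
            raise ValueError(
                f"config parameter detect_polarity must be 'both' or 'negative', "
                f"got {self.detect_polarity!r}"
            )
        _check("burst_bin_s", self.burst_bin_s, lo=0, strict_lo=True)
        _check("burst_threshold_sd", self.burst_threshold_sd, lo=0, strict_lo=True)
        _check("burst_min_participation", self.burst_min_participation, lo=0, hi=1)
        _check("active_min_rate_hz", self.active_min_rate_hz, lo=0)
        _check("exclude_min_rate_hz", self.exclude_min_rate_hz, lo=0)
        _check("assay_window_s", self.assay_window_s, lo=0, strict_lo=True)
        _check("assay_bin_s", self.assay_bin_s, lo=0, strict_lo=True)
        _check("sim_n_electrodes", self.sim_n_electrodes, lo=1)
        _check("sim_duration_s", self.sim_duration_s, lo=0, strict_lo=True)
        _check("sim_fs_hz", self.sim_fs_hz, lo=0, strict_lo=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config parameter(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives the default profile."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)
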