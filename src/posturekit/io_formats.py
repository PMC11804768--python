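"""Tabular I/O and run configuration.

All time series travel as CSV with a header row, comma separator and '.'
decimal mark; parsing is column-name based so column order never matters.
Units are fixed at the boundary: newtons, newton-metres, centimetres,
seconds.  Readers convert nothing.

Channel layouts
---------------
corner_board : ``t, tl, tr, bl, br``  (four vertical corner forces, N)
wrench_plate : ``t, fx, fy, fz, mx, my, mz``  (forces N, moments N*m)
COP files    : ``t_s, cop_ml_cm, cop_ap_cm``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cop_compute import CopTrajectory
from .errors import ConfigError, DataError, FormatError

__all__ = [
    "RawRecording",
    "RunConfig",
    "DEVICE_CHANNELS",
    "read_recording",
    "write_recording",
    "read_cop",
    "write_cop",
    "load_config",
]

log = logging.getLogger("posturekit.io")

DEVICE_CHANNELS = {
    "corner_board": ("tl", "tr", "bl", "br"),
    "wrench_plate": ("fx", "fy", "fz", "mx", "my", "mz"),
}

DEVICE_NOMINAL_RATES = {"corner_board": 40.0, "wrench_plate": 100.0}


@dataclass
class RawRecording:
    """A timestamped multichannel force recording from one device."""

    device_tag: str
    nominal_rate: float
    timestamps: np.ndarray
    channels: dict

    def __post_init__(self) -> None:
        if self.device_tag not in DEVICE_CHANNELS:
            raise DataError(f"unknown device tag {self.device_tag!r}")
        if self.nominal_rate <= 0:
            raise DataError("nominal_rate must be positive")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        expected = DEVICE_CHANNELS[self.device_tag]
        missing = [c for c in expected if c not in self.channels]
        if missing:
            raise DataError(f"missing channel(s) for {self.device_tag}: {', '.join(missing)}")
        n = self.timestamps.size
        for name, series in self.channels.items():
            if series.size != n:
                raise DataError(
                    f"channel {name!r} length {series.size} != {n} timestamps"
                )
        if n >= 2:
            bad = np.flatnonzero(np.diff(self.timestamps) <= 0)
            if bad.size:
                raise DataError(
                    f"timestamps not strictly increasing at index {int(bad[0]) + 1}"
                )

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.nominal_rate

    def trimmed(self, start: int, length: int) -> "RawRecording":
        sl = slice(start, start + length)
        return RawRecording(
            self.device_tag,
            self.nominal_rate,
            self.timestamps[sl],
            {k: v[sl] for k, v in self.channels.items()},
        )

    def total_force(self) -> np.ndarray:
        """Total vertical force in N (corner sum, or fz for the wrench)."""
        if self.device_tag == "corner_board":
            return sum(self.channels[c] for c in DEVICE_CHANNELS["corner_board"])
        return self.channels["fz"]


@dataclass
class RunConfig:
    """All tunable constants of the processing pipeline.

    Defaults follow common posturography practice for dual-device balance
    board validation: 10 Hz low-pass cutoff, design order 4 applied
    forward and backward, a 20 Hz common analysis rate, 20 s bipedal and
    15 s unipedal segments.
    """

    cutoff_hz: float = 10.0
    filter_order: int = 4
    common_rate_hz: float = 20.0
    bipedal_segment_s: float = 20.0
    unipedal_segment_s: float = 15.0
    board_sensor_span_ml: float = 43.3   # cm between left/right sensor columns
    board_sensor_span_ap: float = 23.8   # cm between top/bottom sensor rows
    plate_top_offset_cm: float = 5.3     # plate origin -> board surface
    board_mass_kg: float = 3.9
    gravity: float = 9.81
    random_seed: int = 0
    force_floor_n: float = 50.0
    max_lag_s: float = 5.0
    stable_window_s: float = 2.0
    stable_tolerance: float = 0.05       # fraction of the series median
    psd_window_s: float = 5.0
    psd_overlap: float = 0.5
    icc_marginal_threshold: float = 0.01

    def __post_init__(self) -> None:
        positive = (
            "cutoff_hz", "common_rate_hz", "bipedal_segment_s", "unipedal_segment_s",
            "board_sensor_span_ml", "board_sensor_span_ap", "board_mass_kg",
            "gravity", "max_lag_s", "stable_window_s", "psd_window_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.filter_order <= 0 or self.filter_order % 2:
            raise ConfigError(f"filter_order must be a positive even integer, got {self.filter_order}")
        if self.plate_top_offset_cm < 0 or self.force_floor_n < 0:
            raise ConfigError("plate_top_offset_cm and force_floor_n must be non-negative")
        if not 0 <= self.psd_overlap < 1:
            raise ConfigError("psd_overlap must be in [0, 1)")
        for rate in DEVICE_NOMINAL_RATES.values():
            if self.common_rate_hz > rate:
                raise ConfigError(
                    f"common_rate_hz {self.common_rate_hz} exceeds a device nominal rate {rate}"
                )

    def segment_duration_s(self, task: str) -> float:
        if task == "bipedal":
            return self.bipedal_segment_s
        if task == "unipedal":
            return self.unipedal_segment_s
        raise ConfigError(f"unknown task {task!r}; expected 'bipedal' or 'unipedal'")


def read_recording(path, device_tag: str) -> RawRecording:
    """Read a device CSV into a validated :class:`RawRecording`.

    Rows containing NaN or infinite values are dropped with a logged count.
    """
    if device_tag not in DEVICE_CHANNELS:
        raise FormatError(f"unknown device tag {device_tag!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=",")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    expected = ("t",) + DEVICE_CHANNELS[device_tag]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    df = df[list(expected)].apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(df.to_numpy()).all(axis=1)
    n_bad = int((~finite).sum())
    if n_bad:
        log.warning("%s: dropped %d row(s) with NaN/inf values", path, n_bad)
        df = df.loc[finite]
    t = df["t"].to_numpy(dtype=float)
    if t.size >= 2:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise DataError(
                f"{path}: timestamps not strictly increasing at row index {int(bad[0]) + 1}"
            )
    channels = {c: df[c].to_numpy(dtype=float) for c in DEVICE_CHANNELS[device_tag]}
    return RawRecording(device_tag, DEVICE_NOMINAL_RATES[device_tag], t, channels)


def write_recording(path, rec: RawRecording) -> None:
    """Write a recording in the CSV dialect :func:`read_recording` accepts."""
    cols = {"t": rec.timestamps}
    cols.update({c: rec.channels[c] for c in DEVICE_CHANNELS[rec.device_tag]})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def write_cop(path, traj: CopTrajectory) -> None:
    """Write a COP trajectory as a three-column CSV (t_s, cop_ml_cm, cop_ap_cm)."""
    traj.require_finite()
    df = pd.DataFrame(
        {"t_s": traj.times, "cop_ml_cm": traj.ml, "cop_ap_cm": traj.ap}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_cop(path) -> CopTrajectory:
    """Read a COP CSV written by :func:`write_cop`; the rate is inferred from t_s."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in ("t_s", "cop_ml_cm", "cop_ap_cm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least 2 samples to infer the rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError(f"{path}: timestamps not strictly increasing")
    rate = 1.0 / float(np.median(dt))
    if abs(rate - round(rate)) < 1e-6 * rate:  # absorb float noise in written t_s
        rate = float(round(rate))
    return CopTrajectory(rate, df["cop_ml_cm"].to_numpy(float), df["cop_ap_cm"].to_numpy(float))


def load_config(path=None) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML key-value file.

    Missing keys take their defaults; unknown keys are an error so typos
    do not silently fall back to defaults.  ``load_config(None)`` returns
    the defaults.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
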