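"""Per-sensor linear calibration of the four-corner balance board.

The board is calibrated from two static recordings: one with nothing on
the board (zero load) and one with a known mass centred on it.  Each
corner sensor gets an affine map ``raw -> gain * (raw - offset)`` where
the offset is the zero-load channel mean and the gain maps the loaded
channel mean onto the expected quarter share of the known weight
(``known_mass * g / 4``, centred mass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cop_compute import CORNER_CHANNELS
from .errors import CalibrationError, DataError
from .io_formats import RawRecording

__all__ = ["CalibrationModel", "fit_linear_calibration", "apply_calibration"]


@dataclass
class CalibrationModel:
    """Affine per-channel calibration for the four corner sensors."""

    offsets: dict   # channel -> offset in raw units
    gains: dict     # channel -> N per raw unit
    known_mass_kg: float

    def __post_init__(self) -> None:
        for d, what in ((self.offsets, "offsets"), (self.gains, "gains")):
            if set(d) != set(CORNER_CHANNELS):
                raise DataError(f"{what} must cover exactly the channels {CORNER_CHANNELS}")
        for c, gain in self.gains.items():
            if not np.isfinite(gain) or gain == 0:
                raise DataError(f"gain for channel {c!r} must be finite and nonzero")

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(
            offsets={c: 0.0 for c in CORNER_CHANNELS},
            gains={c: 1.0 for c in CORNER_CHANNELS},
            known_mass_kg=0.0,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"offsets": self.offsets, "gains": self.gains,
             "known_mass_kg": self.known_mass_kg}, indent=2))

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(offsets=d["offsets"], gains=d["gains"],
                   known_mass_kg=d["known_mass_kg"])


def _require_corner(rec: RawRecording, what: str) -> None:
    if rec.device_tag != "corner_board":
        raise CalibrationError(f"{what} recording must come from the corner board")


def fit_linear_calibration(
    zero_rec: RawRecording,
    load_rec: RawRecording,
    known_mass_kg: float,
    g: float = 9.81,
) -> CalibrationModel:
    """Fit the two-point linear calibration.

    ``offset_c = mean(zero)``; ``gain_c = (m g / 4) / (mean(load) - offset_c)``.
    A channel whose loaded mean does not exceed its zero mean cannot be
    calibrated (the sensor saw no load) and raises :class:`CalibrationError`.
    """
    _require_corner(zero_rec, "zero-load")
    _require_corner(load_rec, "known-mass")
    if known_mass_kg <= 0:
        raise CalibrationError(f"known mass must be positive, got {known_mass_kg}")
    expected = known_mass_kg * g / 4.0
    offsets, gains = {}, {}
    for c in CORNER_CHANNELS:
        offset = float(np.mean(zero_rec.channels[c]))
        loaded = float(np.mean(load_rec.channels[c]))
        if loaded <= offset:
            raise CalibrationError(
                f"channel {c!r}: loaded mean {loaded:.6g} <= zero mean {offset:.6g}; "
                "sensor not loaded"
            )
        offsets[c] = offset
        gains[c] = expected / (loaded - offset)
    return CalibrationModel(offsets=offsets, gains=gains, known_mass_kg=known_mass_kg)


def apply_calibration(rec: RawRecording, cal: CalibrationModel) -> RawRecording:
    """Map every corner channel through its affine calibration; time untouched."""
    _require_corner(rec, "input")
    channels = {
        c: cal.gains[c] * (rec.channels[c] - cal.offsets[c]) for c in CORNER_CHANNELS
    }
    return RawRecording(rec.device_tag, rec.nominal_rate, rec.timestamps.copy(), channels)
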