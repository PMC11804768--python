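"""Center-of-pressure computation for both force-measuring devices.

Two routes to the same quantity:

* a four-corner-sensor balance board (index device): the COP is the
  force-weighted position of the four vertical loads;
* a six-component force/moment plate (reference device): the COP follows
  from the moment balance about the plate origin, corrected for the extra
  moment arm and dead weight introduced by the board stacked on top.

Axis convention throughout: ``ml`` = x, positive toward the subject's
right; ``ap`` = y, positive anterior; origin at the plate centre; COP in
centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError, UnloadedPlateError

__all__ = [
    "CopTrajectory",
    "cop_from_corner_forces",
    "cop_from_wrench",
    "corner_forces_from_cop",
]

#: Default minimum total vertical force (N) for a frame to count as loaded.
DEFAULT_FORCE_FLOOR_N = 50.0

CORNER_CHANNELS = ("tl", "tr", "bl", "br")
WRENCH_CHANNELS = ("fx", "fy", "fz", "mx", "my", "mz")


@dataclass
class CopTrajectory:
    """Uniformly sampled ML/AP center-of-pressure positions in cm."""

    rate: float
    ml: np.ndarray
    ap: np.ndarray

    def __post_init__(self) -> None:
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.ml.shape != self.ap.shape or self.ml.ndim != 1:
            raise DataError("ml and ap must be 1-D series of equal length")

    def __len__(self) -> int:
        return self.ml.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate

    def require_finite(self) -> None:
        if not (np.all(np.isfinite(self.ml)) and np.all(np.isfinite(self.ap))):
            raise DataError("COP trajectory contains non-finite values")

    def slice(self, start: int, length: int) -> "CopTrajectory":
        if start < 0 or length <= 0 or start + length > len(self):
            raise ParameterError(
                f"slice [{start}, {start + length}) outside trajectory of {len(self)} samples"
            )
        return CopTrajectory(self.rate, self.ml[start : start + length],
                             self.ap[start : start + length])

    def decimate(self, rate_out: float) -> "CopTrajectory":
        """Keep every k-th sample; requires an integer rate ratio.

        The caller is responsible for prior low-pass filtering.
        """
        ratio = self.rate / rate_out
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ParameterError(
                f"rate ratio {self.rate}/{rate_out} is not a positive integer"
            )
        k = int(round(ratio))
        return CopTrajectory(rate_out, self.ml[::k], self.ap[::k])


def _first_below(total: np.ndarray, floor: float) -> int | None:
    bad = np.flatnonzero(total <= floor)
    return int(bad[0]) if bad.size else None


def cop_from_corner_forces(
    channels: dict,
    rate: float,
    span_ml_cm: float,
    span_ap_cm: float,
    force_floor_n: float = DEFAULT_FORCE_FLOOR_N,
) -> CopTrajectory:
    """COP from four calibrated corner forces (N).

    With sensors at the corners of a ``span_ml_cm`` x ``span_ap_cm``
    rectangle and total force ``F = tl+tr+bl+br``::

        ml = (span_ml/2) * ((tr+br) - (tl+bl)) / F
        ap = (span_ap/2) * ((tl+tr) - (bl+br)) / F

    Parameters
    ----------
    channels:
        Mapping with keys ``tl, tr, bl, br`` (top/bottom = anterior/
        posterior, left/right = subject's left/right) of equal-length
        force series in newtons.
    """
    missing = [c for c in CORNER_CHANNELS if c not in channels]
    if missing:
        raise DataError(f"missing corner channel(s): {', '.join(missing)}")
    if span_ml_cm <= 0 or span_ap_cm <= 0:
        raise ParameterError("sensor spans must be positive")
    tl, tr, bl, br = (np.asarray(channels[c], dtype=float) for c in CORNER_CHANNELS)
    total = tl + tr + bl + br
    i = _first_below(total, force_floor_n)
    if i is not None:
        raise UnloadedPlateError(
            f"total vertical force {total[i]:.1f} N <= floor {force_floor_n:.1f} N "
            f"at sample {i}: plate unloaded"
        )
    ml = (span_ml_cm / 2.0) * ((tr + br) - (tl + bl)) / total
    ap = (span_ap_cm / 2.0) * ((tl + tr) - (bl + br)) / total
    return CopTrajectory(rate, ml, ap)


def cop_from_wrench(
    channels: dict,
    rate: float,
    top_offset_cm: float,
    added_mass_kg: float = 0.0,
    g: float = 9.81,
    force_floor_n: float = DEFAULT_FORCE_FLOOR_N,
) -> CopTrajectory:
    """COP from a six-component wrench with stacked-board corrections.

    The board on top of the plate adds (a) its own weight to ``fz`` and
    (b) a vertical offset ``d`` between the plate origin and the surface
    the subject actually stands on, which gives horizontal shear forces an
    extra moment arm.  With ``fz' = fz - added_mass_kg * g`` and ``d`` the
    top offset::

        ml = (-my - fx * d) / fz'
        ap = ( mx - fy * d) / fz'

    Moments are in N*m about the plate origin (right-handed frame, z up);
    the result is converted to cm.
    """
    missing = [c for c in WRENCH_CHANNELS if c not in channels]
    if missing:
        raise DataError(f"missing wrench channel(s): {', '.join(missing)}")
    fx, fy, fz, mx, my, _mz = (np.asarray(channels[c], dtype=float) for c in WRENCH_CHANNELS)
    d_m = top_offset_cm / 100.0
    fz_c = fz - added_mass_kg * g
    i = _first_below(fz_c, force_floor_n)
    if i is not None:
        raise UnloadedPlateError(
            f"weight-corrected vertical force {fz_c[i]:.1f} N <= floor "
            f"{force_floor_n:.1f} N at sample {i}"
        )
    ml = 100.0 * (-my - fx * d_m) / fz_c
    ap = 100.0 * (mx - fy * d_m) / fz_c
    return CopTrajectory(rate, ml, ap)


def corner_forces_from_cop(
    total_force: np.ndarray,
    ml_cm: np.ndarray,
    ap_cm: np.ndarray,
    span_ml_cm: float,
    span_ap_cm: float,
) -> dict:
    """Distribute a total vertical load onto four corner sensors.

    Bilinear load distribution: a point load at COP ``(x, y)`` on a plate
    supported at the corners ``(+-a, +-b)`` splits as
    ``F_corner = F (a -+ x)(b -+ y) / (4ab)``.  This is the exact inverse
    of :func:`cop_from_corner_forces` and is shared by the synthetic
    renderer and the alignment stage's virtual corner decomposition.
    """
    a = span_ml_cm / 2.0
    b = span_ap_cm / 2.0
    f = np.asarray(total_force, dtype=float)
    x = np.asarray(ml_cm, dtype=float)
    y = np.asarray(ap_cm, dtype=float)
    if np.any(np.abs(x) > a) or np.any(np.abs(y) > b):
        raise ParameterError("COP outside the sensor span; corner loads would be negative")
    return {
        "tl": f * (a - x) * (b + y) / (4 * a * b),
        "tr": f * (a + x) * (b + y) / (4 * a * b),
        "bl": f * (a - x) * (b - y) / (4 * a * b),
        "br": f * (a + x) * (b - y) / (4 * a * b),
    }
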