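"""The six classical COP sway parameters for one analysis segment.

* SD of ML and AP displacement (cm) — sample SD, n-1 denominator;
* mean velocity per axis (cm/s) — per-axis path over elapsed time;
* pathlength (cm) — total Euclidean distance travelled;
* 95% prediction ellipse area, PEA95 (cm^2) — area of the ellipse
  expected to contain 95% of future COP positions, from the 2x2 sample
  covariance with the small-sample F-based prediction factor.

Velocities and pathlength are computed at the segment's native rate; the
PEA is computed on the 20 Hz decimated signal, matching common practice
for dual-device comparison.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as spst

from .cop_compute import CopTrajectory
from .errors import DataError, ParameterError
from .io_formats import RunConfig
from .signal_pipeline import Segment

__all__ = [
    "SwayMetrics",
    "sd_displacement",
    "mean_velocity",
    "path_length",
    "prediction_ellipse_area_95",
    "prediction_ellipse_factor",
    "compute_all",
]


@dataclass(frozen=True)
class SwayMetrics:
    """The six COP parameters of one segment, in cm / cm/s / cm^2."""

    sd_ml_cm: float
    sd_ap_cm: float
    v_ml_cm_s: float
    v_ap_cm_s: float
    pathlength_cm: float
    pea95_cm2: float
    segment_rate_hz: float
    segment_duration_s: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _series(x, min_n: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise DataError(f"{name}: need a 1-D series of >= {min_n} samples, got {x.shape}")
    return x


def sd_displacement(series) -> float:
    """Sample SD (n-1 denominator) of a displacement series about its mean."""
    x = _series(series, 2, "sd_displacement")
    return float(np.std(x, ddof=1))


def mean_velocity(series, rate: float) -> float:
    """Mean absolute velocity along one axis: sum|dx| / ((n-1)/rate)."""
    x = _series(series, 2, "mean_velocity")
    if rate <= 0:
        raise ParameterError("rate must be positive")
    elapsed = (x.size - 1) / rate
    return float(np.sum(np.abs(np.diff(x))) / elapsed)


def path_length(ml, ap) -> float:
    """Total Euclidean distance travelled by the COP."""
    ml = _series(ml, 2, "path_length")
    ap = _series(ap, 2, "path_length")
    if ml.size != ap.size:
        raise DataError(f"axis length mismatch: {ml.size} vs {ap.size}")
    return float(np.sum(np.hypot(np.diff(ml), np.diff(ap))))


def prediction_ellipse_factor(n: int, coverage: float = 0.95) -> float:
    """Scaling factor c(n) of the bivariate prediction ellipse.

    ``area = pi * c(n) * sqrt(det S)`` with
    ``c(n) = ((n+1)/n) * (2(n-1)/(n-2)) * F_cov(2, n-2)``.
    As n grows, c(n) approaches the chi-square quantile
    ``chi2_cov(2)`` (5.9915 for 95% coverage).
    """
    if n < 4:
        raise ParameterError(f"prediction ellipse needs n >= 4, got {n}")
    return float(
        ((n + 1) / n) * (2 * (n - 1) / (n - 2)) * spst.f.ppf(coverage, 2, n - 2)
    )


def prediction_ellipse_area_95(ml, ap) -> float:
    """95% prediction ellipse area (cm^2) from the ML/AP sample covariance.

    A degenerate covariance (zero variance along some direction) yields
    area 0 with a warning rather than an error.
    """
    ml = _series(ml, 4, "prediction_ellipse_area_95")
    ap = _series(ap, 4, "prediction_ellipse_area_95")
    if ml.size != ap.size:
        raise DataError(f"axis length mismatch: {ml.size} vs {ap.size}")
    n = ml.size
    cov = np.cov(ml, ap, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0:
        warnings.warn("degenerate ellipse: singular ML/AP covariance; area 0",
                      stacklevel=2)
        return 0.0
    return float(np.pi * prediction_ellipse_factor(n) * np.sqrt(det))


def compute_all(traj: CopTrajectory, seg: Segment, cfg: RunConfig) -> SwayMetrics:
    """All six parameters on a segment of a COP trajectory.

    SDs, velocities and pathlength use the segment's native rate; the PEA
    is computed after decimation to ``cfg.common_rate_hz`` when the
    trajectory is sampled faster than that.
    """
    if abs(seg.rate - traj.rate) > 1e-9:
        raise ParameterError(f"segment rate {seg.rate} != trajectory rate {traj.rate}")
    window = traj.slice(seg.start_index, seg.length)
    if traj.rate > cfg.common_rate_hz:
        pea_window = window.decimate(cfg.common_rate_hz)
    else:
        pea_window = window
    return SwayMetrics(
        sd_ml_cm=sd_displacement(window.ml),
        sd_ap_cm=sd_displacement(window.ap),
        v_ml_cm_s=mean_velocity(window.ml, window.rate),
        v_ap_cm_s=mean_velocity(window.ap, window.rate),
        pathlength_cm=path_length(window.ml, window.ap),
        pea95_cm2=prediction_ellipse_area_95(pea_window.ml, pea_window.ap),
        segment_rate_hz=window.rate,
        segment_duration_s=seg.duration_s,
    )
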