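"""Power spectral densities of COP signals and group averaging.

Spectra are Welch estimates (Hann window, 5 s windows, 50% overlap, mean
removed per window, density scaling, cm^2/Hz) of the 20 Hz analysis-rate
COP signals.  Per-participant spectra are averaged bin-wise for
device-comparison plots: excess power of the index device above the
reference device at frequencies >= 2.5 Hz is the signature of broadband
sensor noise rather than postural adjustment, which in quiet standing
concentrates between 0 and 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, ParameterError

__all__ = ["PsdEstimate", "psd", "group_average"]


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided PSD on a uniform frequency grid (cm^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    n_segments_averaged: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.freqs.shape != self.power.shape:
            raise DataError("freqs and power must have equal shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise DataError("frequency grid must be increasing")
        if np.any(self.power < 0):
            raise DataError("power must be non-negative")

    def total_power(self) -> float:
        """Integral of the PSD over frequency (trapezoidal)."""
        return float(np.trapezoid(self.power, self.freqs))


def psd(series, rate: float, window_s: float = 5.0, overlap: float = 0.5) -> PsdEstimate:
    """Welch PSD of one COP series (cm input -> cm^2/Hz output)."""
    x = np.asarray(series, dtype=float)
    if rate <= 0 or window_s <= 0:
        raise ParameterError("rate and window_s must be positive")
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must be in [0, 1)")
    nperseg = int(round(window_s * rate))
    if x.size < nperseg:
        raise ParameterError(
            f"series of {x.size} samples shorter than one {nperseg}-sample window"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, power = sps.welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant", scaling="density",
    )
    step = nperseg - noverlap
    n_segments = 1 + (x.size - nperseg) // step
    return PsdEstimate(freqs=freqs, power=power, n_segments_averaged=n_segments)


def group_average(psds) -> PsdEstimate:
    """Bin-wise arithmetic mean of spectra sharing one frequency grid."""
    psds = list(psds)
    if not psds:
        raise DataError("cannot average an empty list of spectra")
    ref = psds[0].freqs
    for p in psds[1:]:
        if p.freqs.shape != ref.shape or not np.allclose(p.freqs, ref):
            raise DataError("frequency grid mismatch between spectra")
    power = np.mean([p.power for p in psds], axis=0)
    return PsdEstimate(
        freqs=ref.copy(), power=power,
        n_segments_averaged=sum(p.n_segments_averaged for p in psds),
    )
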