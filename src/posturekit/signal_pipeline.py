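"""Signal conditioning and dual-device synchronisation.

Processing order for a validation trial:

1. zero-phase low-pass filtering of every force channel (Butterworth,
   design order 4, applied forward and backward);
2. decimation of both devices to a common analysis rate (20 Hz);
3. lag estimation between the two devices by normalised cross-correlation
   of the bottom-left sensor signals at the common rate, then trimming at
   each native rate;
4. stable-onset detection on total vertical force and selection of the
   central 20 s (bipedal) / 15 s (unipedal) analysis segment;

plus sampling-interval jitter diagnostics (reported, never corrected:
series are treated as uniformly sampled at the nominal rate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .cop_compute import corner_forces_from_cop, cop_from_wrench
from .errors import AlignmentError, DataError, ParameterError, SegmentError
from .io_formats import RawRecording, RunConfig

__all__ = [
    "Segment",
    "JitterStats",
    "lowpass_zero_phase",
    "downsample",
    "estimate_lag",
    "align_recordings",
    "detect_stable_onset",
    "select_segment",
    "sampling_jitter",
    "filter_recording",
]

log = logging.getLogger("posturekit.pipeline")


@dataclass(frozen=True)
class Segment:
    """A contiguous analysis window within a uniformly sampled signal."""

    start_index: int
    length: int
    rate: float

    def __post_init__(self) -> None:
        if self.start_index < 0 or self.length <= 0 or self.rate <= 0:
            raise ParameterError(
                f"invalid segment (start={self.start_index}, length={self.length}, "
                f"rate={self.rate})"
            )

    @property
    def duration_s(self) -> float:
        return self.length / self.rate

    @property
    def stop_index(self) -> int:
        return self.start_index + self.length


@dataclass(frozen=True)
class JitterStats:
    """Sampling-interval variability of a group of recordings (ms)."""

    per_recording_sd_ms: tuple
    mean_ms: float
    ci95_low_ms: float
    ci95_high_ms: float


def lowpass_zero_phase(x, rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    The design order is applied in each direction, so the magnitude
    response is the square of the single-pass response (-6 dB at the
    cutoff) while the phase response is identically zero.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= rate / 2:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {rate / 2} Hz")
    if cutoff <= 0 or rate <= 0:
        raise ParameterError("rate and cutoff must be positive")
    if order <= 0 or order % 2:
        raise ParameterError(f"order must be a positive even integer, got {order}")
    if x.size <= 3 * order:
        raise ParameterError(f"series of {x.size} samples too short for order {order}")
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def downsample(x, rate_in: float, rate_out: float) -> np.ndarray:
    """Keep every (rate_in/rate_out)-th sample starting at index 0.

    The ratio must be an integer; the caller must have low-pass filtered
    below the output Nyquist beforehand.
    """
    x = np.asarray(x)
    ratio = rate_in / rate_out
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ParameterError(
            f"rate ratio {rate_in}/{rate_out} is not a positive integer"
        )
    return x[:: int(round(ratio))]


def estimate_lag(a, b, max_lag: int) -> int:
    """Lag (in samples) of series ``b`` relative to ``a``.

    Returns the lag ``L`` maximising the normalised cross-correlation of
    the mean-removed series, with the convention that a positive ``L``
    means ``b`` started ``L`` samples later than ``a`` (``b[t]`` matches
    ``a[t + L]``).  Ties are broken toward the smallest ``|L|``.  If the
    best match is a *negative* correlation the lag of the largest
    ``|correlation|`` is still returned, with a warning (likely a sign
    convention mismatch between the devices).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size <= 2 * max_lag or b.size <= 2 * max_lag:
        raise ParameterError(
            f"series too short ({a.size}, {b.size}) for max_lag {max_lag}"
        )
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)), 1.0)
    a = a - a.mean()
    b = b - b.mean()
    if a.std() <= 1e-9 * scale or b.std() <= 1e-9 * scale:
        raise AlignmentError("zero-variance input; cannot estimate lag")

    best_lag, best_corr = 0, 0.0
    for lag in sorted(range(-max_lag, max_lag + 1), key=abs):
        if lag >= 0:
            aa, bb = a[lag:], b[: b.size - lag if lag else b.size]
        else:
            aa, bb = a[: a.size + lag], b[-lag:]
        m = min(aa.size, bb.size)
        aa, bb = aa[:m], bb[:m]
        denom = np.linalg.norm(aa) * np.linalg.norm(bb)
        if denom == 0:
            continue
        corr = float(np.dot(aa, bb) / denom)
        if abs(corr) > abs(best_corr):
            best_lag, best_corr = lag, corr
    if best_corr < 0:
        warnings.warn(
            f"best alignment is anticorrelated (r = {best_corr:.3f} at lag {best_lag}); "
            "check device sign conventions",
            stacklevel=2,
        )
    return best_lag


def _matching_signal(rec: RawRecording, cfg: RunConfig) -> np.ndarray:
    """The bottom-left sensor signal used for dual-device matching.

    The corner board reports it directly; for the wrench plate a virtual
    bottom-left load is reconstructed from the wrench COP by the same
    bilinear corner decomposition the board obeys physically.
    """
    if rec.device_tag == "corner_board":
        return rec.channels["bl"]
    traj = cop_from_wrench(
        rec.channels, rec.nominal_rate, cfg.plate_top_offset_cm,
        added_mass_kg=cfg.board_mass_kg, g=cfg.gravity,
        force_floor_n=cfg.force_floor_n,
    )
    fz_corrected = rec.channels["fz"] - cfg.board_mass_kg * cfg.gravity
    ml = np.clip(traj.ml, -cfg.board_sensor_span_ml / 2, cfg.board_sensor_span_ml / 2)
    ap = np.clip(traj.ap, -cfg.board_sensor_span_ap / 2, cfg.board_sensor_span_ap / 2)
    corners = corner_forces_from_cop(
        fz_corrected, ml, ap, cfg.board_sensor_span_ml, cfg.board_sensor_span_ap
    )
    return corners["bl"]


def align_recordings(
    idx: RawRecording, ref: RawRecording, cfg: RunConfig
) -> tuple[RawRecording, RawRecording]:
    """Synchronise the index and reference recordings.

    The lag is estimated at the common rate on the (filtered, decimated)
    bottom-left signals, rescaled to each native rate by rounding, the
    later-starting device's head trimmed away, and both tails cut to the
    common duration.  Lags beyond ``cfg.max_lag_s`` raise
    :class:`AlignmentError`.
    """
    sigs = {}
    for name, rec in (("idx", idx), ("ref", ref)):
        s = _matching_signal(rec, cfg)
        s = lowpass_zero_phase(s, rec.nominal_rate, cfg.cutoff_hz, cfg.filter_order)
        sigs[name] = downsample(s, rec.nominal_rate, cfg.common_rate_hz)
    max_lag = int(round(cfg.max_lag_s * cfg.common_rate_hz))
    n_min = min(sigs["idx"].size, sigs["ref"].size)
    if n_min <= 2 * max_lag:
        max_lag = max(1, (n_min - 1) // 2)
    overlap_limit = min(idx.duration_s, ref.duration_s)
    lag = estimate_lag(sigs["idx"], sigs["ref"], max_lag)
    lag_s = lag / cfg.common_rate_hz
    if abs(lag_s) > cfg.max_lag_s:
        raise AlignmentError(f"estimated lag {lag_s:.2f} s exceeds {cfg.max_lag_s} s")
    if abs(lag_s) >= overlap_limit:
        raise AlignmentError(
            f"estimated lag {lag_s:.2f} s leaves no overlap between recordings"
        )
    log.info("alignment: lag %+d samples at %g Hz (%+.3f s)", lag, cfg.common_rate_hz, lag_s)

    # positive lag: ref started later -> drop the head of idx
    if lag >= 0:
        trim_idx = int(round(lag * idx.nominal_rate / cfg.common_rate_hz))
        trim_ref = 0
    else:
        trim_idx = 0
        trim_ref = int(round(-lag * ref.nominal_rate / cfg.common_rate_hz))
    idx_t = idx.trimmed(trim_idx, len(idx) - trim_idx)
    ref_t = ref.trimmed(trim_ref, len(ref) - trim_ref)

    common_s = min(idx_t.duration_s, ref_t.duration_s)
    n_idx = int(np.floor(common_s * idx_t.nominal_rate))
    n_ref = int(np.floor(common_s * ref_t.nominal_rate))
    if n_idx < 1 or n_ref < 1:
        raise AlignmentError("no overlapping samples after alignment")
    return idx_t.trimmed(0, n_idx), ref_t.trimmed(0, n_ref)


def detect_stable_onset(
    total_force, rate: float, window_s: float = 2.0, tolerance: float = 0.05
) -> int:
    """First index from which total force stays near the series median.

    "Near" means within ``tolerance`` (default +-5%) of the median for a
    continuous ``window_s`` (default 2 s).  Falls back to 0 with a warning
    if the condition is never met.
    """
    x = np.asarray(total_force, dtype=float)
    w = int(round(window_s * rate))
    if x.size <= w:
        raise ParameterError(
            f"series of {x.size} samples shorter than the {w}-sample stability window"
        )
    med = float(np.median(x))
    ok = np.abs(x - med) <= tolerance * abs(med)
    run = np.convolve(ok.astype(int), np.ones(w, dtype=int), mode="valid")
    hits = np.flatnonzero(run == w)
    if hits.size == 0:
        warnings.warn(
            "no stable 2 s window found; falling back to onset 0", stacklevel=2
        )
        return 0
    return int(hits[0])


def select_segment(
    traj_len: int, rate: float, task: str, onset: int, cfg: RunConfig
) -> Segment:
    """Central analysis window of the post-onset span.

    Bipedal tasks use ``cfg.bipedal_segment_s`` (20 s), unipedal tasks
    ``cfg.unipedal_segment_s`` (15 s).
    """
    duration = cfg.segment_duration_s(task)
    need = int(round(duration * rate))
    avail = traj_len - onset
    if avail < need:
        raise SegmentError(
            f"{task} segment needs {duration:g} s ({need} samples at {rate:g} Hz) "
            f"but only {avail / rate:g} s ({avail} samples) available after onset"
        )
    start = onset + (avail - need) // 2
    return Segment(start_index=start, length=need, rate=rate)


def sampling_jitter(timestamp_sets) -> JitterStats:
    """Per-recording SD of inter-sample intervals, with a group t-CI.

    Parameters
    ----------
    timestamp_sets:
        Iterable of timestamp arrays (seconds), one per recording; each
        needs at least 3 timestamps.  The group mean and its 95%
        t-interval are taken over the per-recording SDs (ms).
    """
    sds = []
    for i, t in enumerate(timestamp_sets):
        t = np.asarray(t, dtype=float)
        if t.size < 3:
            raise DataError(f"recording {i}: need >= 3 timestamps, got {t.size}")
        # population SD of the intervals (a descriptive statistic of the
        # recording itself, not an estimate from a sample)
        sds.append(float(np.std(np.diff(t) * 1000.0)))
    sds_arr = np.asarray(sds)
    mean = float(sds_arr.mean())
    if sds_arr.size >= 2 and sds_arr.std(ddof=1) > 0:
        half = float(
            spst.t.ppf(0.975, sds_arr.size - 1)
            * sds_arr.std(ddof=1) / np.sqrt(sds_arr.size)
        )
    else:
        half = 0.0
    return JitterStats(
        per_recording_sd_ms=tuple(sds),
        mean_ms=mean,
        ci95_low_ms=mean - half,
        ci95_high_ms=mean + half,
    )


def filter_recording(rec: RawRecording, cfg: RunConfig) -> RawRecording:
    """Low-pass every channel of a recording (timestamps untouched)."""
    channels = {
        name: lowpass_zero_phase(series, rec.nominal_rate, cfg.cutoff_hz, cfg.filter_order)
        for name, series in rec.channels.items()
    }
    return RawRecording(rec.device_tag, rec.nominal_rate, rec.timestamps.copy(), channels)
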