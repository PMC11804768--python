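"""Synthetic quiet-stance sway and dual-device force recordings.

Ground-truth COP sway is modelled per axis as a stationary
Ornstein-Uhlenbeck (OU) process — the simplest mean-reverting Gaussian
process whose power concentrates below ~1 Hz, where postural adjustments
in quiet standing live.  This is a statistical stand-in, not a
biomechanical model.

The renderer maps a truth trajectory onto the two devices:

* corner board (index device): subject weight split over the four corner
  sensors by the exact bilinear inverse of the corner-COP formula, plus
  per-channel Gaussian noise and an extra broadband medio-lateral noise
  term (high-passed white noise above a corner frequency, default
  2.5 Hz) injected antisymmetrically at sensor level;
* wrench plate (reference device): moments built from the same truth with
  the board's dead weight on fz, plus small channel noise.

A configurable inter-device start lag and Gaussian sampling-interval
jitter complete the picture.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import linalg as spla
from scipy import signal as sps

from .cop_compute import CopTrajectory, corner_forces_from_cop
from .errors import ParameterError
from .io_formats import RawRecording, RunConfig

__all__ = [
    "SwaySimConfig",
    "simulate_sway",
    "render_devices",
    "simulate_cohort",
    "CohortResult",
    "simulate_two_way_matrix",
    "sd_estimator_relvar",
    "solve_within_rel_sd",
    "truth_device_view",
]


@dataclass(frozen=True)
class SwaySimConfig:
    """Study conditions for one simulated stance trial.

    Defaults emulate a bipedal eyes-open quiet stance trial on a
    consumer balance board stacked on a laboratory plate: sway SDs of
    0.17 cm (ML) / 0.42 cm (AP), ~1 s mean-reversion time constants
    (spectral corner well below 1 Hz), a 79.4 kg subject, 40 / 100 Hz
    device rates, 1 ms timestamp jitter, and an index device whose ML
    channel carries broadband sensor noise above 2.5 Hz.
    """

    sd_ml_cm: float = 0.17
    sd_ap_cm: float = 0.42
    tau_ml_s: float = 1.0
    tau_ap_s: float = 1.0
    subject_mass_kg: float = 79.4
    duration_s: float = 30.0
    board_rate_hz: float = 40.0
    plate_rate_hz: float = 100.0
    master_rate_hz: float = 200.0
    device_lag_s: float = 0.0
    jitter_sd_ms: float = 1.0
    board_noise_sd_n: float = 0.5
    plate_noise_sd_n: float = 0.05
    board_ml_noise_sd_n: float = 2.0
    ml_noise_corner_hz: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_ml_cm, self.sd_ap_cm, self.jitter_sd_ms,
               self.board_noise_sd_n, self.plate_noise_sd_n,
               self.board_ml_noise_sd_n) < 0:
            raise ParameterError("noise and sway SDs must be >= 0")
        if min(self.tau_ml_s, self.tau_ap_s, self.duration_s,
               self.subject_mass_kg) <= 0:
            raise ParameterError("time constants, duration and mass must be positive")
        if self.device_lag_s < 0:
            raise ParameterError("device_lag_s must be >= 0")
        for rate in (self.board_rate_hz, self.plate_rate_hz):
            ratio = self.master_rate_hz / rate
            if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
                raise ParameterError(
                    f"master rate {self.master_rate_hz} must be an integer multiple "
                    f"of device rate {rate}"
                )
        # OU spectral corner 1/(2 pi tau) must sit well inside device bands
        for tau in (self.tau_ml_s, self.tau_ap_s):
            if 1.0 / (2 * np.pi * tau) > min(self.board_rate_hz, self.plate_rate_hz) / 4:
                raise ParameterError("OU bandwidth too high for the device rates")


def _ou_exact(n: int, dt: float, sigma: float, tau: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary OU sample path by exact discretisation."""
    if sigma == 0:
        return np.zeros(n)
    phi = np.exp(-dt / tau)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    eps = rng.standard_normal(n)
    x[0] = sigma * eps[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov_sd * eps[i]
    return x


def simulate_sway(cfg: SwaySimConfig, rng: np.random.Generator | None = None
                  ) -> CopTrajectory:
    """Ground-truth COP trajectory at the master rate.

    Covers ``duration_s + device_lag_s`` so the renderer can offset the
    two device streams against each other.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.master_rate_hz
    n = int(round((cfg.duration_s + cfg.device_lag_s) * cfg.master_rate_hz)) + 1
    ml = _ou_exact(n, dt, cfg.sd_ml_cm, cfg.tau_ml_s, rng)
    ap = _ou_exact(n, dt, cfg.sd_ap_cm, cfg.tau_ap_s, rng)
    return CopTrajectory(cfg.master_rate_hz, ml, ap)


def _jittered_timestamps(n: int, rate: float, jitter_sd_ms: float,
                         rng: np.random.Generator) -> np.ndarray:
    dt = np.full(n - 1, 1.0 / rate)
    if jitter_sd_ms > 0:
        dt = dt + rng.normal(0.0, jitter_sd_ms / 1000.0, size=n - 1)
        dt = np.maximum(dt, 0.1 / rate)  # keep strictly increasing
    return np.concatenate(([0.0], np.cumsum(dt)))


def _highpassed_noise(n: int, rate: float, sd: float, corner_hz: float,
                      rng: np.random.Generator) -> np.ndarray:
    """White noise high-passed above corner_hz, rescaled to the target SD."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = sps.butter(4, corner_hz, btype="high", fs=rate, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def render_devices(
    truth: CopTrajectory,
    cfg: SwaySimConfig,
    run_cfg: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RawRecording, RawRecording]:
    """Render a truth trajectory onto both devices.

    The board records from truth time 0; the plate starts
    ``device_lag_s`` later (it is then the later-starting recording), so
    the alignment stage should estimate a positive lag of
    ``device_lag_s * common_rate`` samples and trim the board's head.
    Returns ``(corner_board, wrench_plate)`` recordings; board channels
    are in calibrated newtons.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if run_cfg is None:
        run_cfg = RunConfig()
    if abs(truth.rate - cfg.master_rate_hz) > 1e-9:
        raise ParameterError("truth trajectory must be sampled at the master rate")
    needed = cfg.duration_s + cfg.device_lag_s
    if truth.duration_s + 1e-9 < needed:
        raise ParameterError(
            f"truth covers {truth.duration_s:.2f} s but {needed:.2f} s needed "
            "(duration + lag)"
        )
    w_subject = cfg.subject_mass_kg * run_cfg.gravity
    lag_master = int(round(cfg.device_lag_s * cfg.master_rate_hz))

    # --- corner board: records [0, duration + lag) ---
    step_b = int(round(cfg.master_rate_hz / cfg.board_rate_hz))
    n_board = int(np.floor((cfg.duration_s + cfg.device_lag_s) * cfg.board_rate_hz))
    ix = np.arange(n_board) * step_b
    board_f = np.full(n_board, w_subject)
    corners = corner_forces_from_cop(
        board_f, truth.ml[ix], truth.ap[ix],
        run_cfg.board_sensor_span_ml, run_cfg.board_sensor_span_ap,
    )
    if cfg.board_noise_sd_n > 0:
        for c in corners:
            corners[c] = corners[c] + rng.normal(0, cfg.board_noise_sd_n, n_board)
    ml_noise = _highpassed_noise(
        n_board, cfg.board_rate_hz, cfg.board_ml_noise_sd_n,
        cfg.ml_noise_corner_hz, rng,
    )
    corners["tr"] = corners["tr"] + ml_noise / 2
    corners["br"] = corners["br"] + ml_noise / 2
    corners["tl"] = corners["tl"] - ml_noise / 2
    corners["bl"] = corners["bl"] - ml_noise / 2
    board = RawRecording(
        "corner_board", cfg.board_rate_hz,
        _jittered_timestamps(n_board, cfg.board_rate_hz, cfg.jitter_sd_ms, rng),
        corners,
    )

    # --- wrench plate: records [lag, lag + duration) ---
    step_p = int(round(cfg.master_rate_hz / cfg.plate_rate_hz))
    n_plate = int(np.floor(cfg.duration_s * cfg.plate_rate_hz))
    jx = lag_master + np.arange(n_plate) * step_p
    ml_m = truth.ml[jx] / 100.0
    ap_m = truth.ap[jx] / 100.0
    board_weight = run_cfg.board_mass_kg * run_cfg.gravity
    channels = {
        "fx": np.zeros(n_plate),
        "fy": np.zeros(n_plate),
        "fz": np.full(n_plate, w_subject + board_weight),
        "mx": ap_m * w_subject,
        "my": -ml_m * w_subject,
        "mz": np.zeros(n_plate),
    }
    if cfg.plate_noise_sd_n > 0:
        for c in channels:
            channels[c] = channels[c] + rng.normal(0, cfg.plate_noise_sd_n, n_plate)
    plate = RawRecording(
        "wrench_plate", cfg.plate_rate_hz,
        _jittered_timestamps(n_plate, cfg.plate_rate_hz, cfg.jitter_sd_ms, rng),
        channels,
    )
    return board, plate


def truth_device_view(truth: CopTrajectory, device_rate: float) -> CopTrajectory:
    """The truth trajectory as an ideal device would sample it (decimation)."""
    return truth.decimate(device_rate)


# ---------------------------------------------------------------------------
# cohort simulation for reliability studies
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def sd_sampling_moments(tau_s: float, rate_hz: float, n: int) -> tuple[float, float]:
    """Mean and variance of the sample SD of a unit-variance OU segment.

    For a stationary Gaussian AR(1) series (the exactly discretised OU
    process) the sample variance is the quadratic form ``x'Ax`` with
    ``A = (I - 11'/n)/(n-1)``, so with C the Toeplitz autocovariance::

        E[s^2]   = tr(A C)          (< 1: autocorrelation biases s^2 down)
        Var[s^2] = 2 tr((A C)^2)

    and by the delta method ``Var[s] ~= Var[s^2] / (4 E[s^2])``.
    Returns ``(E[s^2], Var[s])``, both scale-free.
    """
    phi = np.exp(-1.0 / (rate_hz * tau_s))
    c = spla.toeplitz(phi ** np.arange(n))
    a = (np.eye(n) - 1.0 / n) / (n - 1)
    ac = a @ c
    q = float(np.trace(ac))
    var_s2 = float(2.0 * np.sum(ac * ac.T))
    return q, var_s2 / (4.0 * q)


def sd_estimator_relvar(tau_s: float, rate_hz: float, n: int) -> float:
    """Relative sampling variance of the segment-SD metric (delta method)."""
    return sd_sampling_moments(tau_s, rate_hz, n)[1]


def _derived_icc(b2: float, w2: float, q: float, v: float) -> float:
    """Population ICC of the realized segment-SD metric.

    With ``m_ij = theta0 (1 + u_i + e_ij) s_ij`` and the unit-SD estimator
    moments ``E[s^2] = q``, ``Var[s] = v`` (so ``E[s]^2 = q - v``):
    between-subject variance ``(q - v) b^2``; within-subject variance
    ``q w^2 + (1 + b^2) v``.
    """
    between = (q - v) * b2
    within = q * w2 + (1 + b2) * v
    return between / (between + within)


def solve_within_rel_sd(
    target_icc: float, between_rel_sd: float,
    tau_s: float, rate_hz: float, n: int,
) -> float:
    """Within-subject relative SD that yields a target ICC of the realized metric.

    The realized segment-SD metric carries three variance components:
    between-subject (b^2), within-subject session-to-session (w^2) and
    the SD-estimator sampling variance; inverts the expression in
    :func:`sd_sampling_moments` / ``_derived_icc`` for w.
    """
    if not 0 < target_icc < 1:
        raise ParameterError("target ICC must be in (0, 1)")
    b2 = between_rel_sd ** 2
    q, v = sd_sampling_moments(tau_s, rate_hz, n)
    w2 = ((q - v) * b2 * (1 - target_icc) / target_icc - (1 + b2) * v) / q
    if w2 < 0:
        raise ParameterError(
            f"target ICC {target_icc} unreachable: SD-estimator noise alone "
            f"(rel. var {v:.4g}) exceeds the allowed within-subject variance"
        )
    return float(np.sqrt(w2))


@dataclass(frozen=True)
class CohortResult:
    """Realized metric matrix and ground truth of a simulated cohort."""

    metric_values: np.ndarray     # n_subjects x k_sessions segment SDs (cm)
    true_sd_cm: np.ndarray        # the drawn per-trial stationary SDs
    derived_true_icc: float       # induced ICC of the realized metric
    between_rel_sd: float
    within_rel_sd: float


def simulate_cohort(
    n_subjects: int,
    k_sessions: int,
    cfg: SwaySimConfig | None = None,
    between_rel_sd: float = 0.35,
    within_rel_sd: float = 0.05,
    segment_s: float = 20.0,
    rng: np.random.Generator | None = None,
) -> CohortResult:
    """Simulate a two-session (or k-session) cohort with known true ICC.

    Each trial's ML stationary SD is drawn as
    ``sigma_ij = sd_ml_cm * (1 + u_i + e_ij)`` with subject effects
    ``u_i ~ N(0, between_rel_sd^2)`` and session effects
    ``e_ij ~ N(0, within_rel_sd^2)``; the metric is the sample SD of an
    OU segment (``segment_s`` at the board rate) simulated at that
    parameter.  ``derived_true_icc`` accounts for the SD-estimator
    sampling variance, so realized ICCs are directly comparable to it.
    """
    if cfg is None:
        cfg = SwaySimConfig()
    if n_subjects < 2 or k_sessions < 2:
        raise ParameterError(
            f"need >= 2 subjects and >= 2 sessions, got {n_subjects} x {k_sessions}"
        )
    if between_rel_sd < 0 or within_rel_sd < 0:
        raise ParameterError("variance components must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(segment_s * cfg.board_rate_hz))
    dt = 1.0 / cfg.board_rate_hz
    base = cfg.sd_ml_cm

    u = rng.normal(0, between_rel_sd, n_subjects)
    e = rng.normal(0, within_rel_sd, (n_subjects, k_sessions))
    sigma = base * np.clip(1.0 + u[:, None] + e, 0.05, None)

    phi = np.exp(-dt / cfg.tau_ml_s)
    innov = np.sqrt(1.0 - phi * phi)
    # vectorized OU over all trials at unit stationary SD
    eps = rng.standard_normal((n_subjects * k_sessions, n_samples))
    x = np.empty_like(eps)
    x[:, 0] = eps[:, 0]
    for t in range(1, n_samples):
        x[:, t] = phi * x[:, t - 1] + innov * eps[:, t]
    metric = x.std(axis=1, ddof=1).reshape(n_subjects, k_sessions) * sigma

    q, v = sd_sampling_moments(cfg.tau_ml_s, cfg.board_rate_hz, n_samples)
    icc_true = _derived_icc(between_rel_sd ** 2, within_rel_sd ** 2, q, v)
    return CohortResult(
        metric_values=metric, true_sd_cm=sigma, derived_true_icc=float(icc_true),
        between_rel_sd=between_rel_sd, within_rel_sd=within_rel_sd,
    )


def simulate_two_way_matrix(
    n: int, k: int,
    var_subject: float, var_session: float, var_error: float,
    rng: np.random.Generator,
    mean: float = 0.0,
) -> np.ndarray:
    """Draw one n x k matrix from the two-way random-effects model.

    ``y_ij = mean + r_i + c_j + e_ij`` with independent Gaussian effects;
    the population two-way absolute-agreement ICC is
    ``var_subject / (var_subject + var_session + var_error)``.
    """
    if n < 2 or k < 2:
        raise ParameterError(f"need n >= 2 and k >= 2, got {n} x {k}")
    if min(var_subject, var_session, var_error) < 0:
        raise ParameterError("variances must be non-negative")
    r = rng.normal(0, np.sqrt(var_subject), (n, 1))
    c = rng.normal(0, np.sqrt(var_session), (1, k))
    e = rng.normal(0, np.sqrt(var_error), (n, k))
    return mean + r + c + e
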