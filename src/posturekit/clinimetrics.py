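"""Reliability and agreement statistics for repeated measurements.

Implements the single-measure intraclass correlation family from explicit
ANOVA mean squares (one-way random ICC(1); two-way random absolute
agreement ICC(A,1); two-way consistency ICC(C,1)), with F tests and 95%
confidence intervals (exact F-based for ICC(1) and ICC(C,1), the
Satterthwaite approximation for ICC(A,1)), plus the derived clinimetrics:

* SEM = SD * sqrt(1 - ICC)  (standard error of measurement)
* MDC = SEM * 1.96 * sqrt(2)  (minimal detectable change, 95%)

and between-device agreement (absolute: reference - index; relative:
100 * (reference - index) / reference, %).

Notation: n subjects (rows) by k sessions or raters (columns); MSR =
between-rows, MSC = between-columns, MSE = two-way residual, MSW =
one-way within-rows mean square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spst

from .errors import DataError, DegenerateDataError, ParameterError

__all__ = [
    "MeasurementMatrix",
    "IccResult",
    "GateDecision",
    "ReliabilityResult",
    "ReliabilityReport",
    "AgreementReport",
    "anova_mean_squares",
    "icc",
    "sem_mdc",
    "agreement",
    "icc_discrepancy_gate",
    "reliability_report",
    "MDC_FACTOR",
]

#: MDC/SEM ratio: 1.96 * sqrt(2).
MDC_FACTOR = 1.96 * np.sqrt(2.0)

ICC_KINDS = ("oneway", "agreement", "consistency")


@dataclass
class MeasurementMatrix:
    """n subjects x k sessions/raters of one metric, complete cases only."""

    values: np.ndarray
    subject_ids: tuple = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D (subjects x sessions) array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise DataError(f"need >= 2 subjects and >= 2 sessions, got {n} x {k}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("values must be complete (use from_sessions to drop rows)")
        if not self.subject_ids:
            self.subject_ids = tuple(range(n))
        if len(self.subject_ids) != n:
            raise DataError("subject_ids length must match the number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_sessions(cls, *sessions, subject_ids=None) -> "MeasurementMatrix":
        """Stack per-session value vectors, dropping subjects with any missing cell."""
        cols = [np.asarray(s, dtype=float) for s in sessions]
        if len({c.size for c in cols}) != 1:
            raise DataError("all sessions must have the same number of subjects")
        values = np.column_stack(cols)
        complete = np.all(np.isfinite(values), axis=1)
        n_dropped = int((~complete).sum())
        ids = tuple(subject_ids) if subject_ids is not None else tuple(range(values.shape[0]))
        ids = tuple(i for i, ok in zip(ids, complete) if ok)
        return cls(values=values[complete], subject_ids=ids, n_dropped=n_dropped)


@dataclass(frozen=True)
class IccResult:
    """A single-measure ICC with its F test and 95% CI."""

    kind: str
    estimate: float
    ci95_low: float
    ci95_high: float
    f_value: float
    df1: float
    df2: float
    p_value: float


@dataclass(frozen=True)
class GateDecision:
    """Which ICC form(s) to report, based on how much the three forms differ."""

    report_oneway_only: bool
    max_pairwise_diff: float
    flag: str


@dataclass(frozen=True)
class AgreementReport:
    """Between-device agreement on paired per-subject values."""

    absolute_mean: float
    absolute_sd: float
    relative_mean_pct: float
    relative_sd_pct: float
    n: int
    n_relative_excluded: int


@dataclass(frozen=True)
class ReliabilityResult:
    """Full test-retest summary for one metric."""

    icc_oneway: IccResult
    icc_agreement: IccResult
    icc_consistency: IccResult
    gate: GateDecision
    pooled_sd: float
    sem: float
    mdc: float
    sd_source: str


#: mapping metric name -> ReliabilityResult, as produced by reliability_report
ReliabilityReport = dict


def anova_mean_squares(m: MeasurementMatrix) -> dict:
    """One- and two-way ANOVA mean squares by explicit sums of squares.

    Returns MSR (rows), MSW (one-way within rows), MSC (columns), MSE
    (two-way residual), plus n and k.  Zero total variance sets the
    ``degenerate`` flag (every MS is then 0).
    """
    x = m.values
    n, k = m.n, m.k
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(np.sum((x - grand) ** 2))
    ss_rows = float(k * np.sum((row_means - grand) ** 2))
    ss_cols = float(n * np.sum((col_means - grand) ** 2))
    ss_within = ss_total - ss_rows
    ss_err = ss_total - ss_rows - ss_cols
    return {
        "MSR": ss_rows / (n - 1),
        "MSW": ss_within / (n * (k - 1)),
        "MSC": ss_cols / (k - 1),
        "MSE": max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        "n": n,
        "k": k,
        "degenerate": ss_total <= 1e-300,
    }


def _f_ci(f_obs: float, k: int, df1: float, df2: float) -> tuple[float, float]:
    """Exact F-pivot CI for ICC(1)/ICC(C,1)."""
    fl = f_obs / spst.f.ppf(0.975, df1, df2)
    fu = f_obs * spst.f.ppf(0.975, df2, df1)
    return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


def icc(m: MeasurementMatrix, kind: str) -> IccResult:
    """Single-measure ICC of the requested kind with F test and 95% CI.

    kind='oneway'      ICC(1)   = (MSR - MSW) / (MSR + (k-1) MSW)
    kind='consistency' ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    kind='agreement'   ICC(A,1) = (MSR - MSE) /
                                  (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Estimates are reported as computed (negative values are not
    truncated).  The ICC(A,1) interval uses the Satterthwaite
    denominator-degrees-of-freedom approximation.
    """
    if kind not in ICC_KINDS:
        raise ParameterError(f"unknown ICC kind {kind!r}; expected one of {ICC_KINDS}")
    ms = anova_mean_squares(m)
    if ms["degenerate"]:
        raise DegenerateDataError("zero total variance: ICC undefined")
    n, k = ms["n"], ms["k"]
    msr, msw, msc, mse = ms["MSR"], ms["MSW"], ms["MSC"], ms["MSE"]

    if kind == "oneway":
        denom = msr + (k - 1) * msw
        est = (msr - msw) / denom if denom > 0 else np.nan
        df1, df2 = n - 1.0, n * (k - 1.0)
        f_obs = msr / msw if msw > 0 else np.inf
        lo, hi = _f_ci(f_obs, k, df1, df2) if np.isfinite(f_obs) else (est, est)
    elif kind == "consistency":
        denom = msr + (k - 1) * mse
        est = (msr - mse) / denom if denom > 0 else np.nan
        df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)
        f_obs = msr / mse if mse > 0 else np.inf
        lo, hi = _f_ci(f_obs, k, df1, df2) if np.isfinite(f_obs) else (est, est)
    else:  # agreement
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msr - mse) / denom if denom > 0 else np.nan
        df1 = n - 1.0
        f_obs = msr / mse if mse > 0 else np.inf
        df2 = (n - 1.0) * (k - 1.0)  # dof of the zero-ICC test
        lo, hi = _agreement_ci(est, msr, msc, mse, n, k)
    p = float(spst.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0
    return IccResult(
        kind=kind, estimate=float(est), ci95_low=float(lo), ci95_high=float(hi),
        f_value=float(f_obs), df1=df1, df2=df2, p_value=p,
    )


def _agreement_ci(est: float, msr: float, msc: float, mse: float,
                  n: int, k: int) -> tuple[float, float]:
    """Satterthwaite 95% CI for ICC(A,1)."""
    if not np.isfinite(est) or est >= 1.0 or mse <= 0:
        return est, est
    a = k * est / (n * (1.0 - est))
    b = 1.0 + k * est * (n - 1.0) / (n * (1.0 - est))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    v = num / den if den > 0 else (n - 1.0) * (k - 1.0)
    f_low = spst.f.ppf(0.975, n - 1.0, v)
    f_up = spst.f.ppf(0.975, v, n - 1.0)
    lo = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return lo, hi


def sem_mdc(pooled_sd: float, icc_estimate: float) -> tuple[float, float]:
    """Standard error of measurement and minimal detectable change.

    ``sem = sd * sqrt(1 - icc)``; ``mdc = sem * 1.96 * sqrt(2)``.
    Negative ICC estimates in [-1, 0) are accepted with a warning (SEM
    then exceeds the SD); values outside [-1, 1] are a parameter error.
    """
    if pooled_sd < 0:
        raise ParameterError(f"pooled SD must be >= 0, got {pooled_sd}")
    if not -1.0 <= icc_estimate <= 1.0:
        raise ParameterError(f"ICC estimate {icc_estimate} outside [-1, 1]")
    if icc_estimate < 0:
        warnings.warn(
            f"negative ICC ({icc_estimate:.3f}): SEM exceeds the observed SD",
            stacklevel=2,
        )
    sem = float(pooled_sd * np.sqrt(1.0 - icc_estimate))
    return sem, float(sem * MDC_FACTOR)


def agreement(reference, index, eps: float = 1e-6) -> AgreementReport:
    """Absolute and relative agreement of paired per-subject values.

    Absolute agreement is ``d = reference - index`` (mean and SD);
    relative agreement is ``100 * d / reference`` (%), computed only for
    subjects whose reference value is bounded away from zero
    (|reference| >= eps); excluded subjects are counted.
    """
    ref = np.asarray(reference, dtype=float)
    idx = np.asarray(index, dtype=float)
    if ref.shape != idx.shape or ref.ndim != 1 or ref.size < 1:
        raise DataError("reference and index must be equal-length 1-D arrays")
    d = ref - idx
    usable = np.abs(ref) >= eps
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} subject(s) with |reference| < {eps:g} excluded from "
            "relative agreement", stacklevel=2,
        )
    rel = 100.0 * d[usable] / ref[usable]
    sd = float(np.std(d, ddof=1)) if d.size >= 2 else 0.0
    rel_mean = float(rel.mean()) if rel.size else np.nan
    rel_sd = float(np.std(rel, ddof=1)) if rel.size >= 2 else 0.0
    return AgreementReport(
        absolute_mean=float(d.mean()), absolute_sd=sd,
        relative_mean_pct=rel_mean, relative_sd_pct=rel_sd,
        n=int(ref.size), n_relative_excluded=n_excluded,
    )


def icc_discrepancy_gate(results, threshold: float = 0.01) -> GateDecision:
    """Decide whether the three ICC forms agree closely enough.

    If the largest pairwise difference between the estimates is below
    ``threshold`` (default 0.01, i.e. agreement at the second decimal)
    the simplest form, ICC(1), suffices; otherwise both two-way forms
    should be reported because the discrepancy indicates non-negligible
    measurement bias.
    """
    estimates = [r.estimate for r in results]
    if len(estimates) != 3:
        raise ParameterError("expected exactly three ICC results")
    diffs = [abs(a - b) for i, a in enumerate(estimates) for b in estimates[i + 1:]]
    max_diff = max(diffs)
    if max_diff < threshold:
        return GateDecision(True, max_diff, "marginal differences; one-way ICC reported")
    return GateDecision(
        False, max_diff,
        "non-negligible measurement bias; two-way agreement and consistency ICCs reported",
    )


def reliability_report(
    session1,
    session2,
    metric_names=None,
    sd_source: str = "all",
    gate_threshold: float = 0.01,
) -> ReliabilityReport:
    """Test-retest reliability for one or more metrics over two sessions.

    Parameters
    ----------
    session1, session2:
        Either per-subject value vectors (one metric) or mappings
        metric-name -> vector.
    sd_source:
        Which SD feeds the SEM: ``"all"`` pools all n*k observations about
        the grand mean (default), ``"session1"`` uses the first session
        only.  The one-way ICC estimate is used, per the discrepancy gate.
    """
    if isinstance(session1, dict) != isinstance(session2, dict):
        raise DataError("session1 and session2 must both be dicts or both arrays")
    if not isinstance(session1, dict):
        session1 = {"metric": session1}
        session2 = {"metric": session2}
    if metric_names is None:
        metric_names = list(session1)
    report: ReliabilityReport = {}
    for name in metric_names:
        m = MeasurementMatrix.from_sessions(session1[name], session2[name])
        results = {kind: icc(m, kind) for kind in ICC_KINDS}
        gate = icc_discrepancy_gate(
            [results[k] for k in ICC_KINDS], threshold=gate_threshold
        )
        if sd_source == "all":
            pooled_sd = float(np.std(m.values, ddof=1))
        elif sd_source == "session1":
            pooled_sd = float(np.std(m.values[:, 0], ddof=1))
        else:
            raise ParameterError(f"unknown sd_source {sd_source!r}")
        sem, mdc = sem_mdc(pooled_sd, results["oneway"].estimate)
        report[name] = ReliabilityResult(
            icc_oneway=results["oneway"],
            icc_agreement=results["agreement"],
            icc_consistency=results["consistency"],
            gate=gate,
            pooled_sd=pooled_sd,
            sem=sem,
            mdc=mdc,
            sd_source=sd_source,
        )
    return report
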