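"""Non-compartmental analysis of concentration-time profiles.

Conventions (documented defaults, selectable where noted):

* AUC: linear-up/log-down trapezoid by default; plain linear by flag.
* Terminal slope: log-linear regression over the contiguous terminal window
  (excluding tmax) maximizing adjusted R-squared, requiring at least three
  points and a window span of at least twice the resulting half-life; ties
  broken toward more points.
* Below-LLOQ samples before the first quantifiable sample count as zero;
  embedded and trailing below-LLOQ samples are excluded.
* AUC extrapolation to infinity uses the regression-predicted last
  concentration.
* Clearance is reported in L/h and volume in L (dose mg -> ng, ml -> L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .params import DoseRegimen

__all__ = [
    "ConcentrationTimeProfile",
    "NCAResult",
    "LambdaZFit",
    "LambdaZError",
    "compute_auc",
    "estimate_lambda_z",
    "nca_single",
    "nca_multiple",
]

OCCASIONS = ("single", "day1", "day6")


class ConcentrationTimeProfile(BaseModel):
    """One subject's sampled plasma concentrations with dosing context.

    ``concentrations[i] is None`` flags a below-LLOQ sample. Times are hours
    from the start of the profiled dose.
    """

    subject_id: str
    cohort_id: str
    dose_mg: float = Field(gt=0)
    regimen: DoseRegimen
    occasion: str = "single"
    times: list[float]
    concentrations: list[Optional[float]]
    lloq: float = Field(gt=0)
    active: bool = True

    @model_validator(mode="after")
    def _validate_samples(self) -> "ConcentrationTimeProfile":
        if self.occasion not in OCCASIONS:
            raise ValueError(f"occasion must be one of {OCCASIONS}")
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations must have equal length")
        if len(self.times) < 2:
            raise ValueError("profile needs at least two samples")
        t = np.asarray(self.times)
        if np.any(t < 0):
            raise ValueError("sample times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"sample times not strictly increasing for subject {self.subject_id}"
            )
        for c in self.concentrations:
            if c is not None and (not math.isfinite(c) or c < 0):
                raise ValueError(f"invalid concentration {c!r}")
        return self

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and values of quantifiable (non-BLQ, positive) samples."""
        pairs = [
            (t, c)
            for t, c in zip(self.times, self.concentrations)
            if c is not None and c > 0
        ]
        if not pairs:
            return np.array([]), np.array([])
        t, c = zip(*pairs)
        return np.asarray(t, dtype=float), np.asarray(c, dtype=float)

    def auc_series(self) -> tuple[np.ndarray, np.ndarray]:
        """Series used for AUC: leading BLQ as zeros, then quantifiable
        samples; embedded/trailing BLQ dropped."""
        tq, _ = self.quantifiable()
        if tq.size == 0:
            raise ValueError(f"no quantifiable samples for subject {self.subject_id}")
        first_q = tq[0]
        t_out, c_out = [], []
        for t, c in zip(self.times, self.concentrations):
            if c is not None and c > 0:
                t_out.append(t)
                c_out.append(c)
            elif t < first_q:
                t_out.append(t)
                c_out.append(0.0)
        return np.asarray(t_out), np.asarray(c_out)


@dataclass
class LambdaZFit:
    lambda_z: float  # 1/h
    intercept_ln: float  # ln(ng/ml) at t=0 of the regression line
    n_points: int
    r2adj: float
    t_first: float
    t_last: float

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.lambda_z

    def predict(self, t: float) -> float:
        return math.exp(self.intercept_ln - self.lambda_z * t)


class LambdaZError(RuntimeError):
    """Terminal-slope estimation failed (flat/rising tail or too few points)."""


@dataclass
class NCAResult:
    subject_id: str
    cohort_id: str
    dose_mg: float
    occasion: str
    cmax: float
    tmax: float
    auc_last: float
    cmin: Optional[float] = None
    auc_inf: Optional[float] = None
    auc_tau: Optional[float] = None
    lambda_z: Optional[float] = None
    lambda_z_n_points: Optional[int] = None
    lambda_z_r2adj: Optional[float] = None
    t_half: Optional[float] = None
    cl: Optional[float] = None
    vd: Optional[float] = None
    cavg: Optional[float] = None
    fluctuation_pct: Optional[float] = None
    accumulation_index: Optional[float] = None
    extrapolated_fraction: Optional[float] = None
    failure_reason: Optional[str] = None


def _interval_auc(t0, c0, t1, c1, method: str) -> float:
    dt = t1 - t0
    if method == "linear" or c1 >= c0 or c0 <= 0 or c1 <= 0:
        return 0.5 * (c0 + c1) * dt
    return (c0 - c1) * dt / math.log(c0 / c1)


def _interp_conc(t0, c0, t1, c1, t, method: str) -> float:
    if method == "linear" or c1 >= c0 or c0 <= 0 or c1 <= 0:
        return c0 + (c1 - c0) * (t - t0) / (t1 - t0)
    lam = math.log(c0 / c1) / (t1 - t0)
    return c0 * math.exp(-lam * (t - t0))


def compute_auc(
    profile: ConcentrationTimeProfile,
    t_end: float,
    method: str = "linear_up_log_down",
) -> float:
    """Trapezoidal AUC from time zero of the profile to ``t_end``.

    Integrates to the last sample if ``t_end`` lies beyond it; cuts the
    spanning interval (with the method's interpolant) if ``t_end`` falls
    between samples.
    """
    if method not in ("linear", "linear_up_log_down"):
        raise ValueError(f"unknown AUC method {method!r}")
    t, c = profile.auc_series()
    nq = np.count_nonzero(np.asarray(t) < t_end + 1e-12)
    if (
        len([1 for ti, ci in zip(t, c) if ci > 0 and ti <= t_end + 1e-12]) < 2
        or t_end < t[1]
    ):
        raise ValueError(
            f"t_end={t_end} leaves fewer than two quantifiable samples"
        )
    total = 0.0
    for (t0, c0), (t1, c1) in zip(zip(t[:-1], c[:-1]), zip(t[1:], c[1:])):
        if t1 <= t_end:
            total += _interval_auc(t0, c0, t1, c1, method)
        elif t0 < t_end:
            c_cut = _interp_conc(t0, c0, t1, c1, t_end, method)
            total += _interval_auc(t0, c0, t_end, c_cut, method)
            break
        else:
            break
    return total


def _adjusted_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def estimate_lambda_z(
    profile: ConcentrationTimeProfile,
    min_points: int = 3,
    span_half_lives: float = 2.0,
) -> LambdaZFit:
    """Terminal slope by best-adjusted-R2 log-linear regression.

    Candidate windows are the contiguous terminal point sets (last k
    samples, k >= ``min_points``) strictly after tmax.  Windows whose span is
    shorter than ``span_half_lives`` half-lives are dropped when any window
    passes that rule.  Raises :class:`LambdaZError` when no window has a
    negative slope.
    """
    t, c = profile.quantifiable()
    if t.size < min_points + 1:
        raise LambdaZError(
            f"need at least {min_points} post-peak samples, got {t.size} quantifiable"
        )
    i_max = int(np.argmax(c))
    logc = np.log(c)

    candidates = []
    for start in range(i_max + 1, t.size - min_points + 1):
        tt, yy = t[start:], logc[start:]
        n = tt.size
        res = stats.linregress(tt, yy)
        if res.slope >= 0:
            continue
        lam = -res.slope
        r2adj = _adjusted_r2(res.rvalue**2, n)
        span_ok = (tt[-1] - tt[0]) >= span_half_lives * math.log(2.0) / lam
        candidates.append(
            (span_ok, r2adj, n, LambdaZFit(lam, res.intercept, n, r2adj, tt[0], tt[-1]))
        )
    if not candidates:
        raise LambdaZError("no terminal window with a negative slope")
    if any(ok for ok, *_ in candidates):
        candidates = [cand for cand in candidates if cand[0]]
    # max adjusted R2, ties toward more points
    candidates.sort(key=lambda cand: (round(cand[1], 10), cand[2]))
    return candidates[-1][3]


def _base_result(profile: ConcentrationTimeProfile) -> tuple[NCAResult, np.ndarray, np.ndarray]:
    t, c = profile.quantifiable()
    if t.size < 2:
        raise ValueError(
            f"profile for subject {profile.subject_id} has fewer than two "
            "quantifiable samples"
        )
    i = int(np.argmax(c))
    res = NCAResult(
        subject_id=profile.subject_id,
        cohort_id=profile.cohort_id,
        dose_mg=profile.dose_mg,
        occasion=profile.occasion,
        cmax=float(c[i]),
        tmax=float(t[i]),
        auc_last=compute_auc(profile, float(t[-1])),
    )
    return res, t, c


def nca_single(
    profile: ConcentrationTimeProfile, method: str = "linear_up_log_down"
) -> NCAResult:
    """Single-dose NCA panel: Cmax, AUCs, terminal slope, CL, Vd."""
    res, t, c = _base_result(profile)
    res.auc_last = compute_auc(profile, float(t[-1]), method)
    try:
        fit = estimate_lambda_z(profile)
    except LambdaZError as exc:
        res.failure_reason = f"lambda_z: {exc}"
        return res
    res.lambda_z = fit.lambda_z
    res.lambda_z_n_points = fit.n_points
    res.lambda_z_r2adj = fit.r2adj
    res.t_half = fit.t_half
    c_last_pred = fit.predict(float(t[-1]))
    res.auc_inf = res.auc_last + c_last_pred / fit.lambda_z
    res.extrapolated_fraction = (res.auc_inf - res.auc_last) / res.auc_inf
    # dose mg -> ng, AUC h*ng/ml -> CL in ml/h -> L
    res.cl = profile.dose_mg * 1e6 / res.auc_inf / 1e3
    res.vd = res.cl / fit.lambda_z
    return res


def nca_multiple(
    profile_day6: ConcentrationTimeProfile, method: str = "linear_up_log_down"
) -> NCAResult:
    """Steady-state (day-6 interval) NCA: AUC over tau, Cavg, fluctuation,
    accumulation index.  Times must be relative to the profiled dose."""
    tau = profile_day6.regimen.dosing_interval_tau
    if tau is None:
        raise ValueError("multiple-dose NCA requires a dosing_interval_tau")
    res, t, c = _base_result(profile_day6)
    res.auc_last = compute_auc(profile_day6, float(t[-1]), method)
    in_tau = c[t <= tau + 1e-9]
    res.cmin = float(in_tau.min()) if in_tau.size else None
    try:
        fit = estimate_lambda_z(profile_day6)
    except LambdaZError as exc:
        res.failure_reason = f"lambda_z: {exc}"
        return res
    res.lambda_z = fit.lambda_z
    res.lambda_z_n_points = fit.n_points
    res.lambda_z_r2adj = fit.r2adj
    res.t_half = fit.t_half

    t_last = float(t[-1])
    if t_last >= tau:
        res.auc_tau = compute_auc(profile_day6, float(tau), method)
    else:
        c_last_pred = fit.predict(t_last)
        tail = (c_last_pred / fit.lambda_z) * (
            1.0 - math.exp(-fit.lambda_z * (tau - t_last))
        )
        res.auc_tau = compute_auc(profile_day6, t_last, method) + tail
    res.cavg = res.auc_tau / tau
    if res.cmin is not None:
        res.fluctuation_pct = (res.cmax - res.cmin) / res.cavg * 100.0
    res.accumulation_index = 1.0 / (1.0 - math.exp(-fit.lambda_z * tau))

    c_last_pred = fit.predict(t_last)
    res.auc_inf = res.auc_last + c_last_pred / fit.lambda_z
    res.extrapolated_fraction = (res.auc_inf - res.auc_last) / res.auc_inf
    res.cl = profile_day6.dose_mg * 1e6 / res.auc_inf / 1e3
    res.vd = res.cl / fit.lambda_z
    return res
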