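"""Dose-proportionality assessment by the power model.

Exposure Y is regressed on dose on the log scale, ln(Y) = alpha + beta
ln(dose), and the confidence interval of the slope is compared with an
acceptance range derived from bioequivalence limits scaled by the log dose
ratio: (1 + ln(theta_low)/ln(R), 1 + ln(theta_high)/ln(R)) with R the ratio
of the highest to the lowest dose studied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats

__all__ = [
    "DoseExposureRecord",
    "DoseProportionalityResult",
    "acceptance_range",
    "fit_power_model",
]

DEFAULT_THETA_LOW = 0.8
DEFAULT_THETA_HIGH = 1.25


class DoseExposureRecord(BaseModel):
    subject_id: str
    dose: float = Field(gt=0)
    parameter_name: str
    value: float = Field(gt=0)


@dataclass
class DoseProportionalityResult:
    parameter_name: str
    alpha: float
    beta: float
    beta_ci90: tuple[float, float]
    ci_level: float
    acceptance_range: tuple[float, float]
    dose_ratio_R: float
    verdict: str  # proportional | not_proportional
    deviation_direction: str  # above | below | none
    n_records: int
    n_doses: int


def acceptance_range(
    theta_low: float, theta_high: float, dose_ratio_R: float
) -> tuple[float, float]:
    """Slope acceptance interval (1 + ln(thetaL)/ln(R), 1 + ln(thetaH)/ln(R))."""
    if not (0 < theta_low < 1 < theta_high):
        raise ValueError("need 0 < theta_low < 1 < theta_high")
    if dose_ratio_R <= 1:
        raise ValueError(f"dose ratio R must exceed 1, got {dose_ratio_R}")
    lnr = math.log(dose_ratio_R)
    return (1.0 + math.log(theta_low) / lnr, 1.0 + math.log(theta_high) / lnr)


def fit_power_model(
    records: list[DoseExposureRecord],
    ci_level: float = 0.90,
    theta_low: float = DEFAULT_THETA_LOW,
    theta_high: float = DEFAULT_THETA_HIGH,
    on_cohort_means: bool = False,
) -> DoseProportionalityResult:
    """OLS of ln(value) on ln(dose) with a t-based slope CI and verdict.

    The verdict is ``proportional`` iff the CI is contained in the
    acceptance range; the deviation direction is ``above``/``below`` by the
    CI midpoint relative to 1 when not contained.  ``on_cohort_means``
    collapses records to geometric cohort means before fitting (for
    summary-only data).
    """
    if not records:
        raise ValueError("no records")
    names = {r.parameter_name for r in records}
    if len(names) != 1:
        raise ValueError(f"records mix parameters {sorted(names)}; fit one at a time")
    doses = np.array([r.dose for r in records])
    values = np.array([r.value for r in records])
    if len(np.unique(doses)) < 3:
        raise ValueError("power model requires at least 3 distinct dose levels")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")

    if on_cohort_means:
        uniq = np.unique(doses)
        x = np.log(uniq)
        y = np.array([np.mean(np.log(values[doses == d])) for d in uniq])
    else:
        x = np.log(doses)
        y = np.log(values)

    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    res = stats.linregress(x, y)
    dof = n - 2
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, dof)
    half = tcrit * res.stderr
    ci = (res.slope - half, res.slope + half)

    big_r = float(doses.max() / doses.min())
    rng = acceptance_range(theta_low, theta_high, big_r)
    contained = rng[0] <= ci[0] and ci[1] <= rng[1]
    if contained:
        verdict, direction = "proportional", "none"
    else:
        mid = 0.5 * (ci[0] + ci[1])
        direction = "above" if mid > 1 else ("below" if mid < 1 else "none")
        verdict = "not_proportional"
    return DoseProportionalityResult(
        parameter_name=next(iter(names)),
        alpha=float(res.intercept),
        beta=float(res.slope),
        beta_ci90=(float(ci[0]), float(ci[1])),
        ci_level=ci_level,
        acceptance_range=rng,
        dose_ratio_R=big_r,
        verdict=verdict,
        deviation_direction=direction,
        n_records=len(records),
        n_doses=int(len(np.unique(doses))),
    )
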