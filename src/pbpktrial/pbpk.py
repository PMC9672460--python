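"""Whole-body permeability-limited PBPK simulator.

The model comprises venous and arterial blood pools plus fourteen tissues,
each split into a vascular and an extravascular sub-compartment.  Lung sits
in series between the venous and arterial pools and receives total cardiac
output; the remaining tissues are perfused in parallel.  Drug enters the
venous pool as a zero-order infusion.  Hepatic elimination is carried by a
saturable uptake flux (blood -> hepatocyte) chained to a saturable efflux
flux (hepatocyte -> bile), the latter an irreversible loss.  An optional
linear clearance acts on venous blood.

State vector (amounts in ng): venous, arterial, vascular amounts of the N
tissues, extravascular amounts of the N tissues, cumulative eliminated.
Internal concentrations are ng/L; plasma output is ng/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .params import DoseRegimen, PBPKParameterSet

__all__ = [
    "SimulationResult",
    "SimulationError",
    "FitNonConvergenceError",
    "simulate",
    "convert_molar_to_mass_concentration",
    "fit_transporter_parameters",
]

MASS_BALANCE_RTOL = 1e-3  # fraction of administered dose


class SimulationError(RuntimeError):
    """Raised when the integrator fails; message names the failing span."""


class FitNonConvergenceError(RuntimeError):
    """Optimizer did not converge; carries best-so-far parameters."""

    def __init__(self, message: str, best_params: PBPKParameterSet, objective: float):
        super().__init__(message)
        self.best_params = best_params
        self.objective = objective
        self.converged = False


@dataclass
class SimulationResult:
    """Trajectories of one deterministic simulation."""

    times: np.ndarray  # h, strictly increasing
    plasma_concentration: np.ndarray  # ng/ml
    tissue_names: list[str]
    vascular_amounts: np.ndarray  # (n_times, n_tissues) ng
    extravascular_amounts: np.ndarray  # (n_times, n_tissues) ng
    venous_amount: np.ndarray  # ng
    arterial_amount: np.ndarray  # ng
    eliminated_amount: np.ndarray  # ng
    infused_amount: np.ndarray  # ng, cumulative input up to each time

    def total_in_system(self) -> np.ndarray:
        return (
            self.venous_amount
            + self.arterial_amount
            + self.vascular_amounts.sum(axis=1)
            + self.extravascular_amounts.sum(axis=1)
        )

    def mass_balance_error(self) -> np.ndarray:
        """|in-system + eliminated - infused| as a fraction of total dose."""
        dose = self.infused_amount[-1]
        gap = self.total_in_system() + self.eliminated_amount - self.infused_amount
        return np.abs(gap) / dose

    def auc_plasma(self, t_end: float | None = None) -> float:
        """Linear-trapezoid AUC of the plasma curve on the simulation grid."""
        t, c = self.times, self.plasma_concentration
        if t_end is not None:
            keep = t <= t_end + 1e-12
            t, c = t[keep], c[keep]
        return float(np.trapezoid(c, t))

    @property
    def cmax_plasma(self) -> float:
        return float(self.plasma_concentration.max())


def convert_molar_to_mass_concentration(c_molar: float, mw: float) -> float:
    """Convert a micromolar concentration to ng/ml using the molar mass.

    uM * g/mol = ug/L = ng/ml, so the conversion is a plain product.
    """
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    if c_molar < 0:
        raise ValueError(f"concentration must be non-negative, got {c_molar}")
    return c_molar * mw


def michaelis_menten_flux(conc: float, vmax: float, km: float) -> float:
    """Saturable transport rate vmax*C/(km+C); units follow vmax."""
    if km <= 0:
        raise ValueError("km must be positive")
    return vmax * conc / (km + conc)


def _infusion_windows(regimen: DoseRegimen) -> list[tuple[float, float]]:
    return [
        (t0, t0 + regimen.infusion_duration) for t0 in regimen.dose_start_times()
    ]


def _cumulative_infused(times: np.ndarray, regimen: DoseRegimen) -> np.ndarray:
    rate = regimen.infusion_rate_ng_per_h
    out = np.zeros_like(times, dtype=float)
    for t0, t1 in _infusion_windows(regimen):
        out += rate * np.clip(times - t0, 0.0, t1 - t0)
    return out


def simulate(
    params: PBPKParameterSet,
    regimen: DoseRegimen,
    t_end: float,
    output_grid: np.ndarray | list[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-3,
) -> SimulationResult:
    """Integrate the model over [0, t_end] and sample it on ``output_grid``.

    Infusion on/off switches are handled as exact segment boundaries (the
    stiff integrator is restarted at each discontinuity), which keeps the
    mass balance tight.  ``atol`` is in ng.
    """
    if t_end < regimen.total_duration:
        raise ValueError(
            f"t_end={t_end} does not cover the regimen "
            f"(needs >= {regimen.total_duration} h)"
        )
    if output_grid is None:
        output_grid = np.linspace(0.0, t_end, 513)
    grid = np.asarray(output_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("output grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("output grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > t_end + 1e-12:
        raise ValueError("output grid must lie within [0, t_end]")

    tissues = params.tissues
    n = len(tissues)
    names = [t.tissue_name for t in tissues]
    lung_ix = names.index("lung")
    liver_ix = names.index("liver")

    q = np.array([t.blood_flow for t in tissues])
    kp = np.array([t.kp for t in tissues])
    ps = np.array([t.pstc for t in tissues])
    v_vas = np.array([t.vascular_volume for t in tissues])
    v_ext = np.array([t.extravascular_volume for t in tissues])
    co = params.cardiac_output
    v_ven = params.venous_volume
    v_art = params.arterial_volume
    fu_b = params.compound.fraction_unbound_blood
    bp = params.compound.blood_to_plasma_ratio
    cl_sys = params.systemic_linear_clearance

    uptake = params.transporter("uptake")
    efflux = params.transporter("efflux")
    # km stored as ng/ml; internal concentrations are ng/L
    up_vmax = uptake.vmax if uptake else 0.0
    up_km = uptake.km * 1e3 if uptake else 1.0
    ef_vmax = efflux.vmax if efflux else 0.0
    ef_km = efflux.km * 1e3 if efflux else 1.0

    parallel = np.ones(n, dtype=bool)
    parallel[lung_ix] = False

    rate = regimen.infusion_rate_ng_per_h

    def rhs(t: float, y: np.ndarray, infusing: float) -> np.ndarray:
        a_ven, a_art = y[0], y[1]
        a_vas = y[2 : 2 + n]
        a_ext = y[2 + n : 2 + 2 * n]
        c_ven = a_ven / v_ven
        c_art = a_art / v_art
        c_vas = a_vas / v_vas
        c_ext = a_ext / v_ext

        j_perm = ps * fu_b * (c_vas - c_ext / kp)

        d_vas = np.empty(n)
        d_vas[parallel] = q[parallel] * (c_art - c_vas[parallel])
        d_vas[lung_ix] = co * (c_ven - c_vas[lung_ix])
        d_vas -= j_perm
        d_ext = j_perm.copy()

        cu_liv_vas = fu_b * c_vas[liver_ix]
        cu_liv_ext = fu_b * c_ext[liver_ix] / kp[liver_ix]
        j_up = up_vmax * cu_liv_vas / (up_km + cu_liv_vas)
        j_ef = ef_vmax * cu_liv_ext / (ef_km + cu_liv_ext)
        d_vas[liver_ix] -= j_up
        d_ext[liver_ix] += j_up - j_ef

        d_ven = (
            float(q[parallel] @ c_vas[parallel])
            - co * c_ven
            - cl_sys * c_ven
            + infusing * rate
        )
        d_art = co * c_vas[lung_ix] - co * c_art
        d_elim = j_ef + cl_sys * c_ven

        out = np.empty_like(y)
        out[0] = d_ven
        out[1] = d_art
        out[2 : 2 + n] = d_vas
        out[2 + n : 2 + 2 * n] = d_ext
        out[-1] = d_elim
        return out

    # Segment boundaries at every infusion switch inside [0, t_end].
    breaks = {0.0, float(t_end)}
    for t0, t1 in _infusion_windows(regimen):
        if t0 < t_end:
            breaks.add(float(t0))
        if t1 < t_end:
            breaks.add(float(t1))
    edges = sorted(breaks)

    def infusing_in(seg_start: float, seg_end: float) -> float:
        mid = 0.5 * (seg_start + seg_end)
        return float(
            any(t0 <= mid < t1 for t0, t1 in _infusion_windows(regimen))
        )

    y = np.zeros(2 + 2 * n + 1)
    samples = np.empty((grid.size, y.size))
    filled = np.zeros(grid.size, dtype=bool)
    if grid[0] == 0.0:
        samples[0] = y
        filled[0] = True

    for seg_start, seg_end in zip(edges[:-1], edges[1:]):
        mask = (~filled) & (grid > seg_start) & (grid <= seg_end + 1e-12)
        t_eval = np.minimum(grid[mask], seg_end)
        sol = solve_ivp(
            rhs,
            (seg_start, seg_end),
            y,
            method="LSODA",
            args=(infusing_in(seg_start, seg_end),),
            rtol=rtol,
            atol=atol,
            t_eval=np.concatenate([t_eval, [seg_end]])
            if (t_eval.size == 0 or t_eval[-1] < seg_end - 1e-12)
            else t_eval,
            dense_output=False,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{seg_start:g}, {seg_end:g}] h: {sol.message}"
            )
        k = t_eval.size
        if k:
            samples[mask] = sol.y[:, :k].T
            filled[mask] = True
        y = sol.y[:, -1]

    if not filled.all():  # pragma: no cover - defensive
        raise SimulationError("output grid points not reached by the integrator")

    a_ven = samples[:, 0]
    c_plasma = a_ven / v_ven / bp / 1e3  # ng/L blood -> ng/ml plasma
    result = SimulationResult(
        times=grid,
        plasma_concentration=c_plasma,
        tissue_names=names,
        vascular_amounts=samples[:, 2 : 2 + n],
        extravascular_amounts=samples[:, 2 + n : 2 + 2 * n],
        venous_amount=a_ven,
        arterial_amount=samples[:, 1],
        eliminated_amount=samples[:, -1],
        infused_amount=_cumulative_infused(grid, regimen),
    )
    err = result.mass_balance_error()
    if np.nanmax(err) > MASS_BALANCE_RTOL:
        raise SimulationError(
            f"mass balance violated: max relative gap {np.nanmax(err):.2e} "
            f"at t={grid[int(np.nanargmax(err))]:g} h"
        )
    return result


def _with_transporter_values(
    params: PBPKParameterSet, km: float, vmax_scale: float
) -> PBPKParameterSet:
    """Copy of ``params`` with shared km and jointly scaled vmax values."""
    transporters = [
        t.model_copy(update={"km": km, "vmax": t.vmax * vmax_scale})
        for t in params.transporters
    ]
    return params.model_copy(update={"transporters": transporters})


def transporter_fit_objective(
    observed,
    params: PBPKParameterSet,
    rtol: float = 1e-6,
) -> float:
    """Sum of squared log-concentration residuals, pooled across profiles.

    ``observed`` is an iterable of objects with ``regimen`` and quantifiable
    ``(time_h, conc)`` pairs (see :class:`pbpktrial.nca.ConcentrationTimeProfile`).
    """
    sse = 0.0
    for profile in observed:
        times, conc = profile.quantifiable()
        t_end = max(float(times[-1]), profile.regimen.total_duration)
        grid = np.unique(np.concatenate([[0.0], times]))
        sim = simulate(params, profile.regimen, t_end=t_end, output_grid=grid, rtol=rtol)
        pred = np.interp(times, sim.times, sim.plasma_concentration)
        pred = np.clip(pred, 1e-9, None)
        sse += float(np.sum((np.log(conc) - np.log(pred)) ** 2))
    return sse


def fit_transporter_parameters(
    observed,
    params: PBPKParameterSet,
    km_bounds: tuple[float, float] = (1.0, 1e6),
    vmax_scale_bounds: tuple[float, float] = (1e-3, 1e3),
    maxiter: int = 80,
) -> PBPKParameterSet:
    """Refit the shared transporter ``km`` and a joint ``vmax`` scale.

    Minimizes the pooled squared log-residual objective with bounded
    quasi-Newton steps in log-parameter space.  The uptake and efflux vmax
    values keep their initial ratio.  Returns an updated parameter set whose
    objective is never above the starting objective.
    """
    doses = {p.dose_mg for p in observed}
    if len(doses) < 2:
        raise ValueError("observed profiles must span at least 2 dose levels")
    if not params.transporters:
        raise ValueError("parameter set has no transporters to fit")

    km0 = params.transporters[0].km

    def objective(x: np.ndarray) -> float:
        km, scale = np.exp(x)
        try:
            return transporter_fit_objective(
                observed, _with_transporter_values(params, km, scale)
            )
        except SimulationError:
            return 1e12

    x0 = np.array([np.log(km0), 0.0])
    f0 = objective(x0)
    bounds = [
        (np.log(km_bounds[0]), np.log(km_bounds[1])),
        (np.log(vmax_scale_bounds[0]), np.log(vmax_scale_bounds[1])),
    ]
    # derivative-free: the objective carries integrator noise that breaks
    # finite-difference line searches
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-10},
    )
    km, scale = np.exp(res.x)
    best = _with_transporter_values(params, float(km), float(scale))
    f_best = min(float(res.fun), f0)
    if float(res.fun) > f0:  # optimizer wandered; keep the start point
        best, f_best = params, f0
    if not res.success and "maximum number" not in str(res.message).lower():
        raise FitNonConvergenceError(
            f"transporter fit did not converge: {res.message}", best, f_best
        )
    return best
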