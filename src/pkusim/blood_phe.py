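"""Extended blood phenylalanine metabolism model with meal-driven absorption.

Plasma Phe in PKU is governed by a small set of fluxes: hydroxylation by PAH
(with substrate activation, scaled by the patient's residual activity fraction
F_PAH), transamination, renal elimination, net protein breakdown, and
first-order absorption of dietary Phe from a gut depot.  The state is
(plasma Phe in mmol/L, gut Phe in mg); meals add discrete boluses to the gut
depot, and a luminal Phe-consuming agent is represented by removing part of
each bolus before absorption.

    dGut/dt = -Ka_gut * Gut            (+ bolus jumps at meal times)
    dPhe/dt = Ka_gut * Gut * F_gp + V_npd - V_PAH - V_trans - V_renal

with F_gp = 1/(MW_Phe * Vd * W) converting mg of absorbed Phe into mmol/L of
plasma.  The elimination fluxes are

    V_PAH   = Vmax_PAH * F_PAH / (1 + Km_PAH/Phe + Km_PAH*Ka_PAH/Phe^2)
    V_trans = Vmax_trans / (1 + Km_trans/Phe)
    V_renal = Phe * CL_renal * Vd

The clinical readout is the fasting plasma Phe sampled 14 h after the last
meal of the day (8:00 AM next morning for the default 0/4/10 h schedule).
Time is in hours throughout this module.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .pal_kinetics import IntegrationError, InvalidInputError

logger = logging.getLogger("pkusim")


@dataclass
class BloodParams:
    """Blood Phe metabolism constants.

    Rates are in (mmol/L)/hr; concentrations in mmol/L; ``cl_renal`` in
    (L/kg)/hr.  ``f_pah`` is the residual PAH activity fraction (0 for
    classical PKU, 0.5 for the carrier assumption, 1 for healthy).
    """

    ka_gut: float = 0.25
    v_npd: float = 0.012
    vmax_pah: float = 0.9
    f_pah: float = 0.0
    km_pah: float = 0.51
    ka_pah: float = 0.54
    vmax_trans: float = 0.063
    km_trans: float = 1.37
    cl_renal: float = 5.696e-4
    mw_phe: float = 165.19
    vd: float = 0.5
    weight: float = 70.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_pah <= 1.0:
            raise InvalidInputError("f_pah must lie in [0, 1]")
        positive = (
            self.ka_gut, self.v_npd, self.vmax_pah, self.km_pah, self.ka_pah,
            self.vmax_trans, self.km_trans, self.cl_renal, self.mw_phe,
            self.vd, self.weight,
        )
        if any(v <= 0 for v in positive):
            raise InvalidInputError("all blood parameters except f_pah must be positive")


DEFAULT_BLOOD = BloodParams()

#: Default initial plasma Phe, mmol/L (untreated classical PKU).
PKU_INITIAL_PHE = 1.18
#: Physiological initial plasma Phe for healthy-subject runs, mmol/L.
HEALTHY_INITIAL_PHE = 0.06


@dataclass
class MealSchedule:
    """Daily dietary Phe split across scheduled meals, with optional removal.

    ``removal_fraction`` removes a fraction of every meal; ``removal_mg_per_meal``
    removes a fixed amount per meal (applied after the fraction).  Removal is
    clipped at each meal's content — a luminal consumer cannot remove Phe that
    is not there.
    """

    daily_phe_g: float = 2.5
    meal_times_hr: tuple[float, ...] = (0.0, 4.0, 10.0)
    per_meal_fraction: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    removal_fraction: float = 0.0
    removal_mg_per_meal: float = 0.0

    def __post_init__(self) -> None:
        if self.daily_phe_g < 0:
            raise InvalidInputError("daily_phe_g must be >= 0")
        if len(self.meal_times_hr) != len(self.per_meal_fraction):
            raise InvalidInputError("meal_times_hr and per_meal_fraction lengths differ")
        if any(not 0 <= f <= 1 for f in self.per_meal_fraction):
            raise InvalidInputError("per_meal_fraction entries must lie in [0, 1]")
        if abs(sum(self.per_meal_fraction) - 1.0) > 1e-9:
            raise InvalidInputError("per_meal_fraction must sum to 1")
        if not 0.0 <= self.removal_fraction <= 1.0:
            raise InvalidInputError("removal_fraction must lie in [0, 1]")
        if self.removal_mg_per_meal < 0:
            raise InvalidInputError("removal_mg_per_meal must be >= 0")
        if any(not 0 <= t < 24 for t in self.meal_times_hr):
            raise InvalidInputError("meal times must lie in [0, 24) hours")

    def meal_boluses_mg(self) -> list[tuple[float, float]]:
        """(time-of-day hr, mg entering the gut) per meal, after removal."""
        out = []
        for t, frac in zip(self.meal_times_hr, self.per_meal_fraction):
            mg = self.daily_phe_g * 1000.0 * frac
            mg *= 1.0 - self.removal_fraction
            mg = max(mg - self.removal_mg_per_meal, 0.0)
            out.append((t, mg))
        return out


# ---------------------------------------------------------------------------
# Fluxes
# ---------------------------------------------------------------------------


def pah_rate(phe, p: BloodParams | None = None, f_pah: float | None = None):
    """PAH hydroxylation flux with substrate activation, (mmol/L)/hr.

    Evaluated as ``Vmax*F*Phe^2 / (Phe^2 + Km*Phe + Km*Ka)`` so the limit at
    zero substrate is exactly 0.
    """
    p = p or DEFAULT_BLOOD
    f = p.f_pah if f_pah is None else f_pah
    phe_arr = np.asarray(phe, dtype=float)
    if np.any(phe_arr < 0):
        raise InvalidInputError("phe must be >= 0")
    out = (
        p.vmax_pah
        * f
        * phe_arr**2
        / (phe_arr**2 + p.km_pah * phe_arr + p.km_pah * p.ka_pah)
    )
    return float(out) if np.isscalar(phe) or phe_arr.ndim == 0 else out


def trans_rate(phe, p: BloodParams | None = None):
    """Transaminase flux ``Vmax_trans*Phe/(Phe + Km_trans)``, (mmol/L)/hr."""
    p = p or DEFAULT_BLOOD
    phe_arr = np.asarray(phe, dtype=float)
    if np.any(phe_arr < 0):
        raise InvalidInputError("phe must be >= 0")
    out = p.vmax_trans * phe_arr / (phe_arr + p.km_trans)
    return float(out) if np.isscalar(phe) or phe_arr.ndim == 0 else out


def renal_rate(phe, p: BloodParams | None = None):
    """Renal elimination flux ``Phe * CL_renal * Vd``, (mmol/L)/hr (linear)."""
    p = p or DEFAULT_BLOOD
    phe_arr = np.asarray(phe, dtype=float)
    if np.any(phe_arr < 0):
        raise InvalidInputError("phe must be >= 0")
    out = phe_arr * p.cl_renal * p.vd
    return float(out) if np.isscalar(phe) or phe_arr.ndim == 0 else out


def gut_to_plasma_factor(p: BloodParams | None = None) -> float:
    """Conversion from gut Phe (mg) to plasma concentration (mmol/L)."""
    p = p or DEFAULT_BLOOD
    return 1.0 / (p.mw_phe * p.vd * p.weight)


def blood_rhs(t: float, state, p: BloodParams):
    """Time derivative of (plasma Phe mmol/L, gut Phe mg)."""
    phe = max(state[0], 0.0)
    gut = max(state[1], 0.0)
    absorption = p.ka_gut * gut * gut_to_plasma_factor(p)
    dphe = absorption + p.v_npd - pah_rate(phe, p) - trans_rate(phe, p) - renal_rate(phe, p)
    return (dphe, -p.ka_gut * gut)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class BloodResult:
    """Dense blood-model trajectory with the schedule and parameters used."""

    t_hr: np.ndarray
    phe: np.ndarray  # mmol/L
    gut: np.ndarray  # mg
    schedule: MealSchedule
    params: BloodParams
    days: int

    @property
    def series(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_hr": self.t_hr, "phe_mmol_per_L": self.phe, "gut_mg": self.gut}
        )


def simulate_blood(
    days: int,
    schedule: MealSchedule | None = None,
    params: BloodParams | None = None,
    f_pah: float | None = None,
    phe0: float = PKU_INITIAL_PHE,
    gut0: float = 0.0,
    grid_hr: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> BloodResult:
    """Integrate the blood model over ``days`` days of a repeating meal schedule.

    Meal boluses are instantaneous additions to the gut depot; the solver is
    restarted at each discontinuity.  The trajectory runs to hour ``24*days``,
    i.e. 14 h past the final 10 h meal of the default schedule.  ``f_pah``
    overrides the activity fraction in ``params`` when given.
    """
    if days < 1:
        raise InvalidInputError("days must be >= 1")
    schedule = schedule or MealSchedule()
    params = params or DEFAULT_BLOOD
    if f_pah is not None:
        params = dataclasses.replace(params, f_pah=f_pah)

    # plain-float RHS closure: equivalent to blood_rhs but avoids per-call
    # array/validation overhead across the many meal-to-meal solver restarts
    f_gp = gut_to_plasma_factor(params)
    vmax_f = params.vmax_pah * params.f_pah
    km, ka = params.km_pah, params.ka_pah
    vmax_tr, km_tr = params.vmax_trans, params.km_trans
    cl_vd = params.cl_renal * params.vd
    ka_gut, v_npd = params.ka_gut, params.v_npd

    def _rhs(t, y):
        phe = y[0] if y[0] > 0.0 else 0.0
        gut = y[1] if y[1] > 0.0 else 0.0
        pah = vmax_f * phe * phe / (phe * phe + km * phe + km * ka)
        trans = vmax_tr * phe / (phe + km_tr)
        dphe = ka_gut * gut * f_gp + v_npd - pah - trans - phe * cl_vd
        return (dphe, -ka_gut * gut)

    boluses = schedule.meal_boluses_mg()
    events: list[tuple[float, float]] = []
    for day in range(days):
        for tod, mg in boluses:
            events.append((day * 24.0 + tod, mg))
    events.sort()
    t_end = 24.0 * days

    t_out: list[np.ndarray] = []
    y_out: list[np.ndarray] = []
    t_cur = 0.0
    y_cur = np.array([float(phe0), float(gut0)])
    # apply any bolus at t = 0 before the first segment
    pending = [(t, mg) for t, mg in events]
    idx = 0
    while idx < len(pending) and pending[idx][0] <= t_cur + 1e-12:
        y_cur[1] += pending[idx][1]
        idx += 1
    breakpoints = [t for t, _ in pending[idx:]] + [t_end]
    for t_next in breakpoints:
        if t_next > t_cur + 1e-12:
            n_steps = max(int(round((t_next - t_cur) / grid_hr)), 1)
            t_eval = np.linspace(t_cur, t_next, n_steps + 1)
            sol = solve_ivp(
                _rhs,
                (t_cur, t_next),
                y_cur,
                method="LSODA",
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise IntegrationError(
                    f"blood simulation failed at t={t_cur:.2f} h "
                    f"(state {y_cur}): {sol.message}"
                )
            t_out.append(sol.t)
            y_out.append(sol.y)
            t_cur = t_next
            y_cur = sol.y[:, -1].copy()
        if idx < len(pending) and abs(pending[idx][0] - t_cur) <= 1e-12:
            while idx < len(pending) and abs(pending[idx][0] - t_cur) <= 1e-12:
                y_cur[1] += pending[idx][1]
                idx += 1
    t_all = np.concatenate(t_out)
    y_all = np.concatenate(y_out, axis=1)
    return BloodResult(
        t_hr=t_all,
        phe=y_all[0],
        gut=y_all[1],
        schedule=schedule,
        params=params,
        days=days,
    )


def fasting_phe(result: BloodResult, schedule: MealSchedule | None = None) -> float:
    """Plasma Phe 14 h after the final day's last meal, in umol/L."""
    schedule = schedule or result.schedule
    t_target = (result.days - 1) * 24.0 + max(schedule.meal_times_hr) + 14.0
    if t_target > result.t_hr[-1] + 1e-9:
        raise InvalidInputError(
            "trajectory ends before the 14 h post-meal fasting readout"
        )
    return float(np.interp(t_target, result.t_hr, result.phe)) * 1000.0


def fasting_equilibrium(params: BloodParams | None = None, f_pah: float | None = None) -> float:
    """Fasting steady state (no meals): root of V_npd = V_PAH + V_trans + V_renal.

    Returns plasma Phe in mmol/L.
    """
    p = params or DEFAULT_BLOOD
    if f_pah is not None:
        p = dataclasses.replace(p, f_pah=f_pah)

    def g(phe):
        return p.v_npd - pah_rate(phe, p) - trans_rate(phe, p) - renal_rate(phe, p)

    return float(brentq(g, 1e-9, 50.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# Scans and inversion
# ---------------------------------------------------------------------------


def diet_reduction_scan(
    reductions,
    f_pah: float = 0.0,
    base_g_per_day: float = 2.5,
    params: BloodParams | None = None,
    days: int = 180,
    phe0: float = PKU_INITIAL_PHE,
) -> pd.DataFrame:
    """Fasting Phe and percent lowering across fractional dietary reductions."""
    base_sched = MealSchedule(daily_phe_g=base_g_per_day)
    baseline = fasting_phe(
        simulate_blood(days, base_sched, params, f_pah=f_pah, phe0=phe0)
    )
    rows = []
    for r in np.asarray(reductions, dtype=float):
        if not 0.0 <= r <= 1.0:
            raise InvalidInputError("reductions must lie in [0, 1]")
        if r == 0.0:
            fp = baseline
        else:
            sched = MealSchedule(daily_phe_g=base_g_per_day, removal_fraction=float(r))
            fp = fasting_phe(simulate_blood(days, sched, params, f_pah=f_pah, phe0=phe0))
        rows.append(
            {
                "reduction": float(r),
                "fasting_phe_umol_L": fp,
                "pct_lowering": 100.0 * (1.0 - fp / baseline),
            }
        )
    return pd.DataFrame(rows)


def required_consumption_for_lowering(
    target_pct: float,
    f_pah: float = 0.0,
    base_g_per_day: float = 2.5,
    params: BloodParams | None = None,
    days: int = 180,
    phe0: float = PKU_INITIAL_PHE,
    tol_mg: float = 1.0,
) -> float:
    """Daily luminal Phe consumption (mg/day) producing a target % lowering.

    Bracketed root-finding over the removal amount, split across meals in
    proportion to their Phe content.  Raises if the target exceeds the
    lowering achievable by removing the entire diet.
    """
    if target_pct == 0.0:
        return 0.0
    if target_pct < 0:
        raise InvalidInputError("target_pct must be >= 0")
    base_sched = MealSchedule(daily_phe_g=base_g_per_day)
    baseline = fasting_phe(
        simulate_blood(days, base_sched, params, f_pah=f_pah, phe0=phe0)
    )
    total_mg = base_g_per_day * 1000.0

    def lowering(removal_mg_per_day: float) -> float:
        sched = MealSchedule(
            daily_phe_g=base_g_per_day,
            removal_mg_per_meal=removal_mg_per_day / len(base_sched.meal_times_hr),
        )
        fp = fasting_phe(simulate_blood(days, sched, params, f_pah=f_pah, phe0=phe0))
        return 100.0 * (1.0 - fp / baseline)

    max_lowering = lowering(total_mg)
    if target_pct >= max_lowering:
        raise InvalidInputError(
            f"target {target_pct}% exceeds the {max_lowering:.1f}% achievable "
            "by removing the entire dietary intake"
        )
    return float(
        brentq(lambda m: lowering(m) - target_pct, 0.0, total_mg, xtol=tol_mg)
    )


def elimination_attribution(
    result: BloodResult,
    params: BloodParams | None = None,
    window_hr: float = 24.0,
) -> dict[str, float]:
    """Fractional share of PAH / transaminase / renal elimination.

    Integrates each elimination flux over the final ``window_hr`` of the
    trajectory (trapezoidal rule on the stored grid) and normalises.
    """
    p = params or result.params
    mask = result.t_hr >= result.t_hr[-1] - window_hr + 1e-9
    t = result.t_hr[mask]
    phe = np.clip(result.phe[mask], 0.0, None)
    integrals = {
        "pah": float(np.trapezoid(pah_rate(phe, p), t)),
        "trans": float(np.trapezoid(trans_rate(phe, p), t)),
        "renal": float(np.trapezoid(renal_rate(phe, p), t)),
    }
    total = sum(integrals.values())
    if total == 0.0:
        raise InvalidInputError("no elimination flux in the attribution window")
    return {k: v / total for k, v in integrals.items()}
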