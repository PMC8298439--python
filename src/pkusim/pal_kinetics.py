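"""Whole-cell phenylalanine ammonia lyase (PAL) kinetics.

An engineered gut bacterium expressing PAL converts L-phenylalanine (Phe) to
trans-cinnamic acid (TCA) in a single irreversible step.  Because Phe must be
imported into the cell before it reaches the cytosolic enzyme, kinetics are
parameterised at the whole-cell level: each cell counts as one enzyme
equivalent and the maximal rate is expressed per 10^9 CFU.  The rate law is
Michaelis-Menten with two multiplicative inhibition terms,

    v = Vmax / (1 + Km/Phe) * Cells * Ki_pH * Ki_TCA

where Ki_pH is a linear function of environmental pH clamped to [0, 1] and
Ki_TCA is a decaying exponential in the extracellular TCA concentration
(product inhibition with a nonzero floor).

This module provides the rate law, a closed-batch in vitro simulator, and
nonlinear least-squares fitters for each of the three calibration experiments
(rate vs substrate, relative activity vs pH, relative activity vs TCA).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.stats import t as t_dist

logger = logging.getLogger("pkusim")

#: Cell-density unit for Vmax: rates are per 1e9 CFU.
CFU_PER_VMAX_UNIT = 1.0e9


class InvalidInputError(ValueError):
    """An argument is outside the physical domain of the model."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a solution."""


class FitError(RuntimeError):
    """A nonlinear fit did not converge."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class PALKinetics:
    """Whole-cell PAL rate parameters with 95% CIs and inhibition coefficients.

    Units: ``km_pal`` in umol/mL (= mM); ``vmax_pal`` in umol/(min x 1e9 CFU).
    The inhibition coefficients parameterise
    ``Ki_pH = clamp(slope*pH + intercept, 0, 1)`` and
    ``Ki_TCA = amp*exp(-rate*TCA_mM) + floor``.
    """

    km_pal: float = 0.0184
    vmax_pal: float = 0.0162
    km_lo: float = 0.005
    km_hi: float = 0.0442
    vmax_lo: float = 0.0154
    vmax_hi: float = 0.0171
    ki_ph_slope: float = 0.25
    ki_ph_intercept: float = -0.7
    ki_tca_amp: float = 0.67
    ki_tca_rate: float = 0.53
    ki_tca_floor: float = 0.33

    def __post_init__(self) -> None:
        if not (self.km_pal > 0 and self.vmax_pal > 0):
            raise InvalidInputError("km_pal and vmax_pal must be positive")
        if not (self.km_lo <= self.km_pal <= self.km_hi):
            raise InvalidInputError("km_pal must lie within [km_lo, km_hi]")
        if not (self.vmax_lo <= self.vmax_pal <= self.vmax_hi):
            raise InvalidInputError("vmax_pal must lie within [vmax_lo, vmax_hi]")

    def activity_corner(self, which: str) -> "PALKinetics":
        """Return the CI-corner parameter set bounding PAL activity.

        ``"upper"`` pairs the low Km with the high Vmax (fastest plausible
        enzyme), ``"lower"`` the high Km with the low Vmax.  Km and Vmax are
        treated as independent since only marginal CIs are available.
        """
        if which == "upper":
            return dataclasses.replace(self, km_pal=self.km_lo, vmax_pal=self.vmax_hi)
        if which == "lower":
            return dataclasses.replace(self, km_pal=self.km_hi, vmax_pal=self.vmax_lo)
        raise InvalidInputError(f"unknown corner {which!r}; use 'upper' or 'lower'")


DEFAULT_PAL = PALKinetics()


# ---------------------------------------------------------------------------
# Rate law
# ---------------------------------------------------------------------------


def ki_ph(ph, params: PALKinetics | None = None):
    """pH inhibition multiplier: ``clamp(slope*pH + intercept, 0, 1)``.

    The raw line crosses 0 near pH 2.8 and 1 near pH 6.8 for the default
    coefficients; clamping keeps the multiplier in its stated [0, 1] range.
    Accepts scalars or arrays.
    """
    p = params or DEFAULT_PAL
    ph_arr = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph_arr)):
        raise InvalidInputError("pH must be finite")
    raw = p.ki_ph_slope * ph_arr + p.ki_ph_intercept
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if np.isscalar(ph) or ph_arr.ndim == 0 else out


def ki_tca(tca_mM, params: PALKinetics | None = None):
    """TCA product-inhibition multiplier: ``amp*exp(-rate*TCA) + floor``.

    ``tca_mM`` is the extracellular TCA concentration in mM (= umol/mL).
    Strictly decreasing from ``amp + floor`` (1.0 for the defaults) to the
    asymptotic floor.
    """
    p = params or DEFAULT_PAL
    tca_arr = np.asarray(tca_mM, dtype=float)
    if not np.all(np.isfinite(tca_arr)) or np.any(tca_arr < 0):
        raise InvalidInputError("TCA concentration must be finite and >= 0")
    out = p.ki_tca_amp * np.exp(-p.ki_tca_rate * tca_arr) + p.ki_tca_floor
    return float(out) if np.isscalar(tca_mM) or tca_arr.ndim == 0 else out


def pal_flux(
    phe_conc,
    cells,
    ph,
    tca_conc,
    params: PALKinetics | None = None,
):
    """Rate of Phe -> TCA conversion, in umol/(mL min).

    Parameters
    ----------
    phe_conc, tca_conc : float
        Concentrations in umol/mL (= mM).
    cells : float
        Cell density in CFU/mL; internally scaled to 1e9-CFU units to match
        the per-10^9-CFU Vmax.
    ph : float
        Environmental pH.

    The saturating form is evaluated as ``Vmax*S/(S + Km)`` so the limit at
    zero substrate is exactly 0.
    """
    p = params or DEFAULT_PAL
    phe = np.asarray(phe_conc, dtype=float)
    cell = np.asarray(cells, dtype=float)
    if np.any(phe < 0) or np.any(cell < 0):
        raise InvalidInputError("phe_conc and cells must be >= 0")
    sat = p.vmax_pal * phe / (phe + p.km_pal)
    out = sat * (cell / CFU_PER_VMAX_UNIT) * ki_ph(ph, p) * ki_tca(tca_conc, p)
    if np.isscalar(phe_conc) and np.isscalar(cells):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Closed-batch (in vitro) simulation
# ---------------------------------------------------------------------------


def simulate_invitro_batch(
    phe0: float,
    cells: float,
    ph: float,
    duration: float,
    params: PALKinetics | None = None,
    record_times: Sequence[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Simulate a closed batch incubation (fixed pH, fixed cell density).

    Integrates ``dPhe/dt = -v``, ``dTCA/dt = +v`` with the product-inhibition
    term evaluated at the instantaneous TCA concentration, starting from
    ``(phe0, TCA=0)``.  Mass is conserved: ``Phe(t) + TCA(t) = phe0``.

    Returns a DataFrame with columns ``t`` (min), ``phe``, ``tca`` (umol/mL),
    ``cells`` (CFU/mL) and ``ph``.
    """
    p = params or DEFAULT_PAL
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    if phe0 < 0 or cells < 0:
        raise InvalidInputError("phe0 and cells must be >= 0")
    if record_times is None:
        record_times = np.linspace(0.0, duration, 121)
    record_times = np.asarray(record_times, dtype=float)

    def rhs(t, y):
        phe, tca = max(y[0], 0.0), max(y[1], 0.0)
        v = pal_flux(phe, cells, ph, tca, p)
        return (-v, v)

    sol = solve_ivp(
        rhs,
        (0.0, float(duration)),
        (float(phe0), 0.0),
        method="LSODA",
        t_eval=record_times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"batch simulation failed: {sol.message}")
    return pd.DataFrame(
        {
            "t": sol.t,
            "phe": sol.y[0],
            "tca": sol.y[1],
            "cells": cells,
            "ph": ph,
        }
    )


# ---------------------------------------------------------------------------
# Rate datasets and fit results
# ---------------------------------------------------------------------------


@dataclass
class RateDataset:
    """Tabular (predictor, response) rate data with optional replicate labels.

    ``x`` is Phe concentration (umol/mL), pH, or TCA (mM) depending on the
    assay; ``y`` is a rate in umol/(min 1e9 CFU) or a relative activity
    fraction.
    """

    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise InvalidInputError("x and y must be 1-D arrays of equal length")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.x.shape:
                raise InvalidInputError("replicate labels must match x in length")

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.x).size)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        if self.replicate is not None:
            df["replicate"] = self.replicate
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RateDataset":
        df = pd.read_csv(path)
        for col in ("x", "y"):
            if col not in df.columns:
                raise InvalidInputError(f"rate dataset CSV missing column {col!r}")
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(df["x"].to_numpy(float), df["y"].to_numpy(float), rep)


@dataclass
class FitResult:
    """Point estimates, asymptotic 95% CIs and goodness of fit."""

    params: dict[str, float]
    ci: dict[str, tuple[float, float]]
    r_squared: float
    n: int
    message: str = "ok"

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "r_squared": None if math.isnan(self.r_squared) else self.r_squared,
            "n": self.n,
            "message": self.message,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return math.nan
    return 1.0 - ss_res / ss_tot


def _asymptotic_ci(
    residual: Callable[[np.ndarray], np.ndarray],
    theta: np.ndarray,
    n: int,
    jac: np.ndarray,
) -> list[tuple[float, float]]:
    """95% Wald intervals from the Jacobian at the solution."""
    dof = max(n - theta.size, 1)
    s2 = float(np.sum(residual(theta) ** 2)) / dof
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(theta.size, np.inf)
    tq = t_dist.ppf(0.975, dof)
    return [(float(th - tq * s), float(th + tq * s)) for th, s in zip(theta, se)]


def _multistart_least_squares(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds,
) -> optimize.OptimizeResult:
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residual, x0, bounds=bounds, method="trf",
                ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
        except Exception:  # singular Jacobian at a bad start etc.
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("nonlinear least squares failed from all starts")
    return best


def fit_michaelis_menten(data: RateDataset) -> FitResult:
    """Fit ``rate = Vmax*S/(S + Km)`` to (concentration, rate) data.

    Requires at least 3 distinct substrate concentrations.  Returns point
    estimates, asymptotic 95% CIs and R^2.
    """
    if data.n_distinct < 3:
        raise InvalidInputError("need >= 3 distinct concentrations for an MM fit")
    x, y = data.x, data.y

    def model(theta):
        km, vmax = theta
        return vmax * x / (x + km)

    def residual(theta):
        return model(theta) - y

    vmax0 = float(np.max(y)) if np.max(y) > 0 else 1.0
    # method-of-moments Km: concentration where the response crosses half max
    half = vmax0 / 2.0
    order = np.argsort(x)
    km0 = float(np.interp(half, y[order], x[order]))
    km0 = km0 if km0 > 0 else float(np.median(x))
    starts = [np.array([km0 * f, vmax0]) for f in (0.3, 1.0, 3.0)]
    best = _multistart_least_squares(residual, starts, ([1e-12, 1e-12], [np.inf, np.inf]))
    km, vmax = best.x
    ci = _asymptotic_ci(residual, best.x, x.size, best.jac)
    return FitResult(
        params={"km": float(km), "vmax": float(vmax)},
        ci={"km": ci[0], "vmax": ci[1]},
        r_squared=_r_squared(y, model(best.x)),
        n=x.size,
    )


def fit_ph_linear(data: RateDataset) -> FitResult:
    """Ordinary least-squares line through (pH, relative activity) data.

    Slope and intercept populate the Ki_pH coefficients.  Constant responses
    are flagged as degenerate (slope 0, undefined R^2).
    """
    if data.n_distinct < 3:
        raise InvalidInputError("need >= 3 distinct pH values for a linear fit")
    x, y = data.x, data.y
    n = x.size
    if np.ptp(y) == 0.0:
        return FitResult(
            params={"slope": 0.0, "intercept": float(y[0])},
            ci={"slope": (0.0, 0.0), "intercept": (float(y[0]), float(y[0]))},
            r_squared=math.nan,
            n=n,
            message="degenerate: constant response, R^2 undefined",
        )
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    dof = max(n - 2, 1)
    s2 = float(np.sum((y - yhat) ** 2)) / dof
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_slope = math.sqrt(s2 / sxx)
    se_inter = math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    tq = t_dist.ppf(0.975, dof)
    return FitResult(
        params={"slope": float(slope), "intercept": float(intercept)},
        ci={
            "slope": (float(slope - tq * se_slope), float(slope + tq * se_slope)),
            "intercept": (float(intercept - tq * se_inter), float(intercept + tq * se_inter)),
        },
        r_squared=_r_squared(y, yhat),
        n=n,
    )


def fit_tca_exponential(data: RateDataset) -> FitResult:
    """Fit ``y = a*exp(-k*x) + c`` to (TCA, relative activity) data.

    Requires >= 4 distinct TCA levels including 0 (so the amplitude and floor
    are identifiable).  A flat dataset converges to k -> 0 and is flagged.
    """
    if data.n_distinct < 4:
        raise InvalidInputError("need >= 4 distinct TCA levels for an exponential fit")
    if np.min(data.x) > 0:
        raise InvalidInputError("TCA design must include the uninhibited 0 level")
    x, y = data.x, data.y

    def model(theta):
        a, k, c = theta
        return a * np.exp(-k * x) + c

    def residual(theta):
        return model(theta) - y

    c0 = float(np.min(y))
    a0 = max(float(np.max(y)) - c0, 1e-6)
    # log-linear initial decay-rate guess from points clearly above the floor
    above = y > c0 + 0.05 * a0
    if np.count_nonzero(above) >= 2:
        z = np.log(np.clip(y[above] - c0 * 0.999, 1e-12, None))
        k0 = max(-np.polyfit(x[above], z, 1)[0], 1e-3)
    else:
        k0 = 1.0
    starts = [np.array([a0, k0 * f, c0]) for f in (0.3, 1.0, 3.0)]
    best = _multistart_least_squares(
        residual, starts, ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
    )
    a, k, c = best.x
    ci = _asymptotic_ci(residual, best.x, x.size, best.jac)
    message = "ok"
    if k < 1e-4:
        message = "warning: no measurable decay (rate ~ 0)"
    return FitResult(
        params={"amp": float(a), "rate": float(k), "floor": float(c)},
        ci={"amp": ci[0], "rate": ci[1], "floor": ci[2]},
        r_squared=_r_squared(y, model(best.x)),
        n=x.size,
        message=message,
    )
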