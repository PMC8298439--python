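"""Synthetic in vitro datasets with known ground truth.

Generates the three calibration-assay dataset flavors (Michaelis-Menten rate
vs substrate, relative activity vs pH, relative activity vs TCA) and a batch
gastric-simulation time course, each from the forward model with configurable
multiplicative noise.  Used for parameter-recovery and regression testing; no
external data are required.

Noise model: responses are multiplied by ``exp(sigma * z)`` with ``z`` standard
normal and ``sigma = sqrt(log(1 + cv^2))``, i.e. lognormal with coefficient of
variation ``noise_cv`` and median equal to the model value.  Multiplicative
noise matches how assay CVs scale with signal and never produces negative
responses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pal_kinetics import (
    InvalidInputError,
    PALKinetics,
    RateDataset,
    simulate_invitro_batch,
)

logger = logging.getLogger("pkusim")

#: Serial two-fold dilution of Phe used for the rate-vs-substrate assay, mM.
MM_DESIGN_MM = (0.312, 0.625, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0)
#: pH levels for the activity-vs-pH assay.
PH_DESIGN = (4.0, 5.0, 6.0, 7.0)
#: Exogenous TCA levels for the product-inhibition assay, mM.
TCA_DESIGN_MM = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)

FLAVORS = ("mm_rates", "ph_activity", "tca_inhibition", "ivs_timecourse")


@dataclass
class FixtureSpec:
    """Specification of one synthetic dataset.

    ``endpoint_min`` (mm_rates only): when set, rates are derived from a batch
    simulation as ``TCA(endpoint)/endpoint`` per 1e9 CFU — the endpoint assay
    convention — instead of the instantaneous rate law.  The default
    instantaneous convention round-trips exactly through the fitters.
    """

    flavor: str
    true_params: PALKinetics = field(default_factory=PALKinetics)
    design_points: tuple[float, ...] | None = None
    replicates: int = 3
    noise_cv: float = 0.0
    seed: int = 0
    cells_per_ml: float = 2.5e7
    ph: float = 7.0
    endpoint_min: float | None = None

    def __post_init__(self) -> None:
        if self.flavor not in FLAVORS:
            raise InvalidInputError(
                f"unknown flavor {self.flavor!r}; expected one of {FLAVORS}"
            )
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")


def _default_design(spec: FixtureSpec) -> np.ndarray:
    if spec.design_points is not None:
        return np.asarray(spec.design_points, dtype=float)
    if spec.flavor == "mm_rates":
        return np.asarray(MM_DESIGN_MM)
    if spec.flavor == "ph_activity":
        return np.asarray(PH_DESIGN)
    if spec.flavor == "tca_inhibition":
        return np.asarray(TCA_DESIGN_MM)
    return np.arange(0.0, 121.0, 10.0)  # ivs_timecourse, min


def _noise_factor(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0.0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, shape))


def _mm_forward(spec: FixtureSpec, conc: np.ndarray) -> np.ndarray:
    p = spec.true_params
    if spec.endpoint_min is None:
        return p.vmax_pal * conc / (conc + p.km_pal)
    rates = []
    for s in conc:
        traj = simulate_invitro_batch(
            float(s),
            spec.cells_per_ml,
            spec.ph,
            spec.endpoint_min,
            p,
            record_times=[0.0, spec.endpoint_min],
        )
        tca_end = float(traj["tca"].iloc[-1])
        rates.append(tca_end / spec.endpoint_min / (spec.cells_per_ml / 1e9))
    return np.asarray(rates)


def generate(spec: FixtureSpec):
    """Evaluate the forward model on the design and apply multiplicative noise.

    Returns a :class:`RateDataset` for the three rate flavors, or a DataFrame
    time course (columns t, phe, tca) for ``ivs_timecourse``.  Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    design = _default_design(spec)
    p = spec.true_params

    if spec.flavor == "ivs_timecourse":
        traj = simulate_invitro_batch(
            20.0, spec.cells_per_ml, spec.ph, float(design[-1]), p, record_times=design
        )
        noisy = traj.copy()
        noisy["tca"] = traj["tca"] * _noise_factor(rng, spec.noise_cv, len(traj))
        noisy["phe"] = traj["phe"] * _noise_factor(rng, spec.noise_cv, len(traj))
        return noisy

    x = np.repeat(design, spec.replicates)
    replicate = np.tile(np.arange(spec.replicates), design.size)
    if spec.flavor == "mm_rates":
        y_true = np.repeat(_mm_forward(spec, design), spec.replicates)
    elif spec.flavor == "ph_activity":
        # raw fitted line (relative to pH 7 activity), deliberately unclamped:
        # the clamp belongs to the inhibition term, not the assay response
        y_true = p.ki_ph_slope * x + p.ki_ph_intercept
    else:  # tca_inhibition
        y_true = p.ki_tca_amp * np.exp(-p.ki_tca_rate * x) + p.ki_tca_floor
    y = y_true * _noise_factor(rng, spec.noise_cv, x.shape)
    return RateDataset(x=x, y=y, replicate=replicate)


def ground_truth(spec: FixtureSpec) -> dict[str, float]:
    """Ground-truth parameter subset matching the flavor's fitter."""
    p = spec.true_params
    if spec.flavor == "mm_rates":
        return {"km": p.km_pal, "vmax": p.vmax_pal}
    if spec.flavor == "ph_activity":
        return {"slope": p.ki_ph_slope, "intercept": p.ki_ph_intercept}
    if spec.flavor == "tca_inhibition":
        return {"amp": p.ki_tca_amp, "rate": p.ki_tca_rate, "floor": p.ki_tca_floor}
    return {
        "km": p.km_pal,
        "vmax": p.vmax_pal,
        "cells_per_ml": spec.cells_per_ml,
        "ph": spec.ph,
    }


def write_fixture(spec: FixtureSpec, csv_path, truth_path=None) -> None:
    """Write the dataset as CSV plus a sidecar JSON of ground-truth parameters."""
    data = generate(spec)
    if isinstance(data, RateDataset):
        data.to_csv(csv_path)
    else:
        data.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(
                {"flavor": spec.flavor, "seed": spec.seed, "truth": ground_truth(spec)},
                fh,
                indent=2,
            )
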