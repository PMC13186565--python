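"""Fate-model predictions under perturbations.

Three idealized perturbations of the stochastic-deterministic model:

* **burst_up** — a chromatin-level perturbation (Set1/COMPASS loss-like)
  that raises the per-interval expression probability of the stochastic
  genes by ``delta_p``.  Since the CCIF mean is ``mu = G*p_bar*x_bar``,
  this shifts the whole sensitivity distribution up and raises stalk
  propensity at every cycle position.  At the single-gene level the same
  change lowers CV² (burst-frequency increase).
* **cycle_arrest** — a cold-shock-like block that holds all cells at one
  cycle time ``arrest_t``, removing the deterministic time dependence.
* **combined** — both at once: a flat curve at the shifted propensity,
  the regime where proportioning fails dramatically.

Predicted curves shift the model mean only (holding sigma at its baseline
value); :func:`perturb_ensemble` recomputes both mu and sigma² for the
ensemble object itself when the full moments are wanted.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fate_model import (
    CCIFEnsemble,
    FateModelParams,
    average_propensity,
    propensity_combined,
)

__all__ = [
    "PerturbationKind",
    "PerturbationScenario",
    "perturb_ensemble",
    "predict_propensity_curve",
    "responsive_fraction",
]


class PerturbationKind(str, enum.Enum):
    NONE = "none"
    BURST_UP = "burst_up"
    CYCLE_ARREST = "cycle_arrest"
    COMBINED = "combined"


@dataclass(frozen=True)
class PerturbationScenario:
    """A perturbation: change to p_bar (``delta_p``) and/or an arrest time."""

    kind: PerturbationKind = PerturbationKind.NONE
    delta_p: float = 0.0
    arrest_t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PerturbationKind(self.kind))
        if self.arrest_t < 0:
            raise ValueError("arrest_t must be >= 0 hours")


def perturb_ensemble(ens: CCIFEnsemble, delta_p: float) -> CCIFEnsemble:
    """Shift the ensemble's burst probability; mu and sigma² follow.

    Raising p_bar raises mu = G*p_bar*x_bar (more cells responsive) while
    each gene's CV² = (1-p)/p + eps²/(p b²) falls — higher mean, lower
    relative variability.
    """
    new_p = ens.p_bar + delta_p
    if not 0.0 <= new_p <= 1.0:
        raise ValueError(f"perturbed p_bar = {new_p} outside [0, 1]")
    return replace(ens, p_bar=new_p)


def _mean_shift(params: FateModelParams, scenario: PerturbationScenario) -> float:
    """Sensitivity-mean shift Δmu = G * delta_p * x_bar for burst_up-type
    scenarios; 0 otherwise.  Requires an ensemble-backed model when
    delta_p != 0."""
    if scenario.kind in (PerturbationKind.BURST_UP, PerturbationKind.COMBINED):
        if scenario.delta_p == 0.0:
            return 0.0
        if params.ccif is None:
            raise ValueError("delta_p perturbations need an ensemble-backed model")
        perturb_ensemble(params.ccif, scenario.delta_p)  # validates range
        return params.ccif.G * scenario.delta_p * params.ccif.x_bar
    return 0.0


def _shifted(params: FateModelParams, dmu: float) -> FateModelParams:
    """Model with the CCIF mean shifted by dmu, sigma held at baseline."""
    if dmu == 0.0:
        return params
    return FateModelParams(decay=params.decay, R=params.R,
                           mu=params.mu + dmu, sigma=params.sigma)


def predict_propensity_curve(params: FateModelParams,
                             scenario: PerturbationScenario,
                             t_grid) -> pd.DataFrame:
    """Baseline and perturbed propensity over a time grid.

    burst_up shifts the curve's mean up at every t; cycle_arrest replaces
    the curve with a constant at P(arrest_t); combined is a constant at
    the shifted P(arrest_t).
    """
    t = np.asarray(list(t_grid), dtype=float)
    baseline = np.asarray(propensity_combined(params, t), dtype=float)
    shifted = _shifted(params, _mean_shift(params, scenario))
    if scenario.kind in (PerturbationKind.CYCLE_ARREST, PerturbationKind.COMBINED):
        level = float(propensity_combined(shifted, scenario.arrest_t))
        perturbed = np.full_like(t, level)
    else:
        perturbed = np.asarray(propensity_combined(shifted, t), dtype=float)
    return pd.DataFrame({"t": t, "baseline": baseline, "perturbed": perturbed})


def responsive_fraction(params: FateModelParams,
                        scenario: PerturbationScenario,
                        dose_shift: float = 0.0,
                        t_max: float = 5.0) -> float:
    """Fraction of a t-uniform population in the signal-responsive state.

    Signal dose is modelled as a monotone shift of the effective
    threshold: ``R_eff = R - dose_shift * sigma`` (log-dose maps linearly
    onto ``dose_shift``).  With no dose shift and no perturbation this is
    exactly the window-averaged propensity; it increases with dose and
    with delta_p, and tends to 1 as the dose grows without bound.
    """
    if not math.isfinite(dose_shift):
        return 1.0 if dose_shift > 0 else 0.0
    shifted = _shifted(params, _mean_shift(params, scenario))
    eff = FateModelParams(decay=shifted.decay,
                          R=shifted.R - dose_shift * shifted.sigma,
                          mu=shifted.mu, sigma=shifted.sigma)
    if scenario.kind in (PerturbationKind.CYCLE_ARREST, PerturbationKind.COMBINED):
        return float(propensity_combined(eff, scenario.arrest_t))
    return average_propensity(eff, 0.0, t_max)
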