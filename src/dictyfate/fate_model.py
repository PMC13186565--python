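"""Closed-form forward model of probabilistic stalk/spore fate choice.

Sensitivity of a *Dictyostelium* cell to stalk-inducing signals is modelled
as the sum of two components:

* **CCAF** (cell-cycle-associated factor): deterministic, maximal just after
  mitosis and decaying through the cycle, ``A_t = A0 - beta*t`` for the
  default linear shape.
* **CCIF** (cell-cycle-independent factor): stochastic, the sum of the
  contributions of ``G`` telegraph-expressed genes.  Each gene is expressed
  in a given interval with probability ``p_bar`` and, when expressed,
  contributes an amount drawn from ``Normal(x_bar, s2)``.  The sum is
  approximately Gaussian with mean ``mu = G*p_bar*x_bar`` and variance
  ``sigma2 = G*p_bar*s2 + p_bar*(1-p_bar)*G*x_bar**2``.

A cell adopts stalk fate when total sensitivity exceeds a threshold ``R``,
so the stalk propensity at cycle time ``t`` is the upper tail of the
sensitivity distribution:

    P_t = 1/2 * (1 + erf[(C0 - beta*t - R) / (sigma*sqrt(2))])

with ``C0 = mu + A0``.  Rescaling to standard-deviation units and measuring
sensitivity as distance from the threshold collapses this to the
two-parameter form ``P_t = 1/2*(1 + erf[(C0_star - beta*t)/sqrt(2)])``.

Burst-level statistics for a single gene (mean ``p*b``, variance
``p*eps2 + p*(1-p)*b**2`` and the derived CV²) live here as well.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "DecayKind",
    "CCIFDist",
    "DecayParams",
    "CCIFEnsemble",
    "FateModelParams",
    "BurstGene",
    "ccaf_level",
    "ccif_moments",
    "propensity_stochastic_only",
    "propensity_combined",
    "propensity_rescaled",
    "average_propensity",
    "propensity_gamma",
    "burst_mean_var",
    "burst_cv2",
]

_SQRT2 = math.sqrt(2.0)


class DecayKind(str, enum.Enum):
    """Functional form of CCAF decay through the cell cycle."""

    LINEAR = "linear"
    EXPONENTIAL = "exponential"
    QUADRATIC = "quadratic"
    CUBIC = "cubic"


class CCIFDist(str, enum.Enum):
    """Distributional family assumed for CCIF."""

    GAUSSIAN = "gaussian"
    GAMMA = "gamma"


@dataclass(frozen=True)
class DecayParams:
    """CCAF decay curve parameters.

    Parameters
    ----------
    kind
        Decay shape.  Linear is the default model; exponential, quadratic
        and cubic are alternatives used in model comparison.
    A0
        Starting CCAF level just after the end of mitosis (sensitivity
        units; on the rescaled model these are standard-deviation units).
    beta
        Primary decay rate (sensitivity units per hour), must be >= 0.
    gamma, delta
        Higher-order coefficients, used only by the quadratic/cubic kinds.
    """

    kind: DecayKind = DecayKind.LINEAR
    A0: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        kind = DecayKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if kind in (DecayKind.LINEAR, DecayKind.EXPONENTIAL):
            if self.gamma != 0.0 or self.delta != 0.0:
                raise ValueError(
                    f"gamma/delta are only meaningful for quadratic/cubic decay "
                    f"(kind={kind.value})"
                )
        if kind is DecayKind.QUADRATIC and self.delta != 0.0:
            raise ValueError("delta is only meaningful for cubic decay")


@dataclass(frozen=True)
class CCIFEnsemble:
    """Telegraph-gene ensemble generating CCIF.

    ``G`` genes; each is expressed per interval with probability ``p_bar``
    and contributes ``Normal(x_bar, s2)`` when on.  Derived moments follow
    the law of total variance.
    """

    G: int
    p_bar: float
    x_bar: float
    s2: float

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError(f"G must be >= 1, got {self.G}")
        if not 0.0 <= self.p_bar <= 1.0:
            raise ValueError(f"p_bar must be in [0, 1], got {self.p_bar}")
        if self.s2 < 0:
            raise ValueError(f"s2 must be >= 0, got {self.s2}")

    @property
    def mu(self) -> float:
        """Mean CCIF level, G*p_bar*x_bar."""
        return self.G * self.p_bar * self.x_bar

    @property
    def sigma2(self) -> float:
        """CCIF variance, G*p_bar*s2 + p_bar*(1-p_bar)*G*x_bar**2."""
        return (
            self.G * self.p_bar * self.s2
            + self.p_bar * (1.0 - self.p_bar) * self.G * self.x_bar**2
        )


@dataclass(frozen=True)
class BurstGene:
    """Single-gene bursting parameters: burst probability ``p`` per
    interval, burst size ``b`` and within-on-state variance ``eps2``."""

    p: float
    b: float
    eps2: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if self.eps2 < 0:
            raise ValueError(f"eps2 must be >= 0, got {self.eps2}")


@dataclass(frozen=True)
class FateModelParams:
    """Full parameterization of the stochastic-deterministic fate model.

    Either an explicit ``(mu, sigma)`` pair or a :class:`CCIFEnsemble` (from
    which the moments are derived) describes CCIF.  ``R`` is the stalk-fate
    threshold on the sensitivity scale.  ``C0 = mu + A0`` and the rescaled
    reference ``C0_star = (C0 - R)/sigma`` are derived.
    """

    decay: DecayParams = field(default_factory=DecayParams)
    R: float = 0.0
    mu: Optional[float] = None
    sigma: Optional[float] = None
    ccif: Optional[CCIFEnsemble] = None
    ccif_dist: CCIFDist = CCIFDist.GAUSSIAN
    gamma_shape: Optional[float] = None
    gamma_scale: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ccif_dist", CCIFDist(self.ccif_dist))
        if self.ccif is not None:
            if self.mu is not None or self.sigma is not None:
                raise ValueError("give either ccif ensemble or explicit (mu, sigma)")
            object.__setattr__(self, "mu", self.ccif.mu)
            object.__setattr__(self, "sigma", math.sqrt(self.ccif.sigma2))
        if self.mu is None or self.sigma is None:
            raise ValueError("CCIF must be specified (ensemble or mu/sigma)")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.ccif_dist is CCIFDist.GAMMA:
            if self.gamma_shape is None or self.gamma_scale is None:
                raise ValueError("gamma CCIF requires gamma_shape and gamma_scale")
            if self.gamma_shape <= 0 or self.gamma_scale <= 0:
                raise ValueError("gamma_shape and gamma_scale must be > 0")

    @property
    def C0(self) -> float:
        return self.mu + self.decay.A0

    @property
    def C0_star(self) -> float:
        return (self.C0 - self.R) / self.sigma

    @classmethod
    def from_rescaled(cls, C0_star: float, beta: float,
                      kind: DecayKind | str = DecayKind.LINEAR,
                      gamma: float = 0.0, delta: float = 0.0) -> "FateModelParams":
        """Build the standardized model (sigma=1, R=0, mu=0, A0=C0_star)."""
        return cls(
            decay=DecayParams(kind=DecayKind(kind), A0=C0_star, beta=beta,
                              gamma=gamma, delta=delta),
            R=0.0, mu=0.0, sigma=1.0,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decay"]["kind"] = self.decay.kind.value
        d["ccif_dist"] = self.ccif_dist.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FateModelParams":
        d = dict(d)
        decay = d.pop("decay")
        ccif = d.pop("ccif", None)
        if ccif is not None:  # moments are re-derived from the ensemble
            d.pop("mu", None)
            d.pop("sigma", None)
        return cls(
            decay=DecayParams(**decay),
            ccif=CCIFEnsemble(**ccif) if ccif else None,
            **d,
        )


def ccaf_level(decay: DecayParams, t):
    """CCAF level at time ``t`` (hours after the end of mitosis).

    Linear: ``A0 - beta*t``; exponential: ``A0*exp(-beta*t)``; quadratic
    and cubic append ``-gamma*t**2`` and ``-delta*t**3`` terms.  The value
    may go negative: sensitivity is measured on an effect scale, not as a
    molecular concentration.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (hours post-mitosis)")
    kind = DecayKind(decay.kind)
    if kind is DecayKind.LINEAR:
        out = decay.A0 - decay.beta * t
    elif kind is DecayKind.EXPONENTIAL:
        out = decay.A0 * np.exp(-decay.beta * t)
    elif kind is DecayKind.QUADRATIC:
        out = decay.A0 - decay.beta * t - decay.gamma * t**2
    elif kind is DecayKind.CUBIC:
        out = decay.A0 - decay.beta * t - decay.gamma * t**2 - decay.delta * t**3
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown decay kind: {decay.kind!r}")
    return out if out.ndim else float(out)


def ccif_moments(ens: CCIFEnsemble) -> tuple[float, float]:
    """Mean and variance of the CCIF sum over the telegraph ensemble."""
    return ens.mu, ens.sigma2


def propensity_stochastic_only(mu: float, sigma: float, R: float):
    """Stalk propensity when only CCIF (no cell-cycle input) matters.

    ``P = 1/2*(1 + erf[(mu - R)/(sigma*sqrt(2))])`` — the upper tail of
    ``Normal(mu, sigma^2)`` above the threshold ``R``; constant in time.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    z = (np.asarray(mu, dtype=float) - R) / (sigma * _SQRT2)
    out = 0.5 * (1.0 + special.erf(z))
    return out if out.ndim else float(out)


def propensity_combined(params: FateModelParams, t):
    """Stalk propensity at cycle time ``t`` under the combined model.

    ``P_t = 1/2*(1 + erf[(A_t + mu - R)/(sigma*sqrt(2))])``.  For the
    linear decay this is the printed three-constant form with
    ``C0 = mu + A0``.  Dispatches to the gamma tail when the model uses
    gamma-distributed CCIF.
    """
    if params.ccif_dist is CCIFDist.GAMMA:
        return propensity_gamma(params, t)
    a_t = ccaf_level(params.decay, t)
    c_t = np.asarray(a_t, dtype=float) + params.mu
    z = (c_t - params.R) / (params.sigma * _SQRT2)
    out = 0.5 * (1.0 + special.erf(z))
    return out if out.ndim else float(out)


def propensity_rescaled(C0_star: float, beta: float, t):
    """Two-parameter standardized model: ``1/2*(1+erf[(C0*-beta*t)/sqrt(2)])``.

    Identical to :func:`propensity_combined` with sigma=1, R=0, C0=C0_star;
    both parameters are in standard-deviation units.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = 0.5 * (1.0 + special.erf((C0_star - beta * t) / _SQRT2))
    return out if out.ndim else float(out)


def average_propensity(params: FateModelParams, t_min: float = 0.0,
                       t_max: float = 5.0) -> float:
    """Uniform time-average of P_t over ``[t_min, t_max]``.

    With cells spread uniformly through the window this is the expected
    population stalk fraction ("steady-state" propensity for the fitted
    0-5 hr window).  Adaptive quadrature, absolute tolerance <= 1e-9.
    """
    if not t_max > t_min or t_min < 0:
        raise ValueError(f"need t_max > t_min >= 0, got [{t_min}, {t_max}]")
    val, _ = integrate.quad(lambda u: propensity_combined(params, u),
                            t_min, t_max, epsabs=1e-9, limit=200)
    return val / (t_max - t_min)


def propensity_gamma(params: FateModelParams, t):
    """Stalk propensity with gamma-distributed CCIF added to CCAF.

    ``P_t = P(Gamma(shape, scale) > R - A_t)``; 1 whenever the residual
    threshold ``R - A_t`` falls at or below zero (the gamma has
    non-negative support).
    """
    if params.gamma_shape is None or params.gamma_scale is None:
        raise ValueError("model has no gamma CCIF parameters")
    if params.gamma_shape <= 0 or params.gamma_scale <= 0:
        raise ValueError("gamma_shape and gamma_scale must be > 0")
    a_t = np.asarray(ccaf_level(params.decay, t), dtype=float)
    resid = params.R - a_t
    out = np.where(
        resid <= 0, 1.0,
        stats.gamma.sf(np.maximum(resid, 0.0), a=params.gamma_shape,
                       scale=params.gamma_scale),
    )
    return out if out.ndim else float(out)


def burst_mean_var(g: BurstGene) -> tuple[float, float]:
    """Cross-cell mean and variance of a bursting gene's expression.

    Mean ``p*b``; variance ``p*eps2 + p*(1-p)*b**2`` (a point mass at 0
    with probability 1-p mixed with ``Normal(b, eps2)``).
    """
    mean = g.p * g.b
    var = g.p * g.eps2 + g.p * (1.0 - g.p) * g.b**2
    return mean, var


def burst_cv2(g: BurstGene) -> float:
    """Squared coefficient of variation, ``(1-p)/p + eps2/(p*b**2)``.

    Strictly decreasing in burst probability ``p``: raising burst
    frequency lowers cell-cell variability even as the mean rises.
    """
    if g.p <= 0 or g.b <= 0:
        raise ValueError("CV2 is undefined for p=0 or b=0")
    return (1.0 - g.p) / g.p + g.eps2 / (g.p * g.b**2)
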