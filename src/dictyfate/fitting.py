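"""Normalization, nonlinear least-squares fitting and AIC model comparison
for stalk-propensity time courses.

A time course is a table of (set label, hours post-mitosis, stalk
propensity) observations.  Multiple strain x condition sets are combined
by shifting each set so its mean propensity matches the global mean, named
outliers may be removed (after which the remaining raw values are
re-normalized), and the two-parameter standardized model

    P_t = 1/2 * (1 + erf[(C0_star - beta*t)/sqrt(2)])

or one of its variants (exponential / quadratic / cubic CCAF decay,
gamma-distributed CCIF) is fitted by Levenberg-Marquardt from a
deterministic multi-start grid.  Fits are compared by Gaussian-likelihood
AIC and relative likelihoods exp(dAIC/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .fate_model import DecayKind, FateModelParams, propensity_rescaled

__all__ = [
    "PropensityTimecourse",
    "FitResult",
    "ModelComparison",
    "read_timecourse",
    "normalize_propensity_sets",
    "remove_outlier",
    "flag_outliers",
    "fit_model",
    "aic",
    "adjusted_r2",
    "relative_likelihood",
    "compare_models",
]

AIC_SENTINEL = -np.inf

#: model kinds accepted by fit_model / compare_models
MODEL_KINDS = ("linear", "exponential", "quadratic", "cubic", "gamma_ccif")


@dataclass(frozen=True)
class PropensityTimecourse:
    """Stalk-propensity observations across one or more experimental sets.

    ``data`` has columns ``set`` (strain x condition label), ``t`` (hours
    post-mitosis) and ``propensity``.  When ``adjusted`` is True the
    ``propensity`` column holds set-mean-matched values; the original raw
    values are retained in ``raw_propensity``.
    """

    data: pd.DataFrame
    adjusted: bool = False
    excluded_points: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = self.data
        missing = {"set", "t", "propensity"} - set(df.columns)
        if missing:
            raise ValueError(f"timecourse missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("empty timecourse")
        if (df["t"] < 0).any():
            raise ValueError("timepoints must be >= 0 hours")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def n_points(self) -> int:
        return len(self.data)

    def values(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, propensity) arrays used for fitting."""
        return (self.data["t"].to_numpy(float),
                self.data["propensity"].to_numpy(float))


def read_timecourse(path, adjusted: bool = False) -> PropensityTimecourse:
    """Read a TSV/CSV with columns set, timepoint_hr, propensity.

    ``adjusted=True`` declares that the file already holds set-adjusted
    values (e.g. a supplementary table) so normalization is not re-applied.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={"timepoint_hr": "t"})
    tc = PropensityTimecourse(df[["set", "t", "propensity"]])
    if adjusted:
        tc = replace(tc, adjusted=True)
    return tc


def _renormalize(df: pd.DataFrame) -> pd.DataFrame:
    """Shift each set so its mean matches the global mean of raw values."""
    out = df.copy()
    raw = out["raw_propensity"] if "raw_propensity" in out else out["propensity"]
    out["raw_propensity"] = raw
    global_mean = raw.mean()
    shift = global_mean - raw.groupby(out["set"]).transform("mean")
    adj = raw + shift
    clipped = adj.clip(0.0, 1.0)
    if not np.allclose(adj, clipped):
        warnings.warn("normalization pushed propensities outside [0, 1]; clipped")
    out["propensity"] = clipped
    return out


def normalize_propensity_sets(raw: PropensityTimecourse) -> PropensityTimecourse:
    """Combine sets by matching each set's mean propensity to the global mean.

    A single set is returned unchanged (its mean is the global mean).  The
    shift is additive per set; the global mean of the combined data is
    preserved exactly whenever no value has to be clipped into [0, 1].
    """
    counts = raw.data.groupby("set").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"each set needs >= 2 timepoints; too small: {bad}")
    return PropensityTimecourse(
        _renormalize(raw.data), adjusted=True, excluded_points=raw.excluded_points
    )


def remove_outlier(data: PropensityTimecourse, set_label: str,
                   t: float) -> PropensityTimecourse:
    """Remove one named (set, t) observation and re-normalize.

    Mirrors by-name outlier handling: the point is dropped from the raw
    values, the set-mean adjustment is re-run on what remains, and the
    removal is recorded.  Removing the same point twice is an error.
    """
    key = (set_label, float(t))
    if key in data.excluded_points:
        raise ValueError(f"point {key} was already removed")
    mask = (data.data["set"] == set_label) & np.isclose(data.data["t"], t)
    if not mask.any():
        raise ValueError(f"no observation at set={set_label!r}, t={t}")
    kept = data.data.loc[~mask]
    return PropensityTimecourse(
        _renormalize(kept), adjusted=True,
        excluded_points=data.excluded_points + (key,),
    )


def flag_outliers(data: PropensityTimecourse, fit: "FitResult",
                  threshold: float = 3.0) -> list[tuple[str, float]]:
    """Optional studentized-residual flagger (|r| > threshold); off by
    default in the pipeline — outlier removal is normally by name."""
    t, y = data.values()
    resid = y - _model_function(fit.model_kind)(np.asarray(fit.theta), t)
    dof = max(len(y) - fit.k, 1)
    s = math.sqrt(float(resid @ resid) / dof)
    if s == 0:
        return []
    flagged = np.abs(resid / s) > threshold
    return [(row["set"], float(row["t"]))
            for _, row in data.data.loc[flagged].iterrows()]


# --- model functions in rescaled (standard-deviation) units -----------------

def _phi(z):
    from scipy.special import erf
    return 0.5 * (1.0 + erf(np.asarray(z) / math.sqrt(2.0)))


def _model_function(kind: str):
    """Return f(theta, t) -> propensity for the named model kind."""
    if kind == "linear":
        return lambda th, t: _phi(th[0] - th[1] * t)
    if kind == "exponential":
        # P = Phi(a + c*exp(-beta*t)): baseline a plus exponentially
        # decaying CCAF with amplitude c.
        return lambda th, t: _phi(th[0] + th[1] * np.exp(-th[2] * t))
    if kind == "quadratic":
        return lambda th, t: _phi(th[0] - th[1] * t - th[2] * t**2)
    if kind == "cubic":
        return lambda th, t: _phi(th[0] - th[1] * t - th[2] * t**2 - th[3] * t**3)
    if kind == "gamma_ccif":
        from scipy.stats import gamma as gamma_dist

        def f(th, t):
            shape, scale, d0, beta = th
            resid = d0 + beta * np.asarray(t, float)
            return np.where(resid <= 0, 1.0,
                            gamma_dist.sf(np.maximum(resid, 0), a=abs(shape),
                                          scale=abs(scale)))
        return f
    raise ValueError(f"unknown model kind: {kind!r}; choose from {MODEL_KINDS}")


def _start_grid(kind: str) -> list[np.ndarray]:
    """Deterministic multi-start grid (C0* x beta core, extras appended)."""
    c0s = (-1.0, 0.0, 0.5, 1.0, 2.0)
    betas = (0.1, 0.5, 1.0)
    core = [(c, b) for c in c0s for b in betas]
    if kind == "linear":
        return [np.array(p) for p in core]
    if kind == "exponential":
        return [np.array([c - 1.0, 1.0, b]) for c, b in core]
    if kind == "quadratic":
        return [np.array([c, b, 0.01]) for c, b in core]
    if kind == "cubic":
        return [np.array([c, b, 0.01, 0.001]) for c, b in core]
    if kind == "gamma_ccif":
        # shape, scale, d0, beta
        return [np.array([s, 1.0 / s, -0.5, b])
                for s in (1.0, 5.0, 50.0) for b in (0.1, 0.5, 1.0)]
    raise ValueError(f"unknown model kind: {kind!r}")


_PARAM_NAMES = {
    "linear": ("C0_star", "beta"),
    "exponential": ("baseline", "amplitude", "beta"),
    "quadratic": ("C0_star", "beta", "gamma"),
    "cubic": ("C0_star", "beta", "gamma", "delta"),
    "gamma_ccif": ("shape", "scale", "d0", "beta"),
}


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of one model kind to a propensity time course."""

    model_kind: str
    estimates: dict
    n: int
    k: int
    RSS: float
    TSS: float
    adjusted_R2: float
    AIC: float
    converged: bool

    @property
    def theta(self) -> tuple:
        return tuple(self.estimates.values())

    def predict(self, t):
        return _model_function(self.model_kind)(np.asarray(self.theta), t)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind, **self.estimates, "n": self.n,
            "k": self.k, "RSS": self.RSS, "TSS": self.TSS,
            "adjusted_R2": self.adjusted_R2, "AIC": self.AIC,
            "converged": self.converged,
        }


def aic(n: int, k: int, rss: float, convention: str = "gaussian") -> float:
    """Akaike Information Criterion for a Gaussian least-squares fit.

    Default ``gaussian`` convention counts the error variance as a fitted
    parameter: ``n*ln(2*pi*RSS/n) + n + 2*(k+1)`` (matches
    NonlinearModelFit-style reporting).  ``classic`` gives the reduced form
    ``n*ln(RSS/n) + 2*k``.  RSS == 0 returns -inf as a sentinel.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if rss < 0:
        raise ValueError("RSS must be >= 0")
    if rss == 0:
        return AIC_SENTINEL
    if convention == "gaussian":
        return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (k + 1)
    if convention == "classic":
        return n * math.log(rss / n) + 2.0 * k
    raise ValueError(f"unknown AIC convention: {convention!r}")


def adjusted_r2(n: int, k: int, rss: float, tss: float,
                denom: str = "n-k") -> float:
    """Adjusted R-squared, ``1 - (RSS/(n-k)) / (TSS/(n-1))`` by default.

    ``denom='n-k-1'`` switches the residual degrees of freedom convention.
    """
    if tss <= 0:
        raise ValueError("TSS must be > 0 for adjusted R2")
    df_resid = n - k if denom == "n-k" else n - k - 1
    if df_resid <= 0:
        raise ValueError("not enough residual degrees of freedom")
    return 1.0 - (rss / df_resid) / (tss / (n - 1))


def relative_likelihood(aic_best: float, aic_other: float) -> float:
    """How many times more likely the better model is: exp((AIC_other - AIC_best)/2)."""
    return math.exp((aic_other - aic_best) / 2.0)


def fit_model(data: PropensityTimecourse, model_kind: str = "linear",
              aic_convention: str = "gaussian",
              r2_denom: str = "n-k") -> FitResult:
    """Fit one model kind by Levenberg-Marquardt least squares.

    Runs LM from every point of a deterministic start grid and keeps the
    lowest-RSS converged solution.  RSS/TSS, adjusted R-squared and AIC
    are computed on the fitted points.
    """
    if data.data["t"].nunique() < 3:
        raise ValueError("need >= 3 distinct timepoints to fit")
    t, y = data.values()
    f = _model_function(model_kind)
    names = _PARAM_NAMES[model_kind]
    k = len(names)
    if len(y) <= k:
        raise ValueError(f"n={len(y)} points cannot constrain k={k} parameters")

    best = None
    for x0 in _start_grid(model_kind):
        try:
            sol = optimize.least_squares(lambda th: f(th, t) - y, x0,
                                         method="lm", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        rss = 2.0 * sol.cost
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol)
    if best is None:
        raise RuntimeError(
            f"Levenberg-Marquardt failed to converge for kind={model_kind!r} "
            f"from all {len(_start_grid(model_kind))} starts"
        )
    rss, sol = best
    theta = sol.x
    if model_kind == "gamma_ccif":  # shape/scale enter through abs()
        theta = np.array([abs(theta[0]), abs(theta[1]), theta[2], theta[3]])
    tss = float(np.sum((y - y.mean()) ** 2))
    return FitResult(
        model_kind=model_kind,
        estimates=dict(zip(names, map(float, theta))),
        n=len(y), k=k, RSS=float(rss), TSS=tss,
        adjusted_R2=adjusted_r2(len(y), k, rss, tss, denom=r2_denom),
        AIC=aic(len(y), k, rss, convention=aic_convention),
        converged=True,
    )


@dataclass(frozen=True)
class ModelComparison:
    """AIC ranking of several model kinds on the same data.

    ``relative_likelihood[m] = exp(-delta_AIC[m]/2)`` is in (0, 1] with 1
    for the best model; its reciprocal is "how many times more likely" the
    best model is than model m.
    """

    fits: dict
    delta_AIC: dict
    relative_likelihood: dict
    errors: dict = field(default_factory=dict)

    @property
    def best_kind(self) -> str:
        return min(self.delta_AIC, key=lambda m: self.delta_AIC[m])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, fit in self.fits.items():
            row = fit.to_dict()
            row["delta_AIC"] = self.delta_AIC[kind]
            row["relative_likelihood"] = self.relative_likelihood[kind]
            rows.append(row)
        return pd.DataFrame(rows).sort_values("delta_AIC").reset_index(drop=True)


def compare_models(data: PropensityTimecourse, kinds=("linear", "exponential"),
                   aic_convention: str = "gaussian") -> ModelComparison:
    """Fit each kind and rank by AIC; per-model fit errors are collected
    without aborting the rest.  Ties keep declaration order."""
    kinds = list(kinds)
    if len(kinds) < 2:
        raise ValueError("need >= 2 model kinds to compare")
    fits, errors = {}, {}
    seen: dict[str, int] = {}
    for kind in kinds:
        seen[kind] = seen.get(kind, 0) + 1
        label = kind if seen[kind] == 1 else f"{kind}#{seen[kind]}"
        try:
            fits[label] = fit_model(data, kind, aic_convention=aic_convention)
        except Exception as exc:  # propagate per-model, continue others
            errors[label] = str(exc)
    if not fits:
        raise RuntimeError(f"all model fits failed: {errors}")
    best_aic = min(f.AIC for f in fits.values())
    # -inf AIC marks a zero-RSS (interpolating) fit; ties there are exact
    delta = {m: (0.0 if f.AIC == best_aic else f.AIC - best_aic)
             for m, f in fits.items()}
    rel = {m: math.exp(-d / 2.0) for m, d in delta.items()}
    return ModelComparison(fits=fits, delta_AIC=delta,
                           relative_likelihood=rel, errors=errors)


def params_from_fit(fit: FitResult) -> FateModelParams:
    """Convenience: turn a linear-kind fit into rescaled model parameters."""
    if fit.model_kind != "linear":
        raise ValueError("only the linear kind maps onto (C0_star, beta)")
    return FateModelParams.from_rescaled(fit.estimates["C0_star"],
                                         fit.estimates["beta"])
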