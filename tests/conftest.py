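import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dictyfate import (
    CCIFEnsemble,
    FateModelParams,
    GeneClassSpec,
    PropensityTimecourse,
    propensity_rescaled,
    simulate_expression_matrix,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the fitted two-parameter model of the reference analysis
FITTED_C0_STAR = 0.57
FITTED_BETA = 0.41


@pytest.fixture
def fitted_params() -> FateModelParams:
    """Rescaled model at the reference fitted estimates."""
    return FateModelParams.from_rescaled(FITTED_C0_STAR, FITTED_BETA)


@pytest.fixture
def ensemble() -> CCIFEnsemble:
    return CCIFEnsemble(G=100, p_bar=0.5, x_bar=1.0, s2=0.25)


def noiseless_timecourse(c0_star: float, beta: float, n_sets: int = 1,
                         timepoints=(0, 1, 2, 3, 4, 5)) -> PropensityTimecourse:
    """Exact model-generated propensities (zero residual on refit)."""
    rows = [
        {"set": f"set{s + 1}", "t": float(t),
         "propensity": float(propensity_rescaled(c0_star, beta, float(t)))}
        for s in range(n_sets) for t in timepoints
    ]
    return PropensityTimecourse(pd.DataFrame(rows))


@pytest.fixture
def four_set_outlier_tc() -> PropensityTimecourse:
    """Four noiseless sets with one planted high outlier at (set4, t=5)."""
    tc = noiseless_timecourse(FITTED_C0_STAR, FITTED_BETA, n_sets=4)
    df = tc.data.copy()
    mask = (df["set"] == "set4") & (df["t"] == 5.0)
    df.loc[mask, "propensity"] = 0.60  # true value is ~0.069
    return PropensityTimecourse(df)


def stable_gene_spec(n_genes: int = 1000, n_mean_levels: int = 20):
    """Stable (Poisson) genes spread over log-spaced mean levels so the
    CV²-mean trend is identifiable."""
    means = np.geomspace(2.0, 200.0, n_mean_levels)
    per = n_genes // n_mean_levels
    spec = [GeneClassSpec("stable", per, mean=float(m)) for m in means]
    rest = n_genes - per * n_mean_levels
    if rest:
        spec.append(GeneClassSpec("stable", rest, mean=20.0))
    return spec


@pytest.fixture
def small_matrix():
    """500 genes x 300 cells: stable + cycle + telegraph genes with truth."""
    spec = stable_gene_spec(400, 10) + [
        GeneClassSpec("cycle_MS", 25, mean=10.0, phase_multiplier=5.0),
        GeneClassSpec("cycle_G2", 25, mean=10.0, phase_multiplier=5.0),
        GeneClassSpec("stochastic", 50, p=0.1, b=50.0),
    ]
    return simulate_expression_matrix(300, spec, seed=1234)
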