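"""Ground-truth synthetic data generators.

Every analysis stage in the package is exercisable without downloads:

* populations of single cells with uniform cell-cycle ages, telegraph
  CCIF draws and threshold fate assignment;
* stalk-propensity time courses with binomial sampling noise (optionally
  split into offset experimental sets, to exercise set normalization);
* gene x cell count matrices containing stable (Poisson), cell-cycle-phased
  and stochastically bursting (telegraph) genes with full truth tables.

All generators are bit-reproducible given (seed, parameters): every draw
comes from one ``numpy.random.default_rng(seed)`` stream.

A note on the CCIF sampling scheme: contributions ``x_i ~ Normal(x_bar, s2)``
are drawn fresh per cell *and* per gene.  This is the scheme whose
population moments equal the closed-form ``mu = G*p_bar*x_bar`` and
``sigma2 = G*p_bar*s2 + p_bar*(1-p_bar)*G*x_bar**2``; fixing ``x_i`` per
gene across cells would give a different cross-cell variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fate_model import (
    CCIFEnsemble,
    DecayParams,
    FateModelParams,
    ccaf_level,
    propensity_combined,
)
from .fitting import PropensityTimecourse

__all__ = [
    "GeneClassSpec",
    "SyntheticCountMatrix",
    "DEFAULT_PHASE_PROPORTIONS",
    "simulate_population",
    "simulate_propensity_timecourse",
    "simulate_expression_matrix",
    "monte_carlo_ccif",
]

#: default cell-cycle group proportions (M/S, G2.1, G2.2), 25/31/25 of 81 cells
DEFAULT_PHASE_PROPORTIONS = {"MS": 25 / 81, "G2.1": 31 / 81, "G2.2": 25 / 81}


def simulate_population(n_cells: int, ens: CCIFEnsemble, decay: DecayParams,
                        R: float, T_cycle: float, seed: int) -> pd.DataFrame:
    """Simulate single cells with cycle age, CCAF, CCIF and fate.

    Ages are Uniform[0, T_cycle]; CCIF is the sum over the ensemble's G
    genes of Bernoulli(p_bar) x Normal(x_bar, s2) draws (fresh per cell per
    gene); a cell is stalk iff CCAF + CCIF >= R.

    Returns a DataFrame with one row per cell: ``cell_id, t, ccaf, ccif,
    sensitivity, fate``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if T_cycle <= 0:
        raise ValueError("T_cycle must be > 0 hours")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, T_cycle, size=n_cells)
    ccaf = np.asarray(ccaf_level(decay, t), dtype=float)
    ccif = _ccif_draws(rng, ens, n_cells)
    sens = ccaf + ccif
    return pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "t": t,
        "ccaf": ccaf,
        "ccif": ccif,
        "sensitivity": sens,
        "fate": np.where(sens >= R, "stalk", "spore"),
    })


def _ccif_draws(rng: np.random.Generator, ens: CCIFEnsemble,
                n: int, chunk: int = 100_000) -> np.ndarray:
    """n sums of G Bernoulli(p_bar) x Normal(x_bar, s2) draws, chunked to
    bound memory at large n*G."""
    s = float(np.sqrt(ens.s2))
    out = np.empty(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        on = rng.random((m, ens.G)) < ens.p_bar
        x = rng.normal(ens.x_bar, s, size=(m, ens.G))
        out[lo:hi] = (on * x).sum(axis=1)
    return out


def monte_carlo_ccif(ens: CCIFEnsemble, n_draws: int, seed: int) -> np.ndarray:
    """Monte-Carlo CCIF samples — the independent oracle for the moment
    formulas.  Direct per-gene sampling; no distributional shortcuts."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    return _ccif_draws(rng, ens, n_draws)


def simulate_propensity_timecourse(params: FateModelParams, timepoints,
                                   cells_per_timepoint: int, seed: int,
                                   n_sets: int = 1,
                                   set_offsets=None) -> PropensityTimecourse:
    """Binomially noisy propensity estimates at each timepoint.

    At each t the observed propensity is Binomial(n, P_t)/n with
    n = cells_per_timepoint.  With ``n_sets > 1`` each set's true curve is
    shifted by its offset (default: evenly spaced in +/-0.05) and clipped
    to [0, 1], producing the between-set mean differences that
    :func:`dictyfate.fitting.normalize_propensity_sets` removes.
    """
    timepoints = np.asarray(list(timepoints), dtype=float)
    if timepoints.size == 0:
        raise ValueError("timepoints must be non-empty")
    rng = np.random.default_rng(seed)
    if set_offsets is None:
        set_offsets = (np.linspace(-0.05, 0.05, n_sets) if n_sets > 1
                       else np.zeros(1))
    set_offsets = np.asarray(set_offsets, dtype=float)
    if set_offsets.size != n_sets:
        raise ValueError("set_offsets length must equal n_sets")
    p_t = np.asarray(propensity_combined(params, timepoints), dtype=float)
    rows = []
    for s in range(n_sets):
        p_set = np.clip(p_t + set_offsets[s], 0.0, 1.0)
        draws = rng.binomial(cells_per_timepoint, p_set)
        for t, x in zip(timepoints, draws):
            rows.append({"set": f"set{s + 1}", "t": t,
                         "propensity": x / cells_per_timepoint})
    return PropensityTimecourse(pd.DataFrame(rows))


@dataclass(frozen=True)
class GeneClassSpec:
    """Specification of one gene class in a synthetic count matrix.

    ``kind`` is one of stable / cycle_MS / cycle_G2 / stochastic.  Stable
    genes are Poisson(mean); cycle genes are Poisson(mean * phase_multiplier)
    in their high phase and Poisson(mean) elsewhere; stochastic genes are
    telegraph: Poisson(b) with probability p, else 0 (so eps2 = b).
    """

    kind: str
    n_genes: int
    mean: float = 10.0
    p: float = 0.1
    b: float = 50.0
    phase_multiplier: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("stable", "cycle_MS", "cycle_G2", "stochastic"):
            raise ValueError(f"unknown gene class kind: {self.kind!r}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCountMatrix:
    """Gene x cell integer counts plus ground truth.

    ``counts`` is genes (rows) x cells (columns); ``gene_truth`` records
    each gene's class and generating parameters; ``cell_truth`` records
    each cell's phase.
    """

    counts: pd.DataFrame
    gene_truth: pd.DataFrame
    cell_truth: pd.DataFrame
    seed: int = field(default=0)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        if len(self.gene_truth) != self.counts.shape[0]:
            raise ValueError("gene truth table does not align with matrix rows")
        if len(self.cell_truth) != self.counts.shape[1]:
            raise ValueError("cell truth table does not align with matrix columns")


def simulate_expression_matrix(n_cells: int, gene_spec, seed: int,
                               phase_proportions=None,
                               size_factor_sd: float = 0.0) -> SyntheticCountMatrix:
    """Simulate a count matrix with stable, cycle-phased and bursty genes.

    Each cell draws a phase from ``phase_proportions`` (default 25/31/25
    over M/S, G2.1, G2.2; both G2 sub-groups count as G2 for cycle_G2
    genes).  ``size_factor_sd > 0`` adds a per-cell lognormal scaling
    factor to emulate library-size differences.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    specs = list(gene_spec)
    if not specs or sum(s.n_genes for s in specs) == 0:
        raise ValueError("gene_spec must request at least one gene")
    if phase_proportions is None:
        phase_proportions = DEFAULT_PHASE_PROPORTIONS
    phases = list(phase_proportions)
    probs = np.array([phase_proportions[ph] for ph in phases], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    cell_phase = rng.choice(phases, size=n_cells, p=probs)
    in_ms = np.char.startswith(cell_phase.astype(str), "MS")
    in_g2 = ~in_ms
    size = (rng.lognormal(0.0, size_factor_sd, size=n_cells)
            if size_factor_sd > 0 else np.ones(n_cells))

    blocks, truth_rows = [], []
    for spec in specs:
        for _ in range(spec.n_genes):
            if spec.kind == "stable":
                lam = spec.mean * size
            elif spec.kind == "cycle_MS":
                lam = spec.mean * np.where(in_ms, spec.phase_multiplier, 1.0) * size
            elif spec.kind == "cycle_G2":
                lam = spec.mean * np.where(in_g2, spec.phase_multiplier, 1.0) * size
            else:  # stochastic telegraph gene
                on = rng.random(n_cells) < spec.p
                lam = np.where(on, spec.b, 0.0) * size
            blocks.append(rng.poisson(lam))
            truth_rows.append({"class": spec.kind, "mean": spec.mean,
                               "p": spec.p, "b": spec.b,
                               "phase_multiplier": spec.phase_multiplier})

    counts = np.vstack(blocks)
    gene_ids = [f"g{i:05d}" for i in range(counts.shape[0])]
    cell_ids = [f"c{j:05d}" for j in range(n_cells)]
    return SyntheticCountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=cell_ids),
        gene_truth=pd.DataFrame(truth_rows, index=gene_ids),
        cell_truth=pd.DataFrame({"phase": cell_phase,
                                 "size_factor": size}, index=cell_ids),
        seed=seed,
    )
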