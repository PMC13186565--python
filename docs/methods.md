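# Methods

## The stochastic–deterministic fate model

A cell's sensitivity to stalk-inducing signals is modelled as
`S(t) = A_t + X`, where `A_t` is the deterministic cell-cycle-associated
component (CCAF) and `X` the stochastic cell-cycle-independent component
(CCIF). The cell adopts stalk fate iff `S(t) ≥ R`. Sensitivity is an
*effect scale*, not a molecular concentration: `A_t` may go negative and
only differences relative to `R` in units of the CCIF spread matter.

**CCAF decay.** The default shape is linear, `A_t = A0 − βt`, with `t`
in hours after the end of mitosis (`t = 0` is "just divided"). For model
comparison three alternatives are provided: exponential `A0·e^{−βt}`,
quadratic `A0 − βt − γt²` and cubic `A0 − βt − γt² − δt³`. The
polynomial forms are minimal nestings of the linear model; the decay rate
`β` is constrained non-negative, the higher-order coefficients are free.

**CCIF.** `X = Σᵢ eᵢ·xᵢ` over `G` genes, with `eᵢ ~ Bernoulli(p̄)` and
`xᵢ ~ Normal(x̄, s²)` drawn independently. By the law of total variance

```
μ  = G·p̄·x̄
σ² = G·p̄·s² + p̄(1 − p̄)·G·x̄²
```

and for moderate `G` (≳ 50) the sum is well approximated by
`Normal(μ, σ²)` — the test suite checks skew and excess kurtosis of
Monte-Carlo sums at `G = 100`. A draw scheme note that matters: `xᵢ` is
drawn *fresh per cell per gene*. Fixing each gene's contribution across
cells would remove the `G·p̄·s²` term from the cross-cell variance and
break the moment formulas above; the synthetic generator therefore uses
fresh draws.

**Propensity.** The stalk propensity is the upper tail of the
sensitivity distribution,

```
P_t = ½(1 + erf[(C0 − βt − R)/(σ√2)]),   C0 = μ + A0 ,
```

with limits `σ → 0` (deterministic step at `A_t + μ = R`) and `β → 0`
(constant propensity `½(1 + erf[(μ − R)/(σ√2)])`). For fitting, the
three constants collapse into `C0* = (C0 − R)/σ`, giving the
two-parameter form `P_t = ½(1 + erf[(C0* − βt)/√2])` with both
parameters in standard-deviation units. erf is evaluated to machine
precision via `scipy.special.erf`.

**Gamma CCIF variant.** As a robustness alternative to the Gaussian
assumption, CCIF may be `Gamma(shape, scale)` added to `A_t`, giving
`P_t = P(Gamma > R − A_t)` and `P_t = 1` whenever `R − A_t ≤ 0` (the
gamma support is non-negative). The choice to replace *CCIF only* (not
total sensitivity) keeps the two variants symmetric. In fitting, the
variant is parameterized as `SF_Gamma(d0 + βt; shape, scale)` with
`d0 = R − A0`, all four parameters free (no moment matching): on a short
0–5 hr window distinct (shape, scale, d0) triples can generate curves
identical to below 1e−7, so fitted gamma parameters should be read as a
curve, not as mechanistic constants.

**"Steady-state" propensity** is defined as the uniform average of `P_t`
over `t ∈ [0, 5]` hr — the window covered by the fitted data, over which
cycle times are treated as uniformly distributed. The window is a
configurable argument; the average uses adaptive quadrature with absolute
tolerance 1e−9.

## Fitting and model comparison

Multi-set propensity time courses (strain × condition sets) are combined
by shifting each set additively so its mean propensity equals the global
mean; values are clipped to [0, 1] only if a shift pushes them outside
the unit interval (with a warning, since clipping perturbs the preserved
global mean). Outlier removal is *by name*: a (set, t) point is removed
and the remaining raw values re-normalized; removal is recorded and
re-removal is an error. An optional studentized-residual flagger
(`|r| > 3`) is provided for exploration but is off by default — no
automatic exclusion.

Fits use `scipy.optimize.least_squares(method="lm")`
(Levenberg–Marquardt) started from a fixed deterministic grid
(`C0* ∈ {−1, 0, 0.5, 1, 2} × β ∈ {0.1, 0.5, 1}`, with analogous grids
for the larger models); the lowest-RSS converged solution wins. Points
are unweighted (ordinary least squares). At least three distinct
timepoints and `n > k` points are required.

**AIC convention.** The default is the Gaussian-likelihood form with the
error variance counted as a parameter,

```
AIC = n·ln(2π·RSS/n) + n + 2(k + 1),
```

which matches the reporting convention of common nonlinear-fit tools
(back-solving this formula at `n = 23`, `k = 2` against the published
adjusted R² and AIC of the reference fit is self-consistent). The
reduced form `n·ln(RSS/n) + 2k` is available via
`aic(..., convention="classic")`. Zero RSS returns `−inf` as a sentinel.
Adjusted R² defaults to `1 − (RSS/(n−k))/(TSS/(n−1))`; the `n−k−1`
denominator is an option. Model comparison reports per-model
`ΔAIC` and relative likelihood `exp(−ΔAIC/2)` (1 for the best model);
`relative_likelihood(aic_best, aic_other)` returns the reciprocal, "how
many times more likely" the best model is. Ties keep declaration order.

A selection caveat measured during development: against the exponential
variant — whose `β → 0` boundary contains near-linear curves — AIC can
prefer the true linear model in at most `P(χ²₁ < 2) ≈ 0.84` of noisy
replicates; simulation at 200 cells/timepoint across four sets gives
≈ 0.78. Model selection between these kinds on short windows is
therefore informative but not near-certain at realistic noise.

## Synthetic data

The generators produce the statistical structure the analysis assumes,
with known truth:

* **Populations**: cycle ages `Uniform[0, T_cycle]` (default 5 hr, the
  fitted window), CCIF by direct per-gene telegraph draws, threshold
  fates. Empirical stalk fractions match the window-averaged propensity
  within binomial error.
* **Time courses**: observed propensity at each timepoint is
  `Binomial(n_cells, P_t)/n_cells`; optional multi-set generation adds
  set-level offsets (default evenly spaced in ±0.05) to exercise the
  normalization step. Default 200 cells/timepoint, hourly points 0–5 hr,
  four sets — the scale of the reference experiment.
* **Count matrices**: stable genes `Poisson(m)`; cycle-phased genes
  `Poisson(m·multiplier)` in their high phase (default multiplier 4);
  bursty genes telegraph-with-Poisson-bursts, i.e. `Poisson(b)` with
  probability `p` else 0, so the within-on-state variance is `ε² = b`
  (defaults `p = 0.1`, `b = 50`, typical of a strongly bursty gene).
  Cell phases are drawn from (25, 31, 25)/81 for (M/S, G2.1, G2.2), the
  three cluster sizes of the reference single-cell data; the mapping of
  cluster sizes to phases is configurable since it is not uniquely
  determined. An optional lognormal per-cell size factor emulates
  library-size variation.

What the generators do **not** emulate: UMI/barcode-level sampling,
dropout beyond telegraph zeros, gene–gene correlation blocks, batch
effects, or doublets. Passing tests therefore demonstrate correctness of
the statistical machinery under the model's own assumptions, not
robustness to every artefact of real single-cell data.

All generators draw from a single `numpy.random.default_rng(seed)` and
are bit-reproducible given (seed, parameters).

## Variability calling

Counts are normalized by median-of-ratios size factors (geometric-mean
reference per gene; factors rescaled to geometric mean 1), falling back
to library-size scaling when no gene is expressed in every cell; all-zero
cells receive a neutral factor and are flagged downstream. Genes with
fewer than `min_count` (default 5) total raw counts are excluded.

The mean–variability trend is `CV²(m) = a + b/m`, fitted by least
squares (linear in `a, b`); a soft-L1 robust refit is the default inside
the caller so extreme genes do not drag the trend. The excess test
models `log(CV²_obs/CV²_trend)` as `Normal(0, spread(m))` under the
null, with `spread(m)` estimated in 20 equal-occupancy log-mean bins and
linearly interpolated. Within a bin the spread is the *left-sided*
robust scale `−q25/0.6745`: genuinely variable genes contaminate only
the upper tail, so a left-sided estimator stays calibrated even when a
mean bin is rich in true positives (a median/MAD estimator loses power
exactly where planted variable genes cluster). P-values are one-sided
upper-tail; FDR is Benjamini–Hochberg (`statsmodels`); calls require
FDR < 0.05 by default.

Cycle association uses the rank-based AUROC (Mann–Whitney U with average
ranks for ties) of each gene against each cell group versus the rest,
taking the per-gene maximum; genes above 0.65 (a deliberately relaxed
cut, to catch weak cycle signatures) are cycle-associated. Variable
genes are then partitioned exhaustively into `variable_cycle` /
`variable_stochastic`; everything else is `not_variable`. Within-group
CV² re-runs the full trend + test inside each cell group (shared size
factors; groups under 3 cells skipped with a warning), which is how
cycle-associated genes can be shown to carry *additional* stochastic
variation at every cycle stage.

Phase assignment scores each cell by its mean normalized expression over
M/S and G2 marker sets (filtered to expressed genes), standardizes the
log ratio (pseudocount 0.5) across cells and cuts at 0: above → M/S,
below → G2. Cells with zero expression of both sets are left unassigned.
Clustering cells into finer groups is out of scope; group labels are an
input.

## Indices, enrichment and screen classes

Developmental index `dev/(growth + dev)` and cell-type index
`prestalk/(prestalk + prespore)` are scale-invariant ratios in [0, 1],
undefined (NaN-flagged) when both inputs are zero; the "developmental
gene" cut defaults to index ≥ 0.9 and is a parameter. Enrichment uses
the exact binomial tail (one-sided, enrichment direction, by default)
and a seeded without-replacement resampling null (default 1000 samples)
for index histograms. REMI screen records are classified from Z-scores
with enrichment `Z > 1.5` in DIF-selection round 2 *or* 6 and depletion
`Z < −1`, with precedence growth phenotype → cAMP-nonresponsive →
DIF-insensitive; non-enriched or Z-less records are unclassified.
Assignment of insertions to genes (including the promoter-proximal
500 bp rule) happens upstream; this module consumes gene-assigned
records.

## Perturbation predictions

`burst_up` raises `p̄` by `delta_p`: the ensemble's mean shifts by
`Δμ = G·Δp̄·x̄` and each gene's CV² falls. Predicted *curves* shift the
model mean only, holding σ at its baseline value — the strict ordering
"perturbed above baseline at every t" is then exact (erf is strictly
increasing), whereas letting σ change with p̄ can reverse the ordering
in the upper tail; `perturb_ensemble` recomputes both moments when the
full perturbed ensemble is wanted, and the simulation cross-check in the
test suite covers that case too. `cycle_arrest` idealizes cold shock as
all cells held at a single `arrest_t` (default 0, around mitosis);
`combined` applies both and produces the flat, near-saturated curve of
the double perturbation. Signal dose enters as a monotone threshold
shift `R_eff = R − dose_shift·σ` (log-dose linear), since dose–response
data constrain responsiveness only ordinally. Whether a Set1-like
perturbation also moves the threshold `R` directly cannot be separated
from a `μ` shift by this model; only `μ` (via `p̄`) is moved, and the
confound is acknowledged.

## Numerical choices and degenerate inputs

* Quadrature: `scipy.integrate.quad`, `epsabs = 1e−9`, limit 200.
* LM tolerances `xtol = ftol = 1e−12`; non-convergence from all grid
  starts raises with diagnostics.
* `CV²` is undefined for `p = 0` or `b = 0` (error), and `sigma ≤ 0` is
  rejected wherever a Gaussian CCIF is required.
* Normalization of a single set is the identity; empty sets, all-zero
  matrices, empty marker overlaps and oversized resampling subsets raise
  data errors naming the problem.
* Pipeline outputs are written with fixed float formatting so identical
  configs give byte-identical files (SHA-256 recorded in the manifest).

## Problem sizes used by the checks

Simulation-based checks run at: 200 replicates per condition for
estimator bias/RMSE (50/200/1000 cells per timepoint), 10⁶ draws for
Monte-Carlo moment and burst-statistic oracles (20 random ensembles),
50 seeds of 1000-gene × 300-cell null matrices for false-positive
control, and one 2000-gene × 2000-cell matrix (100 planted bursty genes)
for recall. These sizes give Monte-Carlo standard errors comfortably
below the tolerances being asserted.

## Known limitations

* The fitted `C0*` and `β` are in standard-deviation units; absolute
  CCAF/CCIF levels, `R`, and σ are not identifiable from propensity data
  alone.
* The gamma fitting variant is weakly identifiable on short windows (see
  above).
* The excess-variability test is calibrated under the generator's
  Poisson-based noise; heavier-tailed technical noise in real data would
  need the spread model re-estimated (which the binned empirical design
  does automatically, at some power cost).
* The published counts of variable genes (≈ 2000 at FDR < 0.05, split
  roughly evenly by cycle association in the reference data) depend on
  the exact spread model of the original caller and on accession data,
  and are treated as reference numbers, not reproduction targets.
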