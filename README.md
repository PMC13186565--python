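# dictyfate

Stochastic–deterministic modelling of cell-fate proportioning in
*Dictyostelium discoideum*.

When starved, *D. discoideum* amoebae differentiate into stalk and spore
cells at robust proportions without spatial cues. `dictyfate` implements a
quantitative model of how single cells make this probabilistic choice, and
the analysis pipeline needed to fit and test it: a cell's sensitivity to
stalk-inducing signals (such as DIF-1) is the sum of

* **CCAF** — a deterministic cell-cycle-associated factor, maximal just
  after mitosis and decaying through the cycle, `A_t = A0 − βt`; and
* **CCIF** — a stochastic cell-cycle-independent factor, the summed
  contribution of many telegraph-expressed genes (each on per interval
  with probability `p̄`, contributing `Normal(x̄, s²)` when on), so that
  CCIF `~ Normal(μ, σ²)` with `μ = G·p̄·x̄` and
  `σ² = G·p̄·s² + p̄(1 − p̄)·G·x̄²`.

A cell adopts stalk fate when total sensitivity exceeds a threshold `R`,
giving the stalk propensity at cycle time `t`

```
P_t = ½ (1 + erf[(C0 − βt − R) / (σ√2)]),   C0 = μ + A0
```

or, rescaled to standard-deviation units, the two-parameter form
`P_t = ½(1 + erf[(C0* − βt)/√2])`. At the single-gene level the same
telegraph picture gives burst statistics: mean `p·b`, variance
`p·ε² + p(1 − p)·b²`, and `CV² = (1 − p)/p + ε²/(p·b²)` — so raising
burst frequency raises mean expression while *lowering* cell–cell
variability, the signature used to interpret chromatin (Set1/COMPASS)
perturbations.

The package is aimed at quantitative/systems biologists who want to fit
threshold-response fate models to propensity time courses, call
excess-variability genes from single-cell count matrices, and explore
perturbation predictions — all exercisable on built-in synthetic data.

## What's inside

| module | contents |
|---|---|
| `dictyfate.fate_model` | closed-form propensity curves, CCIF moments, burst statistics, gamma-CCIF variant |
| `dictyfate.fitting` | set-mean normalization, named-outlier removal, Levenberg–Marquardt fits, AIC/adjusted-R², model comparison |
| `dictyfate.synthetic` | populations of cells, binomially noisy time courses, count matrices (stable / cycle-phased / bursty genes) with truth tables |
| `dictyfate.variability` | median-of-ratios normalization, CV²-vs-mean trend, one-sided excess-variability test with BH FDR, AUROC cycle association, M/S-vs-G2 phase assignment |
| `dictyfate.classification` | developmental / cell-type indices, binomial enrichment, resampling nulls, REMI screen classes |
| `dictyfate.perturbation` | burst-probability increase, cell-cycle arrest and combined scenarios |
| `dictyfate.pipeline` / `dictyfate.cli` | config-driven runs with manifests; `dictyfate` console script |

## Worked example

Simulate a noisy stalk-propensity time course at the published parameter
estimates and refit it:

```sh
dictyfate simulate timecourse --seed 2 --cells-per-timepoint 500 --out tc.tsv
dictyfate fit tc.tsv --model linear
```

prints (abridged):

```json
{
  "model_kind": "linear",
  "C0_star": 0.5727024652334737,
  "beta": 0.41191305165739944,
  "n": 24,
  "adjusted_R2": 0.9964141366669031,
  "starting_propensity": 0.7165769159991271,
  "average_propensity": 0.34900120284333636
}
```

The generator drew binomial samples (500 cells per timepoint, four
experimental sets) from the model at `C0* = 0.57`, `β = 0.41 hr⁻¹`; the
fit recovers both to two decimals. `starting_propensity` is `P_0` (the
probability that a cell starved immediately after mitosis becomes stalk)
and `average_propensity` is the mean of `P_t` over cells spread uniformly
across the 0–5 hr window — the expected population stalk fraction.

The same workflow runs end to end on a count matrix:

```sh
dictyfate simulate matrix --seed 7 --n-cells 500 --out counts.tsv
dictyfate variability call counts.tsv --fdr 0.05 --out variable_genes.tsv
```

which calls bursty genes as excess-variable while controlling the false
discovery rate on the stable background (truth labels are written next to
the matrix for checking).

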