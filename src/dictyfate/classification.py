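"""Gene indices, enrichment statistics and REMI screen classification.

* **Developmental index**: dev / (growth + dev) average expression — 0 is
  exclusive to growth, 1 exclusive to development.
* **Cell-type index**: prestalk / (prestalk + prespore) expression — above
  0.5 reads as prestalk-biased, below as prespore-biased.
* **Enrichment**: exact binomial tail of observing ``hits`` successes in a
  subset of size ``n`` against a genome-wide background rate, plus a
  resampling null for index histograms.
* **REMI screen classes**: mutants enriched under DIF-1 selection
  (Z > 1.5 in round 2 or 6) are partitioned, with precedence, into growth
  advantage, cAMP-nonresponsive (depleted, Z < -1, in the 8-Br-cAMP
  screen) and DIF-insensitive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "developmental_index",
    "cell_type_index",
    "enrichment_binomial",
    "random_sample_null",
    "classify_remi_mutants",
]


def _ratio_index(numer, denom_other) -> np.ndarray:
    a = np.asarray(numer, dtype=float)
    b = np.asarray(denom_other, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be non-negative")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, a / total, np.nan)
    return out


def developmental_index(growth_expr, dev_expr):
    """dev / (growth + dev) per gene; NaN where both are zero."""
    out = _ratio_index(dev_expr, growth_expr)
    return out if out.ndim else float(out)


def cell_type_index(prestalk_expr, prespore_expr):
    """prestalk / (prestalk + prespore) per gene; NaN where both are zero."""
    out = _ratio_index(prestalk_expr, prespore_expr)
    return out if out.ndim else float(out)


def enrichment_binomial(subset_hits: int, subset_n: int, background_rate: float,
                        side: str = "greater") -> float:
    """Exact binomial tail p-value for subset enrichment vs background."""
    if not 0 < background_rate < 1:
        raise ValueError("background_rate must be in (0, 1)")
    if not 0 <= subset_hits <= subset_n:
        raise ValueError("need 0 <= hits <= n")
    return stats.binomtest(subset_hits, subset_n, background_rate,
                           alternative=side).pvalue


def random_sample_null(index_values, subset_size: int, n_samples: int = 1000,
                       seed: int = 0, bins=None) -> tuple[np.ndarray, np.ndarray]:
    """Average binned index distribution over random gene subsets.

    Resamples ``subset_size`` genes without replacement ``n_samples``
    times from the index universe and averages the histograms — the null
    against which an observed subset's index distribution is displayed.
    Returns (bin_edges, mean_counts).
    """
    values = np.asarray(index_values, dtype=float)
    values = values[np.isfinite(values)]
    if subset_size > values.size:
        raise ValueError("subset_size exceeds the index universe")
    if bins is None:
        bins = np.linspace(0.0, 1.0, 21)
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(np.atleast_1d(bins)) - 1)
    for _ in range(n_samples):
        sample = rng.choice(values, size=subset_size, replace=False)
        counts, edges = np.histogram(sample, bins=bins)
        acc += counts
    return edges, acc / n_samples


def classify_remi_mutants(records: pd.DataFrame, z_enrich: float = 1.5,
                          z_deplete: float = -1.0) -> pd.DataFrame:
    """Classify REMI screen mutants from enrichment Z-scores.

    A mutant is *enriched* if Z > ``z_enrich`` in DIF-selection round 2 or
    round 6.  Enriched mutants are partitioned with precedence
    growth > cAMP > DIF: a known growth phenotype gives
    ``growth_advantage``; depletion (Z < ``z_deplete``) in the 8-Br-cAMP
    screen gives ``camp_nonresponsive``; the remainder are
    ``dif_insensitive``.  Everything else (including records with missing
    Z-scores, which draw a warning) is ``unclassified``.
    """
    required = {"z_dif_r2", "z_dif_r6", "z_camp", "growth_flag"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns: {sorted(missing_cols)}")
    out = records.copy()
    z2 = pd.to_numeric(out["z_dif_r2"], errors="coerce")
    z6 = pd.to_numeric(out["z_dif_r6"], errors="coerce")
    zc = pd.to_numeric(out["z_camp"], errors="coerce")
    incomplete = z2.isna() & z6.isna()
    if incomplete.any():
        warnings.warn(f"{int(incomplete.sum())} records have no DIF Z-score; "
                      "left unclassified")
    enriched = (z2 > z_enrich) | (z6 > z_enrich)
    growth = out["growth_flag"].fillna(False).astype(bool)
    camp_depleted = zc < z_deplete
    cls = np.select(
        [enriched & growth,
         enriched & ~growth & camp_depleted,
         enriched & ~growth & ~camp_depleted],
        ["growth_advantage", "camp_nonresponsive", "dif_insensitive"],
        default="unclassified",
    )
    out["class"] = cls
    return out
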