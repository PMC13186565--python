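"""Excess gene-expression variability and cell-cycle phase calling.

The pipeline mirrors the classic CV²-versus-mean analysis of single-cell
counts: counts are depth-normalized (median-of-ratios size factors), the
mean-dependent trend CV²(m) = a + b/m is fitted across genes, each gene is
tested one-sided for excess CV² above the trend, and Benjamini-Hochberg
FDR is applied.  The excess test assumes the log ratio
log(CV²_obs / CV²_trend) is normal around zero with a mean-dependent
spread, which is estimated empirically in equal-occupancy mean bins and
interpolated.

Variable genes are then split into cell-cycle-associated and stochastic
(cycle-independent) classes by a rank-based AUROC of expression against
cell groups, and cells are assigned a cycle phase from the normalized
ratio of M/S-phase to G2-phase marker expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_counts",
    "fit_cv2_trend",
    "call_variable_genes",
    "auroc_association",
    "partition_variable_genes",
    "within_group_cv2",
    "assign_cell_cycle_phase",
]


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size-factor normalization (DESeq-style).

    The reference for each gene is its geometric mean across cells; a
    cell's size factor is the median ratio of its counts to the reference
    over genes with nonzero counts in every cell.  When no such universal
    gene exists (sparse single-cell matrices) the library-size fallback is
    used.  Factors are rescaled to geometric mean 1; the normalized matrix
    is counts / factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 cells to normalize")
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all-zero count matrix")
    universal = (mat > 0).all(axis=1)
    if universal.any():
        sub = mat[universal]
        log_ref = np.log(sub).mean(axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    else:
        warnings.warn("no gene expressed in all cells; falling back to "
                      "library-size scaling")
        lib = mat.sum(axis=0)
        factors = lib.astype(float)
        empty = lib == 0
        if empty.any():
            # all-zero cells get a neutral factor; downstream callers flag them
            warnings.warn(f"{int(empty.sum())} cell(s) with zero total counts "
                          "assigned a neutral size factor")
            factors[empty] = np.exp(np.mean(np.log(lib[~empty])))
    factors = factors / np.exp(np.mean(np.log(factors)))
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    return counts / factors, sf


def fit_cv2_trend(means, cv2s, robust: bool = False) -> tuple[float, float]:
    """Fit the mean-variability trend CV²(m) = a + b/m by least squares.

    The model is linear in (a, b); ``robust=True`` refits with a soft-L1
    loss so single extreme genes do not drag the trend.
    """
    m = np.asarray(means, dtype=float)
    c = np.asarray(cv2s, dtype=float)
    keep = (m > 0) & np.isfinite(c)
    m, c = m[keep], c[keep]
    if m.size < 10:
        raise ValueError("need >= 10 genes with positive mean to fit the trend")
    if np.ptp(m) == 0:
        raise ValueError("degenerate input: all gene means identical")
    X = np.column_stack([np.ones_like(m), 1.0 / m])
    coef, *_ = np.linalg.lstsq(X, c, rcond=None)
    if robust:
        sol = optimize.least_squares(lambda th: X @ th - c, coef, loss="soft_l1",
                                     f_scale=np.std(c) or 1.0)
        coef = sol.x
    return float(coef[0]), float(coef[1])


def _excess_variability(norm: pd.DataFrame, fdr_threshold: float,
                        n_bins: int, robust_trend: bool) -> pd.DataFrame:
    """Core excess-CV² test on a normalized (sub)matrix."""
    mat = norm.to_numpy(dtype=float)
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = var / mean**2
    testable = (mean > 0) & np.isfinite(cv2) & (cv2 > 0)

    a, b = fit_cv2_trend(mean[testable], cv2[testable], robust=robust_trend)
    expected = np.full_like(mean, np.nan)
    expected[testable] = np.maximum(a + b / mean[testable], 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cv2 / expected
    log_ratio = np.where(testable, np.log(np.where(testable, ratio, 1.0)), np.nan)

    spread = _binned_spread(mean, log_ratio, testable, n_bins)
    z = np.full_like(mean, np.nan)
    z[testable] = log_ratio[testable] / spread[testable]
    pval = np.full_like(mean, np.nan)
    pval[testable] = stats.norm.sf(z[testable])

    fdr = np.full_like(mean, np.nan)
    if testable.any():
        fdr[testable] = multipletests(pval[testable], method="fdr_bh")[1]
    variable = testable & (fdr < fdr_threshold)

    return pd.DataFrame({
        "mean": mean, "cv2_obs": cv2, "cv2_expected": expected,
        "ratio": ratio, "z": z, "p_value": pval, "fdr": fdr,
        "variable": variable,
    }, index=norm.index)


def _binned_spread(mean, log_ratio, testable, n_bins: int) -> np.ndarray:
    """Mean-dependent null spread of log(CV² ratio) in equal-occupancy
    log-mean bins, linearly interpolated between bin centres.

    Within a bin the spread is estimated from the lower quartile of the
    deviations (-q25 / 0.6745, the normal-consistent left-sided scale).
    Genuinely variable genes contaminate only the upper tail, so a
    left-sided estimator stays calibrated even when a mean bin is rich in
    true positives.
    """
    idx = np.where(testable)[0]
    lm = np.log(mean[idx])
    lr = log_ratio[idx]
    order = np.argsort(lm)
    n_bins = max(1, min(n_bins, idx.size // 10 or 1))
    splits = np.array_split(order, n_bins)
    centres, sds = [], []
    for sp in splits:
        if sp.size == 0:
            continue
        vals = lr[sp]
        sd = -np.quantile(vals, 0.25) / 0.6745
        if sd <= 0:  # degenerate bin (few negative deviations): fall back
            sd = 1.4826 * np.median(np.abs(vals - np.median(vals)))
        if sd <= 0:
            sd = np.std(vals) or 1e-6
        centres.append(np.mean(lm[sp]))
        sds.append(sd)
    out = np.full(mean.shape, np.nan)
    if len(centres) == 1:
        out[idx] = sds[0]
    else:
        out[idx] = np.interp(lm, np.asarray(centres), np.asarray(sds))
    return out


def call_variable_genes(counts: pd.DataFrame, fdr_threshold: float = 0.05,
                        min_count: int = 5, n_bins: int = 20,
                        robust_trend: bool = True) -> pd.DataFrame:
    """Call genes with excess CV² from a raw count matrix.

    Normalizes, drops genes with fewer than ``min_count`` total raw counts,
    fits the a + b/m trend, applies the one-sided mean-binned z-test and BH
    FDR.  Returns a per-gene table (over all input genes; untestable genes
    carry NaN statistics and ``variable=False``).
    """
    norm, _ = normalize_counts(counts)
    low = counts.sum(axis=1) < min_count
    res = _excess_variability(norm.loc[~low], fdr_threshold, n_bins, robust_trend)
    res = res.reindex(counts.index)
    res["variable"] = res["variable"].fillna(False).astype(bool)
    return res


def auroc_association(norm: pd.DataFrame, group_labels,
                      threshold: float = 0.65) -> pd.DataFrame:
    """Per-gene AUROC of expression discriminating each cell group vs rest.

    The AUROC is the Mann-Whitney U statistic normalized by n1*n2,
    computed from average ranks (ties shared).  A gene's association score
    is the max over groups; genes above ``threshold`` are flagged as
    cycle-associated.
    """
    labels = pd.Series(np.asarray(group_labels), index=norm.columns)
    groups = labels.dropna().unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 cell groups for AUROC association")
    counts_per = labels.value_counts()
    if (counts_per < 2).any():
        raise ValueError("each group needs >= 2 cells")
    mat = norm.to_numpy(dtype=float)
    ranks = stats.rankdata(mat, axis=1)
    n_cells = mat.shape[1]
    out = {}
    for g in groups:
        in_g = (labels == g).to_numpy()
        n1 = int(in_g.sum())
        n2 = n_cells - n1
        u = ranks[:, in_g].sum(axis=1) - n1 * (n1 + 1) / 2.0
        out[f"auroc_{g}"] = u / (n1 * n2)
    res = pd.DataFrame(out, index=norm.index)
    res["max_auroc"] = res.max(axis=1)
    res["cycle_associated"] = res["max_auroc"] > threshold
    return res


def partition_variable_genes(variability: pd.DataFrame,
                             cycle_flags: pd.Series) -> pd.Series:
    """Split genes into not_variable / variable_cycle / variable_stochastic.

    Exhaustive and disjoint: every gene in the shared universe gets
    exactly one class.
    """
    if not variability.index.equals(cycle_flags.index):
        raise ValueError("variability and AUROC tables cover different genes")
    cls = np.where(
        ~variability["variable"].to_numpy(bool), "not_variable",
        np.where(cycle_flags.to_numpy(bool), "variable_cycle",
                 "variable_stochastic"),
    )
    return pd.Series(cls, index=variability.index, name="class")


def within_group_cv2(counts: pd.DataFrame, group_labels,
                     fdr_threshold: float = 0.05, min_count: int = 5,
                     n_bins: int = 20,
                     robust_trend: bool = True) -> dict[str, pd.DataFrame]:
    """Re-run the excess-CV² test independently within each cell group.

    Genes stochastically bursty irrespective of cycle stage stay variable
    inside every group.  Groups with fewer than 3 cells are skipped with a
    warning.  Normalization is performed once on the full matrix so size
    factors are shared across groups.
    """
    norm, _ = normalize_counts(counts)
    labels = pd.Series(np.asarray(group_labels), index=counts.columns)
    results: dict[str, pd.DataFrame] = {}
    for g, cells in labels.groupby(labels).groups.items():
        if len(cells) < 3:
            warnings.warn(f"group {g!r} has < 3 cells; skipped")
            continue
        sub = norm[list(cells)]
        low = counts[list(cells)].sum(axis=1) < min_count
        res = _excess_variability(sub.loc[~low], fdr_threshold, n_bins,
                                  robust_trend)
        res = res.reindex(counts.index)
        res["variable"] = res["variable"].astype("boolean").fillna(False).astype(bool)
        results[str(g)] = res
    return results


def assign_cell_cycle_phase(counts: pd.DataFrame, ms_marker_ids,
                            g2_marker_ids,
                            pseudocount: float = 0.5) -> pd.DataFrame:
    """Assign each cell to M/S or G2 phase from marker-set expression.

    Marker sets are filtered to genes present in the matrix with any
    expression; a cell's score per set is its mean normalized expression
    over the set.  The log ratio of M/S to G2 scores (with a pseudocount)
    is standardized across cells; standardized ratio > 0 calls M/S, else
    G2.  Cells with zero expression of both sets are left unassigned.
    """
    norm, _ = normalize_counts(counts)
    ms = [g for g in ms_marker_ids if g in norm.index and counts.loc[g].sum() > 0]
    g2 = [g for g in g2_marker_ids if g in norm.index and counts.loc[g].sum() > 0]
    if not ms or not g2:
        raise ValueError("marker sets are empty after filtering to expressed genes")
    ms_score = norm.loc[ms].mean(axis=0)
    g2_score = norm.loc[g2].mean(axis=0)
    log_ratio = np.log((ms_score + pseudocount) / (g2_score + pseudocount))
    assignable = (ms_score + g2_score) > 0
    mu = log_ratio[assignable].mean()
    sd = log_ratio[assignable].std(ddof=0)
    std_ratio = (log_ratio - mu) / (sd if sd > 0 else 1.0)
    phase = pd.Series(pd.NA, index=norm.columns, dtype="object")
    phase[assignable] = np.where(std_ratio[assignable] > 0, "MS", "G2")
    return pd.DataFrame({
        "MS_score": ms_score, "G2_score": g2_score,
        "ratio": std_ratio, "phase": phase,
        "assigned": assignable,
    })
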