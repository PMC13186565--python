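"""Variability caller, AUROC association and phase assignment tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from dictyfate import (
    GeneClassSpec,
    assign_cell_cycle_phase,
    auroc_association,
    call_variable_genes,
    fit_cv2_trend,
    normalize_counts,
    partition_variable_genes,
    simulate_expression_matrix,
    within_group_cv2,
)

from conftest import stable_gene_spec


class TestNormalizeCounts:
    def test_identical_cells_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 5, 3], "b": [10, 5, 3]},
                              index=["g1", "g2", "g3"])
        _, sf = normalize_counts(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_cell_median_of_ratios(self):
        # cell b = 2x cell a: factors are (1/sqrt(2), sqrt(2))
        counts = pd.DataFrame({"a": [10, 4, 6], "b": [20, 8, 12]},
                              index=["g1", "g2", "g3"])
        norm, sf = normalize_counts(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert sf["b"] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert np.allclose(norm["a"], norm["b"])

    def test_sparse_fallback_warns(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="library-size"):
            _, sf = normalize_counts(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [0, 0]})
        with pytest.raises(ValueError):
            normalize_counts(counts)

    def test_normalization_undoes_per_cell_size_factors(self, small_matrix):
        # multiplying each cell by its own size factor (geometric mean 1)
        # must not change the normalized matrix
        counts = small_matrix.counts
        norm_a, sf = normalize_counts(counts)
        norm_b, _ = normalize_counts(counts * sf)
        assert np.max(np.abs(norm_a.to_numpy() - norm_b.to_numpy())) < 1e-9


class TestCv2Trend:
    def test_exact_recovery(self):
        m = np.geomspace(1, 100, 50)
        cv2 = 0.1 + 5.0 / m
        a, b = fit_cv2_trend(m, cv2)
        assert a == pytest.approx(0.1, abs=1e-6)
        assert b == pytest.approx(5.0, abs=1e-6)

    def test_poisson_genes_give_inverse_mean_trend(self):
        rng = np.random.default_rng(1)
        means = np.geomspace(2, 200, 400)
        counts = rng.poisson(means[:, None], size=(400, 500)).astype(float)
        m = counts.mean(axis=1)
        cv2 = counts.var(axis=1, ddof=1) / m**2
        a, b = fit_cv2_trend(m, cv2)
        assert a == pytest.approx(0.0, abs=0.02)   # no overdispersion
        assert b == pytest.approx(1.0, rel=0.15)   # CV2 = 1/mean

    def test_robust_mode_resists_outlier(self):
        m = np.geomspace(1, 100, 100)
        cv2 = 0.1 + 5.0 / m
        m_out = np.append(m, 2.0)
        cv2_out = np.append(cv2, 50.0)
        a0, b0 = fit_cv2_trend(m, cv2, robust=True)
        a1, b1 = fit_cv2_trend(m_out, cv2_out, robust=True)
        assert abs(b1 - b0) / b0 < 0.05
        assert abs(a1 - a0) < 0.05 * (0.1 + 5.0)

    def test_degenerate_means_rejected(self):
        with pytest.raises(ValueError):
            fit_cv2_trend(np.full(20, 3.0), np.linspace(0.1, 1, 20))


class TestCallVariableGenes:
    def test_all_stable_false_positives_bounded(self):
        mtx = simulate_expression_matrix(300, stable_gene_spec(1000), seed=50)
        res = call_variable_genes(mtx.counts, fdr_threshold=0.05)
        assert res["variable"].mean() <= 0.05

    def test_planted_telegraph_genes_recalled(self):
        spec = stable_gene_spec(950) + [GeneClassSpec("stochastic", 50,
                                                      p=0.1, b=50.0)]
        mtx = simulate_expression_matrix(2000, spec, seed=51)
        res = call_variable_genes(mtx.counts, fdr_threshold=0.05)
        is_tele = (mtx.gene_truth["class"] == "stochastic").to_numpy()
        recall = res["variable"].to_numpy()[is_tele].mean()
        assert recall >= 0.9

    def test_zero_fdr_threshold_calls_nothing(self, small_matrix):
        res = call_variable_genes(small_matrix.counts, fdr_threshold=0.0)
        assert not res["variable"].any()

    def test_low_count_genes_excluded(self, small_matrix):
        counts = small_matrix.counts.copy()
        counts.iloc[0] = 0
        counts.iloc[0, 0] = 2  # 2 < min_count=5 total
        res = call_variable_genes(counts, min_count=5)
        assert np.isnan(res["p_value"].iloc[0])
        assert not res["variable"].iloc[0]


class TestBenjaminiHochberg:
    def _brute_force_bh(self, p):
        # textbook step-up: adjusted p = cummin over descending rank of p*n/i
        p = np.asarray(p)
        n = p.size
        order = np.argsort(p)
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(adj, 1.0)
        return out

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(10, 1000))
        assert np.allclose(multipletests(p, method="fdr_bh")[1],
                           self._brute_force_bh(p), atol=1e-12)


class TestAurocAssociation:
    def _norm_with_labels(self, seed=60):
        spec = [GeneClassSpec("cycle_MS", 10, mean=10, phase_multiplier=5.0),
                GeneClassSpec("stable", 30, mean=10)]
        mtx = simulate_expression_matrix(200, spec, seed=seed)
        norm, _ = normalize_counts(mtx.counts)
        return norm, mtx.cell_truth["phase"]

    def test_exclusive_gene_has_auroc_one(self):
        norm = pd.DataFrame([[5.0, 6.0, 0.0, 0.0]], index=["g"],
                            columns=list("abcd"))
        labels = ["grp1", "grp1", "grp2", "grp2"]
        res = auroc_association(norm, labels)
        assert res.loc["g", "auroc_grp1"] == 1.0

    def test_label_independent_gene_near_half(self):
        rng = np.random.default_rng(2)
        norm = pd.DataFrame(rng.poisson(10, size=(200, 400)).astype(float))
        labels = np.repeat(["a", "b"], 200)
        res = auroc_association(norm, labels)
        # permutation null: AUROC sd ~ sqrt((n1+n2+1)/(12 n1 n2)) ~ 0.029
        assert abs(res["max_auroc"].mean() - 0.5) < 0.05
        assert res["cycle_associated"].mean() < 0.2

    def test_flipping_labels_mirrors_auroc(self):
        norm, phase = self._norm_with_labels()
        binary = np.where(phase == "MS", "MS", "G2")
        res = auroc_association(norm, binary)
        assert np.allclose(res["auroc_MS"], 1.0 - res["auroc_G2"], atol=1e-12)

    def test_matches_sklearn(self):
        norm, phase = self._norm_with_labels()
        res = auroc_association(norm, phase)
        for g in norm.index[:10]:
            expected = roc_auc_score((phase == "MS").astype(int), norm.loc[g])
            assert res.loc[g, "auroc_MS"] == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        labels = ["a"] * 5 + ["b"] * 7
        norm = pd.DataFrame([x], index=["g"], columns=[f"c{i}" for i in range(12)])
        res = auroc_association(norm, labels)
        pos, neg = x[:5], x[5:]
        pairs = sum((pi > ni) + 0.5 * (pi == ni) for pi in pos for ni in neg)
        assert res.loc["g", "auroc_a"] == pytest.approx(pairs / 35, abs=1e-12)

    def test_single_group_rejected(self):
        norm = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            auroc_association(norm, ["a"] * 4)


class TestPartition:
    def test_planted_classes_recovered(self, small_matrix):
        counts = small_matrix.counts
        res = call_variable_genes(counts, fdr_threshold=0.05)
        norm, _ = normalize_counts(counts)
        aur = auroc_association(norm, small_matrix.cell_truth["phase"])
        classes = partition_variable_genes(res, aur["cycle_associated"])
        truth = small_matrix.gene_truth["class"]
        pred_stochastic = classes == "variable_stochastic"
        true_stochastic = (truth == "stochastic").to_numpy()
        acc = (pred_stochastic.to_numpy() == true_stochastic).mean()
        assert acc >= 0.9
        # partition is exhaustive and disjoint by construction
        assert set(classes.unique()) <= {"not_variable", "variable_cycle",
                                         "variable_stochastic"}

    def test_no_variable_genes_gives_empty_classes(self, small_matrix):
        res = call_variable_genes(small_matrix.counts, fdr_threshold=0.0)
        flags = pd.Series(True, index=res.index)
        classes = partition_variable_genes(res, flags)
        assert (classes == "not_variable").all()

    def test_mismatched_universes_rejected(self, small_matrix):
        res = call_variable_genes(small_matrix.counts)
        with pytest.raises(ValueError):
            partition_variable_genes(res, pd.Series(True, index=["x", "y"]))


class TestWithinGroupCv2:
    def test_telegraph_genes_variable_within_every_group(self):
        spec = stable_gene_spec(570) + [GeneClassSpec("stochastic", 30,
                                                      p=0.1, b=50.0)]
        mtx = simulate_expression_matrix(900, spec, seed=70)
        groups = mtx.cell_truth["phase"]
        results = within_group_cv2(mtx.counts, groups)
        assert set(results) == {"MS", "G2.1", "G2.2"}
        is_tele = (mtx.gene_truth["class"] == "stochastic").to_numpy()
        for g, res in results.items():
            recall = res["variable"].to_numpy()[is_tele].mean()
            assert recall >= 0.8, g

    def test_homogeneous_fixture_controls_type_one(self):
        mtx = simulate_expression_matrix(600, stable_gene_spec(600), seed=71)
        results = within_group_cv2(mtx.counts, mtx.cell_truth["phase"])
        for res in results.values():
            assert res["variable"].mean() <= 0.05

    def test_tiny_group_skipped_with_warning(self, small_matrix):
        groups = np.array(["big"] * 298 + ["tiny"] * 2)
        with pytest.warns(UserWarning, match="tiny"):
            results = within_group_cv2(small_matrix.counts, groups)
        assert "tiny" not in results


class TestPhaseAssignment:
    def _marker_matrix(self, seed=80, n_cells=300):
        spec = [GeneClassSpec("cycle_MS", 20, mean=10, phase_multiplier=5.0),
                GeneClassSpec("cycle_G2", 20, mean=10, phase_multiplier=5.0),
                GeneClassSpec("stable", 60, mean=20)]
        mtx = simulate_expression_matrix(n_cells, spec, seed=seed)
        ms_ids = list(mtx.counts.index[:20])
        g2_ids = list(mtx.counts.index[20:40])
        return mtx, ms_ids, g2_ids

    def test_truth_phase_recovered(self):
        mtx, ms_ids, g2_ids = self._marker_matrix()
        res = assign_cell_cycle_phase(mtx.counts, ms_ids, g2_ids)
        truth = np.where(mtx.cell_truth["phase"] == "MS", "MS", "G2")
        acc = (res["phase"].to_numpy() == truth).mean()
        assert acc >= 0.9

    def test_exclusively_ms_cell_called_ms(self):
        counts = pd.DataFrame(
            {"c_ms": [50, 60, 0, 0, 10], "other1": [5, 5, 40, 50, 10],
             "other2": [6, 4, 45, 55, 10]},
            index=["ms1", "ms2", "g21", "g22", "house"])
        res = assign_cell_cycle_phase(counts, ["ms1", "ms2"], ["g21", "g22"])
        assert res.loc["c_ms", "phase"] == "MS"

    def test_all_zero_cell_unassigned(self):
        counts = pd.DataFrame(
            {"c1": [10, 8, 5], "c2": [4, 12, 5], "dead": [0, 0, 0]},
            index=["ms1", "g21", "house"])
        res = assign_cell_cycle_phase(counts, ["ms1"], ["g21"])
        assert not res.loc["dead", "assigned"]
        assert pd.isna(res.loc["dead", "phase"])

    def test_empty_marker_overlap_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            assign_cell_cycle_phase(small_matrix.counts, ["nope"], ["nada"])
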