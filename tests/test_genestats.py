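"""Window scores, correlation machinery, group tests, enrichment, CyTOF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import h33dyn as h
from helpers import (
    constant_track,
    make_layout,
    mirror_gene,
    mirror_track,
    oracle_bh,
    oracle_hypergeom_upper,
    oracle_mannwhitney_exact,
    oracle_spearman_rho,
    oracle_two_sample_t,
    oracle_window_score,
    random_track,
)


class TestGeneWindowScore:
    def test_constant_track_scores_constant(self):
        layout = make_layout({"chr1": 30000})
        genes = [h.GeneModel("a", "chr1", "+", 10000, 15000),
                 h.GeneModel("b", "chr1", "-", 12000, 20000)]
        scores = h.gene_window_score(constant_track(layout, 3.5), genes, exclude_chroms=())
        assert (scores.scores == 3.5).all()

    def test_single_hot_bin_among_nine(self):
        # value 9 in exactly one of the 9 window bins averages to 1.0
        layout = make_layout({"chr1": 30000})
        gene = h.GeneModel("g", "chr1", "+", 10000, 15000)
        values = {"chr1": np.zeros(150)}
        values["chr1"][(10000 - 1100) // 200] = 9.0  # midpoint offset -1100, upstream window
        track = h.BinnedTrack(layout=layout, values=values, total_mapped=9.0)
        scores = h.gene_window_score(track, [gene], exclude_chroms=())
        assert scores.scores["g"] == pytest.approx(1.0)

    def test_minus_strand_counts_physical_upstream_as_downstream(self):
        layout = make_layout({"chr1": 30000})
        gene = h.GeneModel("g", "chr1", "-", 5000, 15000)  # tss at 15000
        values = {"chr1": np.zeros(150)}
        # physically upstream of txEnd = downstream of transcription start
        values["chr1"][(15000 - 600) // 200] = 4.5  # oriented offset +500, in (+400, +1200)
        track = h.BinnedTrack(layout=layout, values=values, total_mapped=4.5)
        scores = h.gene_window_score(track, [gene], exclude_chroms=())
        assert scores.scores["g"] == pytest.approx(0.5)
        assert oracle_window_score(track, gene) == pytest.approx(0.5)

    def test_matches_base_pair_oracle_on_random_genes(self):
        layout = make_layout({"chr1": 60000})
        rng = np.random.default_rng(21)
        track = random_track(rng, layout)
        for _ in range(30):
            tss = int(rng.integers(5000, 55000))
            strand = rng.choice(["+", "-"])
            if strand == "+":
                gene = h.GeneModel("g", "chr1", "+", tss, tss + 3000)
            else:
                gene = h.GeneModel("g", "chr1", "-", tss - 3000, tss)
            score = h.gene_window_score(track, [gene], exclude_chroms=()).scores["g"]
            assert score == pytest.approx(oracle_window_score(track, gene), abs=1e-12)

    def test_mirror_invariance_exact(self):
        layout = make_layout({"chr1": 60000})
        rng = np.random.default_rng(22)
        track = random_track(rng, layout)
        mirrored = mirror_track(track)
        for _ in range(20):
            tss = int(rng.integers(5000, 55000))
            gene = h.GeneModel("g", "chr1", "+", tss, tss + 2000)
            s1 = h.gene_window_score(track, [gene], exclude_chroms=()).scores["g"]
            s2 = h.gene_window_score(mirrored, [mirror_gene(gene, 60000)],
                                     exclude_chroms=()).scores["g"]
            # identical bins either side; only the summation order differs
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_boundary_genes_dropped_excluded_chroms_absent(self):
        layout = make_layout({"chr1": 30000, "chr8": 30000})
        genes = [h.GeneModel("edge", "chr1", "+", 400, 2000),
                 h.GeneModel("mid", "chr1", "+", 10000, 12000),
                 h.GeneModel("dup8", "chr8", "+", 10000, 12000)]
        scores = h.gene_window_score(constant_track(layout), genes)
        assert list(scores.scores.index) == ["mid"]
        assert scores.n_dropped == 1
        with pytest.raises(ValueError, match="all genes dropped"):
            h.gene_window_score(constant_track(layout), [genes[0]])


class TestSpearman:
    def test_perfect_monotone(self):
        assert h.spearman_correlation([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert h.spearman_correlation([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_pearson_oracle(self):
        x, y = [1, 1, 2, 3], [2, 1, 4, 3]
        assert h.spearman_correlation(x, y).rho == pytest.approx(oracle_spearman_rho(x, y))
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert h.spearman_correlation(x, y).rho == pytest.approx(oracle_spearman_rho(x, y))

    def test_exact_permutation_p_small_n(self):
        # perfect rank agreement at n=4: only 2 of 24 permutations reach |rho| = 1
        report = h.spearman_correlation([1, 2, 3, 4], [5, 6, 7, 8])
        assert report.p_value == pytest.approx(2 / 24)
        assert "permutation" in report.method

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            h.spearman_correlation([1.0, 1.0, 1.0], [1, 2, 3])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-100, 100), min_size=5, max_size=12, unique=True).map(sorted),
           st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, xs, seed):
        rng = np.random.default_rng(seed)
        y = rng.permutation(len(xs)).astype(float)
        x = np.array(xs, dtype=float)
        if np.ptp(y) == 0:
            return
        base = h.spearman_correlation(x, y).rho
        assert h.spearman_correlation(np.exp(x / 50), y).rho == pytest.approx(base)
        assert h.spearman_correlation(x, 3 * y + 7).rho == pytest.approx(base)


class TestGroupComparisons:
    def test_t_matches_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        stat, p = h.compare_group_scores(a, b, test="t")
        t_oracle, p_oracle = oracle_two_sample_t(a, b)
        assert stat == pytest.approx(t_oracle)
        assert p == pytest.approx(p_oracle)

    def test_u_exact_small_n(self):
        stat, p = h.compare_group_scores([1, 2], [3, 4, 5])
        assert stat == 0.0
        assert p == pytest.approx(2 / 10)
        _, p_oracle = oracle_mannwhitney_exact([1, 2], [3, 4, 5])
        assert p == pytest.approx(p_oracle)

    def test_identical_groups_p_one(self):
        _, p = h.compare_group_scores([1, 2, 3], [1, 2, 3], test="u")
        assert p == pytest.approx(1.0)

    def test_unequal_sizes_default_to_u(self):
        stat_u, p_u = h.compare_group_scores([1, 2], [3, 4, 5])
        stat_forced, p_forced = h.compare_group_scores([1, 2], [3, 4, 5], test="u")
        assert (stat_u, p_u) == (stat_forced, p_forced)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            h.compare_group_scores([], [1.0])


class TestCompareCorrelations:
    def test_equal_correlations_give_unit_p(self):
        z, p = h.compare_correlations(0.4, 100, 0.4, 50)
        assert z == 0.0 and p == 1.0

    def test_matches_hand_computed_fisher_formula(self):
        z, p = h.compare_correlations(0.5, 500, 0.3, 500)
        z_hand = (np.arctanh(0.5) - np.arctanh(0.3)) / np.sqrt(2 / 497)
        assert z == pytest.approx(z_hand)
        from scipy.stats import norm
        assert p == pytest.approx(2 * norm.sf(abs(z_hand)))

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError, match="Fisher z"):
            h.compare_correlations(1.0, 100, 0.5, 100)

    def test_nominal_type_one_error_on_bivariate_normal_null(self):
        """Equal population correlations: rejection at alpha=0.05 within 2 MC SE."""
        rng = np.random.default_rng(55)
        n, reps, rho = 100, 1000, 0.4
        cov = [[1, rho], [rho, 1]]
        rejections = 0
        for _ in range(reps):
            a = rng.multivariate_normal([0, 0], cov, n)
            b = rng.multivariate_normal([0, 0], cov, n)
            ra = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
            rb = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
            rejections += h.compare_correlations(ra, n, rb, n)[1] < 0.05
        se2 = 2 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= se2


class TestEnrichment:
    def test_whole_universe_category_is_unenriched(self):
        genes = [f"g{i}" for i in range(10)]
        table = h.hypergeometric_enrichment(genes, genes, {"all": genes})
        assert table.loc["all", "p"] == pytest.approx(1.0)
        assert table.loc["all", "fold"] == pytest.approx(1.0)

    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        cat = universe[:5]
        table = h.hypergeometric_enrichment(cat, universe, {"c": cat})
        from math import comb
        assert table.loc["c", "p"] == pytest.approx(1 / comb(20, 5))
        assert table.loc["c", "p"] == pytest.approx(oracle_hypergeom_upper(5, 20, 5, 5))

    def test_random_instances_match_summation_oracle(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            cat = list(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            gset = list(rng.choice(universe, size=rng.integers(1, 15), replace=False))
            table = h.hypergeometric_enrichment(gset, universe, {"c": cat})
            k = len(set(cat) & set(gset))
            assert table.loc["c", "p"] == pytest.approx(
                oracle_hypergeom_upper(k, 30, len(cat), len(gset)))

    def test_bh_correction_and_monotonicity(self):
        universe = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(8)
        cats = {f"c{j}": list(rng.choice(universe, size=10, replace=False)) for j in range(6)}
        table = h.hypergeometric_enrichment(universe[:8], universe, cats)
        np.testing.assert_allclose(table["q"], oracle_bh(table["p"].to_numpy()))
        assert (table["q"] >= table["p"] - 1e-12).all()
        ordered = table.sort_values("p")
        assert ordered["q"].is_monotonic_increasing

    def test_bh_hand_example(self):
        from scipy.stats import false_discovery_control
        np.testing.assert_allclose(false_discovery_control([0.01, 0.02, 0.03, 0.04], method="bh"),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(oracle_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            h.hypergeometric_enrichment(["x"], ["a", "b"], {})
        with pytest.raises(ValueError, match="empty universe"):
            h.hypergeometric_enrichment([], [], {})


class TestCytof:
    def _matrix(self, data, roles):
        return h.CytofMatrix(data=pd.DataFrame(data), roles=roles)

    def test_zero_variance_marker_named_in_error(self):
        m = self._matrix({"H3": [1.0, 1.0], "K27me3": [0.5, 2.0]},
                         {"H3": "core_histone", "K27me3": "epigenetic"})
        with pytest.raises(ValueError, match="H3"):
            h.cytof_normalize(m)

    def test_epigenetic_equal_to_sole_core_cancels(self):
        m = self._matrix({"H3": [1.0, 4.0, 9.0], "mark": [1.0, 4.0, 9.0]},
                         {"H3": "core_histone", "mark": "epigenetic"})
        out = h.cytof_normalize(m)
        np.testing.assert_allclose(out.data["mark"], 0.0, atol=1e-12)

    def test_two_cell_toy_matches_hand_computation(self):
        data = {"H3": [2.0, 8.0], "H4": [1.0, 3.0], "mark": [0.0, 5.0], "other": [1.0, 2.0]}
        roles = {"H3": "core_histone", "H4": "core_histone",
                 "mark": "epigenetic", "other": "other"}
        out = h.cytof_normalize(self._matrix(data, roles), cofactor=5.0)
        t = {k: np.arcsinh(np.array(v) / 5.0) for k, v in data.items()}
        z = {k: (v - v.mean()) / v.std() for k, v in t.items()}
        core = (z["H3"] + z["H4"]) / 2
        np.testing.assert_allclose(out.data["mark"], z["mark"] - core)
        np.testing.assert_allclose(out.data["H3"], z["H3"])  # cores stay standardised
        np.testing.assert_allclose(out.data["other"], z["other"])

    def test_requires_core_histone(self):
        m = self._matrix({"mark": [0.5, 2.0]}, {"mark": "epigenetic"})
        with pytest.raises(ValueError, match="core_histone"):
            h.cytof_normalize(m)


class TestBindingExpressionCorrelation:
    def _expr(self, values, n_samples=1):
        genes = list(values.index)
        tpm = pd.DataFrame({f"s{i}": values for i in range(n_samples)}, index=genes)
        meta = pd.DataFrame({"line": "WT", "timepoint_h": 72, "state": "ESC",
                             "replicate": range(n_samples)}, index=tpm.columns)
        return h.ExpressionMatrix(tpm=tpm, meta=meta)

    def test_monotone_scores_give_unit_rho(self):
        vals = pd.Series(np.arange(1.0, 13.0), index=[f"g{i}" for i in range(12)])
        scores = h.GeneScoreVector(scores=vals**2)
        report = h.binding_expression_correlation(scores, self._expr(vals), "s0")
        assert report.rho == pytest.approx(1.0)

    def test_small_intersection_rejected(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        scores = h.GeneScoreVector(scores=vals)
        with pytest.raises(ValueError, match="shared"):
            h.binding_expression_correlation(scores, self._expr(vals), "s0")


class TestCorrelationMatrix:
    def test_duplicated_vectors_give_all_ones(self):
        v = pd.Series(np.arange(12.0), index=[f"g{i}" for i in range(12)])
        mat = h.correlation_matrix([v, v.copy(), v.copy()])
        np.testing.assert_allclose(mat.to_numpy(), 1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(12)
        idx = [f"g{i}" for i in range(30)]
        vs = [pd.Series(rng.random(30), index=idx) for _ in range(3)]
        mat = h.correlation_matrix(vs, labels=["a", "b", "c"]).to_numpy()
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 1.0)
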