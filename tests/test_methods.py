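"""Correctness of the six enrichment methods against independent oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_es, hypergeom_tail_by_enumeration

from gsebench import (
    ExpressionDataset,
    GeneSetCollection,
    get_method,
    list_methods,
    run_camera,
    run_gsea,
    run_method,
    run_ora,
    run_padog,
    run_safe,
    run_samgs,
)
from gsebench.genestats import sam_t_matrix, ordinary_t_matrix
from gsebench.methods import (
    enrichment_scores,
    membership_matrix,
    padog_gene_weights,
    permutation_pvalue,
    permuted_indicators,
    variance_inflation_factor,
)

ALL_IMPLEMENTED = ["ora", "gsea", "safe", "padog", "camera", "samgs"]


class TestPermutationPvalue:
    @pytest.mark.parametrize(
        "observed,null,tail,expected",
        [
            (10.0, np.zeros(99), "upper", 0.01),          # b=0, B=99
            (0.0, np.zeros(99), "upper", 1.0),            # b=B
            (5.0, np.array([1.0, 6.0, 7.0]), "upper", 0.75),
            (-5.0, np.array([1.0, -6.0, 7.0]), "two_sided", 0.75),
        ],
    )
    def test_formula(self, observed, null, tail, expected):
        assert permutation_pvalue(observed, null, tail) == pytest.approx(expected)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(1.0, [], "upper")

    def test_matches_exhaustive_enumeration_on_3v3_toy(self):
        """Permutation p agrees with brute force over all label assignments."""
        rng = np.random.default_rng(0)
        matrix = rng.normal(size=(5, 6))
        ind_obs = np.array([0, 0, 0, 1, 1, 1])

        def set_stat(ind):
            t, _, _, _ = ordinary_t_matrix(matrix, ind)
            return float(np.sum(t[:3] ** 2))

        obs = set_stat(ind_obs)
        null = []
        for ones in combinations(range(6), 3):
            ind = np.zeros(6, dtype=int)
            ind[list(ones)] = 1
            null.append(set_stat(ind))
        p = permutation_pvalue(obs, np.asarray(null), "upper")
        b = sum(v >= obs for v in null)
        assert p == pytest.approx((b + 1) / (len(null) + 1))
        assert 0 < p <= 1

    def test_block_respecting_shuffles_stay_within_blocks(self):
        ind = np.array([0, 1, 0, 1, 0, 1])
        blocks = ["a", "a", "b", "b", "c", "c"]
        perms = permuted_indicators(ind, 50, np.random.default_rng(1), blocks)
        # each pair keeps exactly one case label
        sums = perms.reshape(50, 3, 2).sum(axis=2)
        assert np.all(sums == 1)


class TestOra:
    def test_exact_hypergeometric_examples(self, toy_collection):
        universe = {f"g{i}" for i in range(1, 11)}
        de = {"g1", "g2", "g3", "g4", "g5"}
        coll = GeneSetCollection(sets={"S": ["g1", "g2"]})
        r = run_ora(de, universe, coll)
        assert r.table.p_value[0] == pytest.approx(10 / 45)
        assert r.table.statistic[0] == 2

        coll0 = GeneSetCollection(sets={"S": ["g6", "g7"]})
        r0 = run_ora(de, universe, coll0)
        assert r0.table.p_value[0] == pytest.approx(1.0)

        r4 = run_ora({"g1", "g2"}, {"g1", "g2", "g3", "g4"},
                     GeneSetCollection(sets={"S": ["g1"]}))
        assert r4.table.p_value[0] == pytest.approx(0.5)

    def test_matches_enumeration_over_small_configurations(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            N = int(rng.integers(4, 11))
            K = int(rng.integers(1, N))
            m = int(rng.integers(1, N))
            universe = [f"g{i}" for i in range(N)]
            de = set(universe[:K])
            genes = list(rng.choice(universe, size=m, replace=False))
            r = run_ora(de, universe, GeneSetCollection(sets={"S": genes}))
            k = len(de.intersection(genes))
            assert r.table.p_value[0] == pytest.approx(
                hypergeom_tail_by_enumeration(N, K, m, k), abs=1e-12
            )

    def test_empty_de_list_advises_fallback(self, toy_collection):
        with pytest.raises(ValueError, match="fallback"):
            run_ora(set(), {"g1", "g2"}, toy_collection)

    def test_extra_background_genes_do_not_lower_overlap(self):
        universe = {f"g{i}" for i in range(10)}
        de = {"g0", "g1", "g2"}
        coll = GeneSetCollection(sets={"S": ["g0", "g1", "g5"]})
        r_small = run_ora(de, universe, coll)
        r_big = run_ora(de, universe | {f"x{i}" for i in range(10)}, coll)
        assert r_big.table.statistic[0] == r_small.table.statistic[0]
        # a bigger non-DE background makes the same overlap more surprising
        assert r_big.table.p_value[0] <= r_small.table.p_value[0]


class TestGseaScore:
    def test_perfect_separation_scores_plus_minus_one(self):
        s = np.array([4.0, 3.0, 2.0, 1.0])
        top = np.array([[True, True, False, False]])
        bottom = np.array([[False, False, True, True]])
        assert enrichment_scores(s, top, weight_exponent=0)[0] == pytest.approx(1.0)
        assert enrichment_scores(s, bottom, weight_exponent=0)[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("exponent", [0.0, 1.0, 1.5])
    def test_matches_brute_force_on_random_toys(self, exponent):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            s = rng.normal(size=n)
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=int(rng.integers(1, n - 1)), replace=False)] = True
            got = enrichment_scores(s, m[None, :], weight_exponent=exponent)[0]
            want = brute_force_es(s, m, exponent)
            assert got == pytest.approx(want, abs=1e-12)

    def test_full_or_empty_set_rejected(self):
        s = np.arange(4.0)
        with pytest.raises(ValueError):
            enrichment_scores(s, np.ones((1, 4), dtype=bool))


class TestSafe:
    def _dataset_with_known_t_order(self):
        """10 genes whose |t| order is forced by effect size."""
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.05, (10, 12))
        shifts = np.linspace(0, 4.5, 10)  # gene 9 most DE
        base[:, 6:] += shifts[:, None]
        return ExpressionDataset(
            matrix=base,
            gene_ids=[f"g{i}" for i in range(10)],
            sample_ids=[f"s{j}" for j in range(12)],
            groups=["A"] * 6 + ["B"] * 6,
        )

    def test_top_t_set_attains_maximal_rank_sum(self):
        ds = self._dataset_with_known_t_order()
        coll = GeneSetCollection(sets={"top": ["g7", "g8", "g9"], "rest": ["g0", "g1"]})
        r = run_safe(ds, coll, n_perm=20, seed=0)
        row = r.table.set_index("set_id")
        assert row.loc["top", "statistic"] == pytest.approx(8 + 9 + 10)

    def test_identical_statistics_sit_at_expected_rank_sum(self):
        # every gene carries the same sample pattern, so all |t| are exactly
        # tied and midranks put each set gene at (N+1)/2
        row = np.array([0.1, -0.2, 0.05, 1.1, 0.9, 1.3])
        matrix = np.tile(row, (8, 1))
        ds = ExpressionDataset(
            matrix=matrix,
            gene_ids=[f"g{i}" for i in range(8)],
            sample_ids=[f"s{j}" for j in range(6)],
            groups=["A"] * 3 + ["B"] * 3,
        )
        coll = GeneSetCollection(sets={"S": ["g0", "g1", "g2"]})
        r = run_safe(ds, coll, n_perm=20, seed=0)
        # rank sum expectation for m=3 of N=8: 3 * (8+1)/2 = 13.5
        assert r.table.statistic[0] == pytest.approx(13.5, abs=1.0)

    def test_local_statistic_is_pluggable(self, small_dataset, small_scenario):
        coll, _, _ = small_scenario
        r1 = run_safe(small_dataset, coll, local_stat="ordinary_t", n_perm=30, seed=1)
        r2 = run_safe(small_dataset, coll, local_stat="moderated_t", n_perm=30, seed=1)
        assert r1.set_ids and sorted(r1.set_ids) == sorted(r2.set_ids)
        assert not np.allclose(
            r1.table.sort_values("set_id").statistic,
            r2.table.sort_values("set_id").statistic,
        )
        with pytest.raises(ValueError, match="global"):
            run_safe(small_dataset, coll, global_stat="nope", n_perm=5)

    def test_whole_universe_set_rejected(self, small_dataset):
        coll = GeneSetCollection(sets={"all": list(small_dataset.gene_ids)})
        with pytest.raises(ValueError, match="background"):
            run_safe(small_dataset, coll, n_perm=5)


class TestPadog:
    def test_closed_form_weights(self):
        # frequencies 1..5 across overlapping sets
        gene_ids = [f"g{i}" for i in range(5)]
        sets = {f"S{j}": [g for i, g in enumerate(gene_ids) if i >= 4 - j] for j in range(5)}
        coll = GeneSetCollection(sets=sets)
        w = padog_gene_weights(coll, gene_ids)
        # g0 appears once (f=1 -> w=2), g4 in all five (f=5 -> w=1), f=3 -> ~1.707
        assert w[0] == pytest.approx(2.0)
        assert w[4] == pytest.approx(1.0)
        assert w[2] == pytest.approx(1.0 + np.sqrt(0.5), abs=1e-9)

    def test_disjoint_sets_give_unit_weights_and_mean_stat(self, small_dataset):
        genes = small_dataset.gene_ids
        coll = GeneSetCollection(
            sets={"A": genes[:10], "B": genes[10:20], "C": genes[20:30]}
        )
        w = padog_gene_weights(coll, genes)
        assert np.all(w[:30] == 1.0)
        from gsebench.genestats import moderated_t_matrix

        r = run_padog(small_dataset, coll, n_perm=30, seed=1)
        t, _, _, _ = moderated_t_matrix(small_dataset.matrix, small_dataset.group_indicator())
        expected = np.abs(t[:10]).mean()
        assert r.table.set_index("set_id").loc["A", "statistic"] == pytest.approx(expected)

    def test_pvalues_uniform_on_null_data(self):
        """Standardized permutation p-values are calibrated under the null."""
        from gsebench import sample_random_sets, simulate_expression

        ds, _ = simulate_expression(n_genes=800, n_per_group=8, de_fraction=0.0, seed=55)
        coll = sample_random_sets(ds.gene_ids, size=15, count=200, seed=56)
        r = run_padog(ds, coll, n_perm=200, seed=57)
        ks = stats.kstest(r.table.p_value, "uniform")
        assert ks.pvalue > 0.01

    def test_small_n_perm_warns(self, small_dataset, small_scenario, caplog):
        coll, _, _ = small_scenario
        with caplog.at_level("WARNING"):
            run_padog(small_dataset, coll, n_perm=10, seed=0)
        assert any("unstable" in r.message for r in caplog.records)


class TestCamera:
    def test_vif_arithmetic(self):
        assert variance_inflation_factor(101, 0.01) == pytest.approx(2.0)
        assert variance_inflation_factor(1, 0.5) == pytest.approx(1.0)

    def test_rho_zero_reduces_to_two_sample_t_on_z(self, small_dataset):
        coll = GeneSetCollection(sets={"S": small_dataset.gene_ids[:20]})
        r = run_camera(small_dataset, coll, inter_gene_cor=0.0)
        from gsebench.methods.camera import _moderated_z

        z = _moderated_z(small_dataset)
        t_ref, p_ref = stats.ttest_ind(z[:20], z[20:], equal_var=True)[:2]
        assert r.table.statistic[0] == pytest.approx(float(t_ref), rel=1e-9)

    def test_positive_rho_is_more_conservative(self, small_dataset, small_scenario):
        coll, _, _ = small_scenario
        r0 = run_camera(small_dataset, coll, inter_gene_cor=0.0)
        r1 = run_camera(small_dataset, coll, inter_gene_cor=0.2)
        merged = r0.table.set_index("set_id").join(
            r1.table.set_index("set_id"), lsuffix="_0", rsuffix="_1"
        )
        assert np.all(merged.p_value_1 >= merged.p_value_0 - 1e-12)

    def test_estimated_rho_controls_correlated_null_sets(self):
        """On correlated null data, estimating rho rejects less than rho=0."""
        from gsebench import simulate_expression

        ds, truth = simulate_expression(
            n_genes=1000, n_per_group=10, de_fraction=0.0,
            within_set_cor=0.1, cor_block_size=20, seed=77,
        )
        sets = {f"B{i}": genes for i, genes in enumerate(truth.cor_blocks[:50])}
        coll = GeneSetCollection(sets=sets)
        r_naive = run_camera(ds, coll, inter_gene_cor=0.0)
        r_est = run_camera(ds, coll, inter_gene_cor="estimate")
        frac_naive = float(np.mean(r_naive.table.p_value < 0.05))
        frac_est = float(np.mean(r_est.table.p_value < 0.05))
        assert frac_est <= frac_naive

    def test_whole_universe_set_rejected(self, small_dataset):
        coll = GeneSetCollection(sets={"all": list(small_dataset.gene_ids)})
        with pytest.raises(ValueError, match="background"):
            run_camera(small_dataset, coll)

    def test_singleton_set_is_defined(self, small_dataset):
        coll = GeneSetCollection(sets={"one": [small_dataset.gene_ids[0]]})
        r = run_camera(small_dataset, coll)
        assert np.isfinite(r.table.statistic[0])
        assert 0 < r.table.p_value[0] <= 1


class TestSamgs:
    def test_statistic_is_sum_of_squared_sam_t(self, small_dataset):
        coll = GeneSetCollection(sets={"S": small_dataset.gene_ids[:12]})
        r = run_samgs(small_dataset, coll, n_perm=10, seed=0)
        sam, _, _ = sam_t_matrix(small_dataset.matrix, small_dataset.group_indicator())
        assert r.table.statistic[0] == pytest.approx(float(np.sum(sam[:12] ** 2)))

    def test_monotone_in_nested_sets(self, small_dataset):
        """The self-contained statistic can only grow as a set gains genes."""
        rng = np.random.default_rng(9)
        order = rng.permutation(small_dataset.gene_ids)
        nested = {f"N{k}": list(order[: 5 * (k + 1)]) for k in range(8)}
        r = run_samgs(small_dataset, GeneSetCollection(sets=nested), n_perm=5, seed=0)
        vals = r.table.set_index("set_id").loc[[f"N{k}" for k in range(8)], "statistic"]
        assert np.all(np.diff(vals.to_numpy()) >= -1e-9)


class TestUniformContract:
    @pytest.mark.parametrize("method", ALL_IMPLEMENTED)
    def test_one_row_per_set_and_valid_pvalues(self, method, small_dataset, small_scenario):
        coll, _, _ = small_scenario
        kw = {"n_perm": 25, "seed": 4} if get_method(method).needs_permutations else {}
        r = run_method(method, small_dataset, coll, **kw)
        assert sorted(r.set_ids) == sorted(coll.sets)
        p = r.table.p_value.to_numpy()
        assert np.all((p > 0) & (p <= 1))
        assert sorted(r.table["rank"]) == list(range(1, len(coll) + 1))
        # ranks follow ascending p-values
        tab = r.table.sort_values("rank")
        assert np.all(np.diff(tab.p_value.to_numpy()) >= -1e-12)

    @pytest.mark.parametrize("method", ["gsea", "safe", "padog", "samgs"])
    def test_seeded_runs_bitwise_reproducible(self, method, small_dataset, small_scenario):
        coll, _, _ = small_scenario
        a = run_method(method, small_dataset, coll, n_perm=20, seed=12)
        b = run_method(method, small_dataset, coll, n_perm=20, seed=12)
        assert a.table.equals(b.table)

    def test_hypothesis_tags_match_method_family(self):
        assert get_method("samgs").hypothesis.value == "self_contained"
        for m in ["ora", "gsea", "safe", "padog", "camera"]:
            assert get_method(m).hypothesis.value == "competitive"

    def test_stubs_raise_not_implemented(self, small_dataset, small_scenario):
        coll, _, _ = small_scenario
        assert set(list_methods()) >= {"globaltest", "gsa", "roast", "gsva"}
        with pytest.raises(NotImplementedError):
            run_method("roast", small_dataset, coll)
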