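"""Gene-level statistics, the count VST, and BH adjustment."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from gsebench import (
    DataKind,
    ExpressionDataset,
    bh_adjust,
    call_de_genes,
    estimate_common_dispersion,
    gene_level_stats,
    log_cpm_transform,
    simulate_expression,
)
from gsebench.genestats import GeneStatVector, t_pvalues


def _two_group_dataset(rows: np.ndarray, groups=None) -> ExpressionDataset:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n = rows.shape[1]
    return ExpressionDataset(
        matrix=rows,
        gene_ids=[f"g{i}" for i in range(rows.shape[0])],
        sample_ids=[f"s{j}" for j in range(n)],
        groups=groups or ["A"] * (n // 2) + ["B"] * (n - n // 2),
    )


class TestCommonDispersion:
    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(np.exp(rng.normal(4, 1, 2000))[:, None], (2000, 16))
        ds = ExpressionDataset(
            matrix=counts.astype(float),
            gene_ids=[f"g{i}" for i in range(2000)],
            sample_ids=[f"s{j}" for j in range(16)],
            groups=["A"] * 8 + ["B"] * 8,
            kind=DataKind.COUNTS,
        )
        assert estimate_common_dispersion(ds) < 0.02

    def test_nb_dispersion_recovered_across_seeds(self):
        phis = []
        for seed in range(20):
            ds, _ = simulate_expression(
                n_genes=2000, n_per_group=10, de_fraction=0.0,
                kind="counts", dispersion=0.1, seed=seed,
            )
            phis.append(estimate_common_dispersion(ds))
        assert all(0.05 <= p <= 0.2 for p in phis)

    def test_constant_matrix_gives_zero(self):
        ds = ExpressionDataset(
            matrix=np.full((10, 6), 7.0),
            gene_ids=[f"g{i}" for i in range(10)],
            sample_ids=[f"s{j}" for j in range(6)],
            groups=["A"] * 3 + ["B"] * 3,
            kind=DataKind.COUNTS,
        )
        assert estimate_common_dispersion(ds) == 0.0

    def test_requires_counts(self, small_dataset):
        with pytest.raises(ValueError):
            estimate_common_dispersion(small_dataset)


class TestLogCpm:
    def _counts_ds(self, matrix):
        m = np.asarray(matrix, dtype=float)
        return ExpressionDataset(
            matrix=m,
            gene_ids=[f"g{i}" for i in range(m.shape[0])],
            sample_ids=[f"s{j}" for j in range(m.shape[1])],
            groups=["A", "A", "B", "B"][: m.shape[1]],
            kind=DataKind.COUNTS,
        )

    def test_closed_form_values_at_equal_library_sizes(self):
        # library size 1e6 per sample, prior 0.5
        col = np.zeros(4, dtype=float)
        counts = np.tile(col, (10, 1))
        counts[0] = 1000.0
        counts[1] = 0.0
        counts[2:] = (1e6 - 1000) / 8  # fill to equal library sizes
        counts = np.round(counts)
        lib = counts.sum(axis=0)
        assert np.allclose(lib, lib[0])
        ds = self._counts_ds(counts)
        out = log_cpm_transform(ds, prior_count=0.5)
        L = lib[0]
        expected_hi = np.log2((1000 + 0.5) / (L + 1.0) * 1e6)
        expected_lo = np.log2(0.5 / (L + 1.0) * 1e6)
        np.testing.assert_allclose(out.matrix[0], expected_hi, rtol=1e-12)
        np.testing.assert_allclose(out.matrix[1], expected_lo, rtol=1e-12)
        # and for a 1e6 library those are the familiar ~9.966 / ~-1.000
        if L == 1e6:
            assert abs(expected_hi - 9.966) < 1e-3
            assert abs(expected_lo - (-1.0)) < 5e-3

    def test_scale_invariance_under_count_doubling(self):
        # the prior keeps its size relative to the library, so doubling all
        # counts shifts values only by the vanishing prior-to-count ratio
        rng = np.random.default_rng(0)
        counts = rng.poisson(500, (30, 4)).astype(float)
        a = log_cpm_transform(self._counts_ds(counts), prior_count=0.5)
        b = log_cpm_transform(self._counts_ds(2 * counts), prior_count=0.5)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=5e-3)

    def test_all_zero_sample_names_sample(self):
        counts = np.ones((5, 4))
        counts[:, 2] = 0
        with pytest.raises(ValueError, match="s2"):
            log_cpm_transform(self._counts_ds(counts))

    def test_auto_prior_uses_dispersion(self):
        ds, _ = simulate_expression(
            n_genes=800, n_per_group=6, de_fraction=0.0, kind="counts",
            dispersion=0.1, seed=2,
        )
        out = log_cpm_transform(ds, prior_count="auto")
        assert out.kind is DataKind.LOG_INTENSITY
        assert np.all(np.isfinite(out.matrix))


class TestGeneLevelStats:
    def test_hand_computed_t_s2n_logfc(self):
        ds = _two_group_dataset([[1, 2, 3, 4, 5, 6]])
        t = gene_level_stats(ds, "ordinary_t")
        s2n = gene_level_stats(ds, "s2n")
        lfc = gene_level_stats(ds, "logfc")
        assert t.values[0] == pytest.approx(-3.674, abs=1e-3)
        assert s2n.values[0] == pytest.approx(-1.5)
        assert lfc.values[0] == pytest.approx(-3.0)

    def test_moderated_equals_ordinary_when_variances_equal(self):
        # every gene has the same within-group variance pattern
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rows = np.stack([base + shift for shift in range(6)])
        ds = _two_group_dataset(rows)
        mod = gene_level_stats(ds, "moderated_t")
        ordi = gene_level_stats(ds, "ordinary_t")
        np.testing.assert_allclose(mod.values, ordi.values, rtol=1e-9)

    def test_within_group_sample_order_irrelevant(self, small_dataset):
        perm = np.r_[np.random.default_rng(0).permutation(8),
                     8 + np.random.default_rng(1).permutation(8)]
        shuffled = ExpressionDataset(
            matrix=small_dataset.matrix[:, perm],
            gene_ids=small_dataset.gene_ids,
            sample_ids=[small_dataset.sample_ids[i] for i in perm],
            groups=[small_dataset.groups[i] for i in perm],
        )
        for stat in ("ordinary_t", "moderated_t", "sam_t", "s2n", "logfc"):
            a = gene_level_stats(small_dataset, stat).values
            b = gene_level_stats(shuffled, stat).values
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_regularized_statistics_shrink_low_variance_genes(self, small_dataset):
        ordi = gene_level_stats(small_dataset, "ordinary_t")
        sam = gene_level_stats(small_dataset, "sam_t")
        mod = gene_level_stats(small_dataset, "moderated_t")
        s2 = small_dataset.matrix.var(axis=1)
        low = s2 < np.quantile(s2, 0.1)
        assert np.all(np.abs(sam.values[low]) < np.abs(ordi.values[low]))
        assert np.mean(np.abs(mod.values[low]) < np.abs(ordi.values[low])) > 0.9

    def test_counts_are_transformed_before_stats(self):
        ds, _ = simulate_expression(
            n_genes=300, n_per_group=5, de_fraction=0.0, kind="counts", seed=7
        )
        sv = gene_level_stats(ds, "ordinary_t")
        assert np.all(np.isfinite(sv.values[~np.isin(sv.gene_ids, list(sv.flagged))]))

    def test_zero_variance_gene_flagged(self):
        rows = np.vstack([[1, 2, 3, 4, 5, 6], [2, 2, 2, 2, 2, 2]])
        ds = _two_group_dataset(rows)
        sv = gene_level_stats(ds, "ordinary_t")
        assert sv.flagged == {"g1"}
        assert np.isnan(sv.values[1])

    def test_paired_blocks_use_within_block_differences(self):
        # block differences are constant 1 -> infinite-precision paired t blows up
        rows = np.array([[0.0, 1.0, 0.5, 1.5, 1.0, 2.0, 0.2, 1.2]])
        ds = ExpressionDataset(
            matrix=rows,
            gene_ids=["g0"],
            sample_ids=[f"s{j}" for j in range(8)],
            groups=["A", "B"] * 4,
            blocks=["b1", "b1", "b2", "b2", "b3", "b3", "b4", "b4"],
        )
        lfc = gene_level_stats(ds, "logfc")
        assert lfc.values[0] == pytest.approx(-1.0)

    def test_null_pvalues_uniform(self):
        ds, _ = simulate_expression(n_genes=2000, n_per_group=10, de_fraction=0.0, seed=13)
        sv = gene_level_stats(ds, "ordinary_t")
        ks = stats.kstest(sv.p_values, "uniform")
        assert ks.pvalue > 0.01


class TestVstAdequacy:
    def test_per_gene_type_one_error_on_nb_null_counts(self):
        """Ordinary & moderated t on auto-prior logCPM control error at 5%."""
        ds, _ = simulate_expression(
            n_genes=2000, n_per_group=10, de_fraction=0.0, kind="counts",
            dispersion=0.1, seed=31,
        )
        log = log_cpm_transform(ds, prior_count="auto")
        sd = np.sqrt(0.05 * 0.95 / 2000)
        for stat in ("ordinary_t", "moderated_t"):
            sv = gene_level_stats(log, stat)
            frac = float(np.mean(np.asarray(sv.p_values) < 0.05))
            assert abs(frac - 0.05) <= 3 * sd, (stat, frac)


class TestBhAndDeCalls:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_matches_brute_force_on_random_vectors(self):
        from conftest import brute_force_bh

        rng = np.random.default_rng(5)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_de_call_thresholds(self):
        sv = GeneStatVector(
            gene_ids=["a", "b", "c"],
            statistic="moderated_t",
            values=np.array([5.0, 4.0, 1.0]),
            p_values=np.array([0.001, 0.0001, 0.5]),
            logfc=np.array([1.5, 0.5, 2.0]),
        )
        # with 3 genes BH keeps the small ones well under 0.05
        assert call_de_genes(sv, criterion="both") == {"a"}
        assert call_de_genes(sv, criterion="p_only") == {"a", "b"}
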