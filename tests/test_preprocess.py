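import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuropathnet.datatypes import ExpressionMatrix, PhenotypeTable
from neuropathnet.preprocess import (
    GeneMinMaxScaler,
    apply_pca,
    fit_pca,
    harmonize_batches,
    intersect_and_filter,
    minmax_normalize,
    moment_match,
    normalize_phenotypes,
    residualize_covariates,
)


def _expr(values, gene_ids, cohort="c0"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        cohort=[cohort] * values.shape[0],
    )


class TestIntersectAndFilter:
    def test_plain_intersection_preserves_order(self, rng):
        m1 = _expr(rng.standard_normal((4, 3)), ["A", "B", "C"])
        m2 = _expr(rng.standard_normal((5, 3)), ["B", "C", "D"])
        out = intersect_and_filter([m1, m2])
        assert list(out[0].gene_ids) == ["B", "C"]
        assert list(out[1].gene_ids) == ["B", "C"]

    def test_null_heavy_gene_removed_before_intersection(self, rng):
        v = rng.standard_normal((10, 2))
        v[:7, 1] = np.nan  # gene B null in 70% of samples
        m = _expr(v, ["A", "B"])
        out = intersect_and_filter([m], max_null_fraction=2 / 3)
        assert list(out[0].gene_ids) == ["A"]

    def test_three_cohorts_against_brute_force_oracle(self, rng):
        genes = [["A", "B", "C", "D", "E"]] * 3
        mats = [_expr(rng.standard_normal((5, 5)), g) for g in genes]
        mats[1].values[:4, 1] = np.nan  # gene B 80% null in cohort 2
        # brute-force oracle: per-matrix surviving sets, then intersection
        surviving = []
        for m in mats:
            surviving.append(
                {
                    g
                    for j, g in enumerate(m.gene_ids)
                    if np.isnan(m.values[:, j]).mean() <= 2 / 3
                }
            )
        expected = set.intersection(*surviving)
        out = intersect_and_filter(mats)
        assert set(out[0].gene_ids) == expected
        assert all(list(o.gene_ids) == list(out[0].gene_ids) for o in out)

    def test_empty_intersection_is_an_error(self, rng):
        m1 = _expr(rng.standard_normal((3, 1)), ["A"])
        m2 = _expr(rng.standard_normal((3, 1)), ["B"])
        with pytest.raises(ValueError, match="empty gene intersection"):
            intersect_and_filter([m1, m2])


class TestMinMaxNormalize:
    def test_simple_column(self):
        m = _expr(np.array([[2.0], [4.0], [6.0]]), ["A"])
        out, _ = minmax_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [0, 0.5, 1])
        assert out.normalized

    def test_constant_gene_maps_to_zero_and_is_flagged(self):
        m = _expr(np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]]), ["A", "B"])
        out, scaler = minmax_normalize(m)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        assert scaler.constant_mask_[0] and not scaler.constant_mask_[1]

    def test_random_matrix_matches_direct_formula(self, rng):
        X = rng.standard_normal((10, 4))
        m = _expr(X, ["A", "B", "C", "D"])
        out, _ = minmax_normalize(m)
        expected = (X - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        np.testing.assert_allclose(out.values.min(axis=0), 0, atol=1e-15)
        np.testing.assert_allclose(out.values.max(axis=0), 1, atol=1e-15)

    def test_stored_parameters_apply_to_new_samples(self, rng):
        X = rng.random((8, 3))
        _, scaler = minmax_normalize(_expr(X, ["A", "B", "C"]))
        new = rng.random((4, 3))
        np.testing.assert_allclose(
            scaler.transform(new), (new - X.min(axis=0)) / np.ptp(X, axis=0)
        )

    def test_double_normalization_guarded(self, rng):
        out, _ = minmax_normalize(_expr(rng.random((5, 2)), ["A", "B"]))
        with pytest.raises(ValueError, match="already normalized"):
            minmax_normalize(out)

    def test_log_first_rejects_negative_values(self):
        m = _expr(np.array([[-1.0], [2.0]]), ["A"])
        with pytest.raises(ValueError, match="negative"):
            minmax_normalize(m, log_first=True)

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=3,
            max_size=12,
        )
    )
    def test_output_always_within_unit_interval(self, column):
        scaler = GeneMinMaxScaler().fit(np.asarray(column)[:, None])
        out = scaler.transform(np.asarray(column)[:, None])
        assert out.min() >= -1e-12 and out.max() <= 1 + 1e-12


class TestNormalizePhenotypes:
    def test_braak_and_cerad_scales(self):
        braak = np.arange(7.0)
        cerad = np.array([1.0, 2, 3, 4, 1, 2, 3])
        raw = np.zeros((7, 6))
        raw[:, 5] = braak
        raw[:, 2] = cerad
        mask = np.ones((7, 6), dtype=bool)
        out = normalize_phenotypes(raw, mask, ["c0"] * 7, [f"s{i}" for i in range(7)])
        np.testing.assert_allclose(out.values[:, 5], braak / 6)
        np.testing.assert_allclose(out.values[:4, 2], [0, 1 / 3, 2 / 3, 1])

    def test_cohorts_scaled_independently(self, rng):
        raw = np.zeros((8, 6))
        raw[:4, 4] = [0, 5, 10, 20]  # tangle counts, cohort A
        raw[4:, 4] = [1, 2, 3, 5]  # different range, cohort B
        mask = np.zeros((8, 6), dtype=bool)
        mask[:, 4] = True
        cohort = ["A"] * 4 + ["B"] * 4
        out = normalize_phenotypes(raw, mask, cohort, [f"s{i}" for i in range(8)])
        for rows in (slice(0, 4), slice(4, 8)):
            vals = out.values[rows, 4]
            assert vals.min() == 0 and vals.max() == 1

    def test_unobserved_cohort_phenotype_stays_masked(self):
        raw = np.zeros((4, 6))
        mask = np.zeros((4, 6), dtype=bool)
        mask[:2, 0] = True  # phenotype 0 observed only in cohort A
        out = normalize_phenotypes(
            raw, mask, ["A", "A", "B", "B"], [f"s{i}" for i in range(4)]
        )
        assert not out.mask[2:, 0].any()


class TestHarmonizeBatches:
    def test_constant_offset_removed(self, rng):
        base = rng.standard_normal((20, 5))
        X = np.vstack([base, base + 3.0])
        batch = np.array(["a"] * 20 + ["b"] * 20)
        m = _expr(X, [f"G{i}" for i in range(5)])
        out = harmonize_batches(m, batch)
        means_a = out.values[:20].mean(axis=0)
        means_b = out.values[20:].mean(axis=0)
        np.testing.assert_allclose(means_a, means_b, atol=1e-10)

    def test_batch_free_data_round_trips(self, rng):
        X = rng.standard_normal((30, 4))
        batch = np.array(["a", "b"] * 15)
        rows_a = batch == "a"
        m = _expr(X, [f"G{i}" for i in range(4)])
        out = harmonize_batches(m, batch)
        # each half was standardized then rescaled to pooled moments: the
        # per-batch moments now equal the pooled moments exactly
        np.testing.assert_allclose(
            out.values[rows_a].mean(axis=0), X.mean(axis=0), atol=1e-10
        )
        np.testing.assert_allclose(
            out.values[rows_a].std(axis=0), X.std(axis=0), atol=1e-10
        )

    def test_planted_batch_effect_variance_drops(self, rng):
        n, g = 100, 30
        signal = rng.standard_normal((2 * n, g))
        offset = rng.normal(0, 2.0, g)
        scale = np.exp(rng.normal(0, 0.3, g))
        X = signal.copy()
        X[n:] = X[n:] * scale + offset
        batch = np.array(["a"] * n + ["b"] * n)

        def batch_r2(values):
            # per-gene ANOVA oracle: R^2 of the batch one-hot regression
            out = []
            for j in range(g):
                y = values[:, j]
                grand = y.mean()
                ss_between = sum(
                    (y[batch == b].mean() - grand) ** 2 * (batch == b).sum()
                    for b in ("a", "b")
                )
                out.append(ss_between / ((y - grand) ** 2).sum())
            return np.mean(out)

        before = batch_r2(X)
        after = batch_r2(
            harmonize_batches(_expr(X, [f"G{i}" for i in range(g)]), batch).values
        )
        assert before > 0.2
        assert after < 0.01

    def test_singleton_batch_skips_scale_step(self, rng, caplog):
        X = rng.standard_normal((5, 3))
        batch = np.array(["a"] * 4 + ["b"])
        with caplog.at_level(logging.WARNING):
            harmonize_batches(_expr(X, ["G0", "G1", "G2"]), batch)
        assert any("single sample" in r.message for r in caplog.records)

    def test_external_method_passes_through(self, rng):
        m = _expr(rng.standard_normal((6, 2)), ["A", "B"])
        out = harmonize_batches(m, ["a", "b"] * 3, method="external")
        np.testing.assert_array_equal(out.values, m.values)


class TestPCA:
    def test_rank2_exact_recovery(self, rng):
        U = rng.standard_normal((50, 2))
        V = rng.standard_normal((2, 20))
        X = U @ V
        pca = fit_pca(X, k=2)
        scores = apply_pca(pca, X)
        np.testing.assert_allclose(pca.inverse(scores), X, atol=1e-8)

    def test_full_rank_variance_conserved(self, rng):
        X = rng.standard_normal((30, 10))
        pca = fit_pca(X, k=10)
        total = ((X - X.mean(axis=0)) ** 2).sum() / (X.shape[0] - 1)
        np.testing.assert_allclose(pca.explained_variance.sum(), total, atol=1e-8)

    def test_scores_match_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((50, 20))
        pca = fit_pca(X, k=5)
        scores = apply_pca(pca, X)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1][:5]
        oracle = Xc @ evecs[:, order]
        for j in range(5):  # components defined up to sign
            assert min(
                np.abs(scores[:, j] - oracle[:, j]).max(),
                np.abs(scores[:, j] + oracle[:, j]).max(),
            ) < 1e-8

    def test_loadings_orthonormal(self, rng):
        pca = fit_pca(rng.standard_normal((40, 15)), k=8)
        L = pca.component_loadings
        np.testing.assert_allclose(L.T @ L, np.eye(8), atol=1e-8)

    def test_k_beyond_rank_truncated_with_warning(self, rng, caplog):
        U = rng.standard_normal((30, 3))
        X = U @ rng.standard_normal((3, 10))
        with caplog.at_level(logging.WARNING):
            pca = fit_pca(X, k=200)
        assert pca.k <= 10
        assert any("truncat" in r.message for r in caplog.records)


class TestMomentMatch:
    def test_single_gene_matched(self, rng):
        X = rng.normal(10, 2, size=(200, 1))
        out = moment_match(_expr(X, ["A"]), np.array([0.5]), np.array([0.1]))
        assert abs(out.values.mean() - 0.5) < 1e-10
        assert abs(out.values.std() - 0.1) < 1e-10

    def test_constant_gene_set_to_reference_mean(self):
        X = np.full((5, 1), 7.0)
        out = moment_match(_expr(X, ["A"]), np.array([0.3]), np.array([0.2]))
        np.testing.assert_allclose(out.values, 0.3)

    def test_full_matrix_moments_recomputed(self, rng):
        X = rng.standard_normal((80, 100)) * rng.random(100) + rng.random(100)
        ref_mean = rng.random(100)
        ref_sd = rng.random(100) + 0.1
        out = moment_match(_expr(X, [f"G{i}" for i in range(100)]), ref_mean, ref_sd)
        np.testing.assert_allclose(out.values.mean(axis=0), ref_mean, atol=1e-8)
        np.testing.assert_allclose(out.values.std(axis=0), ref_sd, atol=1e-8)


class TestResidualize:
    def _tables(self, X, pmi, rin):
        from neuropathnet.datatypes import CovariateTable

        n = X.shape[0]
        expr = _expr(X, [f"G{i}" for i in range(X.shape[1])])
        covs = CovariateTable(
            sample_ids=expr.sample_ids,
            individual_id=[f"i{j}" for j in range(n)],
            sex=np.zeros(n),
            pmi=pmi,
            rin=rin,
        )
        return expr, covs

    def test_exact_linear_dependence_removed(self, rng):
        pmi = rng.random(30) * 10
        X = (2 * pmi + 1)[:, None]
        expr, covs = self._tables(X, pmi, rng.random(30))
        out, _ = residualize_covariates(expr, covs)
        np.testing.assert_allclose(out.values, 0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        X = rng.standard_normal((50, 3))
        expr, covs = self._tables(X, rng.random(50), rng.random(50))
        out, covs2 = residualize_covariates(expr, covs)
        for j in range(3):
            assert abs(np.dot(out.values[:, j], covs2.pmi - covs2.pmi.mean())) < 1e-8

    def test_planted_model_matches_normal_equations_oracle(self, rng):
        n = 200
        pmi, rin = rng.random(n), rng.random(n)
        signal = rng.standard_normal(n)
        X = (0.3 * pmi - 0.2 * rin + signal)[:, None]
        expr, covs = self._tables(X, pmi, rin)
        out, _ = residualize_covariates(expr, covs)
        D = np.column_stack([np.ones(n), pmi, rin])
        beta = np.linalg.solve(D.T @ D, D.T @ X)
        np.testing.assert_allclose(out.values, X - D @ beta, atol=1e-10)
        r_raw = np.corrcoef(X[:, 0], signal)[0, 1]
        r_res = np.corrcoef(out.values[:, 0], signal)[0, 1]
        assert r_res >= r_raw

    def test_samples_with_missing_covariates_dropped(self, rng):
        X = rng.standard_normal((10, 2))
        pmi = rng.random(10)
        pmi[3] = np.nan
        expr, covs = self._tables(X, pmi, rng.random(10))
        out, _ = residualize_covariates(expr, covs)
        assert out.n_samples == 9
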