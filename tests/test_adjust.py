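"""VDW scoring, metagene, stage encoding, and residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri
from scipy.stats import rankdata

from repairsurv.adjust import (
    adjust_expression,
    compute_metagene,
    correlate_with_metagene,
    encode_stage,
    residualize,
    vdw_transform,
    vdw_transform_matrix,
    AdjustedExpression,
)
from repairsurv.catalog import MetageneGeneSet
from repairsurv.errors import CollinearityError, DegenerateInputError, FormatError


class TestVDW:
    def test_three_values_hit_quartiles(self):
        z = vdw_transform(np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(z, [ndtri(0.25), 0.0, ndtri(0.75)], atol=1e-12)

    def test_four_values_match_normal_quantiles(self):
        z = vdw_transform(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(z, [-0.8416, -0.2533, 0.2533, 0.8416], atol=5e-5)

    @given(st.lists(st.integers(-10 ** 6, 10 ** 6), min_size=3, max_size=60,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, values):
        x = np.array(values, dtype=float)
        np.testing.assert_allclose(vdw_transform(x), vdw_transform(np.exp(x / 1e6) * 3 + 7),
                                   atol=1e-10)

    def test_tie_free_mean_zero(self, rng):
        z = vdw_transform(rng.standard_normal(501))
        assert abs(z.mean()) < 1e-10

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            vdw_transform(np.ones(10))

    @pytest.mark.parametrize("n", [100, 500, 2000])
    def test_variance_band_tie_free(self, n, rng):
        z = vdw_transform(rng.standard_normal(n))
        v = z.var()
        assert 0.9 <= v <= 1.0

    def test_variance_monotone_in_n(self, rng):
        v = [vdw_transform(np.arange(n, dtype=float)).var() for n in (100, 400, 1600)]
        assert v[0] < v[1] < v[2] <= 1.0

    def test_matrix_rowwise_matches_vector(self, rng):
        X = rng.standard_normal((5, 40))
        Z = vdw_transform_matrix(X)
        for i in range(5):
            np.testing.assert_allclose(Z[i], vdw_transform(X[i]), atol=1e-12)

    def test_ties_use_midranks(self):
        z = vdw_transform(np.array([1.0, 1.0, 2.0]))
        ptile = rankdata([1, 1, 2], method="average") / 4
        np.testing.assert_allclose(z, ndtri(ptile), atol=1e-12)


class TestMetagene:
    def _matrix(self, data, samples=("S1",)):
        return pd.DataFrame(data, columns=list(samples))

    def test_median_of_three(self):
        expr = pd.DataFrame({"S1": [1.0, 5.0, 9.0]}, index=["A", "B", "C"])
        sig = MetageneGeneSet(genes=["A", "B", "C"])
        assert compute_metagene(expr, sig)["S1"] == 5.0

    def test_all_equal_value(self):
        expr = pd.DataFrame({"S1": [7.0, 7.0]}, index=["A", "B"])
        assert compute_metagene(expr, MetageneGeneSet(genes=["A", "B"]))["S1"] == 7.0

    def test_gene_order_invariance(self, rng):
        expr = pd.DataFrame(rng.random((6, 10)),
                            index=list("ABCDEF"),
                            columns=[f"S{i}" for i in range(10)])
        a = compute_metagene(expr, MetageneGeneSet(genes=list("ABCDEF")))
        b = compute_metagene(expr, MetageneGeneSet(genes=list("FEDCBA")))
        pd.testing.assert_series_equal(a, b)

    def test_absent_genes_ignored_none_fatal(self):
        expr = pd.DataFrame({"S1": [1.0, 3.0]}, index=["A", "B"])
        sig = MetageneGeneSet(genes=["A", "B", "MISSING"])
        assert compute_metagene(expr, sig)["S1"] == 2.0
        with pytest.raises(DegenerateInputError):
            compute_metagene(expr, MetageneGeneSet(genes=["X", "Y"]))


class TestStage:
    def test_midranks(self):
        np.testing.assert_allclose(encode_stage(["I", "II", "II", "IV"]),
                                   [1, 2.5, 2.5, 4])

    def test_substage_order(self):
        r = encode_stage(["IIIA", "IIIB"])
        assert r[0] < r[1]

    @pytest.mark.parametrize("dialect", ["Stage IIIA", "IIIA", "iii a", "stage iiia"])
    def test_dialects_equal(self, dialect):
        base = encode_stage(["IIIA", "IV"])
        np.testing.assert_allclose(encode_stage([dialect, "IV"]), base)

    def test_unrecognized_label_listed(self):
        with pytest.raises(FormatError, match="Stage X"):
            encode_stage(["I", "Stage X"])


class TestResidualize:
    def test_exact_multiple_gives_zero(self, rng):
        x = rng.standard_normal(50)
        r = residualize(2 * x, [x])
        np.testing.assert_allclose(r, 0, atol=1e-10)

    def test_no_covariates_centers(self, rng):
        y = rng.standard_normal(30) + 5
        np.testing.assert_allclose(residualize(y, []), y - y.mean(), atol=1e-12)

    def test_orthogonality_matches_normal_equations(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        r = residualize(y, [x])
        # normal-equations oracle
        X = np.column_stack([np.ones(n), x])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(r, y - X @ beta_hat, atol=1e-10)
        assert abs(np.corrcoef(r, x)[0, 1]) < 1e-8
        assert abs(r.mean()) < 1e-10

    def test_idempotent(self, rng):
        y = rng.standard_normal(80)
        C = [rng.standard_normal(80) for _ in range(3)]
        once = residualize(y, C)
        np.testing.assert_allclose(residualize(once, C), once, atol=1e-10)

    def test_collinear_pair_named(self, rng):
        x = rng.standard_normal(40)
        with pytest.raises(CollinearityError, match="0 and 1"):
            residualize(rng.standard_normal(40), [x, 2 * x])


class TestAdjustChain:
    def _cohort(self, rng, n=120, p=6):
        expr = pd.DataFrame(np.exp(rng.standard_normal((p, n))),
                            index=[f"G{i}" for i in range(p)],
                            columns=[f"S{i}" for i in range(n)])
        cov = {"age": vdw_transform(rng.standard_normal(n)),
               "metagene": vdw_transform(rng.standard_normal(n))}
        return expr, cov

    def test_residuals_orthogonal_and_centered(self, rng):
        expr, cov = self._cohort(rng)
        adj = adjust_expression(expr, list(expr.index), cov)
        R = adj.residuals.to_numpy()
        assert np.abs(R.mean(axis=1)).max() < 1e-10
        for v in cov.values():
            cors = [abs(np.corrcoef(row, v)[0, 1]) for row in R]
            assert max(cors) < 1e-8

    def test_sample_permutation_equivariance(self, rng):
        expr, cov = self._cohort(rng)
        adj = adjust_expression(expr, list(expr.index), cov)
        perm = rng.permutation(expr.shape[1])
        expr_p = expr.iloc[:, perm]
        cov_p = {k: v[perm] for k, v in cov.items()}
        adj_p = adjust_expression(expr_p, list(expr.index), cov_p)
        np.testing.assert_allclose(adj_p.residuals.to_numpy(),
                                   adj.residuals.to_numpy()[:, perm], atol=1e-10)

    def test_missing_cells_handled(self, rng):
        expr, cov = self._cohort(rng, n=50)
        expr.iloc[0, :5] = np.nan          # 10% missing -> imputed
        expr.iloc[1, :30] = np.nan         # 60% missing -> dropped
        adj = adjust_expression(expr, list(expr.index), cov)
        assert "G1" in adj.dropped_genes
        assert "G0" in adj.residuals.index


class TestMetageneCorrelation:
    def _adjusted(self, R, samples):
        return AdjustedExpression(
            residuals=pd.DataFrame(R, index=[f"G{i}" for i in range(R.shape[0])],
                                   columns=samples),
            covariates=())

    def test_perfect_and_negated(self, rng):
        m = rng.standard_normal(60)
        samples = [f"S{i}" for i in range(60)]
        adj = self._adjusted(np.vstack([m, -m]), samples)
        r = correlate_with_metagene(adj, pd.Series(m, index=samples))
        np.testing.assert_allclose(r.to_numpy(), [1.0, -1.0], atol=1e-12)

    def test_zero_variance_residual_is_missing(self, rng):
        m = rng.standard_normal(30)
        samples = [f"S{i}" for i in range(30)]
        adj = self._adjusted(np.vstack([np.zeros(30)]), samples)
        r = correlate_with_metagene(adj, pd.Series(m, index=samples))
        assert np.isnan(r.iloc[0])

    def test_null_correlation_is_small(self, rng):
        """Independent gene vs metagene at n=1000: |r| < 0.1 nearly always."""
        n, seeds = 1000, 40
        samples = [f"S{i}" for i in range(n)]
        hits = 0
        for _ in range(seeds):
            m = rng.standard_normal(n)
            adj = self._adjusted(rng.standard_normal((1, n)), samples)
            r = correlate_with_metagene(adj, pd.Series(m, index=samples)).iloc[0]
            hits += abs(r) < 0.1
        assert hits / seeds >= 0.85
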