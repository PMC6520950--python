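"""Correlation/eigen/varimax machinery, best-PC selection, Cox directionality."""

import numpy as np
import pandas as pd
import pytest

from repairsurv.bestpc import (
    BestPCResult,
    assign_gene_directions,
    binarize_pc_scores,
    correlation_matrix,
    cox_direction,
    eigendecompose,
    fit_pc_model,
    pathway_composition,
    pc_scores,
    select_best_binarized_pc,
    varimax_criterion,
    varimax_rotate,
    GeneDirectionTable,
    UP_PROLONGS,
    DOWN_PROLONGS,
)
from repairsurv.errors import DegenerateInputError
from repairsurv.screen import logrank_chi2_many
from repairsurv.synthetic import SimulationConfig, simulate_cohort


def _frame(X, prefix="G"):
    return pd.DataFrame(X, index=[f"{prefix}{i}" for i in range(X.shape[0])],
                        columns=[f"S{j}" for j in range(X.shape[1])])


class TestCorrelationMatrix:
    def test_single_vector(self, rng):
        C = correlation_matrix(_frame(rng.standard_normal((1, 20))))
        np.testing.assert_allclose(C, [[1.0]])

    def test_identical_vectors(self, rng):
        x = rng.standard_normal(30)
        C = correlation_matrix(_frame(np.vstack([x, x])))
        np.testing.assert_allclose(C[0, 1], 1.0, atol=1e-12)

    def test_constant_vector_names_gene(self, rng):
        X = rng.standard_normal((2, 20))
        X[1] = 3.0
        with pytest.raises(DegenerateInputError, match="G1"):
            correlation_matrix(_frame(X))

    def test_binarized_mode(self, rng):
        X = rng.standard_normal((3, 50))
        C = correlation_matrix(_frame(X), mode="binarized")
        assert C.shape == (3, 3)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)

    def test_null_offdiagonal_small(self, rng):
        hits = sum(
            abs(correlation_matrix(_frame(rng.standard_normal((2, 1000))))[0, 1]) < 0.1
            for _ in range(40)
        )
        assert hits / 40 >= 0.85


class TestEigendecompose:
    def test_identity(self):
        vals, vecs = eigendecompose(np.eye(4))
        np.testing.assert_allclose(vals, 1.0)

    @pytest.mark.parametrize("r", [-0.6, 0.0, 0.3, 0.9])
    def test_two_by_two_closed_form(self, r):
        vals, _ = eigendecompose(np.array([[1.0, r], [r, 1.0]]))
        np.testing.assert_allclose(vals, [1 + abs(r), 1 - abs(r)], atol=1e-12)

    def test_spectral_reconstruction(self, rng):
        A = rng.standard_normal((6, 6))
        C = np.corrcoef(A @ A.T + np.eye(6))
        vals, vecs = eigendecompose(C)
        np.testing.assert_allclose(vecs @ np.diag(vals) @ vecs.T, C, atol=1e-10)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1.0, 0.5], [0.1, 1.0]]))


class TestVarimax:
    def test_identity_loadings_unchanged(self):
        rotated, R, trace = varimax_rotate(np.eye(4))
        np.testing.assert_allclose(np.abs(rotated), np.eye(4), atol=1e-8)

    def test_perfect_simple_structure_fixed_point(self, rng):
        # one nonzero per row: already at a varimax optimum
        L = np.zeros((6, 3))
        for i in range(6):
            L[i, i % 3] = rng.uniform(0.5, 1.0)
        rotated, R, trace = varimax_rotate(L)
        assert varimax_criterion(rotated) >= varimax_criterion(L) - 1e-10
        # same sparsity pattern up to column permutation/sign
        nz = np.abs(rotated) > 1e-6
        assert nz.sum() == 6

    def test_criterion_monotone_and_improves(self, rng):
        for _ in range(10):
            L = rng.standard_normal((5, 5))
            rotated, R, trace = varimax_rotate(L)
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-9)

    def test_rotation_orthogonal(self, rng):
        L = rng.standard_normal((8, 4))
        rotated, R, _ = varimax_rotate(L)
        np.testing.assert_allclose(R.T @ R, np.eye(4), atol=1e-8)

    def test_communalities_preserved(self, rng):
        L = rng.standard_normal((8, 4))
        rotated, _, _ = varimax_rotate(L)
        np.testing.assert_allclose((rotated ** 2).sum(axis=1),
                                   (L ** 2).sum(axis=1), atol=1e-8)


class TestScores:
    def test_identity_loadings_return_data(self, rng):
        Z = rng.standard_normal((20, 4))
        Z -= Z.mean(axis=0)
        np.testing.assert_allclose(pc_scores(Z, np.eye(4)), Z)

    def test_sign_flip_column(self, rng):
        Z = rng.standard_normal((15, 3))
        L = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        S = pc_scores(Z, L)
        L2 = L.copy()
        L2[:, 1] *= -1
        S2 = pc_scores(Z, L2)
        np.testing.assert_allclose(S2[:, 1], -S[:, 1])

    def test_orthogonal_loadings_reconstruct_data(self, rng):
        Z = rng.standard_normal((25, 4))
        L = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        S = pc_scores(Z, L)
        np.testing.assert_allclose(S @ L.T, Z, atol=1e-8)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            pc_scores(rng.standard_normal((10, 3)), np.eye(4))

    def test_score_columns_centered(self, rng):
        R = _frame(rng.standard_normal((5, 60)))
        model = fit_pc_model(R)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0, atol=1e-8)


class TestBestPC:
    def _surv(self, rng, n):
        t = rng.exponential(40, n)
        c = np.quantile(t, 0.7)
        return np.minimum(t, c), (t <= c).astype(int)

    def test_single_pc_is_best(self, rng):
        R = _frame(rng.standard_normal((1, 50)))
        t, e = self._surv(rng, 50)
        best = select_best_binarized_pc(fit_pc_model(R), t, e, fit_cox=False)
        assert best.pc_index == 0

    def test_matches_exhaustive_rescan(self, rng):
        R = _frame(rng.standard_normal((6, 80)))
        t, e = self._surv(rng, 80)
        model = fit_pc_model(R)
        best = select_best_binarized_pc(model, t, e, fit_cox=False)
        # independent re-scan over every column
        chis = []
        for j in range(model.scores.shape[1]):
            g = (model.scores[:, j] > 0).astype(float)
            chis.append(logrank_chi2_many(t, e, g) if 0 < g.sum() < len(g) else np.nan)
        assert best.pc_index == int(np.nanargmax(chis))
        assert best.chi2 == pytest.approx(np.nanmax(chis))

    def test_planted_factor_found(self):
        """The component carrying the planted factor should win the KM scan."""
        cfg = SimulationConfig(n_samples=400, seed=77, planted_log_hazard=0.7)
        cohort = simulate_cohort(cfg)
        from repairsurv.experiments import _adjusted_cohort
        _, adjusted, t, e = _adjusted_cohort(cfg)
        planted = cohort.truth["planted_genes"]
        model = fit_pc_model(adjusted.residuals.loc[planted])
        best = select_best_binarized_pc(model, t, e, fit_cox=False)
        u = np.asarray(cohort.truth["u"])
        assert abs(np.corrcoef(best.score, u)[0, 1]) > 0.5

    def test_gene_order_invariance_of_best_chi2(self, rng):
        R = _frame(rng.standard_normal((5, 100)))
        t, e = self._surv(rng, 100)
        b1 = select_best_binarized_pc(fit_pc_model(R), t, e, fit_cox=False)
        perm = rng.permutation(5)
        b2 = select_best_binarized_pc(fit_pc_model(R.iloc[perm]), t, e, fit_cox=False)
        assert b1.chi2 == pytest.approx(b2.chi2, rel=1e-8)

    def test_zero_score_goes_to_group_zero(self):
        g = binarize_pc_scores(np.array([-1.0, 0.0, 2.0]))
        np.testing.assert_array_equal(g, [0, 0, 1])


class TestCox:
    def _surv_from_score(self, rng, score, beta):
        t = rng.exponential(1.0 / (0.01 * np.exp(beta * score)))
        c = np.quantile(t, 0.7)
        return np.minimum(t, c), (t <= c).astype(int)

    def test_negated_score_inverts_hr(self, rng):
        score = rng.standard_normal(200)
        t, e = self._surv_from_score(rng, score, 0.5)
        hr, _ = cox_direction(t, e, score)
        hr_neg, _ = cox_direction(t, e, -score)
        assert hr_neg == pytest.approx(1.0 / hr, rel=1e-6)

    def test_null_ci_covers_one(self, rng):
        cover = 0
        n_seeds = 40
        for _ in range(n_seeds):
            score = rng.standard_normal(300)
            t, e = self._surv_from_score(rng, np.zeros(300), 0.0)
            _, (lo, hi) = cox_direction(t, e, score)
            cover += lo <= 1.0 <= hi
        assert cover / n_seeds >= 0.85

    def test_parameter_recovery_single(self, rng):
        score = rng.standard_normal(2000)
        t, e = self._surv_from_score(rng, score, 0.5)
        hr, _ = cox_direction(t, e, score)
        assert np.log(hr) == pytest.approx(0.5, abs=0.1)

    def test_constant_score_rejected(self):
        with pytest.raises(DegenerateInputError):
            cox_direction([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0])


def _best(loadings: dict, hr: float) -> BestPCResult:
    s = pd.Series(loadings)
    return BestPCResult(pc_index=0, chi2=10.0, pvalue=0.001,
                        groups=np.array([0, 1]), loadings=s,
                        score=np.array([-1.0, 1.0]), hazard_ratio=hr)


class TestDirections:
    def test_hr_below_one_positive_loading_up(self):
        table = assign_gene_directions(_best({"A": 0.8}, hr=0.7)).table
        assert table.loc[0, "direction"] == UP_PROLONGS

    def test_hr_above_one_positive_loading_down(self):
        table = assign_gene_directions(_best({"A": 0.8}, hr=1.4)).table
        assert table.loc[0, "direction"] == DOWN_PROLONGS

    def test_sign_flip_invariance(self):
        a = assign_gene_directions(_best({"A": 0.8, "B": -0.5}, hr=0.7)).table
        b = assign_gene_directions(_best({"A": -0.8, "B": 0.5}, hr=1 / 0.7)).table
        pd.testing.assert_series_equal(a["direction"], b["direction"])

    def test_threshold_filters(self):
        table = assign_gene_directions(_best({"A": 0.8, "B": 0.2}, hr=0.7),
                                       threshold=0.4).table
        assert list(table["gene"]) == ["A"]

    def test_hr_exactly_one_rejected(self):
        with pytest.raises(DegenerateInputError):
            assign_gene_directions(_best({"A": 0.8}, hr=1.0))


class TestPathwayComposition:
    def test_stomach_worked_example(self, packaged_catalog):
        table = pd.DataFrame({"gene": ["CUL4A", "POLQ"],
                              "loading": [0.8, 0.7],
                              "direction": [UP_PROLONGS, UP_PROLONGS]})
        comp = pathway_composition(table, packaged_catalog)
        got = dict(zip(comp["pathway"], comp["percent"]))
        assert got == {"NER": 50.0, "TLS": 50.0}

    def test_breast_worked_example(self, packaged_catalog):
        table = pd.DataFrame({"gene": ["RAD50", "PMS1"],
                              "loading": [0.8, 0.7],
                              "direction": [UP_PROLONGS, UP_PROLONGS]})
        comp = pathway_composition(table, packaged_catalog)
        got = dict(zip(comp["pathway"], comp["percent"]))
        assert got == {"DDS": 50.0, "MMR": 50.0}

    def test_single_gene_hundred_percent(self, packaged_catalog):
        table = pd.DataFrame({"gene": ["MGMT"], "loading": [0.9],
                              "direction": [DOWN_PROLONGS]})
        comp = pathway_composition(table, packaged_catalog)
        assert comp["percent"].tolist() == [100.0]

    def test_percentages_sum_to_hundred(self, packaged_catalog, rng):
        genes = list(rng.choice(packaged_catalog.genes, size=7, replace=False))
        table = pd.DataFrame({"gene": genes, "loading": [0.5] * 7,
                              "direction": [UP_PROLONGS] * 4 + [DOWN_PROLONGS] * 3})
        comp = pathway_composition(table, packaged_catalog)
        for _, sub in comp.groupby("direction"):
            assert sub["percent"].sum() == pytest.approx(100.0, abs=0.2)

    def test_unknown_gene_rejected(self, packaged_catalog):
        table = pd.DataFrame({"gene": ["NOPE"], "loading": [0.9],
                              "direction": [UP_PROLONGS]})
        with pytest.raises(KeyError):
            pathway_composition(table, packaged_catalog)
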