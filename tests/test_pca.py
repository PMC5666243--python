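"""PCA correctness: SVD route vs independent eigendecomposition oracle."""

import numpy as np
import pandas as pd
import pytest

from oxflux import (
    ToyModelSpec,
    assemble_flux_matrix,
    condition_correlation_matrix,
    flux_matrix_from_frame,
    individual_contributions,
    run_pca,
    sample_condition_fluxes,
    solve_model,
    variable_correlations,
)
from oxflux.pca import FluxMatrix
from oxflux.toy import build_toy_model


def _random_matrix(seed, n=50, p=3):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, 1)) @ rng.normal(size=(1, p))
    return FluxMatrix(
        values=base + 0.3 * rng.normal(size=(n, p)),
        row_ids=[f"R{i}" for i in range(n)],
        col_ids=[f"C{j}" for j in range(p)],
    )


def _correlation_eig_oracle(X):
    """Independent route: eigendecomposition of the correlation matrix."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = np.corrcoef(Xs, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestAssembly:
    def test_inactive_reaction_excluded(self):
        sols = {
            "a": {"R1": 1.0, "R2": 0.0},
            "b": {"R1": 2.0, "R2": 0.0},
            "c": {"R1": 3.0, "R2": 1e-12},
        }
        matrix = assemble_flux_matrix(sols)
        assert matrix.row_ids == ["R1"]

    def test_all_active_keeps_all_rows(self):
        sols = {"a": {"R1": 1.0, "R2": 0.5}, "b": {"R1": 2.0, "R2": 0.1}}
        assert assemble_flux_matrix(sols).n_rows == 2

    def test_fewer_than_two_conditions_rejected(self):
        with pytest.raises(ValueError, match="two conditions"):
            assemble_flux_matrix({"a": {"R1": 1.0}})

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            assemble_flux_matrix({"a": {"R1": 1.0}, "b": {"R2": 1.0}})

    def test_empty_active_set_rejected(self):
        with pytest.raises(ValueError, match="active"):
            assemble_flux_matrix({"a": {"R1": 0.0}, "b": {"R1": 0.0}})

    def test_toy_solutions_show_monotone_lactate(self):
        """Lactate export grows monotonically as oxygen tightens:
        lactate = 2g − min(2g, q/3) from the toy closed form."""
        base = ToyModelSpec(glucose_uptake_cap=1.0, oxygen_uptake_cap=6.0)
        model = build_toy_model(base)
        sols = {}
        for name, frac in (("Normoxia", 1.0), ("Hypoxia", 0.1), ("Anoxia", 0.0)):
            cond = model.with_reaction_bounds("EX_o2", -6.0 * frac, 0.0)
            sols[name] = solve_model(cond, resolve_degeneracy=True)
        matrix = assemble_flux_matrix(sols)
        assert "EX_lac" in matrix.row_ids
        row = matrix.to_frame().loc["EX_lac"]
        np.testing.assert_allclose(row.to_numpy(), [0.0, 1.8, 2.0], atol=1e-6)


class TestRunPCA:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_svd_matches_correlation_eigendecomposition(self, seed):
        matrix = _random_matrix(seed)
        result = run_pca(matrix, standardize=True)
        evals, evecs = _correlation_eig_oracle(matrix.values)
        np.testing.assert_allclose(result.eigenvalues, evals[: result.n_components],
                                   atol=1e-10)
        # scores agree up to sign with the eigenvector projection
        Xs = (matrix.values - matrix.values.mean(0)) / matrix.values.std(0, ddof=1)
        proj = Xs @ evecs[:, : result.n_components]
        np.testing.assert_allclose(
            np.abs(result.individual_scores.to_numpy()), np.abs(proj), atol=1e-8
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sklearn_agreement(self, seed):
        from sklearn.decomposition import PCA as SkPCA

        matrix = _random_matrix(seed)
        Xs = (matrix.values - matrix.values.mean(0)) / matrix.values.std(0, ddof=1)
        sk = SkPCA().fit(Xs)
        result = run_pca(matrix)
        np.testing.assert_allclose(
            result.eigenvalues, sk.explained_variance_[: result.n_components],
            atol=1e-10,
        )

    def test_rank_one_matrix_single_component(self):
        col = np.arange(10, dtype=float)
        matrix = FluxMatrix(
            values=np.column_stack([col, col, col]),
            row_ids=[f"R{i}" for i in range(10)],
            col_ids=["a", "b", "c"],
        )
        result = run_pca(matrix)
        assert result.variance_fraction[0] == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(
            variable_correlations(result)["PC1"].to_numpy(), [1.0, 1.0, 1.0],
            atol=1e-12,
        )

    def test_contributions_sum_to_100_per_component(self):
        result = run_pca(_random_matrix(7))
        sums = result.individual_contributions.sum(axis=0)
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-9)

    def test_loadings_bounded_by_one(self):
        result = run_pca(_random_matrix(11))
        assert (result.variable_loadings.abs().to_numpy() <= 1 + 1e-12).all()

    def test_scores_orthogonal(self):
        scores = run_pca(_random_matrix(5)).individual_scores.to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_eigenvalue_sum_equals_n_conditions_when_standardized(self):
        result = run_pca(_random_matrix(9))
        assert result.eigenvalues.sum() == pytest.approx(3.0, abs=1e-9)

    def test_permutation_equivariance(self):
        matrix = _random_matrix(13)
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_rows)
        permuted = FluxMatrix(
            values=matrix.values[perm],
            row_ids=[matrix.row_ids[i] for i in perm],
            col_ids=matrix.col_ids,
        )
        a, b = run_pca(matrix), run_pca(permuted)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-12)
        pd.testing.assert_frame_equal(
            a.variable_loadings, b.variable_loadings, atol=1e-10
        )
        pd.testing.assert_frame_equal(
            a.individual_scores.sort_index(), b.individual_scores.sort_index(),
            atol=1e-10,
        )

    def test_zero_variance_column_named_in_error(self):
        matrix = FluxMatrix(
            values=np.column_stack([np.arange(5.0), np.ones(5)]),
            row_ids=list("abcde"),
            col_ids=["varies", "flat"],
        )
        with pytest.raises(ValueError, match="flat"):
            run_pca(matrix)

    def test_sign_convention_deterministic(self):
        result = run_pca(_random_matrix(21))
        for k in result.variable_loadings.columns:
            col = result.variable_loadings[k]
            assert col.loc[col.abs().idxmax()] > 0


class TestContributionsTable:
    def test_ranked_by_pc1_with_id_tiebreak(self):
        result = run_pca(_random_matrix(3))
        table = individual_contributions(result)
        pc1 = table["PC1"].to_numpy()
        assert np.all(np.diff(pc1) <= 1e-15)
        top = individual_contributions(result, top_n=5)
        assert len(top) == 5


class TestConditionCorrelations:
    def test_duplicated_column_correlates_perfectly(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        matrix = FluxMatrix(
            values=np.column_stack([x, x, rng.normal(size=20)]),
            row_ids=[f"R{i}" for i in range(20)],
            col_ids=["a", "b", "c"],
        )
        res = condition_correlation_matrix(matrix)
        assert res.correlations.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.diag(res.correlations.to_numpy()), 1.0)
        assert res.significant.loc["a", "b"]

    def test_anticorrelated_columns(self):
        x = np.arange(10.0)
        matrix = FluxMatrix(
            values=np.column_stack([x, -x]),
            row_ids=[f"R{i}" for i in range(10)],
            col_ids=["x", "neg"],
        )
        res = condition_correlation_matrix(matrix)
        assert res.correlations.loc["x", "neg"] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_column_reported_missing_with_warning(self):
        matrix = FluxMatrix(
            values=np.column_stack([np.arange(6.0), np.full(6, 2.0)]),
            row_ids=list("abcdef"),
            col_ids=["varies", "flat"],
        )
        with pytest.warns(UserWarning, match="flat"):
            res = condition_correlation_matrix(matrix)
        assert np.isnan(res.correlations.loc["varies", "flat"])
        assert not res.significant.loc["varies", "flat"]


class TestEndToEnd:
    def test_toy_flux_dataset_structure_dominates_noise(self):
        """Between normoxia and hypoxia the flux shifts are strongly
        correlated, so PC1 dominates even with 5% multiplicative noise."""
        frames = []
        for seed in (1, 2):
            frame = sample_condition_fluxes(
                oxygen_fractions=(1.0, 0.1), seed=seed, noise_sd=0.05,
                condition_names=["Normoxia", "Hypoxia"],
            )
            frames.append(frame)
            result = run_pca(flux_matrix_from_frame(frame))
            assert result.variance_fraction[0] > 90.0
        # different seeds produce different tables
        assert not np.allclose(frames[0].to_numpy(), frames[1].to_numpy())
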