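"""AMMI decomposition: double-centering, SVD scores, axis df, biplot axes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metstab import SyntheticSpec, cell_means, generate
from metstab.ammi import (
    ammi1_coordinates,
    axis_significance,
    double_center,
    fit_ammi,
    gollob_df,
)
from metstab.trial_data import MeansMatrix, ValidationError


def toy_matrix(values):
    values = np.asarray(values, dtype=float)
    g, e = values.shape
    return MeansMatrix([f"G{i}" for i in range(g)],
                       [f"E{j}" for j in range(e)], values)


matrix_strategy = st.integers(2, 6).flatmap(
    lambda g: st.integers(2, 6).flatmap(
        lambda e: st.lists(
            st.floats(0.1, 20, allow_nan=False, allow_infinity=False),
            min_size=g * e, max_size=g * e,
        ).map(lambda vals: np.array(vals).reshape(g, e))))


class TestDoubleCenter:
    def test_additive_matrix_has_zero_interaction(self, rng):
        a, b = rng.uniform(1, 3, 5), rng.uniform(0, 2, 4)
        z = double_center(toy_matrix(a[:, None] + b[None, :]))
        np.testing.assert_allclose(z, 0, atol=1e-12)

    def test_two_by_two_hand_value(self):
        # Y11 - row1 mean - col1 mean + grand = 1 - 0.5 - 0.5 + 0.5 = 0.5
        z = double_center(toy_matrix([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(z, [[0.5, -0.5], [-0.5, 0.5]])

    @settings(deadline=None, max_examples=40)
    @given(matrix_strategy)
    def test_margins_always_zero(self, values):
        z = double_center(toy_matrix(values))
        scale = max(1.0, np.abs(values).max())
        np.testing.assert_allclose(z.sum(axis=0) / scale, 0, atol=1e-9)
        np.testing.assert_allclose(z.sum(axis=1) / scale, 0, atol=1e-9)

    def test_wheat_interaction_ss(self, wheat):
        # r * sum(Z^2) reproduces the treatment-partition interaction SS
        z = double_center(wheat.means)
        ss = 2 * float((z ** 2).sum())
        assert ss == pytest.approx(37.399, abs=0.001)


class TestFitAmmi:
    def test_reconstruction_identity(self, rng):
        m = toy_matrix(rng.uniform(1, 6, size=(5, 4)))
        fit = fit_ammi(m, reps=2)
        np.testing.assert_allclose(fit.reconstruct(), m.values, atol=1e-10)
        # with all axes kept the residual is numerically zero
        np.testing.assert_allclose(fit.residual, 0, atol=1e-10)

    def test_truncated_fit_keeps_residual(self, rng):
        m = toy_matrix(rng.uniform(1, 6, size=(6, 5)))
        fit = fit_ammi(m, reps=2, n_axes=1)
        assert fit.gen_scores.shape == (6, 1)
        np.testing.assert_allclose(fit.reconstruct(), m.values, atol=1e-10)
        assert float(np.abs(fit.residual).max()) > 0

    def test_sigma_squared_match_eigensolver_oracle(self, rng):
        m = toy_matrix(rng.uniform(1, 9, size=(4, 3)))
        fit = fit_ammi(m, reps=1)
        z = double_center(m)
        eig = np.sort(np.linalg.eigvalsh(z @ z.T))[::-1]
        np.testing.assert_allclose(fit.singular_values ** 2,
                                   eig[: len(fit.singular_values)], atol=1e-9)

    def test_score_orthogonality_and_conservation(self, rng):
        m = toy_matrix(rng.uniform(1, 6, size=(7, 5)))
        fit = fit_ammi(m, reps=2)
        z = double_center(m)
        # u_n . u_m = 0 for n != m  (scores are sqrt(sigma)-scaled u)
        gram = fit.gen_scores.T @ fit.gen_scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-9)
        gram_e = fit.env_scores.T @ fit.env_scores
        np.testing.assert_allclose(gram_e - np.diag(np.diag(gram_e)), 0,
                                   atol=1e-9)
        assert (fit.singular_values ** 2).sum() == pytest.approx(
            float((z ** 2).sum()), rel=1e-12)

    def test_scale_equivariance(self, rng):
        vals = rng.uniform(1, 6, size=(5, 4))
        c = 3.7
        f1 = fit_ammi(toy_matrix(vals), reps=2)
        f2 = fit_ammi(toy_matrix(c * vals), reps=2)
        np.testing.assert_allclose(f2.singular_values, c * f1.singular_values,
                                   atol=1e-9)
        np.testing.assert_allclose(np.abs(f2.gen_scores),
                                   np.sqrt(c) * np.abs(f1.gen_scores),
                                   atol=1e-9)

    def test_symmetric_scaling_score_products(self, rng):
        # genotype score x environment score = sigma_n * u_ni * v_nj
        m = toy_matrix(rng.uniform(1, 6, size=(5, 4)))
        fit = fit_ammi(m, reps=2)
        z = double_center(m)
        np.testing.assert_allclose(fit.gen_scores @ fit.env_scores.T, z,
                                   atol=1e-10)
        for n in range(fit.n_axes_kept):
            assert (fit.gen_scores[:, n] ** 2).sum() == pytest.approx(
                fit.singular_values[n], rel=1e-9)

    def test_axes_out_of_range_rejected(self, rng):
        m = toy_matrix(rng.uniform(1, 6, size=(4, 4)))
        with pytest.raises(ValidationError):
            fit_ammi(m, n_axes=4)
        with pytest.raises(ValidationError):
            fit_ammi(m, n_axes=0)

    def test_rank1_construction_fully_explained(self):
        obs, _ = generate(SyntheticSpec(
            n_genotypes=6, n_environments=5, n_replicates=2,
            gei_singular_values=(2.0,), sigma_err=0, sigma_block=0, seed=5))
        fit = fit_ammi(cell_means(obs), reps=2)
        assert fit.pct_explained[0] == pytest.approx(100, abs=1e-8)
        assert fit.singular_values[0] == pytest.approx(2.0, abs=1e-9)

    def test_wheat_axis_shares(self, wheat_ammi):
        pct = wheat_ammi.pct_explained
        assert pct[0] == pytest.approx(45.5, abs=1.5)
        assert pct[1] == pytest.approx(24.7, abs=1.5)
        # non-increasing spectrum
        assert np.all(np.diff(wheat_ammi.singular_values) <= 1e-12)

    def test_wheat_score_sums_match_published_columns(self, wheat_ammi):
        # sums over genotypes of squared axis scores equal sigma_n; the
        # published score columns imply 2.92 and 2.15
        assert (wheat_ammi.gen_scores[:, 0] ** 2).sum() == pytest.approx(
            2.92, rel=0.05)
        assert (wheat_ammi.gen_scores[:, 1] ** 2).sum() == pytest.approx(
            2.15, rel=0.05)

    def test_wheat_largest_ipca1_is_ardi(self, wheat_ammi):
        i = int(np.argmax(np.abs(wheat_ammi.gen_scores[:, 0])))
        assert wheat_ammi.genotypes[i] == "Ardi"
        assert abs(wheat_ammi.gen_scores[i, 0]) == pytest.approx(1.35, abs=0.01)


class TestGollobDf:
    @pytest.mark.parametrize("axis, g, e, expected", [
        (1, 12, 9, 18), (2, 12, 9, 16), (3, 12, 9, 14),
        (1, 2, 2, 1), (2, 3, 3, 1),
    ])
    def test_formula(self, axis, g, e, expected):
        assert gollob_df(axis, g, e) == expected

    def test_invalid_axis_rejected(self):
        with pytest.raises(ValidationError):
            gollob_df(0, 12, 9)
        with pytest.raises(ValidationError):
            gollob_df(9, 12, 9)

    def test_axis_table_flags_untested_without_error_term(self, wheat_ammi):
        t = axis_significance(wheat_ammi)
        assert not t["tested"].any()
        assert t["df"].tolist()[:2] == [18, 16]
        t2 = axis_significance(wheat_ammi, error_ms=0.24, error_df=99)
        assert t2["tested"].all()
        assert (t2.loc[:1, "p"] < 0.01).all()


class TestAmmi1Coordinates:
    def test_wheat_points(self, wheat_ammi):
        gen, env = ammi1_coordinates(wheat_ammi)
        assert gen.loc["Fentale 1", "mean_yield"] == pytest.approx(3.62,
                                                                   abs=0.005)
        assert env.loc["Girja", "mean_yield"] == pytest.approx(1.95, abs=0.005)
        assert wheat_ammi.mu == pytest.approx(3.14, abs=0.005)

    def test_additive_data_lie_on_the_axis(self, rng):
        a, b = rng.uniform(1, 3, 5), rng.uniform(0, 2, 4)
        fit = fit_ammi(toy_matrix(a[:, None] + b[None, :]), reps=1)
        gen, env = ammi1_coordinates(fit)
        # scores carry sqrt(sigma), so float-eps interactions appear at ~1e-8
        np.testing.assert_allclose(gen["ipca1"], 0, atol=1e-6)
        np.testing.assert_allclose(env["ipca1"], 0, atol=1e-6)
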