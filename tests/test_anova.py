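"""Sum-of-squares partition, F-tests, LSD/CV and homogeneity of variance."""

import numpy as np
import pytest
from scipy import stats

from metstab import SyntheticSpec, cell_means, generate
from metstab.anova import (
    anova_replicated,
    homogeneity_test,
    homogeneity_test_samples,
    lsd_cv,
    partition_ss,
    per_environment_error,
)
from metstab.trial_data import MeansMatrix, TrialObservation, ValidationError


def toy_matrix(values, gens=None, envs=None):
    values = np.asarray(values, dtype=float)
    g, e = values.shape
    return MeansMatrix(gens or [f"G{i}" for i in range(g)],
                       envs or [f"E{j}" for j in range(e)], values)


class TestPartitionSS:
    def test_two_by_two_against_hand_expansion(self):
        m = toy_matrix([[1.0, 2.0], [3.0, 5.0]])
        # mu=2.75, row means (1.5, 4), col means (2, 3.5)
        ss_g = 2 * 1 * ((1.5 - 2.75) ** 2 + (4 - 2.75) ** 2)
        ss_e = 2 * 1 * ((2 - 2.75) ** 2 + (3.5 - 2.75) ** 2)
        z = 1.0 - 1.5 - 2.0 + 2.75          # same +-0.25 in all four cells
        ss_i = 4 * z ** 2
        t = partition_ss(m, reps=1).set_index("source")
        assert t.loc["Genotypes", "SS"] == pytest.approx(ss_g)
        assert t.loc["Environments", "SS"] == pytest.approx(ss_e)
        assert t.loc["Interactions", "SS"] == pytest.approx(ss_i)

    def test_constant_matrix_all_zero(self):
        t = partition_ss(toy_matrix(np.full((3, 4), 2.5)), reps=2)
        assert (t["SS"] == 0).all()

    def test_scales_linearly_in_reps(self, rng):
        m = toy_matrix(rng.uniform(1, 6, size=(5, 4)))
        t1 = partition_ss(m, reps=1).set_index("source")["SS"]
        t3 = partition_ss(m, reps=3).set_index("source")["SS"]
        np.testing.assert_allclose(t3, 3 * t1)

    def test_pct_explained_sums_to_100(self, rng):
        m = toy_matrix(rng.uniform(1, 6, size=(6, 5)))
        t = partition_ss(m, reps=2)
        tre = t[t["source"] != "Treatment total"]
        assert tre["pct_explained"].sum() == pytest.approx(100.0)

    def test_reps_below_one_rejected(self, rng):
        with pytest.raises(ValidationError):
            partition_ss(toy_matrix(rng.uniform(1, 6, size=(3, 3))), reps=0)

    def test_wheat_shares_bracket_published_values(self, wheat):
        t = partition_ss(wheat.means, wheat.replicates).set_index("source")
        assert t.loc["Environments", "SS"] == pytest.approx(161.29, rel=0.01)
        assert 75.5 <= t.loc["Environments", "pct_explained"] <= 77.5
        assert 4.0 <= t.loc["Genotypes", "pct_explained"] <= 6.0
        assert 17.5 <= t.loc["Interactions", "pct_explained"] <= 19.5


def _balanced_obs(rng, G=4, E=3, R=2):
    return [TrialObservation(f"G{i}", f"E{j}", r + 1,
                             float(rng.uniform(0.5, 8)))
            for i in range(G) for j in range(E) for r in range(R)]


class TestAnovaReplicated:
    def test_matches_nested_loop_oracle(self, rng):
        obs = _balanced_obs(rng)
        t = anova_replicated(obs).set_index("source")
        y = {(o.genotype, o.environment, o.replicate): o.yield_t_ha
             for o in obs}
        G, E, R = 4, 3, 2
        mu = sum(y.values()) / len(y)
        gm = {g: np.mean([y[(g, f"E{j}", r + 1)] for j in range(E)
                          for r in range(R)]) for g in [f"G{i}" for i in range(G)]}
        em = {e: np.mean([y[(f"G{i}", e, r + 1)] for i in range(G)
                          for r in range(R)]) for e in [f"E{j}" for j in range(E)]}
        ss_g = E * R * sum((v - mu) ** 2 for v in gm.values())
        ss_e = G * R * sum((v - mu) ** 2 for v in em.values())
        ss_gei = R * sum(
            (np.mean([y[(g, e, r + 1)] for r in range(R)])
             - gm[g] - em[e] + mu) ** 2
            for g in gm for e in em)
        ss_total = sum((v - mu) ** 2 for v in y.values())
        assert t.loc["Genotypes", "SS"] == pytest.approx(ss_g)
        assert t.loc["Environments", "SS"] == pytest.approx(ss_e)
        assert t.loc["Interactions", "SS"] == pytest.approx(ss_gei)
        assert t.loc["Total", "SS"] == pytest.approx(ss_total)

    def test_components_sum_to_total(self, rng):
        t = anova_replicated(_balanced_obs(rng, 5, 4, 3)).set_index("source")
        parts = t.loc[["Environments", "Replication(Environment)",
                       "Genotypes", "Interactions", "Error"], "SS"].sum()
        assert parts == pytest.approx(t.loc["Total", "SS"], rel=1e-9)

    def test_df_follow_the_design(self, rng):
        t = anova_replicated(_balanced_obs(rng, 12, 9, 2)).set_index("source")
        assert t.loc["Genotypes", "df"] == 11
        assert t.loc["Environments", "df"] == 8
        assert t.loc["Replication(Environment)", "df"] == 9
        assert t.loc["Interactions", "df"] == 88
        assert t.loc["Error", "df"] == 99
        assert t.loc["Total", "df"] == 215

    def test_zero_noise_gives_zero_error_ss(self):
        obs, _ = generate(SyntheticSpec(
            n_genotypes=5, n_environments=4, n_replicates=2,
            gei_singular_values=(1.0,), sigma_err=0, sigma_block=0, seed=3))
        t = anova_replicated(obs).set_index("source")
        assert t.loc["Error", "SS"] == pytest.approx(0, abs=1e-9)

    def test_treatment_rows_agree_with_means_partition(self, rng):
        obs = _balanced_obs(rng, 6, 4, 2)
        t_rep = anova_replicated(obs).set_index("source")
        t_mean = partition_ss(cell_means(obs), reps=2).set_index("source")
        for src in ("Genotypes", "Environments", "Interactions"):
            assert t_rep.loc[src, "SS"] == pytest.approx(
                t_mean.loc[src, "SS"], rel=1e-9)

    def test_unbalanced_rejected(self, rng):
        obs = _balanced_obs(rng)[:-1]
        with pytest.raises(ValidationError, match="unbalanced"):
            anova_replicated(obs)


class TestLsdCv:
    def test_zero_residual_variance(self):
        obs = [TrialObservation(g, "E", r, y)
               for g, y in [("A", 2.0), ("B", 3.0), ("C", 5.0)]
               for r in (1, 2)]
        lsd, cv = lsd_cv(obs)
        assert lsd == pytest.approx(0, abs=1e-9)
        assert cv == pytest.approx(0, abs=1e-9)

    def test_matches_textbook_formula(self, rng):
        G, R = 6, 3
        obs = [TrialObservation(f"G{i}", "E", r + 1,
                                float(rng.uniform(1, 7)))
               for i in range(G) for r in range(R)]
        lsd, cv = lsd_cv(obs, alpha=0.05)
        y = np.array([[o.yield_t_ha for o in obs
                       if o.genotype == f"G{i}"] for i in range(G)])
        mu = y.mean()
        ss_err = ((y - y.mean(1, keepdims=True)
                   - y.mean(0, keepdims=True) + mu) ** 2).sum()
        df_err = (G - 1) * (R - 1)
        ms_err = ss_err / df_err
        assert lsd == pytest.approx(
            stats.t.ppf(0.975, df_err) * np.sqrt(2 * ms_err / R))
        assert cv == pytest.approx(100 * np.sqrt(ms_err) / mu)

    def test_cv_invariant_to_genotype_relabeling(self, rng):
        obs = [TrialObservation(f"G{i}", "E", r + 1,
                                float(rng.uniform(1, 7)))
               for i in range(5) for r in range(2)]
        relabeled = [TrialObservation("X" + o.genotype, o.environment,
                                      o.replicate, o.yield_t_ha) for o in obs]
        assert lsd_cv(obs)[1] == pytest.approx(lsd_cv(relabeled)[1])

    def test_single_replicate_rejected(self):
        obs = [TrialObservation(f"G{i}", "E", 1, 2.0) for i in range(4)]
        with pytest.raises(ValidationError):
            lsd_cv(obs)


class TestHomogeneity:
    def test_equal_variances_give_zero_statistic(self):
        stat, p = homogeneity_test([2.0, 2.0, 2.0], [5, 5, 5])
        assert stat == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_evaluated_formula(self):
        v, d = np.array([1.0, 4.0]), np.array([10.0, 12.0])
        n = d.sum()
        pooled = (d * v).sum() / n
        c = 1 + (np.sum(1 / d) - 1 / n) / (3 * 1)
        expect = (n * np.log(pooled) - (d * np.log(v)).sum()) / c
        stat, p = homogeneity_test(v, d)
        assert stat == pytest.approx(expect)
        assert p == pytest.approx(float(stats.chi2.sf(expect, 1)))

    def test_scale_invariance(self):
        s1, _ = homogeneity_test([1.0, 3.0, 0.5], [4, 6, 8])
        s2, _ = homogeneity_test([2.0, 6.0, 1.0], [4, 6, 8])
        assert s1 == pytest.approx(s2)

    def test_summary_version_agrees_with_scipy_on_samples(self, rng):
        groups = [rng.normal(0, s, size=12) for s in (1.0, 1.5, 0.7)]
        stat_scipy, p_scipy = homogeneity_test_samples(groups, "bartlett")
        stat_sum, p_sum = homogeneity_test(
            [np.var(g, ddof=1) for g in groups], [len(g) - 1 for g in groups])
        assert stat_sum == pytest.approx(stat_scipy, rel=1e-9)
        assert p_sum == pytest.approx(p_scipy, rel=1e-9)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValidationError):
            homogeneity_test([1.0, 0.0], [4, 4])

    def test_per_environment_errors_feed_the_test(self, rng):
        obs, _ = generate(SyntheticSpec(n_genotypes=6, n_environments=4,
                                        n_replicates=2, sigma_err=0.3,
                                        seed=11))
        err = per_environment_error(obs)
        assert len(err) == 4
        assert (err["df"] == 5).all()
        stat, p = homogeneity_test(err["error_variance"], err["df"])
        assert 0 <= p <= 1
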