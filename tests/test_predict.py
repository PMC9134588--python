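"""Kolmogorov solver, occupancy, profiles and simulation CIs."""

import numpy as np
import pytest
from scipy.linalg import expm

from exacmsm import events as ev
from exacmsm import parametric as pm
from exacmsm import predict as pr
from exacmsm import synth


def _progressive_q(rates):
    Q = np.zeros((5, 5))
    for (r, s), v in rates.items():
        Q[r - 1, s - 1] = v
    Q[np.arange(5), np.arange(5)] = -Q.sum(axis=1)
    return Q


class TestTransitionProbabilities:
    def test_zero_interval_is_identity(self, weibull_fit):
        P = pr.transition_probabilities(pr.intensity_matrix(weibull_fit),
                                        0.3, 0.3)
        np.testing.assert_array_equal(P.matrix, np.eye(5))

    def test_homogeneous_matches_matrix_exponential(self):
        Q = _progressive_q(synth.DEFAULT_RATES)
        P = pr.transition_probabilities(pr.homogeneous_intensity(Q),
                                        0.0, 1.0).matrix
        assert np.abs(P - expm(Q)).max() < 1e-8

    def test_chain_absorption_matches_convolution_oracle(self):
        # strict chain 1->2->3->4->5: P15(t) is the hypoexponential CDF
        lam = np.array([0.9, 0.7, 0.5, 0.3])
        rates = {(1, 2): lam[0], (2, 3): lam[1], (3, 4): lam[2],
                 (4, 5): lam[3]}
        Q = _progressive_q(rates)
        t = 2.0
        P = pr.transition_probabilities(pr.homogeneous_intensity(Q),
                                        0.0, t).matrix
        cdf = 1.0
        for i in range(4):
            coeff = np.prod([lam[j] / (lam[j] - lam[i])
                             for j in range(4) if j != i])
            cdf -= coeff * np.exp(-lam[i] * t)
        assert P[0, 4] == pytest.approx(cdf, abs=1e-8)

    def test_structural_zeros_exact(self, weibull_fit):
        for t in (28 / 365.25, 1.0, 5.0):
            P = pr.transition_probabilities(
                pr.intensity_matrix(weibull_fit), 0.0, t).matrix
            assert np.all(P[pr.FORBIDDEN_MASK] == 0.0)

    def test_rows_sum_to_one(self, weibull_fit):
        P = pr.transition_probabilities(pr.intensity_matrix(weibull_fit),
                                        0.0, 2.0).matrix
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_negative_time_rejected(self, weibull_fit):
        with pytest.raises(ValueError):
            pr.transition_probabilities(pr.intensity_matrix(weibull_fit),
                                        1.0, 0.5)

    def test_invalid_q_rejected(self):
        Q = np.zeros((5, 5))
        Q[0, 2] = 0.5  # the forbidden 1->3 jump
        Q[0, 0] = -0.5
        with pytest.raises(ValueError, match="forbidden"):
            pr.homogeneous_intensity(Q)


class TestIntensityMatrix:
    def test_exponential_constant_in_time(self, exponential_fit):
        im = pr.intensity_matrix(exponential_fit)
        np.testing.assert_allclose(im.Q(0.1), im.Q(2.5), atol=1e-14)

    def test_weibull_time_scaling_identity(self, weibull_fit):
        # q(t)/q(1) = t^(a-1) for every permitted transition
        a = float(np.exp(weibull_fit.anc_values()[0]))
        im = pr.intensity_matrix(weibull_fit)
        t = 0.37
        Q1, Qt = im.Q(1.0), im.Q(t)
        for (r, s) in weibull_fit.transitions:
            assert Qt[r - 1, s - 1] / Q1[r - 1, s - 1] == pytest.approx(
                t ** (a - 1.0), rel=1e-10)

    def test_unknown_profile_covariate_rejected(self, weibull_fit):
        with pytest.raises(KeyError, match="profile"):
            pr.intensity_matrix(weibull_fit, {"bmi": 30.0})

    def test_negative_time_rejected(self, weibull_fit):
        with pytest.raises(ValueError, match="negative"):
            pr.intensity_matrix(weibull_fit).Q(-0.1)


class TestOccupancy:
    def test_initial_occupancy(self, weibull_fit):
        occ = pr.occupancy_curves(weibull_fit, None, [0.0, 28.0])
        np.testing.assert_allclose(occ.probabilities[0], [1, 0, 0, 0, 0],
                                   atol=1e-14)

    def test_death_curve_monotone_rows_sum_one(self, weibull_fit):
        occ = pr.occupancy_curves(weibull_fit, None, pr.default_grid_days())
        np.testing.assert_allclose(occ.probabilities.sum(axis=1), 1.0,
                                   atol=1e-8)
        assert np.all(np.diff(occ.probabilities[:, 4]) >= -1e-10)

    def test_empirical_occupancy_matches_model(self):
        # simulate many patients from known exponential truth and compare
        # the day-364 state distribution with the model's occupancy
        cfg = synth.GeneratorConfig(n=20000, seed=77, family="exponential",
                                    covariate_effects=(), dropout_rate=0.0)
        cohort = synth.simulate_trajectories(cfg)
        final = np.array([seq[-1][0] for seq in cohort.state_sequences])
        emp = np.bincount(final, minlength=6)[1:] / len(final)
        Q = _progressive_q(cfg.rates)
        P = expm(Q * 364 / 365.25)[0]
        se = np.sqrt(P * (1 - P) / len(final))
        assert np.all(np.abs(emp - P) <= 3 * se + 1e-12)


class TestSimulationCI:
    def test_zero_vcov_collapses_to_point(self, weibull_fit):
        import copy

        frozen = copy.copy(weibull_fit)
        frozen.vcov = np.zeros_like(weibull_fit.vcov)
        lo, hi = pr.simulate_normal_ci(frozen, lambda th: th[:3],
                                       n_samples=50, seed=1)
        np.testing.assert_allclose(lo, weibull_fit.theta[:3], atol=1e-12)
        np.testing.assert_allclose(hi, weibull_fit.theta[:3], atol=1e-12)

    def test_fixed_seed_bit_identical(self, weibull_fit):
        f = lambda th: np.exp(th[:2])  # noqa: E731
        a = pr.simulate_normal_ci(weibull_fit, f, n_samples=200, seed=9)
        b = pr.simulate_normal_ci(weibull_fit, f, n_samples=200, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_four_week_matrix_cis_bracket_estimate(self, weibull_fit):
        P = pr.four_week_matrix(weibull_fit, n_samples=120, seed=4)
        free = ~pr.FORBIDDEN_MASK
        assert np.all(P.ci_low[free] <= P.matrix[free] + 1e-12)
        assert np.all(P.matrix[free] <= P.ci_high[free] + 1e-12)
        assert np.all(P.ci_low[pr.FORBIDDEN_MASK] == 0.0)
        assert np.all(P.ci_high[pr.FORBIDDEN_MASK] == 0.0)


@pytest.fixture(scope="module")
def adjusted_fit():
    effects = synth.DEFAULT_EFFECTS + (
        synth.TruthEffect(
            pm.CovariateTerm("prior_exac", "prior_exacs",
                             ev.EXACERBATION_TRANSITIONS, center=1.0),
            0.25),
    )
    cfg = synth.GeneratorConfig(n=3000, seed=13,
                                covariate_effects=effects)
    df = synth.simulate_dataset(cfg)
    spec = tuple(e.term for e in effects)
    return pm.fit(df, "weibull", spec)


class TestProfiles:
    def test_requires_profile_covariates(self, weibull_fit):
        with pytest.raises(ValueError, match="missing"):
            pr.eight_profiles(weibull_fit, [0.0, 364.0])

    def test_groupings_nested_and_monotone_in_prior_exacs(self,
                                                          adjusted_fit):
        prof = pr.eight_profiles(adjusted_fit, [182.0, 364.0, 1826.0])
        wide = prof.pivot_table(index=["profile", "age", "fev1pp",
                                       "prior_exacs", "time_days"],
                                columns="grouping", values="probability")
        assert (wide["death"] <= wide["severe_or_death"] + 1e-12).all()
        assert (wide["severe_or_death"]
                <= wide["ge2_moderate_severe_or_death"] + 1e-12).all()
        assert (wide["ge2_moderate_severe_or_death"]
                <= wide["any_state_ge2"] + 1e-12).all()
        # generating prior-exacerbation effect is positive: more prior
        # exacerbations must raise P(severe or death) at 5 years
        sel = prof[(prof.grouping == "severe_or_death")
                   & (prof.time_days == 1826.0)]
        for (age, fev), grp in sel.groupby(["age", "fev1pp"]):
            p = grp.set_index("prior_exacs")["probability"]
            assert p[2.0] > p[1.0]

    def test_eight_profiles_cover_grid(self, adjusted_fit):
        prof = pr.eight_profiles(adjusted_fit, [364.0])
        assert prof["profile"].nunique() == 8
        combos = prof[["age", "fev1pp", "prior_exacs"]].drop_duplicates()
        assert len(combos) == 8
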