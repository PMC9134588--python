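"""Parametric multi-state likelihood, fitting, HRs, LRT and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from exacmsm import events as ev
from exacmsm import parametric as pm
from exacmsm import synth
from exacmsm.families import get_family

RATES = np.array([0.4, 0.1, 0.02, 0.5, 0.15, 0.04, 0.2, 0.06, 0.3])


def _censored_state1_dataset(t=0.7):
    rows = [("A", 1, s, 0.0, t, "censored") for s in (2, 4, 5)]
    return pd.DataFrame(rows, columns=["patient_id", "from_state",
                                       "to_state", "entry_time",
                                       "exit_time", "status"])


class TestNegLogLikelihood:
    def test_exponential_closed_form_single_censored_patient(self):
        # NLL = (λ12 + λ14 + λ15) * t for one patient censored in state 1
        t = 0.7
        lam = np.array([0.4, 0.1, 0.02])
        nll = pm.neg_log_likelihood(np.log(lam), _censored_state1_dataset(t),
                                    "exponential", time_scale=1.0)
        assert nll == pytest.approx(lam.sum() * t, abs=1e-12)

    def test_wrong_length_theta_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pm.neg_log_likelihood(np.zeros(2), _censored_state1_dataset(),
                                  "exponential")

    @pytest.mark.parametrize("family,anc", [
        ("weibull", [np.log(1.4)]),
        ("gompertz", [0.6]),
        ("gengamma", [np.log(0.8), 0.7]),
    ])
    def test_matches_quadrature_oracle(self, family, anc):
        """Row-wise NLL equals the sojourn integral of the hazard."""
        df = synth.simulate_dataset(synth.GeneratorConfig(n=60, seed=3),
                                    with_covariates=False)
        theta = np.concatenate([np.log(RATES), anc])
        nll = pm.neg_log_likelihood(theta, df, family, time_scale=365.25)
        fam = get_family(family)
        anc = np.asarray(anc)
        total = 0.0
        for row in df.itertuples():
            i = ev.PERMITTED_TRANSITIONS.index((row.from_state, row.to_state))
            lam = RATES[i]
            t0, t1 = row.entry_time / 365.25, row.exit_time / 365.25
            if fam.kind == "ph":
                def h(u):
                    return lam * np.exp(fam.loghaz(u, anc))
            else:
                def h(u):
                    return lam * np.exp(fam.loghaz(u * lam, anc))
            H, _ = quad(h, t0, t1, limit=300)
            total += H
            if row.status == "event":
                total -= np.log(h(t1))
        assert nll == pytest.approx(total, rel=1e-7, abs=1e-7)


class TestFit:
    def test_exponential_mle_is_events_over_persontime(self, dataset,
                                                       exponential_fit):
        for rs in exponential_fit.transitions:
            closed = exponential_fit.n_events[rs] / \
                exponential_fit.exposure[rs]
            assert exponential_fit.rate(rs) == pytest.approx(closed,
                                                             rel=1e-6)

    def test_score_norm_small_at_mle(self, weibull_fit, exponential_fit):
        assert weibull_fit.score_norm < 1e-5
        assert exponential_fit.score_norm < 1e-5

    def test_parameters_within_3se_of_truth(self):
        cfg = synth.GeneratorConfig(n=4000, seed=1)
        df = synth.simulate_dataset(cfg)
        spec = tuple(e.term for e in cfg.covariate_effects)
        f = pm.fit(df, "weibull", spec)
        truth = df.attrs["truth"].theta_by_name()
        se = f.se()
        for name, est, s in zip(f.param_names, f.theta, se):
            assert abs(est - truth[name]) < 3 * s, name

    def test_weibull_shape_ci_covers_one_on_exponential_truth(self):
        cfg = synth.GeneratorConfig(n=3000, seed=5, family="exponential",
                                    covariate_effects=())
        df = synth.simulate_dataset(cfg, with_covariates=False)
        f = pm.fit(df, "weibull")
        s = f.summary().loc["log_shape"]
        assert s.ci_low <= 0.0 <= s.ci_high

    def test_block_diagonal_decomposition(self, dataset):
        # with no shared parameters the joint exponential fit equals
        # independent per-transition occurrence/exposure fits
        f = pm.fit(dataset, "exponential")
        for rs in f.transitions:
            sub = dataset[(dataset.from_state == rs[0])
                          & (dataset.to_state == rs[1])]
            alone = pm.fit(sub, "exponential")
            assert f.rate(rs) == pytest.approx(alone.rate(rs), rel=1e-8)

    def test_vcov_symmetric_psd(self, weibull_fit):
        V = weibull_fit.vcov
        np.testing.assert_allclose(V, V.T, atol=1e-10)
        assert np.linalg.eigvalsh(V).min() > 0

    def test_no_event_transition_flagged_dropped(self):
        df = _censored_state1_dataset()
        df2 = df.copy()
        df2.loc[0, "status"] = "event"  # one 1->2 event only
        f = pm.fit(df2, "exponential")
        assert f.transitions == ((1, 2),)
        assert set(f.dropped_transitions) == {(1, 4), (1, 5)}
        assert f.hazard((1, 4), 0.5) == 0.0

    def test_degenerate_covariate_rejected(self, dataset):
        df = dataset.copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            pm.fit(df, "exponential",
                   [pm.CovariateTerm("flat", "flat", ((1, 2),))])


class TestNesting:
    def test_gengamma_dominates_nested_families(self):
        df = synth.simulate_dataset(synth.GeneratorConfig(n=800, seed=9),
                                    with_covariates=False)
        ll = {fam: pm.fit(df, fam).loglik
              for fam in ("weibull", "lognormal", "gamma", "gengamma")}
        for fam in ("weibull", "lognormal", "gamma"):
            assert ll["gengamma"] >= ll[fam] - 1e-6, fam


class TestAicTable:
    def test_definition_and_ordering(self, dataset):
        fits = [pm.fit(dataset, f) for f in ("exponential", "weibull",
                                             "gompertz")]
        table = pm.aic_table(fits)
        for _, row in table.iterrows():
            assert row.aic == pytest.approx(2 * row.k - 2 * row.loglik,
                                            abs=1e-10)
        assert table.aic.is_monotonic_increasing
        assert table.delta_aic.iloc[0] == 0.0

    def test_identical_fits_have_zero_delta(self, weibull_fit):
        table = pm.aic_table([weibull_fit, weibull_fit])
        assert (table.delta_aic == 0.0).all()

    def test_weibull_preferred_on_weibull_truth(self):
        cfg = synth.GeneratorConfig(n=3000, seed=23, shape=1.5,
                                    covariate_effects=())
        df = synth.simulate_dataset(cfg, with_covariates=False)
        table = pm.aic_table([pm.fit(df, "exponential"),
                              pm.fit(df, "weibull")])
        assert table.family.iloc[0] == "weibull"

    def test_mismatched_datasets_rejected(self, dataset):
        other = synth.simulate_dataset(synth.GeneratorConfig(n=100, seed=2))
        with pytest.raises(ValueError, match="same dataset"):
            pm.aic_table([pm.fit(dataset, "exponential"),
                          pm.fit(other, "exponential")])


class TestHazardRatios:
    def test_identity_for_same_transition(self, weibull_fit):
        [hr] = pm.transition_hazard_ratios(weibull_fit,
                                           [((4, 5), (4, 5))])
        assert hr.hr == pytest.approx(1.0, abs=1e-12)
        assert hr.ci_low <= 1.0 <= hr.ci_high

    def test_ratio_consistency_exact_under_shared_shape(self, weibull_fit):
        pairs = [((4, 5), (2, 5)), ((4, 5), (1, 5)), ((2, 5), (1, 5))]
        h42, h41, h21 = pm.transition_hazard_ratios(weibull_fit, pairs)
        assert h42.hr == pytest.approx(h41.hr / h21.hr, rel=1e-12)

    def test_published_ratio_arithmetic(self):
        # consistency of the printed unadjusted HR table: severe-vs-X
        # death contrasts are ratios of the severe-vs-none contrasts
        assert pm.relative_hazard_ratio(11.4, 2.1) == pytest.approx(
            5.4, abs=0.1)
        assert pm.relative_hazard_ratio(11.4, 1.8) == pytest.approx(
            6.4, abs=0.1)

    def test_time_varying_ratio_requires_reference_time(self, dataset):
        f = pm.fit(dataset, "lognormal")
        with pytest.raises(ValueError, match="t_ref"):
            pm.transition_hazard_ratios(f, [((4, 5), (1, 5))])
        [hr] = pm.transition_hazard_ratios(f, [((4, 5), (1, 5))],
                                           t_ref_years=0.5)
        assert hr.hr > 0 and hr.ci_low < hr.hr < hr.ci_high

    def test_delta_ci_close_to_normal_simulation(self, weibull_fit):
        from exacmsm.predict import simulate_normal_ci

        [hr] = pm.transition_hazard_ratios(weibull_fit, [((4, 5), (1, 5))])
        ia = weibull_fit._index((4, 5))
        ib = weibull_fit._index((1, 5))
        lo, hi = simulate_normal_ci(
            weibull_fit, lambda th: np.exp(th[ia] - th[ib]),
            n_samples=2000, seed=42)
        assert float(lo) == pytest.approx(hr.ci_low, rel=0.05)
        assert float(hi) == pytest.approx(hr.ci_high, rel=0.05)


class TestLikelihoodRatioTest:
    def test_identical_models(self, weibull_fit):
        res = pm.likelihood_ratio_test(weibull_fit, weibull_fit)
        assert res == {"statistic": 0.0, "df": 0, "p_value": 1.0}

    def test_nested_effect_detected(self):
        effect = synth.TruthEffect(
            pm.CovariateTerm("fev1_exac", "fev1pp",
                             ev.EXACERBATION_TRANSITIONS,
                             center=45.0, scale=10.0), -0.4)
        cfg = synth.GeneratorConfig(n=2500, seed=31,
                                    covariate_effects=(effect,))
        df = synth.simulate_dataset(cfg)
        nested = pm.fit(df, "weibull")
        full = pm.fit(df, "weibull", (effect.term,))
        res = pm.likelihood_ratio_test(nested, full)
        assert res["df"] == 1
        assert res["p_value"] < 1e-4

    def test_swapped_models_rejected(self, dataset):
        nested = pm.fit(dataset, "exponential")
        full = pm.fit(dataset, "weibull")
        with pytest.raises(ValueError, match="fewer parameters"):
            pm.likelihood_ratio_test(full, nested)


class TestMarkovDiagnostic:
    def test_degenerate_state1_times_rejected(self):
        paths = [
            ev.StatePath(p, [(1, 0.0), (2, 50.0)], "censored", 364.0, 364.0)
            for p in "ABC"
        ]
        df = ev.paths_to_transition_dataset(paths)
        with pytest.raises(ValueError, match="degenerate"):
            pm.markov_diagnostic(df, "exponential")

    def test_returns_hr_per_late_transition(self, dataset):
        diag = pm.markov_diagnostic(dataset, "exponential")
        assert set(diag.transition) <= {"2->3", "2->4", "2->5", "3->4",
                                        "3->5", "4->5"}
        assert (diag.hr_per_year_in_state1 > 0).all()
        assert (diag.ci_low <= diag.hr_per_year_in_state1).all()
        assert (diag.hr_per_year_in_state1 <= diag.ci_high).all()
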