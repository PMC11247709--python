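"""Generator assembly, transition probabilities, panel likelihood, MLE,
hazard ratios, interaction tests and stratified fits."""

import numpy as np
import pytest
from scipy.linalg import expm

from crmsm import (
    DEFAULT_STRUCTURE,
    IntensityModel,
    TransitionStructure,
    build_intensity_matrix,
    crude_initial_values,
    fit_multistate,
    hazard_ratio_table,
    stratified_fit,
    subject_loglik,
    transition_probability,
    wald_interaction,
)
from crmsm.msm import FittedModel, StructureError, _numeric_hessian
from crmsm.panel import Cohort, StateObservation, Subject, TransitionCountTable
from crmsm.simulate import SimulationConfig, generate_cohort

from _oracles import uniformization_probability


def simple_model(beta=None):
    log_q0 = {tr: np.log(0.1) for tr in DEFAULT_STRUCTURE.allowed}
    return IntensityModel(structure=DEFAULT_STRUCTURE, log_q0=log_q0, beta=beta or {})


class TestStructure:
    def test_default_transitions(self):
        assert (3, 4) in DEFAULT_STRUCTURE.allowed
        assert (3, 1) not in DEFAULT_STRUCTURE.allowed
        assert len(DEFAULT_STRUCTURE) == 7

    def test_no_exit_from_death(self):
        with pytest.raises(StructureError):
            TransitionStructure(allowed=((4, 1),))

    def test_death_reachability_enforced(self):
        with pytest.raises(StructureError):
            TransitionStructure(allowed=((1, 2), (2, 1)))  # no path to death at all
        # reduced structures over a state subset are legal
        TransitionStructure(allowed=((1, 4),))
        TransitionStructure(allowed=((1, 2), (2, 1), (2, 4)))


class TestIntensityMatrix:
    def test_zero_beta_returns_baseline(self):
        m = simple_model()
        Q = build_intensity_matrix(m, {"cr": 2.0})
        off = Q[~np.eye(4, dtype=bool)]
        assert np.allclose(off[off != 0], 0.1)

    def test_cr_effect_multiplies_rate(self):
        m = simple_model({(1, 2): {"cr": np.log(0.78)}})
        Q0 = build_intensity_matrix(m, {"cr": 0.0})
        Q1 = build_intensity_matrix(m, {"cr": 1.0})
        assert Q1[0, 1] / Q0[0, 1] == pytest.approx(0.78, abs=1e-12)

    def test_rows_sum_to_zero(self):
        m = simple_model({(2, 4): {"cr": 0.3, "age_c": 0.05}})
        Q = build_intensity_matrix(m, {"cr": -1.3, "age_c": 9.0})
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)

    def test_missing_covariate_named(self):
        m = simple_model({(1, 2): {"cr": 0.1}})
        with pytest.raises(KeyError, match="cr"):
            build_intensity_matrix(m, {})


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        Q = build_intensity_matrix(simple_model())
        assert np.allclose(transition_probability(Q, 0.0), np.eye(4))

    def test_two_state_closed_form(self):
        # single 0.1/year intensity to the absorbing state, 5 years
        Q = np.array([[-0.1, 0.1], [0.0, 0.0]])
        P = transition_probability(Q, 5.0)
        assert P[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(np.zeros((4, 4)), -1.0)

    def test_invalid_generator_rejected(self):
        Q = np.ones((4, 4))
        with pytest.raises(ValueError):
            transition_probability(Q, 1.0)

    def test_rows_stochastic_on_random_generators(self):
        from conftest import random_generator
        rng = np.random.default_rng(11)
        for _ in range(25):
            P = transition_probability(random_generator(rng), rng.uniform(0.1, 10))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() >= 0.0 and P.max() <= 1.0


class TestSubjectLoglik:
    def test_single_interval_is_log_p(self):
        m = simple_model()
        s = Subject("a", [StateObservation(0, 1), StateObservation(4, 2)], {})
        Q = build_intensity_matrix(m, {})
        assert subject_loglik(s, m, {}) == pytest.approx(np.log(expm(Q * 4)[0, 1]))

    def test_death_term_matches_density_of_absorption(self):
        """The exact-death contribution sum_s P_rs(t) q_s4 equals the time
        derivative of the absorption probability P_r4(t) (independent check
        via uniformization and central differences)."""
        m = simple_model()
        Q = build_intensity_matrix(m, {})
        t, h = 3.7, 1e-6
        for r in (1, 2, 3):
            s = Subject("a", [StateObservation(0, r), StateObservation(t, 4, exact=True)], {})
            ll = subject_loglik(s, m, {})
            dPdt = (uniformization_probability(Q, t + h)[r - 1, 3]
                    - uniformization_probability(Q, t - h)[r - 1, 3]) / (2 * h)
            assert ll == pytest.approx(np.log(dPdt), abs=1e-6)

    def test_impossible_pair_is_minus_inf(self):
        m = simple_model()
        s = Subject("a", [StateObservation(0, 3), StateObservation(2, 1)], {})
        assert subject_loglik(s, m, {}) == -np.inf

    def test_time_unit_invariance(self):
        """Scaling all times by c and all intensities by 1/c leaves the
        likelihood unchanged."""
        m = simple_model({(1, 2): {"cr": -0.2}})
        s = Subject("a", [StateObservation(0, 1), StateObservation(3, 2),
                          StateObservation(7.5, 4, exact=True)], {})
        ll = subject_loglik(s, m, {"cr": 1.0})
        c = 12.0
        m2 = IntensityModel(structure=m.structure,
                            log_q0={tr: v - np.log(c) for tr, v in m.log_q0.items()},
                            beta=m.beta)
        s2 = Subject("a", [StateObservation(0, 1), StateObservation(3 * c, 2),
                           StateObservation(7.5 * c, 4, exact=True)], {})
        # an exact death density picks up a Jacobian factor 1/c
        assert subject_loglik(s2, m2, {"cr": 1.0}) == pytest.approx(ll - np.log(c))


class TestCrudeInitialValues:
    def test_rate_is_events_over_person_time(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 30
        table = TransitionCountTable(counts=counts,
                                     person_time=np.array([600.0, 10, 10, 0]))
        init = crude_initial_values(table)
        assert np.exp(init.log_q0[(1, 2)]) == pytest.approx(0.05)

    def test_unobserved_transition_floored(self):
        table = TransitionCountTable(counts=np.zeros((4, 4), dtype=int),
                                     person_time=np.full(4, 100.0))
        init = crude_initial_values(table, floor=1e-4)
        assert np.exp(init.log_q0[(2, 4)]) == pytest.approx(1e-4)


def two_state_death_cohort(rate, n, horizon, seed):
    """Fully observed survival data: death at its exact time or censoring."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        t = rng.exponential(1 / rate)
        if t < horizon:
            obs = [StateObservation(0, 1), StateObservation(t, 4, exact=True)]
        else:
            obs = [StateObservation(0, 1), StateObservation(horizon, 1)]
        subjects.append(Subject(f"s{i}", obs, {}))
    return Cohort(subjects, [])


class TestFit:
    STRUCT_1TO4 = TransitionStructure(allowed=((1, 4),))

    def test_two_state_mle_equals_events_over_person_time(self):
        cohort = two_state_death_cohort(rate=0.1, n=400, horizon=8.0, seed=2)
        events = sum(1 for s in cohort.subjects if s.states[-1] == 4)
        persontime = sum(s.times[-1] for s in cohort.subjects)
        fit = fit_multistate(cohort, structure=self.STRUCT_1TO4)
        assert np.exp(fit.estimates.log_q0[(1, 4)]) == pytest.approx(
            events / persontime, abs=1e-6)

    def test_wald_ci_coverage_two_state(self):
        """95% Wald CIs for the log-intensity cover the truth at about the
        nominal rate (reduced replicate count; binomial 99% band)."""
        rate, cover, reps = 0.12, 0, 120
        for r in range(reps):
            cohort = two_state_death_cohort(rate, n=150, horizon=10.0, seed=100 + r)
            fit = fit_multistate(cohort, structure=self.STRUCT_1TO4)
            est = fit.estimates.log_q0[(1, 4)]
            se = fit.se((1, 4), "log_q0")
            if abs(est - np.log(rate)) < 1.96 * se:
                cover += 1
        # Binomial(120, 0.95): central 99% interval is [107, 119]
        assert 107 <= cover <= 120

    def test_analytic_and_numeric_gradients_agree_at_optimum(self, small_cohort):
        cohort, _ = small_cohort
        f1 = fit_multistate(cohort, covariates=["cr"], compute_covariance=False)
        f2 = fit_multistate(cohort, covariates=["cr"], compute_covariance=False,
                            gradient="numeric")
        for tr in DEFAULT_STRUCTURE.allowed:
            assert f1.estimates.beta[tr]["cr"] == pytest.approx(
                f2.estimates.beta[tr]["cr"], abs=5e-3)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)

    def test_panel_mle_approaches_truth_with_dense_exams(self):
        """Consistency in the dense-observation limit on the full model."""
        import crmsm.simulate as sim
        cfg = SimulationConfig(n=1500, seed=8)
        orig = sim.exam_times
        sim.exam_times = lambda age, horizon: list(np.arange(0.0, horizon + 1e-9, 1.0))
        try:
            cohort, _ = generate_cohort(cfg)
        finally:
            sim.exam_times = orig
        fit = fit_multistate(cohort, covariates=["cr", "age_c", "female"],
                             compute_covariance=False)
        for tr, hr_true in [((1, 2), 0.78), ((2, 4), 0.82)]:
            assert np.exp(fit.estimates.beta[tr]["cr"]) == pytest.approx(hr_true, abs=0.10)

    def test_sparse_transition_covariates_frozen(self, small_cohort):
        cohort, _ = small_cohort
        fit = fit_multistate(cohort, covariates=["cr"], min_covariate_support=10_000,
                             compute_covariance=False)
        assert len(fit.frozen) > 0
        hr = hazard_ratio_table(fit)
        assert hr["frozen"].any()
        assert hr.loc[hr.frozen, "hr"].isna().all()


class TestHazardRatioTable:
    def make_fitted(self, b, se):
        model = IntensityModel(structure=TransitionStructure(allowed=((1, 4),)),
                               log_q0={(1, 4): np.log(0.1)},
                               beta={(1, 4): {"cr": b}})
        cov = np.diag([0.01, se ** 2])
        return FittedModel(estimates=model, covariance=cov,
                           param_names=[((1, 4), "log_q0"), ((1, 4), "cr")],
                           loglik=-1.0, n_subjects=10, n_transitions=5,
                           convergence={"converged": True})

    def test_null_beta_gives_unit_hr(self):
        tab = hazard_ratio_table(self.make_fitted(0.0, 0.2))
        row = tab.iloc[0]
        assert row["hr"] == pytest.approx(1.0)
        assert row["lo"] * row["hi"] == pytest.approx(1.0)  # symmetric about 1

    def test_reproduces_published_interval_arithmetic(self):
        # beta = ln 0.78 with SE back-calculated from a printed 0.72-0.85 CI
        se = np.log(0.85 / 0.72) / (2 * 1.96)
        tab = hazard_ratio_table(self.make_fitted(np.log(0.78), se))
        row = tab.iloc[0]
        assert round(row["hr"], 2) == 0.78
        assert round(row["lo"], 2) == 0.72
        assert round(row["hi"], 2) == 0.85

    def test_ci_width_monotone_in_se(self):
        widths = [hazard_ratio_table(self.make_fitted(0.1, se)).iloc[0]
                  for se in (0.05, 0.1, 0.2)]
        assert widths[0]["hi"] - widths[0]["lo"] < widths[1]["hi"] - widths[1]["lo"] \
            < widths[2]["hi"] - widths[2]["lo"]

    def test_wald_interaction_null_p_one(self):
        fitted = self.make_fitted(0.0, 0.2)
        z, p = wald_interaction(fitted, "cr", (1, 4))
        assert z == 0.0 and p == 1.0


class TestStratifiedFit:
    def test_identical_strata_agree_with_each_other(self):
        cohort, _ = generate_cohort(SimulationConfig(n=400, seed=21))
        # duplicate the cohort into two identical strata
        subjects = []
        for tag, g in (("a", 0.0), ("b", 1.0)):
            for s in cohort.subjects:
                s2 = Subject(tag + s.id, list(s.observations), dict(s.covariates))
                s2.covariates["g"] = g
                subjects.append(s2)
        both = Cohort(subjects, cohort.covariate_names + ["g"])
        fits = stratified_fit(both, "g", covariates=["cr"], compute_covariance=False)
        for tr in DEFAULT_STRUCTURE.allowed:
            assert fits[0.0].estimates.beta[tr].get("cr", 0.0) == pytest.approx(
                fits[1.0].estimates.beta[tr].get("cr", 0.0), abs=1e-4)

    def test_empty_transition_in_stratum_freezes_not_crashes(self):
        # tiny stratum: no dementia->death transitions observed
        subjects = [Subject(f"s{i}", [StateObservation(0, 1), StateObservation(6, 1)],
                            {"g": 0.0, "cr": 0.1 * i}) for i in range(30)]
        subjects += [Subject(f"t{i}", [StateObservation(0, 1), StateObservation(6, 2),
                                       StateObservation(9, 4, exact=True)],
                             {"g": 1.0, "cr": 0.1 * i}) for i in range(30)]
        cohort = Cohort(subjects, ["g", "cr"])
        fits = stratified_fit(cohort, "g", covariates=["cr"], compute_covariance=False)
        frozen_names = [name for _, name in fits[0.0].frozen]
        assert "log_q0" in frozen_names


class TestObservedInformation:
    def test_hessian_matches_finite_difference_of_value(self, toy_cohort):
        from crmsm.msm import _ParameterMap, _PanelLikelihood, _collect_intervals
        design = {tr: ["cr"] for tr in DEFAULT_STRUCTURE.allowed}
        data, _ = _collect_intervals(toy_cohort, ["cr"])
        pmap = _ParameterMap(DEFAULT_STRUCTURE, design, {})
        like = _PanelLikelihood(data, pmap)
        theta = np.full(pmap.n, -1.5)
        H = _numeric_hessian(like, theta)
        # second difference of the value along a random direction
        rng = np.random.default_rng(0)
        v = rng.standard_normal(pmap.n)
        h = 1e-4
        f = lambda t: like.value_and_grad(t)[0]
        second = (f(theta + h * v) - 2 * f(theta) + f(theta - h * v)) / h ** 2
        assert v @ (-H) @ v == pytest.approx(second, rel=1e-3)
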