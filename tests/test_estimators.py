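"""Point estimators: grid-search oracles, full-sample limits, hand arithmetic."""

import numpy as np
import pytest

from nccdesign import (
    BaselineHazard,
    Cohort,
    SimConfig,
    breslow_ipw,
    breslow_lb,
    compute_weights,
    cumulative_hazard,
    fit_conditional,
    fit_conditional_strata,
    fit_cox,
    fit_ipw,
    full_cohort_weights,
    generate_cohort,
    sample_standard,
)
from nccdesign.sampling import NCCSample


def _stratified_loglik(beta, strata):
    ll = 0.0
    for s in strata:
        eta = s[:, 0] * beta
        ll += eta[0] - np.log(np.exp(eta).sum())
    return ll


class TestConditionalFit:
    def test_loglik_at_zero_is_log_stratum_sizes(self, toy_cohort):
        sample = sample_standard(toy_cohort, 2, seed=0)
        strata = [toy_cohort.covariates_of(sample.matched_set(k)) for k in range(3)]
        fit = fit_conditional_strata(strata, init=None, max_iter=1, tol=1e12)
        # tol set huge so the fit stops at beta = 0 immediately
        assert fit.loglik == pytest.approx(-3 * np.log(3))

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(21)
        strata = [rng.normal(size=(4, 1)) + np.array([[0.8], [0], [0], [0]]) for _ in range(3)]
        fit = fit_conditional_strata(strata)
        grid = np.linspace(fit.beta[0] - 0.5, fit.beta[0] + 0.5, 2001)
        lls = [_stratified_loglik(b, strata) for b in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(fit.beta[0], abs=1e-3)
        assert fit.loglik >= max(lls) - 1e-10

    def test_non_identifiable_direction_stays_at_init(self):
        # case covariate equals every control's: score identically zero
        strata = [np.array([[1.0], [1.0], [1.0]]), np.array([[0.3], [0.3]])]
        fit = fit_conditional_strata(strata, init=[0.7])
        assert fit.beta[0] == 0.7
        assert fit.score_norm < 1e-8

    def test_invariance_to_within_stratum_shift(self):
        rng = np.random.default_rng(3)
        strata = [rng.normal(size=(3, 2)) for _ in range(4)]
        shifted = [s + rng.normal(size=(1, 2)) for s in strata]
        f1 = fit_conditional_strata(strata)
        f2 = fit_conditional_strata(shifted)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-7)

    def test_invariance_to_control_relabeling(self):
        rng = np.random.default_rng(4)
        strata = [rng.normal(size=(4, 1)) for _ in range(5)]
        permuted = [np.vstack([s[:1], s[1:][::-1]]) for s in strata]
        np.testing.assert_allclose(
            fit_conditional_strata(strata).beta, fit_conditional_strata(permuted).beta, atol=1e-9
        )

    def test_missing_covariate_is_hard_error(self, toy_cohort):
        sample = sample_standard(toy_cohort, 2, seed=0)
        toy_cohort.covariates[toy_cohort.index_of([sample.matched_controls[0][0]])[0], 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_conditional(toy_cohort, sample)


class TestIPWFit:
    def test_full_cohort_reduction_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        sim = generate_cohort(SimConfig(n=600, seed=31))
        fit = fit_cox(sim.cohort)
        frame = sim.cohort.to_frame()[["exit", "event", "z1", "z2"]]
        cph = lifelines.CoxPHFitter()
        cph.fit(frame, "exit", "event")
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=5e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov)), cph.standard_errors_.values, rtol=1e-4
        )

    def test_single_case_time_equals_conditional(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(6, 2))
        coh = Cohort(range(6), [0.0] * 6, [1.0] + [2.0] * 5, [1] + [0] * 5, Z)
        ipw = fit_cox(coh)  # one stratum, everyone at risk, unit weights
        cond = fit_conditional_strata([Z])
        np.testing.assert_allclose(ipw.beta, cond.beta, atol=1e-8)

    def test_score_zero_at_convergence(self, toy_cohort):
        sample = sample_standard(toy_cohort, 2, seed=0)
        w = compute_weights(toy_cohort, sample)
        fit = fit_ipw(toy_cohort, sample, w)
        assert fit.score_norm < 1e-8

    def test_left_truncation_risk_sets(self, truncated_cohort):
        # the fit must run with delayed entry and use entry < t <= exit risk sets
        fit = fit_cox(truncated_cohort)
        # S0 at the second case time counts subjects 2..8 and the case (9)
        assert fit.S0 is not None and fit.S0.shape == (3,)
        assert fit.converged


class TestBreslowEstimators:
    def test_lb_at_beta_zero_recovers_nelson_aalen(self, toy_cohort):
        sample = sample_standard(toy_cohort, 2, seed=0)
        bh = breslow_lb(toy_cohort, sample, [0.0, 0.0])
        # |R(t1)| = 10, |R~| = 3: increment = 1/(10/3 * 3) = 1/10
        assert bh.increments[0] == pytest.approx(1 / 10)
        assert bh.increments[1] == pytest.approx(1 / 7)
        assert bh.increments[2] == pytest.approx(1 / 5)

    def test_ipw_full_cohort_at_beta_zero(self, toy_cohort):
        coh = Cohort(
            toy_cohort.ids, toy_cohort.entry, toy_cohort.exit, toy_cohort.event,
            np.zeros((10, 1)),
        )
        fit = fit_cox(coh, max_iter=1, tol=1e12)  # beta pinned at 0
        bh = breslow_ipw(fit)
        np.testing.assert_allclose(bh.increments, [1 / 10, 1 / 7, 1 / 5])

    def test_ipw_increment_matches_hand_arithmetic(self):
        # 5 subjects, one case at t=1; S0 = sum of w e^{bz} over at-risk
        Z = np.array([[0.0], [1.0], [-1.0], [0.5], [2.0]])
        coh = Cohort(range(5), [0.0] * 5, [1.0, 2.0, 3.0, 0.5, 4.0], [1, 0, 0, 0, 0], Z)
        sample = sample_standard(coh, 3, seed=0)  # pool {1,2,4}; takes all 3
        w = compute_weights(coh, sample)
        beta = np.array([0.3])
        fit = fit_ipw(coh, sample, w, init=beta, max_iter=1, tol=1e12)
        bh = breslow_ipw(fit)
        s0_hand = sum(
            wi * np.exp(0.3 * z)
            for wi, z in zip(w.weights, Z[[0, 1, 2, 4], 0])
        )
        assert bh.increments[0] == pytest.approx(1.0 / s0_hand)

    def test_ipw_solves_estimating_equation_exactly(self, toy_cohort):
        sample = sample_standard(toy_cohort, 2, seed=1)
        w = compute_weights(toy_cohort, sample)
        fit = fit_ipw(toy_cohort, sample, w)
        bh = breslow_ipw(fit)
        idx = toy_cohort.index_of(w.subject_ids)
        Z = toy_cohort.covariates[idx]
        for k, t_k in enumerate(fit.case_times):
            at_risk = (toy_cohort.entry[idx] < t_k) & (t_k <= toy_cohort.exit[idx])
            own = (toy_cohort.exit[idx] == t_k) & (toy_cohort.event[idx] == 1)
            resid = np.sum(
                w.weights[at_risk]
                * (own[at_risk] - bh.increments[k] * np.exp(Z[at_risk] @ fit.beta))
            )
            assert resid == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def limit():
    sim = generate_cohort(SimConfig(n=80, lambda0=0.05, seed=13))
    coh = sim.cohort
    sample = sample_standard(coh, coh.n, seed=0)  # m >= every pool size
    return coh, sample


class TestFullSampleLimit:
    """With every at-risk non-case sampled and unit weights, all four NCC
    estimators collapse onto the full-cohort Cox / Breslow estimates."""

    def test_sample_is_everyone_at_risk(self, limit):
        coh, sample = limit
        for k in range(sample.n_case_times):
            assert len(sample.matched_set(k)) == coh.risk_set_size(sample.case_times[k])

    def test_conditional_equals_full_cox(self, limit):
        coh, sample = limit
        full = fit_cox(coh)
        cond = fit_conditional(coh, sample)
        np.testing.assert_allclose(cond.beta, full.beta, atol=1e-8)

    def test_ipw_equals_full_cox(self, limit):
        coh, sample = limit
        full = fit_cox(coh)
        w = compute_weights(coh, sample)
        np.testing.assert_allclose(w.weights, 1.0)
        ipw = fit_ipw(coh, sample, w)
        np.testing.assert_allclose(ipw.beta, full.beta, atol=1e-8)

    def test_breslow_estimators_coincide(self, limit):
        coh, sample = limit
        full = fit_cox(coh)
        lb = breslow_lb(coh, sample, full.beta)
        ipw = breslow_ipw(full)
        np.testing.assert_allclose(lb.increments, ipw.increments, atol=1e-10)


class TestCumulativeHazard:
    def test_whole_line_sums_everything(self):
        bh = BaselineHazard(np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.2, 0.3]))
        assert cumulative_hazard(bh) == pytest.approx(0.6)

    def test_interval_additivity(self):
        bh = BaselineHazard(np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.2, 0.3]))
        assert cumulative_hazard(bh, 0, 1.5) + cumulative_hazard(bh, 1.5, 9) == pytest.approx(
            cumulative_hazard(bh, 0, 9)
        )

    def test_half_open_convention(self):
        bh = BaselineHazard(np.array([1.0, 2.0]), np.array([0.1, 0.2]))
        assert cumulative_hazard(bh, 1.0, 2.0) == pytest.approx(0.2)  # (tau0, tau1]

    def test_simulated_full_cohort_recovers_generative_truth(self):
        # E Lambda0(10) = -log(0.95) under the generative model
        vals = []
        for seed in range(25):
            sim = generate_cohort(SimConfig(n=3000, seed=100 + seed))
            fit = fit_cox(sim.cohort)
            vals.append(breslow_ipw(fit).cumulative(0, 10))
        assert np.mean(vals) == pytest.approx(-np.log(0.95), rel=0.05)
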