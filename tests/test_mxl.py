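"""Mixed logit machinery: probabilities, draws, simulated likelihood, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcewtp import (
    MXLParams,
    MXLSpec,
    PopulationTruth,
    choice_probability,
    conditional_logit_loglik,
    draw_respondents,
    estimate_mxl,
    fit_conditional_logit,
    generate_study,
    make_draws,
    preference_to_wtp,
    simulated_loglik,
    wtp_to_preference,
)
from dcewtp.mxl import _pack, _panel_loglik, _unpack


class TestChoiceProbability:
    def test_symmetric_utilities(self):
        assert np.allclose(choice_probability([0.0, 0.0]), [0.5, 0.5])

    def test_binary_logit_closed_form(self):
        # alpha=1, beta=0, costs 1.25 vs 5.00 EUR: v = (-1.25, -5.00)
        p = choice_probability([-1.25, -5.00])
        assert p[0] == pytest.approx(1 / (1 + np.exp(-3.75)), abs=5e-5)
        assert np.round(p, 4).tolist() == [0.9770, 0.0230]

    def test_no_overflow_for_extreme_utilities(self):
        p = choice_probability([1000.0, 0.0])
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(1.0)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6),
           st.floats(-100, 100))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_normalized_and_shift_invariant(self, v, shift):
        p = choice_probability(v)
        assert abs(p.sum() - 1) < 1e-12
        assert np.all(p > 0)
        assert np.allclose(p, choice_probability(np.asarray(v) + shift), atol=1e-12)

    def test_raising_cost_lowers_probability(self):
        alpha, beta = 1.3, np.zeros(7)
        x = np.zeros((2, 7))
        for c_hi in (2.5, 3.75, 5.0):
            v_lo = alpha * (x @ beta - np.array([1.25, 2.5]))
            v_hi = alpha * (x @ beta - np.array([c_hi, 2.5]))
            assert choice_probability(v_hi)[0] < choice_probability(v_lo)[0]


class TestMakeDraws:
    def test_deterministic_blocks_that_differ_across_respondents(self):
        spec = MXLSpec(n_draws=128, scramble_seed=11)
        d1 = make_draws(spec, 4)
        d2 = make_draws(spec, 4)
        assert np.array_equal(d1, d2)
        assert d1.shape == (4, 128, 8)
        for i in range(3):
            assert not np.array_equal(d1[i], d1[i + 1])

    def test_quasi_random_deviates_are_standard_normal(self):
        spec = MXLSpec(n_draws=4096, scramble_seed=3)
        z = make_draws(spec, 1)[0]
        assert np.all(np.abs(z.mean(axis=0)) < 0.01)
        assert np.all((z.var(axis=0) > 0.95) & (z.var(axis=0) < 1.05))

    def test_pseudo_random_scheme_available(self):
        spec = MXLSpec(n_draws=64, draw_scheme="pseudo_random", scramble_seed=5)
        z = make_draws(spec, 2)
        assert z.shape == (2, 64, 8)


@pytest.fixture(scope="module")
def small_chronic():
    ds = generate_study(n_respondents=12, tasks_per_scenario=3, seed=21)
    return ds.subset("chronic")


class TestSimulatedLoglik:
    def test_degenerate_mixing_equals_analytic_conditional_logit(self, small_chronic):
        params = MXLParams(np.linspace(-2, 2, 7), np.zeros(7), 0.4, 0.0)
        coef = np.append(np.exp(0.4) * params.wtp_mean, -np.exp(0.4))
        analytic = conditional_logit_loglik(small_chronic, coef)
        for D in (1, 7, 50):
            draws = make_draws(MXLSpec(n_draws=D, scramble_seed=1),
                               small_chronic.n_respondents)
            sim = simulated_loglik(small_chronic, params, draws)
            assert sim == pytest.approx(analytic, abs=1e-10)

    def test_single_task_single_draw_is_log_probability(self, scheme):
        truth = PopulationTruth(np.zeros(7), np.zeros(7), 0.0, 0.0)
        resp = draw_respondents(truth, 1, seed=0)
        from dcewtp import ChoiceProfile, ChoiceTask, simulate_choices

        a = ChoiceProfile("round_tablet", "small", "white", 5)
        b = ChoiceProfile("round_tablet", "small", "white", 20)
        ds = simulate_choices([ChoiceTask("chronic", 1, (a, b))], resp, scheme, seed=3)
        params = MXLParams(np.zeros(7), np.zeros(7), 0.0, 0.0)
        draws = make_draws(MXLSpec(n_draws=1, scramble_seed=1), 1)
        ll = simulated_loglik(ds, params, draws)
        chose_cheap = ds.df.loc[ds.df["chosen"] == 1, "copay_pln"].iloc[0] == 5
        p_cheap = 1 / (1 + np.exp(-3.75))
        assert ll == pytest.approx(np.log(p_cheap if chose_cheap else 1 - p_cheap))

    def test_analytic_gradient_matches_finite_differences(self, small_chronic):
        from scipy.optimize import approx_fprime

        groups = small_chronic.to_panel()
        ridx = np.arange(7)
        draws = make_draws(MXLSpec(n_draws=32, scramble_seed=9),
                           small_chronic.n_respondents)
        theta = _pack(np.linspace(-1, 1, 7), np.full(7, 0.6), 0.1, 0.4)

        def f(th):
            ll, _ = _panel_loglik(groups, draws, _unpack(th, 7, ridx), ridx)
            return ll

        _, grad = _panel_loglik(groups, draws, _unpack(theta, 7, ridx), ridx,
                                want_grad=True)
        numeric = approx_fprime(theta, f, 1e-6)
        assert np.max(np.abs(grad - numeric) / (1 + np.abs(numeric))) < 1e-5

    def test_invariant_to_row_permutation(self, small_chronic):
        from dcewtp.design import ChoiceDataset

        params = MXLParams(np.linspace(-1, 1, 7), np.full(7, 0.5), 0.0, 0.3)
        draws = make_draws(MXLSpec(n_draws=64, scramble_seed=2),
                           small_chronic.n_respondents)
        ll = simulated_loglik(small_chronic, params, draws)
        shuffled = ChoiceDataset(
            small_chronic.df.sample(frac=1, random_state=5),
            small_chronic.scheme, validate=False,
        )
        assert simulated_loglik(shuffled, params, draws) == pytest.approx(ll, abs=1e-9)

    def test_sobol_agrees_with_gauss_hermite_and_pseudo_random(
        self, tiny_dataset, gh_oracle
    ):
        params = MXLParams(
            np.array([0.4, 0.9, -2.0, -4.0, 0.5, -0.5, -1.0]),
            np.array([0.0, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0]),
            scale_mu=0.0, scale_sigma=0.0,
        )
        exact = gh_oracle(tiny_dataset, params, "capsule")
        N = tiny_dataset.n_respondents
        spec_qmc = MXLSpec(random_attrs=("capsule",), n_draws=10_000, scramble_seed=7)
        sobol = simulated_loglik(tiny_dataset, params, make_draws(spec_qmc, N),
                                 random_attrs=("capsule",))
        assert sobol == pytest.approx(exact, abs=1e-3)
        spec_mc = MXLSpec(random_attrs=("capsule",), n_draws=1_000_000,
                          draw_scheme="pseudo_random", scramble_seed=8)
        mc = simulated_loglik(tiny_dataset, params, make_draws(spec_mc, N),
                              random_attrs=("capsule",))
        assert mc == pytest.approx(exact, abs=1e-3)


class TestConditionalLogit:
    def test_matches_independent_direct_maximization(self):
        ds = generate_study(
            n_respondents=60, tasks_per_scenario=4,
            truth_chronic=PopulationTruth(
                np.array([0.5, 1.0, -1.0, -2.0, 0.5, -0.5, -1.0]),
                np.zeros(7), 0.0, 0.0),
            seed=13,
        ).subset("chronic")
        fit = fit_conditional_logit(ds)
        # oracle: generic optimizer on the analytic likelihood, no statsmodels
        from scipy.optimize import minimize

        res = minimize(lambda c: -conditional_logit_loglik(ds, c), np.zeros(8),
                       method="BFGS")
        assert np.allclose(fit.coef, res.x, atol=1e-4)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert fit.converged

    def test_recovers_fixed_coefficients_within_ci(self):
        truth_b = np.array([0.5, 1.0, -2.5, -5.0, 0.7, -0.6, -1.1])
        ds = generate_study(
            n_respondents=600, tasks_per_scenario=8,
            truth_chronic=PopulationTruth(truth_b, np.zeros(7), 0.0, 0.0),
            seed=17,
        ).subset("chronic")
        fit = fit_conditional_logit(ds)
        beta_hat, alpha_hat = preference_to_wtp(fit.coef[:-1], fit.coef[-1])
        # truth: alpha = 1, WTP = truth_b; delta-method-free sanity bound
        assert np.all(np.abs(beta_hat - truth_b) < 4 * fit.se[:-1] / alpha_hat + 0.05)
        assert alpha_hat == pytest.approx(1.0, abs=0.15)

    def test_invariant_attribute_rejected(self, scheme):
        from dcewtp import ChoiceProfile, ChoiceTask, simulate_choices

        resp = draw_respondents(
            PopulationTruth(np.zeros(7), np.zeros(7), 0.0, 0.0), 30, seed=1)
        a = ChoiceProfile("round_tablet", "small", "white", 5)
        b = ChoiceProfile("round_tablet", "small", "white", 20)
        ds = simulate_choices(
            [ChoiceTask("chronic", t + 1, (a, b)) for t in range(4)],
            resp, scheme, seed=2)
        with pytest.raises(ValueError, match="singular|variation"):
            fit_conditional_logit(ds)

    def test_mxl_with_no_random_contrasts_nests_conditional_logit(self, small_chronic):
        cl = fit_conditional_logit(small_chronic)
        est = estimate_mxl(small_chronic, MXLSpec(random_attrs=(), n_draws=2,
                                                  scramble_seed=1))
        assert est.loglik == pytest.approx(cl.loglik, abs=1e-6)
        assert np.all(est.wtp_sd == 0)
        assert est.scale_sigma == 0


class TestWtpSpaceTranslation:
    def test_direct_division_example(self):
        beta, alpha = preference_to_wtp(np.array([2.0, -1.0]), -2.0)
        assert alpha == 2.0
        assert np.allclose(beta, [1.0, -0.5])

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=8),
           st.floats(-10, -0.01))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_roundtrip_identity(self, b, a):
        b = np.asarray(b)
        beta, alpha = preference_to_wtp(b, a)
        b2, a2 = wtp_to_preference(beta, alpha)
        assert np.allclose(b2, b, rtol=1e-12) and a2 == pytest.approx(a, rel=1e-12)

    def test_nonnegative_cost_coefficient_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            preference_to_wtp(np.ones(3), 0.5)

    def test_parameterizations_are_behaviorally_equivalent(self, small_chronic):
        b = np.array([0.5, 1.0, -2.0, -4.0, 0.6, -0.5, -1.0])
        a = -1.7
        analytic = conditional_logit_loglik(small_chronic, np.append(b, a))
        beta, alpha = preference_to_wtp(b, a)
        params = MXLParams(beta, np.zeros(7), np.log(alpha), 0.0)
        draws = make_draws(MXLSpec(n_draws=3, scramble_seed=1),
                           small_chronic.n_respondents)
        assert simulated_loglik(small_chronic, params, draws) == pytest.approx(
            analytic, abs=1e-10)


class TestEstimateMXL:
    def test_zero_heterogeneity_data_recovers_near_zero_sds(self):
        truth = PopulationTruth(
            np.array([0.5, 1.0, -2.5, -5.0, 0.7, -0.6, -1.1]),
            np.zeros(7), 0.0, 0.0)
        ds = generate_study(n_respondents=300, tasks_per_scenario=8,
                            truth_chronic=truth, seed=23).subset("chronic")
        est = estimate_mxl(ds, MXLSpec(n_draws=200, scramble_seed=3))
        assert est.converged
        assert est.loglik >= est.start_loglik - 1e-9
        se = np.where(np.isfinite(est.wtp_mean_se), est.wtp_mean_se, 0.5)
        assert np.all(np.abs(est.wtp_mean - truth.wtp_mean) < 4 * se + 0.1)
        # no real heterogeneity to find: the mixing terms barely improve on
        # the nested conditional logit and stay small on the EUR scale
        cl = fit_conditional_logit(ds)
        assert 2 * (est.loglik - cl.loglik) < 20
        assert np.all(est.wtp_sd < 1.0)

    def test_estimates_invariant_to_respondent_relabeling(self, small_chronic):
        spec = MXLSpec(n_draws=100, scramble_seed=4, maxiter=200)
        est1 = estimate_mxl(small_chronic, spec)
        relabeled = small_chronic.df.copy()
        # reverse ids; sorted-id draw alignment keeps the fit identical only
        # up to which block each respondent receives, so relabel monotonically
        relabeled["respondent_id"] = relabeled["respondent_id"] + 1000
        from dcewtp.design import ChoiceDataset

        est2 = estimate_mxl(
            ChoiceDataset(relabeled, small_chronic.scheme, validate=False), spec)
        assert est2.loglik == pytest.approx(est1.loglik, abs=1e-9)
        assert np.allclose(est2.wtp_mean, est1.wtp_mean, atol=1e-6)

    def test_estimate_json_roundtrip(self, tmp_path, small_chronic):
        from dcewtp.mxl import MXLEstimate

        est = estimate_mxl(small_chronic, MXLSpec(n_draws=50, scramble_seed=5))
        path = tmp_path / "est.json"
        est.to_json(path)
        back = MXLEstimate.from_json(path)
        assert np.allclose(back.wtp_mean, est.wtp_mean)
        assert back.loglik == pytest.approx(est.loglik)
        assert back.contrasts == est.contrasts
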