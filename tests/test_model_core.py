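import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist

from socialbayes.exceptions import ConfigurationError, DomainError
from socialbayes.model_core import (
    AgentParams,
    EUPair,
    VARIANTS,
    choice_probability,
    expected_utilities,
    get_variant,
    observations_from_frame,
    pointwise_loglik_core,
    predict_choice_probabilities,
    prior_belief,
    social_update,
    trial_loglik,
    utility,
)
from socialbayes.task_design import LotteryTrial


def make_trial(value=50.0, p=0.5, condition="description", social="none", block="solo"):
    return LotteryTrial(
        trial_id=0, block=block, condition=condition, social=social,
        value_risky=value, p_win=p, safe_value=5.0,
    )


class TestUtility:
    @pytest.mark.parametrize(
        "value,rho,expected", [(5, 1, 5.0), (50, 0.5, 7.0711), (0, 0.7, 0.0)]
    )
    def test_values(self, value, rho, expected):
        assert utility(value, rho) == pytest.approx(expected, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            utility(-1.0, 1.0)
        with pytest.raises(DomainError):
            utility(5.0, 0.0)


class TestPriorBelief:
    def test_pseudocounts(self):
        s = prior_belief(0.5, 2)
        assert (s.alpha, s.beta, s.p_prior) == (1.0, 1.0, 0.5)
        s = prior_belief(0.75, 20)
        assert (s.alpha, s.beta) == (15.0, 5.0)

    def test_mean_invariant_to_rate(self):
        assert prior_belief(0.5, 20).p_prior == prior_belief(0.5, 2).p_prior == 0.5

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_boundary_rejected(self, p):
        with pytest.raises(DomainError):
            prior_belief(p, 2)


class TestSocialUpdate:
    def test_ideal_bayesian_hand_values(self):
        # kappa=2: one pseudo-marble per colour; risky advice adds one more
        assert social_update(prior_belief(0.5, 2), "risky", psi_risky=1.0) == pytest.approx(
            2 / 3, abs=1e-4
        )
        # kappa=20 shifts far less
        assert social_update(prior_belief(0.5, 20), "risky", psi_risky=1.0) == pytest.approx(
            11 / 21, abs=1e-4
        )

    def test_zero_sensitivity_ignores_advice(self):
        for advice in ("safe", "risky", "none"):
            s = prior_belief(0.3, 7.5)
            assert social_update(s, advice, 0.0, 0.0) == s.p_prior

    def test_direction_of_shift(self):
        up = social_update(prior_belief(0.4, 4), "risky", psi_safe=2.0, psi_risky=2.0)
        down = social_update(prior_belief(0.4, 4), "safe", psi_safe=2.0, psi_risky=2.0)
        assert down < 0.4 < up

    def test_monotone_in_weights(self):
        shifts = [
            social_update(prior_belief(0.5, 4), "risky", psi_risky=w) for w in (0.5, 1, 2, 4)
        ]
        assert np.all(np.diff(shifts) > 0)
        shifts = [
            social_update(prior_belief(0.5, 4), "safe", psi_safe=w) for w in (0.5, 1, 2, 4)
        ]
        assert np.all(np.diff(shifts) < 0)

    def test_unknown_level_rejected(self):
        with pytest.raises(ConfigurationError):
            social_update(prior_belief(0.5, 2), "both")

    @pytest.mark.parametrize("advice", ["risky", "safe"])
    def test_matches_integrated_beta_posterior_mean(self, advice):
        """Oracle: p' equals the numerically integrated mean of the updated beta."""
        for p in (0.125, 0.375, 0.625):
            for kappa in (0.8, 2.0, 20.0):
                for psi in (0.0, 1.0, 3.7):
                    s = prior_belief(p, kappa)
                    p_post = social_update(s, advice, psi_safe=psi, psi_risky=psi)
                    a = s.alpha + (psi if advice == "risky" else 0.0)
                    b = s.beta + (psi if advice == "safe" else 0.0)
                    # E[X] = integral of the survival function: smooth even
                    # when the density diverges at the endpoints
                    mean, _ = integrate.quad(
                        lambda x: beta_dist.sf(x, a, b), 0, 1, epsabs=1e-13, limit=200
                    )
                    assert p_post == pytest.approx(mean, abs=1e-10)

    def test_susceptibility_monotonicity(self):
        # |p' - p| strictly decreases in kappa, strictly increases in psi
        kappas = np.array([1, 2, 5, 10, 30], dtype=float)
        shift_k = [
            abs(social_update(prior_belief(0.5, k), "risky", psi_risky=2.0) - 0.5)
            for k in kappas
        ]
        assert np.all(np.diff(shift_k) < 0)
        psis = np.array([0.5, 1, 2, 5], dtype=float)
        shift_p = [
            abs(social_update(prior_belief(0.5, 4), "risky", psi_risky=w) - 0.5)
            for w in psis
        ]
        assert np.all(np.diff(shift_p) > 0)


class TestChoiceRule:
    def test_indifference(self):
        assert choice_probability(EUPair(3.3, 3.3), tau=0.7) == 0.5

    def test_logistic_unit(self):
        assert choice_probability(EUPair(1.0, 0.0), tau=1.0) == pytest.approx(0.7311, abs=1e-4)

    def test_high_temperature_limit(self):
        assert choice_probability(EUPair(1.0, 0.0), tau=1000.0) == pytest.approx(0.5, abs=1e-3)

    def test_invalid_temperature(self):
        with pytest.raises(DomainError):
            choice_probability(EUPair(1.0, 0.0), tau=0.0)

    @given(
        eu_r=st.floats(0, 10), eu_s=st.floats(0, 10),
        tau=st.floats(0.5, 100),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_probability_bounds_and_symmetry(self, eu_r, eu_s, tau):
        cp = choice_probability(EUPair(eu_r, eu_s), tau)
        assert 0.0 < cp < 1.0
        if eu_r == eu_s:
            assert cp == 0.5
        elif abs(eu_r - eu_s) / tau > 1e-12:  # below float resolution cp rounds to 0.5
            assert (cp > 0.5) == (eu_r > eu_s)


class TestExpectedUtilities:
    def test_equal_expected_values(self):
        eus = expected_utilities(make_trial(value=8.0, p=0.625), AgentParams(rho=1.0))
        assert eus.eu_risk == pytest.approx(5.0) and eus.eu_safe == pytest.approx(5.0)

    def test_composition_with_advice(self):
        trial = make_trial(value=50.0, p=0.5, social="risky", block="social")
        params = AgentParams(rho=1.0, kappa_desc=2.0, kappa_exp=2.0, psi_safe=1.0, psi_risky=1.0)
        eus = expected_utilities(trial, params)
        assert eus.eu_risk == pytest.approx(2 / 3 * 50, abs=0.01)

    def test_condition_selects_kappa(self):
        params = AgentParams(kappa_desc=2.0, kappa_exp=30.0, psi_risky=1.0, psi_safe=1.0)
        t_desc = make_trial(social="risky", condition="description", block="social")
        t_exp = make_trial(social="risky", condition="experience", block="social")
        assert expected_utilities(t_desc, params).eu_risk > expected_utilities(t_exp, params).eu_risk

    def test_zero_psi_reduces_to_solo(self, resolved_design_frame):
        params = AgentParams(rho=0.9, kappa_desc=4.0, kappa_exp=2.0, tau=2.0)
        cp_social = predict_choice_probabilities(resolved_design_frame, params)
        solo = resolved_design_frame.assign(social="none")
        cp_solo = predict_choice_probabilities(solo, params)
        np.testing.assert_array_equal(cp_social, cp_solo)


class TestTrialLoglik:
    def test_half_probability(self):
        trial = make_trial(value=8.0, p=0.625)
        params = AgentParams(rho=1.0, tau=1.0)
        for choice in (0, 1):
            assert trial_loglik(trial, choice, params) == pytest.approx(np.log(0.5))

    def test_total_over_constant_design(self):
        # 144 trials at cp = 0.5 sum to 144 * ln 0.5
        trial = make_trial(value=8.0, p=0.625)
        total = sum(trial_loglik(trial, 1, AgentParams()) for _ in range(144))
        assert total == pytest.approx(144 * np.log(0.5), abs=1e-6)

    def test_unknown_variant(self):
        with pytest.raises(ConfigurationError):
            trial_loglik(make_trial(), 1, AgentParams(), variant="m99")

    def test_invalid_choice(self):
        with pytest.raises(DomainError):
            trial_loglik(make_trial(), 2, AgentParams())

    def test_scalar_and_vector_paths_agree(self, resolved_design_frame):
        params = AgentParams(rho=0.9, kappa_desc=3.0, kappa_exp=6.0,
                             psi_safe=1.5, psi_risky=0.5, tau=1.7)
        df = resolved_design_frame.assign(
            choice=(np.arange(len(resolved_design_frame)) % 2)
        )
        obs = observations_from_frame(df)
        vec = pointwise_loglik_core(
            obs, params.rho, params.kappa_desc, params.kappa_exp,
            params.psi_safe, params.psi_risky, params.tau,
        )
        from socialbayes.task_design import frame_to_design

        trials = frame_to_design(df.drop(columns=["choice"]))
        scal = [trial_loglik(t, int(c), params) for t, c in zip(trials, df["choice"])]
        np.testing.assert_allclose(vec, scal, atol=1e-8)


class TestVariantNesting:
    def test_registry_contents(self):
        assert set(VARIANTS) == {"m0", "m1", "m2", "m2s"}
        with pytest.raises(ConfigurationError):
            get_variant("m7")

    def test_psi_zero_matches_m0_bitwise(self, resolved_design_frame):
        params = AgentParams(rho=1.1, kappa_desc=3.0, kappa_exp=7.0, tau=2.0,
                             psi_safe=0.0, psi_risky=0.0)
        cp2 = predict_choice_probabilities(resolved_design_frame, params, "m2")
        cp0 = predict_choice_probabilities(resolved_design_frame, params, "m0")
        assert (cp2 == cp0).all()

    def test_psi_one_matches_m1_bitwise(self, resolved_design_frame):
        params = AgentParams(rho=1.1, kappa_desc=3.0, kappa_exp=7.0, tau=2.0,
                             psi_safe=1.0, psi_risky=1.0)
        cp2 = predict_choice_probabilities(resolved_design_frame, params, "m2")
        cp1 = predict_choice_probabilities(resolved_design_frame, params, "m1")
        assert (cp2 == cp1).all()

    def test_m2s_ties_weights(self, resolved_design_frame):
        params = AgentParams(psi_safe=2.5, psi_risky=0.1, kappa_desc=3, kappa_exp=3)
        tied = AgentParams(psi_safe=2.5, psi_risky=2.5, kappa_desc=3, kappa_exp=3)
        cps = predict_choice_probabilities(resolved_design_frame, params, "m2s")
        cp2 = predict_choice_probabilities(resolved_design_frame, tied, "m2")
        assert (cps == cp2).all()

    def test_kappa_not_identified_on_solo_trials(self, default_design_frame):
        # gradient of the solo-half log-likelihood w.r.t. kappa is zero
        solo = default_design_frame.query("block == 'solo'").assign(choice=1)
        obs = observations_from_frame(solo)

        def total(kappa):
            return pointwise_loglik_core(obs, 1.0, kappa, kappa, 1.0, 1.0, 2.0).sum()

        grad = (total(4.0 + 1e-5) - total(4.0 - 1e-5)) / 2e-5
        assert grad == pytest.approx(0.0, abs=1e-8)

    @given(
        p=st.floats(0.05, 0.95), kappa=st.floats(0.2, 50), psi=st.floats(0, 20),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_posterior_mean_stays_in_unit_interval(self, p, kappa, psi):
        s = prior_belief(p, kappa)
        for advice in ("risky", "safe", "none"):
            q = social_update(s, advice, psi_safe=psi, psi_risky=psi)
            assert 0.0 < q < 1.0
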