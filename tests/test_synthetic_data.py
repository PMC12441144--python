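import math

import numpy as np
import pandas as pd
import pytest

from socialbayes.exceptions import ConfigurationError, MatchingError, StateError
from socialbayes.model_core import AgentParams
from socialbayes.synthetic_data import (
    CHOICES_COLUMNS,
    SUBJECTS_COLUMNS,
    AdvisorPool,
    AdvisorProfile,
    AgeTrendConfig,
    ParamTrend,
    advice_labels,
    build_advisor_pool,
    match_advisor,
    simulate_choices,
    simulate_dataset,
    simulate_population,
    standardized_age_polynomials,
)
from socialbayes.task_design import DesignConfig, build_design, design_to_frame


def flat_age_model(**overrides):
    trends = {
        name: ParamTrend(math.log(v))
        for name, v in dict(
            rho=1.0, kappa_desc=4.0, kappa_exp=4.0, psi_safe=1.0, psi_risky=1.0, tau=1.0
        ).items()
    }
    trends.update(overrides)
    return AgeTrendConfig(trends=trends)


class TestPopulation:
    def test_standardization_invariants(self):
        pop = simulate_population(166, seed=0)
        assert abs(pop["age_lin"].mean()) < 1e-8
        assert abs(pop["age_lin"].std(ddof=0) - 0.5) < 1e-8
        assert abs(pop["age_quad"].mean()) < 1e-8
        assert abs(pop["age_quad"].std(ddof=0) - 0.5) < 1e-8
        assert pop["age"].between(10, 26).all()

    def test_default_age_trends_signs(self):
        pop = simulate_population(166, seed=1)
        assert np.corrcoef(pop["age"], np.log(pop["kappa_exp"]))[0, 1] > 0
        assert np.corrcoef(pop["age"], np.log(pop["psi_safe"]))[0, 1] < 0
        assert np.corrcoef(pop["age"], np.log(pop["psi_risky"]))[0, 1] < 0
        assert np.corrcoef(pop["age"], np.log(pop["tau"]))[0, 1] < 0
        # description-kappa flat: correlation small
        assert abs(np.corrcoef(pop["age"], np.log(pop["kappa_desc"]))[0, 1]) < 0.2

    def test_zero_slopes_zero_dispersion_identical(self):
        pop = simulate_population(20, flat_age_model(), seed=0)
        for name in ("rho", "kappa_desc", "psi_safe", "tau"):
            assert pop[name].nunique() == 1

    def test_seed_reproducibility(self):
        pd.testing.assert_frame_equal(
            simulate_population(30, seed=5), simulate_population(30, seed=5)
        )

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            ParamTrend(0.0, sd=-0.1)

    def test_constant_ages_rejected(self):
        with pytest.raises(ConfigurationError):
            standardized_age_polynomials(np.full(10, 18.0))


class TestSimulateChoices:
    def test_deterministic_limit_all_risky(self):
        cfg = DesignConfig(values=(50.0,), probabilities=(0.75,), repetitions=4)
        design = design_to_frame(build_design(cfg, seed=0)).assign(social="none")
        agent = AgentParams(rho=1.0, tau=1e-4)
        rec = simulate_choices(agent, design, seed=0)
        assert (rec["choice"] == 1).all()
        assert set(rec["points"].unique()) <= {0.0, 50.0}

    def test_long_run_rate_at_equal_ev(self):
        # the (8, 0.625) lottery has EV 5 = safe value: cp = 0.5 at rho = 1
        cfg = DesignConfig(values=(8.0,), probabilities=(0.625,), repetitions=8)
        design = design_to_frame(build_design(cfg, seed=0)).assign(social="none")
        agent = AgentParams(rho=1.0, tau=1.0)
        draws = pd.concat(
            [simulate_choices(agent, design, seed=s) for s in range(1250)]
        )  # 10,000 trials
        rate = draws["choice"].mean()
        assert abs(rate - 0.5) < 3 * 0.5 / math.sqrt(len(draws))

    def test_risky_advice_raises_risky_rate(self):
        cfg = DesignConfig(values=(20.0,), probabilities=(0.25, 0.5), repetitions=8)
        design = design_to_frame(build_design(cfg, seed=1))
        design["social"] = np.where(design["block"] == "social", "risky", "none")
        agent = AgentParams(rho=1.0, kappa_desc=2.0, kappa_exp=2.0,
                            psi_risky=3.0, psi_safe=3.0, tau=1.0)
        rec = pd.concat([simulate_choices(agent, design, seed=s) for s in range(200)])
        risky = rec[rec["social"] == "risky"]["choice"].mean()
        solo = rec[rec["social"] == "none"]["choice"].mean()
        assert risky > solo

    def test_unresolved_social_rejected(self, default_design_frame):
        with pytest.raises(StateError):
            simulate_choices(AgentParams(), default_design_frame, seed=0)

    def test_safe_choice_pays_safe_value(self, resolved_design_frame):
        rec = simulate_choices(AgentParams(tau=5.0), resolved_design_frame, seed=3)
        safe = rec[rec["choice"] == 0]
        assert (safe["points"] == 5.0).all()


def pool_from_counts(counts: dict[int, int]) -> AdvisorPool:
    rows = []
    for aid, c in counts.items():
        rows.append({"advisor_id": aid, "trial_id": 0, "block": "solo", "choice": 0})
    return AdvisorPool(
        choices=pd.DataFrame(rows),
        risky_counts=pd.Series(counts, name="choice").astype(int),
    )


class TestAdvisorMatching:
    def test_exact_excess_selected(self):
        pool = pool_from_counts({0: 40, 1: 45, 2: 50})
        assert match_advisor(30, pool, target_excess=15) == 1

    def test_stepwise_relaxation(self):
        # best available is +12: relax 15 -> 14 -> 13 -> 12
        pool = pool_from_counts({0: 40, 1: 42})
        assert match_advisor(30, pool, target_excess=15) == 1

    def test_tie_breaks_to_lowest_id(self):
        pool = pool_from_counts({5: 45, 2: 45, 9: 45})
        assert match_advisor(30, pool, target_excess=15) == 2

    def test_empty_pool_raises(self):
        with pytest.raises(MatchingError):
            match_advisor(30, pool_from_counts({}), target_excess=15)

    def test_no_match_at_any_relaxation_raises(self):
        pool = pool_from_counts({0: 20})
        with pytest.raises(MatchingError):
            match_advisor(30, pool, target_excess=15)

    def test_accepts_first_half_frame(self):
        pool = pool_from_counts({0: 18})
        first_half = pd.DataFrame({"choice": [1, 1, 1, 0]})
        assert match_advisor(first_half, pool, target_excess=15) == 0


class TestAdvisorPool:
    @pytest.fixture(scope="class")
    def small_design(self):
        return build_design(DesignConfig(repetitions=4), seed=2)

    def test_risk_prone_profile_raises_counts(self, small_design):
        prone = build_advisor_pool(
            20, small_design, seed=0, profile=AdvisorProfile(rho=1.2, rho_sd=0.0, tau_sd=0.0)
        )
        neutral = build_advisor_pool(
            20, small_design, seed=0, profile=AdvisorProfile(rho=1.0, rho_sd=0.0, tau_sd=0.0)
        )
        assert prone.risky_counts.mean() > neutral.risky_counts.mean()

    def test_reproducible(self, small_design):
        a = build_advisor_pool(5, small_design, seed=9)
        b = build_advisor_pool(5, small_design, seed=9)
        pd.testing.assert_series_equal(a.risky_counts, b.risky_counts)

    def test_advice_labels_cover_social_half(self, small_design):
        pool = build_advisor_pool(3, small_design, seed=0)
        labels = advice_labels(pool, 0)
        social_ids = {t.trial_id for t in small_design if t.block == "social"}
        assert set(labels) == social_ids
        assert set(labels.values()) <= {"safe", "risky"}

    def test_unknown_advisor_rejected(self, small_design):
        pool = build_advisor_pool(2, small_design, seed=0)
        with pytest.raises(MatchingError):
            advice_labels(pool, 99)


class TestDataset:
    def test_schema_matches_inference_contract(self, tiny_dataset):
        subjects, choices = tiny_dataset
        assert list(choices.columns) == CHOICES_COLUMNS
        assert list(subjects.columns) == SUBJECTS_COLUMNS
        # every subject has the full design
        assert (choices.groupby("subject_id").size() == 144).all()
        # the simulator's output is directly consumable by the likelihood
        from socialbayes.model_core import observations_from_frame

        obs = observations_from_frame(choices)
        assert obs.choice is not None and len(obs.value) == len(choices)

    def test_round_trip_csv(self, tiny_dataset, tmp_path):
        from socialbayes.synthetic_data import read_choices, write_dataset

        subjects, choices = tiny_dataset
        _, cpath = write_dataset(subjects, choices, tmp_path)
        back = read_choices(cpath)
        pd.testing.assert_frame_equal(back, choices, check_dtype=False)

    def test_reproducible(self, tiny_dataset):
        subjects, choices = tiny_dataset
        s2, c2 = simulate_dataset(n_subjects=6, n_advisors=40, seed=123)
        pd.testing.assert_frame_equal(subjects, s2)
        pd.testing.assert_frame_equal(choices, c2)

    def test_advisor_excess_respected(self, tiny_dataset):
        subjects, choices = tiny_dataset
        pool = build_advisor_pool(40, build_design(seed=123), seed=124)
        solo = choices[choices["block"] == "solo"]
        for sid, aid in zip(subjects["subject_id"], subjects["advisor_id"]):
            count = int(solo.loc[solo["subject_id"] == sid, "choice"].sum())
            excess = int(pool.risky_counts.loc[aid]) - count
            assert 0 <= excess <= 15

    def test_points_structure(self, tiny_dataset):
        _, choices = tiny_dataset
        safe = choices[choices["choice"] == 0]
        risky = choices[choices["choice"] == 1]
        assert (safe["points"] == 5.0).all()
        assert ((risky["points"] == 0) | (risky["points"] == risky["value_risky"])).all()
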