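"""Synthetic participants, advisors and choice datasets.

The study the pipeline is built for collected 166 participants aged 10-26,
each making 144 lottery choices (half alone, half with social information
from a risk-prone advisor).  This module simulates populations with the same
structure so that every downstream stage — hierarchical fitting, model
comparison, recovery suites, behavioural summaries — can be exercised and
validated without the participant data.

Generative age trends
---------------------
Subject-level parameters are log-linear in standardized age polynomials
(mean 0, SD 0.5, matching the convention used for the study's regressions),
with independent log-normal between-subject dispersion.  The default trends
encode the qualitative developmental findings the analysis targets:

* ``kappa_exp`` rises with age (older agents have less internal uncertainty
  when probabilities must be learned from experience) while ``kappa_desc``
  is flat, and is larger on average than ``kappa_exp`` (experience carries
  the higher uncertainty);
* both social-sensitivity weights ``psi_safe``/``psi_risky`` fall with age,
  with a negative quadratic component;
* choice temperature ``tau`` falls with age (older agents choose more
  deterministically);
* reward sensitivity ``rho`` is near-flat, slightly below 1 and slightly
  declining.

Advisors are simulated as risk-prone agents (elevated ``rho``, low ``tau``)
over the same design; each participant is matched to the advisor whose
first-half risky-choice count exceeds their own by 15 (relaxed in integer
steps when no exact match exists), and the advisor's choices on the social
half become the safe/risky advice labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import task_design
from .exceptions import ConfigurationError, MatchingError, StateError
from .model_core import AgentParams, PARAM_NAMES, predict_choice_probabilities
from .task_design import DesignConfig, LotteryTrial, build_design, design_to_frame

#: schema shared by the simulator's output and the inference input
CHOICES_COLUMNS = [
    "subject_id",
    "trial_id",
    "block",
    "condition",
    "social",
    "value_risky",
    "p_win",
    "safe_value",
    "choice",
    "cp",
    "points",
]

SUBJECTS_COLUMNS = [
    "subject_id",
    "age",
    "age_lin",
    "age_quad",
    "group",
    *PARAM_NAMES,
    "advisor_id",
]

#: age-group bins used as hierarchical hyperprior levels (upper edges inclusive)
DEFAULT_AGE_GROUPS: tuple[tuple[str, float, float], ...] = (
    ("10-13", 10.0, 14.0),
    ("14-17", 14.0, 18.0),
    ("18-26", 18.0, 26.0001),
)


@dataclass(frozen=True)
class ParamTrend:
    """Log-scale age trend of one model parameter.

    ``value = exp(intercept + b_lin * age_lin + b_quad * age_quad + sd * z)``
    with ``age_lin``/``age_quad`` the standardized (SD 0.5) age polynomials
    and ``z`` a standard-normal subject effect.
    """

    intercept: float
    b_lin: float = 0.0
    b_quad: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"dispersion must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class AgeTrendConfig:
    """Per-parameter generative age trends for a synthetic population."""

    trends: Mapping[str, ParamTrend]
    age_range: tuple[float, float] = (10.0, 26.0)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.trends)
        if missing:
            raise ConfigurationError(f"age model missing trends for {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AgeTrendConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        trends = {k: ParamTrend(**v) for k, v in raw["trends"].items()}
        return cls(trends=trends, age_range=tuple(raw.get("age_range", (10.0, 26.0))))


def default_age_model() -> AgeTrendConfig:
    """The frozen default population (see module docstring for rationale)."""
    return AgeTrendConfig(
        trends={
            "rho": ParamTrend(math.log(0.95), -0.08, -0.02, 0.15),
            "kappa_desc": ParamTrend(math.log(8.0), 0.00, 0.00, 0.90),
            "kappa_exp": ParamTrend(math.log(3.5), 0.60, 0.00, 0.90),
            "psi_safe": ParamTrend(math.log(2.0), -0.70, -0.20, 0.90),
            "psi_risky": ParamTrend(math.log(2.0), -0.55, -0.15, 0.90),
            "tau": ParamTrend(math.log(1.2), -0.50, -0.15, 0.50),
        }
    )


@dataclass(frozen=True)
class AdvisorProfile:
    """Generative parameters of the risk-prone advisor pool.

    The pool stands in for the previous experiment the advice was sourced
    from, so it is both riskier on average than the participants (the
    matching rule looks for +15 risky choices) and heterogeneous enough
    that its first-half risky counts span the participants' range — the
    exact-count matching rule cannot terminate otherwise.
    """

    rho: float = 1.3
    tau: float = 1.2
    kappa: float = 5.0
    rho_sd: float = 0.25
    tau_sd: float = 0.5


def standardized_age_polynomials(ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear and quadratic age polynomials, standardized to mean 0, SD 0.5.

    The quadratic term is orthogonalised against the linear term before
    rescaling, so the two regressors are uncorrelated in the sample.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.std() == 0:
        raise ConfigurationError("ages are constant; polynomials are undefined")
    lin = (ages - ages.mean()) / ages.std()
    quad = lin**2
    quad = quad - np.polyval(np.polyfit(lin, quad, 1), lin)  # residualise on linear
    lin = 0.5 * lin
    if quad.std() > 0:
        quad = 0.5 * quad / quad.std()
    return lin, quad


def assign_age_group(
    age: float, groups: Sequence[tuple[str, float, float]] = DEFAULT_AGE_GROUPS
) -> str:
    for label, lo, hi in groups:
        if lo <= age < hi:
            return label
    raise ConfigurationError(f"age {age} outside all configured groups")


def simulate_population(
    n_subjects: int = 166,
    age_model: AgeTrendConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic population of subjects with age-graded parameters.

    Returns one row per subject with age, standardized age polynomials,
    age-group label and the six true generative parameters.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects for age standardization")
    age_model = age_model or default_age_model()
    rng = np.random.default_rng(seed)
    lo, hi = age_model.age_range
    ages = rng.uniform(lo, hi, size=n_subjects)
    age_lin, age_quad = standardized_age_polynomials(ages)

    out = {
        "subject_id": np.arange(n_subjects),
        "age": ages,
        "age_lin": age_lin,
        "age_quad": age_quad,
        "group": [assign_age_group(a) for a in ages],
    }
    for name in PARAM_NAMES:
        t = age_model.trends[name]
        z = rng.standard_normal(n_subjects)
        out[name] = np.exp(t.intercept + t.b_lin * age_lin + t.b_quad * age_quad + t.sd * z)
    return pd.DataFrame(out)


def params_from_row(row) -> AgentParams:
    """AgentParams from a subjects-table row (Series or namedtuple)."""
    get = row.__getitem__ if isinstance(row, (pd.Series, dict)) else lambda k: getattr(row, k)
    return AgentParams(**{k: float(get(k)) for k in PARAM_NAMES})


def simulate_choices(
    subject: AgentParams,
    design: Sequence[LotteryTrial] | pd.DataFrame,
    variant: str = "m2",
    seed: int = 0,
    subject_id: int = 0,
) -> pd.DataFrame:
    """Forward-simulate one agent over a (social-resolved) trial list.

    Each trial yields a Bernoulli choice with the model's risky-choice
    probability ``cp``; realized ``points`` are 5 for safe choices and
    ``value_risky`` with probability ``p_win`` (else 0) for risky ones.
    """
    df = design if isinstance(design, pd.DataFrame) else design_to_frame(design)
    if (df["social"] == task_design.SOCIAL_PENDING).any():
        raise StateError(
            "design contains unresolved social placeholders; resolve advice first"
        )
    rng = np.random.default_rng(seed)
    cp = predict_choice_probabilities(df, subject, variant)
    choice = (rng.random(len(df)) < cp).astype(int)
    win = rng.random(len(df)) < df["p_win"].to_numpy()
    points = np.where(
        choice == 1,
        np.where(win, df["value_risky"].to_numpy(), 0.0),
        df["safe_value"].to_numpy(),
    )
    out = df[["trial_id", "block", "condition", "social", "value_risky", "p_win", "safe_value"]].copy()
    out.insert(0, "subject_id", subject_id)
    out["choice"] = choice
    out["cp"] = cp
    out["points"] = points
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# advisors
# ---------------------------------------------------------------------------


@dataclass
class AdvisorPool:
    """Simulated advisor choices over a design, plus first-half risky counts."""

    choices: pd.DataFrame  # advisor_id, trial_id, choice
    risky_counts: pd.Series  # advisor_id -> first-half risky count

    def __len__(self) -> int:
        return len(self.risky_counts)


def build_advisor_pool(
    n_advisors: int,
    design: Sequence[LotteryTrial] | pd.DataFrame,
    seed: int = 0,
    profile: AdvisorProfile | None = None,
) -> AdvisorPool:
    """Simulate a pool of risk-prone advisors over the full design.

    Advisors decide alone (their social column is forced to 'none'), so the
    same design can be reused; their second-half choices later serve as the
    advice labels shown to matched participants.
    """
    if n_advisors < 1:
        raise ConfigurationError("need at least one advisor")
    profile = profile or AdvisorProfile()
    df = (design if isinstance(design, pd.DataFrame) else design_to_frame(design)).copy()
    df["social"] = "none"
    rng = np.random.default_rng(seed)
    frames = []
    for aid in range(n_advisors):
        params = AgentParams(
            rho=float(profile.rho * np.exp(profile.rho_sd * rng.standard_normal())),
            kappa_desc=profile.kappa,
            kappa_exp=profile.kappa,
            psi_safe=0.0,
            psi_risky=0.0,
            tau=float(profile.tau * np.exp(profile.tau_sd * rng.standard_normal())),
        )
        rec = simulate_choices(
            params, df, variant="m2", seed=int(rng.integers(2**31)), subject_id=aid
        )
        rec = rec.rename(columns={"subject_id": "advisor_id"})
        frames.append(rec[["advisor_id", "trial_id", "block", "choice"]])
    choices = pd.concat(frames, ignore_index=True)
    first_half = choices[choices["block"] == "solo"]
    risky_counts = first_half.groupby("advisor_id")["choice"].sum().astype(int)
    return AdvisorPool(choices=choices, risky_counts=risky_counts)


def match_advisor(
    participant_first_half: pd.DataFrame | int,
    pool: AdvisorPool,
    target_excess: int = 15,
) -> int:
    """Select the advisor for one participant.

    The matched advisor made exactly ``target_excess`` more risky first-half
    choices than the participant; when no advisor satisfies the criterion it
    is relaxed in integer steps (15, 14, ... 0) until one does.  Ties go to
    the lowest advisor id.  Exhausting all relaxations raises
    :class:`MatchingError` rather than silently matching a less risky advisor.
    """
    if target_excess < 0:
        raise ConfigurationError("target_excess must be >= 0")
    if len(pool) == 0:
        raise MatchingError("advisor pool is empty")
    if isinstance(participant_first_half, (int, np.integer)):
        count = int(participant_first_half)
    else:
        count = int(participant_first_half["choice"].sum())
    for excess in range(target_excess, -1, -1):
        hits = pool.risky_counts[pool.risky_counts == count + excess]
        if len(hits):
            return int(hits.index.min())
    raise MatchingError(
        f"no advisor with risky count in [{count}, {count + target_excess}] "
        f"(participant count {count}, pool range "
        f"{pool.risky_counts.min()}-{pool.risky_counts.max()})"
    )


def advice_labels(pool: AdvisorPool, advisor_id: int) -> dict[int, str]:
    """Safe/risky advice labels from one advisor's social-half choices.

    Advisors play the identical design, so taking their choice on the same
    trial id matches the participant's (value, probability, condition) cell
    exactly.
    """
    rows = pool.choices[
        (pool.choices["advisor_id"] == advisor_id) & (pool.choices["block"] == "social")
    ]
    if rows.empty:
        raise MatchingError(f"advisor {advisor_id} not in pool")
    return {
        int(t): ("risky" if c == 1 else "safe")
        for t, c in zip(rows["trial_id"], rows["choice"])
    }


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def simulate_dataset(
    n_subjects: int = 166,
    design_config: DesignConfig | None = None,
    age_model: AgeTrendConfig | None = None,
    variant: str = "m2",
    n_advisors: int = 60,
    target_excess: int = 15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a complete study: population, advisors, matched choices.

    Follows the experimental pipeline: every subject first plays the solo
    half; their risky-choice count selects an advisor whose choices resolve
    the social half's advice labels; the subject then plays the social half.
    Per-subject random streams are derived from the master seed so the
    dataset is reproducible and insensitive to subject order.

    Returns ``(subjects, choices)`` in the schemas consumed by inference
    (:data:`SUBJECTS_COLUMNS`, :data:`CHOICES_COLUMNS`).
    """
    design = build_design(design_config, seed=seed)
    subjects = simulate_population(n_subjects, age_model, seed=seed)
    pool = build_advisor_pool(n_advisors, design, seed=seed + 1)

    design_df = design_to_frame(design)
    solo_df = design_df[design_df["block"] == "solo"]
    social_df = design_df[design_df["block"] == "social"]

    advisor_ids = []
    frames = []
    for idx, row in enumerate(subjects.itertuples(index=False)):
        params = params_from_row(row)
        rng_first = np.random.default_rng([seed, 2 * idx])
        rng_second = np.random.default_rng([seed, 2 * idx + 1])
        first = simulate_choices(
            params, solo_df, variant, seed=int(rng_first.integers(2**31)),
            subject_id=int(row.subject_id),
        )
        aid = match_advisor(int(first["choice"].sum()), pool, target_excess)
        labels = advice_labels(pool, aid)
        resolved = social_df.copy()
        resolved["social"] = [labels[t] for t in resolved["trial_id"]]
        second = simulate_choices(
            params, resolved, variant, seed=int(rng_second.integers(2**31)),
            subject_id=int(row.subject_id),
        )
        advisor_ids.append(aid)
        frames.append(pd.concat([first, second], ignore_index=True))

    subjects = subjects.copy()
    subjects["advisor_id"] = advisor_ids
    choices = pd.concat(frames, ignore_index=True)
    choices = choices.sort_values(["subject_id", "trial_id"]).reset_index(drop=True)
    return subjects[SUBJECTS_COLUMNS], choices[CHOICES_COLUMNS]


def write_dataset(
    subjects: pd.DataFrame, choices: pd.DataFrame, directory: str | Path
) -> tuple[Path, Path]:
    """Write ``subjects.csv`` and ``choices.csv`` to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spath, cpath = directory / "subjects.csv", directory / "choices.csv"
    subjects.to_csv(spath, index=False)
    choices.to_csv(cpath, index=False)
    return spath, cpath


def read_choices(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
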