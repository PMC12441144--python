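"""Cognitive model of socially-influenced risky choice.

The model explains a binary choice between a safe jar (certain payoff) and a
risky jar (payoff ``V`` with win probability ``p``) in four steps:

1. **Utility**: outcome values are transformed with a power function
   ``U = V ** rho``; ``rho < 1`` is risk-averse, ``rho > 1`` risk-seeking.
2. **Internal uncertainty**: the agent's belief about the win probability is
   a beta distribution with mean ``p`` and total pseudo-count ``kappa``
   (``alpha = p * kappa`` pseudo-successes, ``beta = (1 - p) * kappa``
   pseudo-failures).  A small ``kappa`` means the agent acts as if only a
   few marbles informed the estimate, i.e. high internal uncertainty.
   ``kappa`` may differ between decisions from description and experience.
3. **Social updating**: seeing another person choose the risky (safe) jar
   adds ``psi_risky`` (``psi_safe``) pseudo-counts to the corresponding side
   of the belief, shifting its mean from ``p`` to ``p'``.  ``psi = 1``
   treats the advice like one observed marble (an ideal Bayesian observer);
   ``psi = 0`` ignores it.
4. **Choice**: the risky jar is chosen with probability
   ``cp = logistic((EU_risk - EU_safe) / tau)`` where
   ``EU_risk = p' * V ** rho``, ``EU_safe = safe_value ** rho`` and ``tau``
   is a temperature controlling choice stochasticity.

Nested variants of the model (ignore advice / ideal Bayesian / free social
sensitivity) are exposed through a registry; all share a single vectorised
likelihood code path, so the nesting relations hold bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError, DomainError, StateError
from .task_design import LotteryTrial, SOCIAL_PENDING

#: clipping bound keeping choice probabilities away from {0, 1} in log-likelihoods
CP_CLIP = 1e-9

PARAM_NAMES = ("rho", "kappa_desc", "kappa_exp", "psi_safe", "psi_risky", "tau")


@dataclass(frozen=True)
class AgentParams:
    """Subject-level parameters (generative truth or estimate)."""

    rho: float = 1.0
    kappa_desc: float = 2.0
    kappa_exp: float = 2.0
    psi_safe: float = 0.0
    psi_risky: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rho", "kappa_desc", "kappa_exp", "tau"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {v}")
        for name in ("psi_safe", "psi_risky"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v}")

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}


class EUPair(NamedTuple):
    """Expected utilities of the two jars, in utility units."""

    eu_risk: float
    eu_safe: float


@dataclass
class BeliefState:
    """Beta-belief about the win probability, before and after advice."""

    alpha: float
    beta: float
    p_prior: float
    p_post: float | None = None
    si_risk: int = 0
    si_safe: int = 0


def utility(value: float, rho: float) -> float:
    """Power utility ``U = value ** rho``."""
    if value < 0:
        raise DomainError(f"value must be non-negative, got {value}")
    if rho <= 0:
        raise DomainError(f"rho must be positive, got {rho}")
    return float(value) ** rho


def prior_belief(p_win: float, kappa: float) -> BeliefState:
    """Belief about the win probability before any social information.

    The belief is a beta distribution with mean ``p_win`` and total
    pseudo-count ``kappa``: ``alpha = p_win * kappa`` pseudo-successes and
    ``beta = (1 - p_win) * kappa`` pseudo-failures.
    """
    if not 0.0 < p_win < 1.0:
        raise DomainError(f"p_win {p_win} outside the open interval (0, 1)")
    if kappa <= 0:
        raise DomainError(f"kappa must be positive, got {kappa}")
    return BeliefState(alpha=p_win * kappa, beta=(1.0 - p_win) * kappa, p_prior=p_win)


def social_update(
    state: BeliefState, social: str, psi_safe: float = 0.0, psi_risky: float = 0.0
) -> float:
    """Posterior mean ``p'`` of the belief after (possibly absent) advice.

    Risky advice adds ``psi_risky`` pseudo-successes, safe advice adds
    ``psi_safe`` pseudo-failures; with ``psi = 1`` this is exact Bayesian
    updating on one observed choice treated as one marble.  ``social='none'``
    leaves the belief untouched.  The updated mean is stored on ``state``.
    """
    if psi_safe < 0 or psi_risky < 0:
        raise DomainError("social-sensitivity weights must be non-negative")
    if social == "none":
        si_risk, si_safe = 0, 0
    elif social == "risky":
        si_risk, si_safe = 1, 0
    elif social == "safe":
        si_risk, si_safe = 0, 1
    else:
        raise ConfigurationError(f"unknown social level {social!r}")
    num = state.alpha + si_risk * psi_risky
    den = num + state.beta + si_safe * psi_safe
    p_post = num / den
    state.si_risk, state.si_safe = si_risk, si_safe
    state.p_post = p_post
    return float(p_post)


@dataclass(frozen=True)
class ModelVariant:
    """A member of the nested model family.

    ``free`` lists the parameters estimated for this variant;
    ``constrain`` maps a full parameter set onto the variant's restricted
    subspace (e.g. forcing ``psi = 0``).
    """

    name: str
    label: str
    free: tuple[str, ...]
    constrain: Callable[[AgentParams], AgentParams]


def _constrain_m0(p: AgentParams) -> AgentParams:
    # advice ignored; kappa is left untouched (it is unidentified and drops
    # out of the likelihood), so m2 with psi=0 matches m0 bitwise
    return replace(p, psi_safe=0.0, psi_risky=0.0)


def _constrain_m1(p: AgentParams) -> AgentParams:
    return replace(p, psi_safe=1.0, psi_risky=1.0)


def _constrain_m2s(p: AgentParams) -> AgentParams:
    return replace(p, psi_risky=p.psi_safe)


VARIANTS: dict[str, ModelVariant] = {
    "m0": ModelVariant("m0", "utility-only", ("rho", "tau"), _constrain_m0),
    "m1": ModelVariant(
        "m1", "ideal Bayesian", ("rho", "tau", "kappa_desc", "kappa_exp"), _constrain_m1
    ),
    "m2": ModelVariant(
        "m2",
        "full",
        ("rho", "tau", "kappa_desc", "kappa_exp", "psi_safe", "psi_risky"),
        lambda p: p,
    ),
    "m2s": ModelVariant(
        "m2s",
        "single-psi",
        ("rho", "tau", "kappa_desc", "kappa_exp", "psi_safe"),
        _constrain_m2s,
    ),
}


def get_variant(name: str) -> ModelVariant:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model variant {name!r}; available: {sorted(VARIANTS)}"
        ) from None


# ---------------------------------------------------------------------------
# vectorised likelihood core
# ---------------------------------------------------------------------------


class Observations(NamedTuple):
    """Column arrays of a trial table, ready for vectorised likelihoods."""

    value: np.ndarray
    p_win: np.ndarray
    is_exp: np.ndarray
    si_risk: np.ndarray
    si_safe: np.ndarray
    safe_value: np.ndarray
    choice: np.ndarray | None


def observations_from_frame(df: pd.DataFrame, require_choice: bool = True) -> Observations:
    """Extract numeric observation arrays from a trial/choice table."""
    if (df["social"] == SOCIAL_PENDING).any():
        raise StateError("trial table contains unresolved social placeholders")
    choice = None
    if "choice" in df.columns:
        choice = df["choice"].to_numpy(dtype=float)
    elif require_choice:
        raise ConfigurationError("trial table has no 'choice' column")
    return Observations(
        value=df["value_risky"].to_numpy(dtype=float),
        p_win=df["p_win"].to_numpy(dtype=float),
        is_exp=(df["condition"] == "experience").to_numpy(),
        si_risk=(df["social"] == "risky").to_numpy(dtype=float),
        si_safe=(df["social"] == "safe").to_numpy(dtype=float),
        safe_value=df["safe_value"].to_numpy(dtype=float),
        choice=choice,
    )


def posterior_means(
    obs: Observations,
    kappa_desc,
    kappa_exp,
    psi_safe,
    psi_risky,
) -> tuple[np.ndarray, np.ndarray]:
    """Prior and post-advice belief means (p, p') for every observation.

    Parameter arguments may be scalars or arrays broadcastable against the
    trailing observation axis, enabling one call per walker/draw batch.
    """
    kappa = np.where(obs.is_exp, kappa_exp, kappa_desc)
    alpha = obs.p_win * kappa
    beta = (1.0 - obs.p_win) * kappa
    p_prior = alpha / (alpha + beta)
    num = alpha + obs.si_risk * psi_risky
    den = num + beta + obs.si_safe * psi_safe
    return p_prior, num / den


def choice_probabilities_core(
    obs: Observations, rho, kappa_desc, kappa_exp, psi_safe, psi_risky, tau
) -> np.ndarray:
    """Risky-choice probability for every observation (vectorised)."""
    _, p_post = posterior_means(obs, kappa_desc, kappa_exp, psi_safe, psi_risky)
    eu_risk = p_post * obs.value**rho
    eu_safe = obs.safe_value**rho
    return expit((eu_risk - eu_safe) / tau)


def pointwise_loglik_core(
    obs: Observations, rho, kappa_desc, kappa_exp, psi_safe, psi_risky, tau
) -> np.ndarray:
    """Bernoulli log-likelihood of each observed choice (vectorised)."""
    if obs.choice is None:
        raise ConfigurationError("observations carry no choices")
    cp = choice_probabilities_core(obs, rho, kappa_desc, kappa_exp, psi_safe, psi_risky, tau)
    cp = np.clip(cp, CP_CLIP, 1.0 - CP_CLIP)
    return obs.choice * np.log(cp) + (1.0 - obs.choice) * np.log(1.0 - cp)


def _params_tuple(params: AgentParams, variant: str | ModelVariant):
    v = get_variant(variant) if isinstance(variant, str) else variant
    p = v.constrain(params)
    return (p.rho, p.kappa_desc, p.kappa_exp, p.psi_safe, p.psi_risky, p.tau)


def predict_choice_probabilities(
    df: pd.DataFrame, params: AgentParams, variant: str | ModelVariant = "m2"
) -> np.ndarray:
    """Model choice probabilities for every row of a trial table."""
    obs = observations_from_frame(df, require_choice=False)
    return choice_probabilities_core(obs, *_params_tuple(params, variant))


# ---------------------------------------------------------------------------
# scalar, trial-level interface
# ---------------------------------------------------------------------------


def expected_utilities(trial: LotteryTrial, params: AgentParams) -> EUPair:
    """Expected utilities of the risky and safe jars on one trial.

    The safe jar's outcome is certain, so its expected utility is simply
    ``safe_value ** rho``.  ``kappa`` is selected by the trial's condition.
    """
    kappa = params.kappa_exp if trial.condition == "experience" else params.kappa_desc
    state = prior_belief(trial.p_win, kappa)
    p_post = social_update(state, trial.social, params.psi_safe, params.psi_risky)
    return EUPair(
        eu_risk=p_post * utility(trial.value_risky, params.rho),
        eu_safe=utility(trial.safe_value, params.rho),
    )


def choice_probability(eus: EUPair, tau: float) -> float:
    """Logistic choice rule: probability of choosing the risky jar."""
    if tau <= 0:
        raise DomainError(f"tau must be positive, got {tau}")
    return float(expit((eus.eu_risk - eus.eu_safe) / tau))


def trial_loglik(
    trial: LotteryTrial,
    choice: int,
    params: AgentParams,
    variant: str | ModelVariant = "m2",
) -> float:
    """Log-probability of one observed choice under a model variant."""
    if choice not in (0, 1):
        raise DomainError(f"choice must be 0 (safe) or 1 (risky), got {choice}")
    v = get_variant(variant) if isinstance(variant, str) else variant
    p = v.constrain(params)
    eus = expected_utilities(trial, p)
    cp = np.clip(choice_probability(eus, p.tau), CP_CLIP, 1.0 - CP_CLIP)
    return float(np.log(cp) if choice == 1 else np.log(1.0 - cp))
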