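"""Parameter estimation for the social-influence choice model.

Two fitting paths are provided:

* :func:`fit_subject_map` / :func:`fit_dataset_map` — a fast penalized-
  likelihood path: per-subject MAP estimates on log-transformed scales with
  weakly-informative priors, followed by a Laplace (Gaussian) approximation
  of the posterior from which draws and a pointwise log-likelihood matrix
  are generated.  This is the workhorse for recovery suites and model
  comparison at desk scale.
* :func:`fit_hierarchical` — the full hierarchical model: subject-level
  parameters (log scale) are drawn from age-group-level normal
  distributions, sampled with an affine-invariant ensemble MCMC sampler
  (emcee).  Split-chain R-hat diagnostics are computed with arviz; a
  convergence warning is attached whenever any R-hat exceeds the threshold.

Both paths expose draws x observations pointwise log-likelihood matrices in
the exact trial order of the input table, which is what approximate
leave-one-trial-out cross-validation consumes.

Priors (overridable via :class:`PriorConfig`): ``log kappa ~ N(log 5, 1)``,
``log tau ~ N(0, 1)``, ``log rho ~ N(0, 0.5)`` and ``psi ~ half-N(0, 2)``.
``psi`` is optimised on the log scale with the half-normal prior plus its
Jacobian; the hierarchical path places the group distribution directly on
``log psi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import halfnorm, norm

from .exceptions import ConfigurationError, InferenceError
from .model_core import (
    PARAM_NAMES,
    AgentParams,
    ModelVariant,
    get_variant,
    observations_from_frame,
    pointwise_loglik_core,
)

#: optimisation bound guard on the unconstrained (log) scale
U_BOUND = 12.0
#: |u| beyond which an estimate is flagged as having hit the bound guard
U_FLAG = 8.0
RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class PriorConfig:
    """Weakly-informative priors on transformed scales."""

    log_rho: tuple[float, float] = (0.0, 0.5)
    log_kappa: tuple[float, float] = (math.log(5.0), 1.0)
    log_tau: tuple[float, float] = (0.0, 1.0)
    psi_halfnormal_scale: float = 2.0
    # group-mean prior for log psi used by the hierarchical path, and the
    # subject-level prior when psi_prior = "lognormal"
    log_psi: tuple[float, float] = (0.0, 1.0)
    # "halfnormal": psi ~ half-N(0, psi_halfnormal_scale) on the natural scale;
    # "lognormal": log psi ~ N(*log_psi) (useful when large weights are expected)
    psi_prior: str = "halfnormal"

    def loc_scale(self, name: str) -> tuple[float, float]:
        if name == "rho":
            return self.log_rho
        if name in ("kappa_desc", "kappa_exp"):
            return self.log_kappa
        if name == "tau":
            return self.log_tau
        if name.startswith("psi"):
            return self.log_psi
        raise ConfigurationError(f"unknown parameter {name!r}")


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-MCMC settings for the hierarchical path."""

    chains: int = 4
    iterations: int = 1000
    warmup: int = 500
    n_keep: int = 400  # thinned posterior draws retained for summaries / LOO

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ConfigurationError("warmup must be smaller than iterations")

    @classmethod
    def desk(cls) -> "MCMCConfig":
        """Scaled-down default for interactive work."""
        return cls(chains=4, iterations=1000, warmup=500)

    @classmethod
    def paper(cls) -> "MCMCConfig":
        """Four chains of 6000 iterations, 2000 discarded as warmup."""
        return cls(chains=4, iterations=6000, warmup=2000)


@dataclass
class FitResult:
    """Posterior summaries, draws and pointwise log-likelihoods of one fit."""

    variant: str
    method: str  # "map" or "hierarchical"
    params: pd.DataFrame  # subject_id x parameter point estimates (natural scale)
    param_sd: pd.DataFrame  # posterior/approximation SDs (natural scale)
    pointwise_loglik: np.ndarray  # draws x observations
    obs_index: pd.DataFrame  # subject_id, trial_id per observation column
    rhat: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    subject_draws: dict = field(default_factory=dict)  # name -> (draws, subjects)
    metadata: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.pointwise_loglik.shape[1]

    def subject_params(self, subject_id) -> AgentParams:
        row = self.params.loc[subject_id]
        return AgentParams(**{k: float(row[k]) for k in PARAM_NAMES})

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "variant": self.variant,
            "method": self.method,
            "params": self.params.reset_index().to_dict(orient="list"),
            "param_sd": self.param_sd.reset_index().to_dict(orient="list"),
            "rhat": {str(k): float(v) for k, v in self.rhat.items()},
            "metadata": {k: v for k, v in self.metadata.items() if _jsonable(v)},
            "warnings": list(self.warnings),
        }
        import json

        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(payload, fh, indent=1)
        np.savez_compressed(
            str(prefix) + "_loglik.npz",
            pointwise_loglik=self.pointwise_loglik,
            subject_id=self.obs_index["subject_id"].to_numpy(),
            trial_id=self.obs_index["trial_id"].to_numpy(),
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "FitResult":
        import json

        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            payload = json.load(fh)
        params = pd.DataFrame(payload["params"]).set_index("subject_id")
        param_sd = pd.DataFrame(payload["param_sd"]).set_index("subject_id")
        arrs = np.load(str(prefix) + "_loglik.npz")
        return cls(
            variant=payload["variant"],
            method=payload["method"],
            params=params,
            param_sd=param_sd,
            pointwise_loglik=arrs["pointwise_loglik"],
            obs_index=pd.DataFrame(
                {"subject_id": arrs["subject_id"], "trial_id": arrs["trial_id"]}
            ),
            rhat=pd.Series(payload["rhat"], dtype=float),
            metadata=payload["metadata"],
            warnings=payload["warnings"],
        )


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, list, dict, type(None)))


# ---------------------------------------------------------------------------
# transformed-scale parameter handling
# ---------------------------------------------------------------------------

_FIXED_VALUES = {
    # values taken by non-free parameters under each variant
    "m0": {"kappa_desc": 1.0, "kappa_exp": 1.0, "psi_safe": 0.0, "psi_risky": 0.0},
    "m1": {"psi_safe": 1.0, "psi_risky": 1.0},
    "m2": {},
    "m2s": {},  # psi_risky tied to psi_safe below
}


def expand_free(u: np.ndarray, variant: ModelVariant) -> tuple:
    """Map unconstrained free-parameter arrays to the six core parameters.

    ``u`` has shape ``(..., n_free)``; returns six arrays broadcastable in
    the core likelihood (each scalar or shape ``(...)``, to be broadcast
    against the observation axis by the caller).
    """
    x = np.exp(u)
    vals = dict(_FIXED_VALUES[variant.name])
    for j, name in enumerate(variant.free):
        vals[name] = x[..., j]
    if variant.name == "m2s":
        vals["psi_risky"] = vals["psi_safe"]
    return tuple(vals[k] for k in PARAM_NAMES)


def params_from_u(u: np.ndarray, variant: ModelVariant) -> AgentParams:
    vals = expand_free(np.asarray(u, dtype=float), variant)
    d = dict(zip(PARAM_NAMES, (float(v) for v in vals)))
    # AgentParams requires positive kappa/tau even when the variant ignores them
    for k in ("kappa_desc", "kappa_exp"):
        d[k] = max(d[k], 1e-12) if d[k] > 0 else 1.0
    return AgentParams(**d)


def log_prior_u(u: np.ndarray, variant: ModelVariant, priors: PriorConfig) -> np.ndarray:
    """Log prior density on the unconstrained scale, shape ``u.shape[:-1]``.

    Gaussian priors are placed directly on the log scale for rho, kappa and
    tau.  psi carries a half-normal prior on the natural scale; its density
    on ``u = log psi`` includes the Jacobian ``dpsi/du = psi``.
    """
    total = np.zeros(u.shape[:-1])
    for j, name in enumerate(variant.free):
        uj = u[..., j]
        if name.startswith("psi") and priors.psi_prior != "lognormal":
            s = priors.psi_halfnormal_scale
            # half-normal density at psi = e^u plus the log-Jacobian u
            total = total + (
                0.5 * math.log(2.0 / math.pi)
                - math.log(s)
                - np.exp(2.0 * uj) / (2.0 * s * s)
                + uj
            )
        else:
            loc, scale = (
                priors.log_psi if name.startswith("psi") else priors.loc_scale(name)
            )
            z = (uj - loc) / scale
            total = total - 0.5 * z * z - math.log(scale) - 0.5 * math.log(2.0 * math.pi)
    return total


def _prior_start(variant: ModelVariant, priors: PriorConfig) -> np.ndarray:
    u0 = []
    for name in variant.free:
        if name.startswith("psi"):
            u0.append(0.0)  # psi = 1
        else:
            u0.append(priors.loc_scale(name)[0])
    return np.array(u0)


def sample_prior_params(
    rng: np.random.Generator, variant: str | ModelVariant = "m2", priors: PriorConfig | None = None
) -> AgentParams:
    """Draw one full parameter set from the priors (prior-predictive use)."""
    variant = get_variant(variant) if isinstance(variant, str) else variant
    priors = priors or PriorConfig()
    u = []
    for name in variant.free:
        if name.startswith("psi"):
            if priors.psi_prior == "lognormal":
                u.append(rng.normal(*priors.log_psi))
            else:
                psi = abs(rng.normal(0.0, priors.psi_halfnormal_scale))
                u.append(math.log(max(psi, 1e-6)))
        else:
            loc, scale = priors.loc_scale(name)
            u.append(rng.normal(loc, scale))
    return params_from_u(np.array(u), variant)


# ---------------------------------------------------------------------------
# MAP + Laplace path
# ---------------------------------------------------------------------------


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


def _laplace_cov(H: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    # symmetrise and floor the curvature spectrum before inverting
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    w = np.clip(w, floor, None)
    return (V / w) @ V.T


def fit_subject_map(
    choices: pd.DataFrame,
    variant: str | ModelVariant = "m2",
    priors: PriorConfig | None = None,
    n_starts: int = 4,
    seed: int = 0,
    n_draws: int = 400,
) -> FitResult:
    """MAP fit of one subject with a Laplace approximation of the posterior.

    Maximises the sum of trial log-likelihoods plus log-priors on the
    unconstrained (log) scale, taking the best of ``n_starts`` multistarts
    (the first start sits at the prior locations, the rest are prior draws).
    The curvature at the mode yields a Gaussian approximation from which
    ``n_draws`` posterior draws and the draws x trials pointwise
    log-likelihood matrix are computed.  Deterministic given ``seed``.
    """
    variant = get_variant(variant) if isinstance(variant, str) else variant
    priors = priors or PriorConfig()
    if len(choices) < 1:
        raise ConfigurationError("need at least one trial")
    choices = choices.reset_index(drop=True)
    obs = observations_from_frame(choices)
    rng = np.random.default_rng(seed)
    nf = len(variant.free)

    def neg_logpost(u: np.ndarray) -> float:
        ll = pointwise_loglik_core(obs, *_broadcast(expand_free(u, variant))).sum()
        lp = log_prior_u(u, variant, priors)
        val = -(ll + lp)
        return float(val) if np.isfinite(val) else 1e12

    starts = [_prior_start(variant, priors)]
    for _ in range(max(n_starts - 1, 0)):
        jitter = []
        for name in variant.free:
            if name.startswith("psi"):
                jitter.append(math.log(max(abs(rng.normal(0, priors.psi_halfnormal_scale)), 1e-3)))
            else:
                loc, scale = priors.loc_scale(name)
                jitter.append(rng.normal(loc, scale))
        starts.append(np.array(jitter))

    best = None
    for x0 in starts:
        res = minimize(
            neg_logpost, x0, method="L-BFGS-B", bounds=[(-U_BOUND, U_BOUND)] * nf
        )
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise InferenceError("all optimisation starts failed to converge")

    u_hat = best.x
    warnings_ = []
    flagged = [n for n, u in zip(variant.free, u_hat) if abs(u) > U_FLAG]
    if flagged:
        warnings_.append(
            f"bound-guard: {flagged} at |log value| > {U_FLAG}; "
            "estimate is prior-dominated or the data are degenerate"
        )
    if obs.choice is not None and len(np.unique(obs.choice)) == 1:
        side = "risky" if obs.choice[0] == 1 else "safe"
        warnings_.append(
            f"bound-guard: all choices are {side}; the likelihood diverges and "
            "the estimates are prior/bound-dominated"
        )

    H = _numeric_hessian(neg_logpost, u_hat)
    cov = _laplace_cov(H)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(nf))
    z = np.random.default_rng(seed + 1).standard_normal((n_draws, nf))
    draws_u = u_hat + z @ chol.T
    draws_u = np.clip(draws_u, -U_BOUND, U_BOUND)

    pw = pointwise_loglik_core(obs, *_broadcast_draws(expand_free(draws_u, variant)))
    natural = np.stack(
        [np.broadcast_to(v, (n_draws,)).astype(float) for v in _draw_columns(draws_u, variant)],
        axis=1,
    )  # (n_draws, 6)

    sid = choices["subject_id"].iloc[0] if "subject_id" in choices.columns else 0
    est = params_from_u(u_hat, variant)
    params = pd.DataFrame([est.to_dict()], index=pd.Index([sid], name="subject_id"))
    sd = pd.DataFrame(
        [dict(zip(PARAM_NAMES, natural.std(axis=0)))], index=params.index
    )
    obs_index = pd.DataFrame(
        {
            "subject_id": sid,
            "trial_id": choices["trial_id"] if "trial_id" in choices.columns else np.arange(len(choices)),
        }
    )
    return FitResult(
        variant=variant.name,
        method="map",
        params=params,
        param_sd=sd,
        pointwise_loglik=pw,
        obs_index=obs_index,
        subject_draws={
            name: natural[:, k][:, None] for k, name in enumerate(PARAM_NAMES)
        },
        metadata={
            "seed": int(seed),
            "n_starts": int(n_starts),
            "n_draws": int(n_draws),
            "neg_logpost": float(best.fun),
            "loglik_at_map": float(
                pointwise_loglik_core(obs, *_broadcast(expand_free(u_hat, variant))).sum()
            ),
            "u_hat": [float(v) for v in u_hat],
        },
        warnings=warnings_,
    )


def _broadcast(vals: tuple) -> tuple:
    # scalars broadcast naturally against the observation axis
    return vals


def _broadcast_draws(vals: tuple) -> tuple:
    # per-draw parameter vectors gain a trailing observation axis
    return tuple(
        v[:, None] if isinstance(v, np.ndarray) and v.ndim == 1 else v for v in vals
    )


def _draw_columns(draws_u: np.ndarray, variant: ModelVariant) -> tuple:
    return expand_free(draws_u, variant)


def fit_dataset_map(
    choices: pd.DataFrame,
    variant: str | ModelVariant = "m2",
    priors: PriorConfig | None = None,
    n_starts: int = 4,
    seed: int = 0,
    n_draws: int = 400,
) -> FitResult:
    """Independent MAP+Laplace fits for every subject in a dataset.

    The combined pointwise log-likelihood matrix stacks the subjects'
    columns in (subject_id, trial_id) order; draws are independent across
    subjects, which matches the non-hierarchical factorisation of the
    posterior.
    """
    variant = get_variant(variant) if isinstance(variant, str) else variant
    choices = choices.sort_values(["subject_id", "trial_id"]).reset_index(drop=True)
    fits = []
    for sid, grp in choices.groupby("subject_id", sort=True):
        sub_seed = int(np.random.default_rng([seed, int(sid)]).integers(2**31))
        fits.append(
            fit_subject_map(grp, variant, priors, n_starts, seed=sub_seed, n_draws=n_draws)
        )
    params = pd.concat([f.params for f in fits])
    sd = pd.concat([f.param_sd for f in fits])
    pw = np.hstack([f.pointwise_loglik for f in fits])
    obs_index = pd.concat([f.obs_index for f in fits], ignore_index=True)
    warnings_ = [w for f in fits for w in f.warnings]
    draws = {
        name: np.hstack([f.subject_draws[name] for f in fits]) for name in PARAM_NAMES
    }
    return FitResult(
        variant=variant.name,
        method="map",
        params=params,
        param_sd=sd,
        pointwise_loglik=pw,
        obs_index=obs_index,
        subject_draws=draws,
        metadata={"seed": int(seed), "n_subjects": len(fits), "n_draws": int(n_draws)},
        warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# hierarchical path
# ---------------------------------------------------------------------------


def fit_hierarchical(
    choices: pd.DataFrame,
    subjects: pd.DataFrame,
    variant: str | ModelVariant = "m2",
    mcmc: MCMCConfig | None = None,
    priors: PriorConfig | None = None,
    seed: int = 0,
    sigma_scale: float = 0.5,
) -> FitResult:
    """Hierarchical fit with age-group hyperpriors.

    Subject-level log parameters are modelled as
    ``u[i, j] = mu[group(i), j] + sigma[j] * z[i, j]`` (non-centred), with
    ``mu`` given the weakly-informative priors of :class:`PriorConfig`,
    ``sigma[j] ~ half-N(0, sigma_scale)`` shared across groups, and
    ``z ~ N(0, 1)``.  The joint posterior is sampled with an ensemble
    sampler; walkers are partitioned into ``mcmc.chains`` pseudo-chains for
    split-chain R-hat.  A convergence warning is attached when any R-hat
    exceeds 1.01.
    """
    variant = get_variant(variant) if isinstance(variant, str) else variant
    mcmc = mcmc or MCMCConfig.desk()
    priors = priors or PriorConfig()
    if "group" not in subjects.columns:
        raise ConfigurationError("subjects table needs a 'group' column")

    choices = choices.sort_values(["subject_id", "trial_id"]).reset_index(drop=True)
    obs = observations_from_frame(choices)
    sids = np.sort(subjects["subject_id"].unique())
    sid_to_idx = {s: i for i, s in enumerate(sids)}
    missing = set(choices["subject_id"].unique()) - set(sids)
    if missing:
        raise ConfigurationError(f"choices reference unknown subjects {sorted(missing)}")
    subj_of_obs = choices["subject_id"].map(sid_to_idx).to_numpy()

    group_labels = sorted(subjects.set_index("subject_id").loc[sids, "group"].unique())
    g_of_subj = (
        subjects.set_index("subject_id")
        .loc[sids, "group"]
        .map({g: k for k, g in enumerate(group_labels)})
        .to_numpy()
    )

    F, G, N = len(variant.free), len(group_labels), len(sids)
    D = F * G + F + F * N
    mu_loc = np.array([priors.loc_scale(n)[0] for n in variant.free])
    mu_scale = np.array([priors.loc_scale(n)[1] for n in variant.free])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        mu = theta[:, : F * G].reshape(W, F, G)
        lam = theta[:, F * G : F * G + F]
        z = theta[:, F * G + F :].reshape(W, F, N)
        sigma = np.exp(np.clip(lam, -10, 3))
        lp = norm.logpdf(mu, mu_loc[None, :, None], mu_scale[None, :, None]).sum(axis=(1, 2))
        lp += (halfnorm.logpdf(sigma, scale=sigma_scale) + np.clip(lam, -10, 3)).sum(axis=1)
        lp += norm.logpdf(z).sum(axis=(1, 2))
        u = mu[:, :, g_of_subj] + sigma[:, :, None] * z  # (W, F, N)
        u_obs = u[:, :, subj_of_obs]  # (W, F, n_obs)
        u_free = np.moveaxis(u_obs, 1, 2)  # (W, n_obs, F)
        ll = pointwise_loglik_core(obs, *expand_free(u_free, variant)).sum(axis=1)
        out = lp + ll
        return np.where(np.isfinite(out), out, -np.inf)

    wpc = max(math.ceil((2 * D + 2) / mcmc.chains), 2)
    nwalkers = wpc * mcmc.chains
    rng = np.random.default_rng(seed)
    center = np.concatenate(
        [np.repeat(mu_loc, G), np.full(F, math.log(0.3)), np.zeros(F * N)]
    )
    jitter = np.concatenate(
        [np.full(F * G, 0.5), np.full(F, 0.3), np.full(F * N, 0.3)]
    )
    p0 = center + jitter * rng.standard_normal((nwalkers, D))

    sampler = emcee.EnsembleSampler(nwalkers, D, log_prob, vectorize=True)
    state = sampler.run_mcmc(p0, mcmc.iterations, progress=False)
    if not np.isfinite(state.log_prob).any():
        raise InferenceError("ensemble sampler produced no finite posterior density")

    chain = sampler.get_chain(discard=mcmc.warmup)  # (steps, walkers, D)
    S = chain.shape[0]
    bychain = chain.transpose(1, 0, 2).reshape(mcmc.chains, wpc * S, D)

    names = (
        [f"mu[{n},{g}]" for n in variant.free for g in group_labels]
        + [f"log_sigma[{n}]" for n in variant.free]
        + [f"z[{n},{s}]" for n in variant.free for s in sids]
    )
    rhat_ds = az.rhat(az.convert_to_dataset(bychain))
    rhat_vals = np.asarray(rhat_ds["x"]).ravel()
    rhat = pd.Series(rhat_vals, index=names)
    warnings_ = []
    if (rhat > RHAT_THRESHOLD).any():
        worst = rhat.idxmax()
        warnings_.append(
            f"convergence: max split-R-hat {rhat.max():.3f} at {worst} exceeds "
            f"{RHAT_THRESHOLD}; increase iterations"
        )

    flat = bychain.reshape(-1, D)
    keep = np.linspace(0, len(flat) - 1, min(mcmc.n_keep, len(flat))).astype(int)
    kept = flat[keep]
    K = len(kept)
    mu = kept[:, : F * G].reshape(K, F, G)
    sigma = np.exp(np.clip(kept[:, F * G : F * G + F], -10, 3))
    z = kept[:, F * G + F :].reshape(K, F, N)
    u_subj = mu[:, :, g_of_subj] + sigma[:, :, None] * z  # (K, F, N)

    # natural-scale subject parameters per draw
    draws_nat = {}
    u_free_subj = np.moveaxis(u_subj, 1, 2)  # (K, N, F)
    cols = expand_free(u_free_subj, variant)
    for k, name in enumerate(PARAM_NAMES):
        v = cols[k]
        draws_nat[name] = (
            np.broadcast_to(v, (K, N)).astype(float) if np.ndim(v) else np.full((K, N), float(v))
        )

    params = pd.DataFrame(
        {name: draws_nat[name].mean(axis=0) for name in PARAM_NAMES},
        index=pd.Index(sids, name="subject_id"),
    )
    sd = pd.DataFrame(
        {name: draws_nat[name].std(axis=0) for name in PARAM_NAMES}, index=params.index
    )

    u_obs = u_subj[:, :, subj_of_obs]
    pw = pointwise_loglik_core(obs, *expand_free(np.moveaxis(u_obs, 1, 2), variant))

    group_mu = pd.DataFrame(
        mu.mean(axis=0), index=pd.Index(list(variant.free), name="param"), columns=group_labels
    )
    return FitResult(
        variant=variant.name,
        method="hierarchical",
        params=params,
        param_sd=sd,
        pointwise_loglik=pw,
        obs_index=choices[["subject_id", "trial_id"]].copy(),
        rhat=rhat,
        subject_draws=draws_nat,
        metadata={
            "seed": int(seed),
            "chains": mcmc.chains,
            "iterations": mcmc.iterations,
            "warmup": mcmc.warmup,
            "nwalkers": int(nwalkers),
            "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
            "group_mu": group_mu,
            "group_labels": list(group_labels),
        },
        warnings=warnings_,
    )


# ---------------------------------------------------------------------------
# age trends
# ---------------------------------------------------------------------------


def fit_age_trend(
    param_estimates: Sequence[float],
    ages: Sequence[float],
    transform: str | None = None,
) -> pd.DataFrame:
    """Least-squares age trend of per-subject parameter estimates.

    Regresses the (optionally log-transformed) estimates on standardized
    linear and quadratic age polynomials (mean 0, SD 0.5).  Returns a table
    with coefficient, standard error, z value and 95% interval for the
    intercept and both polynomial terms.
    """
    from .synthetic_data import standardized_age_polynomials

    y = np.asarray(param_estimates, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(y) != len(ages):
        raise ConfigurationError("estimates and ages differ in length")
    if len(y) < 3:
        raise ConfigurationError("need at least 3 subjects for an age trend")
    if np.std(ages) == 0:
        raise ConfigurationError("ages are constant; design matrix is rank-deficient")
    if transform == "log":
        if (y <= 0).any():
            raise ConfigurationError("log transform requires positive estimates")
        y = np.log(y)
    elif transform is not None:
        raise ConfigurationError(f"unknown transform {transform!r}")

    lin, quad = standardized_age_polynomials(ages)
    X = sm.add_constant(np.column_stack([lin, quad]))
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "z": fit.tvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=pd.Index(["intercept", "age_lin", "age_quad"], name="term"),
    )
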