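# Methods

## Model

A trial offers a safe jar paying `s = 5` points with certainty and a risky
jar paying `V` points with probability `p`.  Choices are modelled in four
steps:

1. **Power utility** `U(V) = V^ρ` with `ρ > 0`; `ρ < 1` is risk-averse,
   `ρ > 1` risk-seeking.  The same exponent is applied to the safe payoff
   (`EU_safe = s^ρ`): the safe jar's outcome is certain, so no belief enters.
2. **Internal uncertainty.**  The agent's belief about `p` is
   `Beta(α, β)` with `α = p·κ`, `β = (1−p)·κ`.  The pseudo-count `κ`
   (units: marbles) controls how firmly the belief is held; it takes
   separate values for decisions from description (`κ_desc`) and from
   experience (`κ_exp`).  On trials without advice the belief mean is
   exactly `p`, so `κ` affects nothing — it is identified only through
   social trials.
3. **Social updating.**  Advice favouring the risky (safe) jar adds
   `ψ_risky` (`ψ_safe`) pseudo-counts to `α` (`β`); the post-advice mean is
   `p′ = (α + SI_r·ψ_r)/(α + SI_r·ψ_r + β + SI_s·ψ_s)`.  `ψ = 1`
   reproduces exact Bayesian updating on one observed choice; `ψ = 0`
   ignores advice.  The shift `|p′ − p|` — the susceptibility to social
   influence — increases in `ψ` and decreases in `κ`.
4. **Choice rule.**  `cp = logistic((EU_risk − EU_safe)/τ)` with
   `EU_risk = p′·V^ρ`.  The temperature `τ` is in the same units as
   utility; because utilities scale as `V^ρ`, `τ` and `ρ` trade off, which
   is why `ρ` carries the tightest prior.

Variants: `m0` fixes `ψ = 0` (advice ignored), `m1` fixes `ψ = 1` (ideal
Bayesian), `m2s` ties `ψ_safe = ψ_risky`, `m2` frees both.  All variants run
through one vectorised likelihood, so the nesting relations hold bitwise.

**Numerical choices.**  Choice probabilities are clipped to
`[1e−9, 1−1e−9]` inside log-likelihoods; the logistic uses the numerically
stable `expit`.  The model is static per trial: no learning across trials,
no probability weighting, no loss aversion.

## Identifiability

Both `p` and `p′` are ratios of pseudo-counts, so the likelihood is exactly
invariant to a common rescaling of `(κ_desc, κ_exp, ψ_safe, ψ_risky)`.
Only pseudo-count *ratios* are data-identified; the overall scale is pinned
by the priors (as in the original hierarchical treatment).  Consequences
are quantified in the recovery suite and summarised under *Limitations*.

## Task design

144 trials = 3 reward levels × 6 probabilities × 8 repetitions, randomised
within halves.  The first 72 trials are played alone; the last 72 show
advice.  Description/experience alternates within each half so every
(value, probability, condition, half) cell is balanced (the original order
is not documented; interleaved-balanced is the default and configurable).
Experience trials show 9 predetermined marbles whose winning count is the
nearest integer to `9p`; at exact .5 ties the count alternates floor/ceil
across a cell's repetitions so the cell mean equals `9p`.  Choice coding:
1 = risky, 0 = safe.  Points convert to a bonus at 0.008 €/point.

## Synthetic population

Subject parameters are log-linear in standardized age polynomials (mean 0,
SD 0.5; the quadratic term is orthogonalised against the linear one), with
independent log-normal between-subject dispersion — positivity plus
multiplicative individual differences.  Defaults (intercept at the mean
age ≈ 18; slope per unit of the standardized covariate; dispersion SD on
the log scale):

| parameter | intercept | age slope | age² slope | SD  |
|-----------|-----------|-----------|------------|-----|
| ρ         | 0.95      | −0.08     | −0.02      | 0.15|
| κ_desc    | 8         | 0         | 0          | 0.9 |
| κ_exp     | 3.5       | +0.60     | 0          | 0.9 |
| ψ_safe    | 2         | −0.70     | −0.20      | 0.9 |
| ψ_risky   | 2         | −0.55     | −0.15      | 0.9 |
| τ         | 1.2       | −0.50     | −0.15      | 0.5 |

Rationale: κ_exp < κ_desc (experience carries more uncertainty) and the
slope signs reproduce the reported developmental trends (internal
uncertainty falls with age in experience, social sensitivity and
temperature fall with age, reward sensitivity near-flat).  Dispersions of
~0.9 reflect the described participant heterogeneity (acting on 2 vs 20
marbles).  The temperature intercept of ~1.2 points matches the choice
sensitivity implied by the reported expected-value effect on choices.
Under these defaults a 166-subject study yields mean susceptibility ≈ 0.11,
an experience-minus-description gap ≈ +0.05 and a negative age slope,
consistent in sign and order of magnitude with the reported regression of
`|p′ − p|` on condition and age.

**Advisors.**  The advice shown to a participant is the trial-matched
choice of one advisor drawn from a simulated pool of risk-prone agents
(`ρ ≈ 1.3`, `τ ≈ 1.2`, `ψ = 0`, log-normal heterogeneity).  The matching
rule selects the advisor whose solo-half risky count exceeds the
participant's by exactly 15, relaxing in integer steps when no exact match
exists, and raising an error (never silently under-matching) if even +0
fails.  The pool is deliberately wide (default 60 advisors) so its risky
counts span the participants' range; a pool that does not bracket a
participant's count makes the matching rule fail by construction.
Advisors play the identical 144-trial design, so taking their choice on the
same trial id matches the participant's (value, probability, condition)
cell exactly.  One master seed derives per-subject streams, making datasets
reproducible and order-insensitive.

**What the generator does not emulate:** slider probability estimates,
reaction times, trial-order effects, learning, and any behaviour outside
the model family.  Passing tests therefore validate the pipeline's
statistical machinery under the model's own assumptions, not the model's
adequacy for real participants.

## Inference

**MAP fast path** (`fit_subject_map` / `fit_dataset_map`): per-subject
penalized likelihood on log scales, best of 4 multistarts (first start at
the prior locations, the rest prior draws), L-BFGS-B within ±12 log units.
Priors: `log κ ~ N(log 5, 1)`, `log τ ~ N(0, 1)`, `log ρ ~ N(0, 0.5)`,
`ψ ~ half-N(0, 2)` (optionally log-normal), all overridable.  A Laplace
approximation at the mode supplies posterior draws and the draws × trials
pointwise log-likelihood matrix; the curvature spectrum is floored at 1e−6
before inversion.  One-sided data (all choices identical) and estimates
beyond 8 log units trigger explicit bound-guard warnings.

**Hierarchical path** (`fit_hierarchical`): non-centred subject effects
`u_ij = μ_{g(i)j} + σ_j z_ij` on log scales, age-group means `μ` (default
groups 10–13, 14–17, 18–26; configurable), shared `σ_j ~ half-N(0, 0.5)`,
sampled with an affine-invariant ensemble sampler (walkers ≥ 2·dim + 2,
partitioned into 4 pseudo-chains).  Split-chain R̂ is computed for every
sampled quantity; any R̂ > 1.01 attaches a convergence warning.  Presets:
`desk` (4 × 1000/500) and `paper` (4 × 6000/2000).  At ~40 subjects the
full model has ~260 dimensions and the ensemble sampler mixes slowly; the
test suite exercises the hierarchical contract at smaller sizes
(9–18 subjects, 300–500 iterations) where it behaves well, and the MAP
path is the default for recovery work.

**Age trends** (`fit_age_trend`): OLS of (optionally log) per-subject
estimates on the standardized age polynomials — a least-squares stand-in
for the original multivariate Bayesian regression; coefficients, SEs and
95% intervals are returned.

## Model comparison

PSIS-LOO is computed from the pointwise log-likelihood matrix (delegated to
arviz), summarised as `looic = −2·elpd_loo`; observations are trials.
Pareto-shape values > 0.7 flag unreliable importance weights per trial
(reported, not silently replaced).  A single-draw matrix falls back to the
in-sample sum, explicitly marked non-Bayesian.  `exact_loo_map` refits with
each trial held out and serves as the independent oracle (they agree within
2 SE on 20-trial datasets).  The model-recovery suite simulates at a
clearly-identifiable scale (`ψ = 5`, `κ = 4`, heterogeneity SD 0.3) and
compares `m0/m1/m2`; with `ψ_safe = ψ_risky` generation, `m2s` is
observationally identical to `m2` (the nesting degeneracy), so it is kept
out of the default comparison set.

## Limitations

- Because of the pseudo-count scale invariance, per-subject recovery of
  `κ_exp` and `ψ_safe` at the default population is capped well below the
  recovery quality of `τ`, `ρ` and `ψ_risky`: `κ_exp` is informed only by
  the 36 experience×social trials, and safe advice is shown on only ~25–30%
  of social trials (a direct consequence of the +15-risky advisor matching
  rule).  A reference fit that uses each subject's exact generative
  age-conditional prior — the best any estimator can do — reaches only
  r ≈ 0.4–0.5 for those two parameters at 144 trials, while `τ` and
  `ψ_risky` reach r ≈ 0.7–0.85.  Population-level trends and
  susceptibility statistics are unaffected; per-subject point estimates of
  `κ_exp`/`ψ_safe` should be interpreted with this in mind.
- The ensemble sampler is a general-purpose substitute for gradient-based
  MCMC and is practical only at small hierarchical sizes.
- Synthetic-data results validate machinery, not psychology: effect sizes
  were calibrated to printed summary statistics, not fitted to data.
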