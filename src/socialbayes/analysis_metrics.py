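"""Derived behavioural and model-based statistics.

The headline quantity is susceptibility to social influence: the shift
``|p' - p|`` between the belief mean before and after seeing advice,
evaluated at a subject's parameter estimates on their actual social trials.
A mean shift of 0.2 means the subject acted as if the advised jar were 20
percentage points more likely to deliver the desired outcome.  Because the
shift grows as the belief pseudo-count ``kappa`` shrinks and as the social
weight ``psi`` grows, it aggregates internal uncertainty and social
sensitivity into one interpretable number per subject, condition and advice
type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .model_core import observations_from_frame, posterior_means
from .synthetic_data import standardized_age_polynomials


def _params_frame(fit_or_frame) -> pd.DataFrame:
    if isinstance(fit_or_frame, pd.DataFrame):
        df = fit_or_frame
        if "subject_id" in df.columns:
            df = df.set_index("subject_id")
        return df
    return fit_or_frame.params  # FitResult


def susceptibility(fit, dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-subject belief shifts caused by social information.

    ``fit`` may be a :class:`~socialbayes.inference.FitResult` or a frame of
    per-subject parameters (true generative values work too, which is how
    the estimate-vs-truth consistency of this statistic is tested).  For
    every social trial the prior mean ``p`` and post-advice mean ``p'`` are
    computed at the subject's parameters and aggregated by
    subject x condition x advice into the mean absolute shift and the mean
    signed shift (positive = towards risky).
    """
    params = _params_frame(fit)
    social = dataset[dataset["social"].isin(["safe", "risky"])].copy()
    if social.empty:
        return pd.DataFrame(
            columns=["subject_id", "condition", "advice", "mean_abs_shift", "signed_shift", "n_trials"]
        )
    missing = set(social["subject_id"].unique()) - set(params.index)
    if missing:
        raise ConfigurationError(f"subjects missing from fit: {sorted(missing)}")

    obs = observations_from_frame(social, require_choice=False)
    by_subj = params.loc[social["subject_id"]]
    p_prior, p_post = posterior_means(
        obs,
        kappa_desc=by_subj["kappa_desc"].to_numpy(),
        kappa_exp=by_subj["kappa_exp"].to_numpy(),
        psi_safe=by_subj["psi_safe"].to_numpy(),
        psi_risky=by_subj["psi_risky"].to_numpy(),
    )
    social["abs_shift"] = np.abs(p_post - p_prior)
    social["signed_shift"] = p_post - p_prior
    out = (
        social.groupby(["subject_id", "condition", "social"], observed=True)
        .agg(
            mean_abs_shift=("abs_shift", "mean"),
            signed_shift=("signed_shift", "mean"),
            n_trials=("abs_shift", "size"),
        )
        .reset_index()
        .rename(columns={"social": "advice"})
    )
    return out


def susceptibility_age_trend(susc: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Regression of the absolute belief shift on age and condition.

    Collapses the susceptibility table to subject x condition means of
    ``mean_abs_shift`` and regresses them on standardized age polynomials
    plus an experience indicator (description = 0, experience = 1) by
    ordinary least squares.  Returns the coefficient table.
    """
    import statsmodels.api as sm

    per = (
        susc.groupby(["subject_id", "condition"], observed=True)["mean_abs_shift"]
        .mean()
        .reset_index()
    )
    meta = subjects.set_index("subject_id")
    ages = meta.loc[per["subject_id"], "age"].to_numpy()
    lin, quad = standardized_age_polynomials(ages)
    is_exp = (per["condition"] == "experience").to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([lin, quad, is_exp]))
    fit = sm.OLS(per["mean_abs_shift"].to_numpy(), X).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "z": fit.tvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=pd.Index(["intercept", "age_lin", "age_quad", "experience"], name="term"),
    )


def summarize_behaviour(
    dataset: pd.DataFrame,
    subjects: pd.DataFrame,
    age_bins: tuple[float, ...] = (10.0, 14.0, 18.0, 27.0),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Risky-choice proportions by age bin x condition x social information.

    Confidence intervals are bootstrap 95% intervals over subjects (not
    trials), respecting the repeated-measures structure.  Empty cells are
    reported with missing values rather than dropped.
    """
    if dataset.empty:
        raise ConfigurationError("empty dataset")
    meta = subjects.set_index("subject_id")
    df = dataset.copy()
    df["age"] = meta.loc[df["subject_id"], "age"].to_numpy()
    df["age_bin"] = pd.cut(df["age"], bins=list(age_bins), right=False)
    rng = np.random.default_rng(seed)

    rows = []
    cells = [
        (abin, cond, soc)
        for abin in df["age_bin"].cat.categories
        for cond in sorted(df["condition"].unique())
        for soc in sorted(df["social"].unique())
    ]
    grouped = dict(iter(df.groupby(["age_bin", "condition", "social"], observed=True)))
    for abin, cond, soc in cells:
        grp = grouped.get((abin, cond, soc), df.iloc[0:0])
        if grp.empty:
            rows.append(
                {
                    "age_bin": str(abin),
                    "condition": cond,
                    "social": soc,
                    "n_subjects": 0,
                    "prop_risky": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
            continue
        per_subj = grp.groupby("subject_id")["choice"].mean()
        boots = per_subj.to_numpy()[
            rng.integers(0, len(per_subj), size=(n_boot, len(per_subj)))
        ].mean(axis=1)
        rows.append(
            {
                "age_bin": str(abin),
                "condition": cond,
                "social": soc,
                "n_subjects": len(per_subj),
                "prop_risky": float(per_subj.mean()),
                "ci_low": float(np.quantile(boots, 0.025)),
                "ci_high": float(np.quantile(boots, 0.975)),
            }
        )
    return pd.DataFrame(rows)
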