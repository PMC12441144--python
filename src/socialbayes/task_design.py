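"""Trial structure of the marble-jar lottery task.

Participants repeatedly choose between a safe jar that always pays a fixed
number of points and a risky jar that pays ``value_risky`` points with
probability ``p_win`` (the proportion of blue marbles) and nothing otherwise.
Win probabilities are either displayed exactly (decisions from description,
low external uncertainty) or must be inferred from a short predetermined
sample of marbles (decisions from experience, high external uncertainty).
The first half of the session is played alone; in the second half each trial
additionally shows which jar another person chose.

This module generates that trial structure: the crossed value x probability
design, the solo/social halves, the description/experience split, and the
representative marble sample sequences for experience trials.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DomainError

#: marker for social-block trials whose advice has not been resolved yet
SOCIAL_PENDING = "pending"

CONDITIONS = ("description", "experience")
SOCIAL_LEVELS = ("none", "safe", "risky")
BLOCKS = ("solo", "social")

#: bonus conversion applied to the points total at the end of the session
BONUS_EUR_PER_POINT = 0.008

DESIGN_COLUMNS = [
    "trial_id",
    "block",
    "condition",
    "social",
    "value_risky",
    "p_win",
    "safe_value",
    "sample_sequence",
]


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of the lottery design.

    Defaults reproduce the published task: 3 reward levels x 6 win
    probabilities x 8 repetitions = 144 trials, a 5-point safe jar, and
    9-marble sample sequences on experience trials.
    """

    values: tuple[float, ...] = (8.0, 20.0, 50.0)
    probabilities: tuple[float, ...] = (0.125, 0.25, 0.375, 0.5, 0.625, 0.75)
    repetitions: int = 8
    safe_value: float = 5.0
    n_samples: int = 9

    def __post_init__(self) -> None:
        if self.repetitions <= 0:
            raise ConfigurationError(f"repetitions must be positive, got {self.repetitions}")
        if not self.values or any(v <= 0 for v in self.values):
            raise ConfigurationError(f"reward values must be positive, got {self.values}")
        for p in self.probabilities:
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"win probability {p} outside (0, 1)")
        if self.n_samples < 1:
            raise ConfigurationError(f"n_samples must be >= 1, got {self.n_samples}")

    @property
    def n_trials(self) -> int:
        return len(self.values) * len(self.probabilities) * self.repetitions

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("values", "probabilities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "values": list(self.values),
            "probabilities": list(self.probabilities),
            "repetitions": self.repetitions,
            "safe_value": self.safe_value,
            "n_samples": self.n_samples,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass(frozen=True)
class LotteryTrial:
    """One choice problem between the safe jar and a risky jar."""

    trial_id: int
    block: str
    condition: str
    social: str
    value_risky: float
    p_win: float
    safe_value: float
    sample_sequence: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.block not in BLOCKS:
            raise ConfigurationError(f"unknown block {self.block!r}")
        if self.social not in SOCIAL_LEVELS + (SOCIAL_PENDING,):
            raise ConfigurationError(f"unknown social level {self.social!r}")


def representative_blue_count(p_win: float, n_samples: int, repetition_index: int) -> int:
    """Number of blue (winning) marbles in a representative sample.

    The blue count is the nearest integer to ``n_samples * p_win``.  At an
    exact .5 tie the count alternates floor/ceil across repetitions so that
    the mean count over an even number of repetitions equals ``n * p``
    exactly.
    """
    if not 0.0 < p_win < 1.0:
        raise DomainError(f"p_win {p_win} outside (0, 1)")
    if n_samples < 1:
        raise DomainError(f"n_samples must be >= 1, got {n_samples}")
    target = n_samples * p_win
    frac = target - math.floor(target)
    if abs(frac - 0.5) < 1e-12:
        return math.floor(target) if repetition_index % 2 == 0 else math.ceil(target)
    return int(round(target))


def make_sample_sequence(p_win: float, n_samples: int = 9, repetition_index: int = 0) -> str:
    """Predetermined marble sequence shown on one experience trial.

    Returns a string over {'B', 'R'} of length ``n_samples`` whose blue count
    is as representative of ``p_win`` as an integer count can be.  The order
    is a deterministic function of ``(p_win, n_samples, repetition_index)``
    so the same trial always shows the same sequence.
    """
    blue = representative_blue_count(p_win, n_samples, repetition_index)
    marbles = np.array(list("B" * blue + "R" * (n_samples - blue)))
    # stable arrangement: derived from the arguments only, not global state
    key = (int(round(p_win * 1_000_000)), n_samples, repetition_index)
    rng = np.random.default_rng(np.array(key, dtype=np.uint64))
    return "".join(rng.permutation(marbles))


def build_design(config: DesignConfig | None = None, seed: int = 0) -> list[LotteryTrial]:
    """Build the full randomised trial list.

    Each (value, probability) cell appears exactly ``config.repetitions``
    times.  Repetitions of a cell are split evenly between the solo first
    half and the social second half, and within each half evenly between the
    description and experience conditions (interleaved-balanced).  Social
    trials carry the placeholder label :data:`SOCIAL_PENDING` until advice
    is resolved from a matched advisor.  Trial order within each half is a
    reproducible function of ``seed``.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)

    cells = list(itertools.product(config.values, config.probabilities))
    solo: list[dict] = []
    social: list[dict] = []
    for value, p in cells:
        exp_rep = 0  # experience-repetition counter within the cell, drives tie alternation
        for rep in range(config.repetitions):
            block = "solo" if rep < (config.repetitions + 1) // 2 else "social"
            # alternate conditions within each half
            condition = CONDITIONS[rep % 2]
            seq = ""
            if condition == "experience":
                seq = make_sample_sequence(p, config.n_samples, exp_rep)
                exp_rep += 1
            rec = {
                "block": block,
                "condition": condition,
                "social": "none" if block == "solo" else SOCIAL_PENDING,
                "value_risky": float(value),
                "p_win": float(p),
                "safe_value": float(config.safe_value),
                "sample_sequence": seq,
            }
            (solo if block == "solo" else social).append(rec)

    rng.shuffle(solo)
    rng.shuffle(social)
    trials = [
        LotteryTrial(trial_id=i, **rec) for i, rec in enumerate(itertools.chain(solo, social))
    ]
    return trials


def design_to_frame(trials: Iterable[LotteryTrial]) -> pd.DataFrame:
    """Tabular view of a trial list (columns :data:`DESIGN_COLUMNS`)."""
    df = pd.DataFrame([vars(t) for t in trials])
    return df[DESIGN_COLUMNS]


def frame_to_design(df: pd.DataFrame) -> list[LotteryTrial]:
    df = df.fillna({"sample_sequence": ""})
    return [
        LotteryTrial(
            trial_id=int(row.trial_id),
            block=row.block,
            condition=row.condition,
            social=row.social,
            value_risky=float(row.value_risky),
            p_win=float(row.p_win),
            safe_value=float(row.safe_value),
            sample_sequence=row.sample_sequence or "",
        )
        for row in df.itertuples(index=False)
    ]


def write_design(trials: Iterable[LotteryTrial], path: str | Path) -> None:
    design_to_frame(trials).to_csv(path, index=False)


def read_design(path: str | Path) -> list[LotteryTrial]:
    df = pd.read_csv(path, dtype={"sample_sequence": str}, keep_default_na=False)
    return frame_to_design(df)


def resolve_social(trials: Sequence[LotteryTrial], labels: dict[int, str]) -> list[LotteryTrial]:
    """Return a copy of ``trials`` with pending social labels filled.

    ``labels`` maps trial_id -> {"safe", "risky"} for every social-block
    trial.  Solo trials are left untouched.
    """
    out = []
    for t in trials:
        if t.block == "social":
            lab = labels.get(t.trial_id)
            if lab not in ("safe", "risky"):
                raise ConfigurationError(
                    f"social trial {t.trial_id} needs a 'safe'/'risky' label, got {lab!r}"
                )
            out.append(replace(t, social=lab))
        else:
            out.append(t)
    return out


def bonus_eur(points_total: float, rate: float = BONUS_EUR_PER_POINT) -> float:
    """Monetary bonus in euros for a points total."""
    return points_total * rate
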