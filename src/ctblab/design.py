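"""Deterministic construction of the MCG and MGT session designs.

The Maastricht Choice Game (MCG) is a convex-time-budget task: on each trial
the participant splits a 100-token endowment between an earlier payment at
date ``t`` (tokens multiplied by a discount factor ``d``) and a later payment
at date ``t + k``.  The default design crosses 2 earlier dates x 3 delays x
20 discount factors = 120 unique combinations, each shown twice, for 240
trials in 5 blocks of 48.

The Maastricht Gambling Task (MGT) is a six-box guessing task: one to five of
the six boxes are pink (the rest blue), a token hides in one box, and the
participant guesses its color for a positive payoff (no losses).  The default
session has 250 trials, balanced over the five pink-box counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DISCOUNT_FACTORS",
    "DesignConfig",
    "ConfigError",
    "default_mgt_payoffs",
    "build_mcg_design",
    "build_mgt_design",
    "design_summary",
]

#: The twenty discount factors applied to the earlier option, as used in the task.
DEFAULT_DISCOUNT_FACTORS: tuple[float, ...] = (
    0.50, 0.525, 0.55, 0.575, 0.60, 0.625, 0.65, 0.675, 0.70, 0.725,
    0.75, 0.775, 0.80, 0.825, 0.85, 0.875, 0.90, 0.925, 0.95, 0.99,
)


class ConfigError(ValueError):
    """A design/study configuration violates its invariants."""


def default_mgt_payoffs() -> dict[int, tuple[int, int]]:
    """EV-constant payoff schedule: payoff_pink(n) = round(60/n), blue mirrors.

    With the token hidden uniformly, the expected value of either guess is 10
    points at every pink-box count, so differences in chosen-lottery spread
    are pure risk attitude.
    """
    pink = {n: round(60 / n) for n in range(1, 6)}
    return {n: (pink[n], pink[6 - n]) for n in range(1, 6)}


@dataclass
class DesignConfig:
    """Configuration for one session's MCG + MGT trial designs."""

    earlier_dates: tuple[int, ...] = (0, 35)
    delays: tuple[int, ...] = (35, 72, 90)
    discount_factors: tuple[float, ...] = DEFAULT_DISCOUNT_FACTORS
    repeats: int = 2
    n_blocks: int = 5
    mgt_n_trials: int = 250
    mgt_payoff_schedule: dict[int, tuple[int, int]] = field(
        default_factory=default_mgt_payoffs
    )
    endowment_tokens: int = 100
    box_tokens: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.earlier_dates and self.delays and self.discount_factors):
            raise ConfigError("earlier_dates, delays and discount_factors must be non-empty")
        if self.endowment_tokens <= 0 or self.box_tokens <= 0:
            raise ConfigError("endowment_tokens and box_tokens must be positive")
        if self.endowment_tokens % self.box_tokens:
            raise ConfigError("endowment_tokens must be a positive multiple of box_tokens")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        n_trials = self.repeats * self.n_combos
        if self.n_blocks < 1 or n_trials % self.n_blocks:
            raise ConfigError(
                f"{n_trials} MCG trials cannot be split into {self.n_blocks} equal blocks"
            )
        for d in self.discount_factors:
            if not 0.0 < d < 1.0:
                raise ConfigError(f"discount factor {d} outside (0, 1)")

    @property
    def n_combos(self) -> int:
        return len(self.earlier_dates) * len(self.delays) * len(self.discount_factors)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mgt_payoff_schedule"] = {int(k): list(v) for k, v in self.mgt_payoff_schedule.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        for key in ("earlier_dates", "delays", "discount_factors"):
            if key in d:
                d[key] = tuple(d[key])
        if "mgt_payoff_schedule" in d:
            d["mgt_payoff_schedule"] = {
                int(k): tuple(v) for k, v in d["mgt_payoff_schedule"].items()
            }
        return cls(**d)


def build_mcg_design(config: DesignConfig, seed: int) -> pd.DataFrame:
    """Build the MCG trial table: full (t, k, d) cross, repeated, shuffled, blocked.

    Returns one row per trial with columns ``trial_id``, ``block``, ``t_days``,
    ``k_days``, ``discount_factor``, ``combo_id``, ``presentation_order``.
    The shuffle is a deterministic function of *seed*.
    """
    combos = [
        (t, k, d)
        for t in config.earlier_dates
        for k in config.delays
        for d in config.discount_factors
    ]
    rows = []
    for combo_id, (t, k, d) in enumerate(combos):
        for _ in range(config.repeats):
            rows.append((t, k, d, combo_id))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    block_size = len(rows) // config.n_blocks
    out = pd.DataFrame(
        [rows[i] for i in order],
        columns=["t_days", "k_days", "discount_factor", "combo_id"],
    )
    out.insert(0, "trial_id", np.arange(1, len(rows) + 1))
    out.insert(1, "block", out.index // block_size + 1)
    out["presentation_order"] = np.arange(1, len(rows) + 1)
    return out


def build_mgt_design(config: DesignConfig, seed: int) -> pd.DataFrame:
    """Build the MGT trial table: balanced pink-box counts, shuffled, token hidden.

    ``token_color`` is pink with probability ``n_pink / 6`` independently per
    trial.  Columns: ``trial_id``, ``n_pink``, ``token_color``, ``payoff_pink``,
    ``payoff_blue``.
    """
    if config.mgt_n_trials <= 0:
        raise ConfigError("mgt_n_trials must be positive")
    missing = [n for n in range(1, 6) if n not in config.mgt_payoff_schedule]
    if missing:
        raise ConfigError(f"payoff schedule missing n_pink levels: {missing}")
    rng = np.random.default_rng(seed)
    base, extra = divmod(config.mgt_n_trials, 5)
    n_pink = np.repeat(np.arange(1, 6), base)
    if extra:  # leftover trials spread over seed-chosen levels
        n_pink = np.concatenate([n_pink, rng.choice(np.arange(1, 6), extra, replace=False)])
    rng.shuffle(n_pink)
    token_pink = rng.random(len(n_pink)) < n_pink / 6.0
    sched = config.mgt_payoff_schedule
    return pd.DataFrame(
        {
            "trial_id": np.arange(1, len(n_pink) + 1),
            "n_pink": n_pink,
            "token_color": np.where(token_pink, "pink", "blue"),
            "payoff_pink": [sched[n][0] for n in n_pink],
            "payoff_blue": [sched[n][1] for n in n_pink],
        }
    )


def design_summary(design: pd.DataFrame) -> dict:
    """Summarize a design table (either task) for logging and sanity checks."""
    if design.empty:
        raise ValueError("empty design")
    summary: dict = {"n_trials": int(len(design))}
    if "combo_id" in design.columns:  # MCG
        summary["n_unique"] = int(design["combo_id"].nunique())
        block_sizes = design.groupby("block").size()
        summary["n_blocks"] = int(block_sizes.size)
        summary["block_size"] = int(block_sizes.iloc[0]) if block_sizes.nunique() == 1 else None
    else:  # MGT
        counts = design.groupby("n_pink").size()
        summary["n_unique"] = int(counts.size)
        summary["per_level_counts"] = {int(k): int(v) for k, v in counts.items()}
    return summary
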