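"""Risk-taking score for the six-box gambling task.

The per-trial risk score is the standard deviation of the chosen lottery's
outcome: a guess of a color with win probability ``p`` and payoff ``X`` pays
``X`` with probability ``p`` and 0 otherwise, so its SD is
``X * sqrt(p * (1 - p))``.  Averaging over trials gives each participant's
session risk-taking score; riskier guesses (low-probability, high-payoff
colors) carry a larger spread.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["lottery_sd", "score_trials", "participant_means"]


def lottery_sd(n_pink: int, choice: str, payoffs: Mapping[int, tuple[float, float]]) -> float:
    """SD of the chosen two-point lottery for one trial.

    ``payoffs`` maps n_pink -> (payoff_pink, payoff_blue).
    """
    if not 1 <= n_pink <= 5:
        raise ValueError(f"n_pink must be in 1..5, got {n_pink}")
    payoff_pink, payoff_blue = payoffs[n_pink]
    if choice == "pink":
        p, x = n_pink / 6.0, payoff_pink
    elif choice == "blue":
        p, x = (6 - n_pink) / 6.0, payoff_blue
    else:
        raise ValueError(f"choice must be 'pink' or 'blue', got {choice!r}")
    return float(x) * float(np.sqrt(p * (1.0 - p)))


def score_trials(mgt_table: pd.DataFrame,
                 schedule: Mapping[int, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Per-trial risk scores; one output row per input trial.

    Payoffs come from the table's ``payoff_pink``/``payoff_blue`` columns when
    present, otherwise from ``schedule``.
    """
    for col in ("n_pink", "choice"):
        if col not in mgt_table.columns:
            raise KeyError(f"MGT table missing required column: {col}")
    out = mgt_table.copy()
    if out.empty:
        out["risk_sd"] = pd.Series(dtype=float)
        return out
    n_pink = out["n_pink"].to_numpy(dtype=float)
    if not np.all((n_pink >= 1) & (n_pink <= 5)):
        raise ValueError("n_pink values outside 1..5")
    if {"payoff_pink", "payoff_blue"} <= set(out.columns):
        pp = out["payoff_pink"].to_numpy(dtype=float)
        pb = out["payoff_blue"].to_numpy(dtype=float)
    elif schedule is not None:
        pp = np.array([schedule[int(n)][0] for n in n_pink], dtype=float)
        pb = np.array([schedule[int(n)][1] for n in n_pink], dtype=float)
    else:
        raise KeyError("MGT table has no payoff columns and no schedule was given")
    is_pink = out["choice"].to_numpy() == "pink"
    p = np.where(is_pink, n_pink / 6.0, (6.0 - n_pink) / 6.0)
    x = np.where(is_pink, pp, pb)
    out["risk_sd"] = x * np.sqrt(p * (1.0 - p))
    return out


def participant_means(score_table: pd.DataFrame) -> pd.DataFrame:
    """Mean risk score per participant x session, with trial counts."""
    if score_table.empty:
        raise ValueError("empty score table")
    keys = [c for c in ("participant_id", "group", "session") if c in score_table.columns]
    if not keys:
        raise KeyError("score table has no participant_id/group/session columns")
    grouped = score_table.groupby(keys, sort=True)["risk_sd"]
    out = grouped.agg(mean_risk_sd="mean", n_trials="size").reset_index()
    return out
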