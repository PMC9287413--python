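"""Synthetic-study generator for the two-task design.

Simulates a placebo-controlled two-session study: each agent has CRRA
curvature ``alpha``, present/future bias ``beta``, daily discount factor
``delta``, an allocation-noise SD ``sigma_alloc`` (token units) and a softmax
temperature ``temp`` for the gambling task.  Session-2 parameters shift by a
common session drift (task familiarity), by the treatment effect in the
probiotics group, and - optionally - by a house-money term proportional to
the money received between sessions.

MCG allocations follow the exact data-generating process the Tobit estimator
assumes: latent allocation = structural optimum + normal noise, censored at
0 and the endowment (optionally snapped to the 10-token box grid).  MGT
guesses are softmax over CRRA expected utilities of the two colors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignConfig, ConfigError, build_mcg_design, build_mgt_design
from .tobit import demand_mean, discount_weight

__all__ = [
    "AgentParams",
    "TreatmentEffect",
    "StudyConfig",
    "draw_population",
    "optimal_allocation",
    "simulate_mcg_allocation",
    "simulate_mgt_choice",
    "simulate_study",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("alpha", "beta", "delta", "sigma_alloc", "temp")

# legal parameter ranges
_BOUNDS = {
    "alpha": (1e-3, 1.0),
    "beta": (1e-3, np.inf),
    "delta": (1e-3, 1.0),
    "sigma_alloc": (0.0, np.inf),
    "temp": (1e-3, np.inf),
}

# truncation ranges for simulated populations: delta stays off the delta = 1
# patience boundary, where every allocation is a low corner and (beta, delta)
# are no longer jointly identified from choice data
_SIM_BOUNDS = {**_BOUNDS, "delta": (1e-3, 0.999), "alpha": (1e-3, 0.9999)}


@dataclass
class AgentParams:
    """One simulated participant's preferences (one session)."""

    alpha: float = 0.92
    beta: float = 1.01
    delta: float = 0.995
    sigma_alloc: float = 3.0
    temp: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = _BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside legal range [{lo}, {hi}]")


@dataclass
class TreatmentEffect:
    """Session-2 parameter shifts.

    ``d_*`` apply to the probiotics group only; ``session_drift`` applies to
    every agent in session 2 (familiarity / reference-point change).  Shifted
    values are clipped back into their legal ranges, with clips logged.
    """

    d_alpha: float = 0.0
    d_beta: float = 0.0
    d_delta: float = 0.0
    d_risk_temp: float = 0.0
    session_drift: dict[str, float] = field(default_factory=dict)


@dataclass
class StudyConfig:
    """Full synthetic-study configuration (defaults = study conditions)."""

    n_probiotics: int = 29
    n_placebo: int = 28
    param_means: dict[str, float] = field(default_factory=lambda: {
        "alpha": 0.92, "beta": 1.01, "delta": 0.995, "sigma_alloc": 3.0, "temp": 1.0,
    })
    param_sds: dict[str, float] = field(default_factory=lambda: {
        "alpha": 0.04, "beta": 0.08, "delta": 0.003, "sigma_alloc": 1.0, "temp": 0.3,
    })
    treatment: TreatmentEffect = field(default_factory=TreatmentEffect)
    rounding: str = "continuous"  # or "grid10"
    participation_fee_eur: float = 7.5  # per hour
    session_hours_mean: float = 2.0
    session_hours_sd: float = 0.25
    token_to_eur: float = 0.05
    #: house-money slope: session-2 alpha shift per euro received between sessions
    payment_risk_slope: float = 0.0
    design: DesignConfig = field(default_factory=DesignConfig)
    beta_mode: str = "indicator"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probiotics + self.n_placebo <= 0:
            raise ConfigError("study needs at least one participant")
        if self.n_probiotics < 0 or self.n_placebo < 0:
            raise ConfigError("group sizes must be nonnegative")
        if any(v < 0 for v in self.param_sds.values()):
            raise ConfigError("population SDs must be nonnegative")
        if self.rounding not in ("continuous", "grid10"):
            raise ConfigError(f"unknown rounding mode {self.rounding!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = self.design.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "design" in d and not isinstance(d["design"], DesignConfig):
            d["design"] = DesignConfig.from_dict(d["design"])
        if "treatment" in d and not isinstance(d["treatment"], TreatmentEffect):
            d["treatment"] = TreatmentEffect(**d["treatment"])
        return cls(**d)


def reduced_study_config(n_per_group: int = 10, n_mgt_trials: int = 60,
                         **overrides) -> StudyConfig:
    """A scaled-down study for Monte-Carlo calibration work.

    Halves each group and shrinks both tasks to ~60 trials per session: the
    MGT to ``n_mgt_trials`` and the MCG to a 2 x 3 x 10 cross (every other
    discount factor, one repeat).  All other conditions keep their defaults.
    """
    design = DesignConfig(
        discount_factors=DesignConfig().discount_factors[::2],
        repeats=1, n_blocks=1, mgt_n_trials=n_mgt_trials,
    )
    return StudyConfig(n_probiotics=n_per_group, n_placebo=n_per_group,
                       design=design, **overrides)


def calibrated_treatment() -> TreatmentEffect:
    """Treatment-effect defaults expressing the study's qualitative findings.

    Probiotics in session 2: lower risk appetite (curvature shift toward risk
    aversion), higher future bias, attenuated growth of the daily discount
    factor.  All agents drift slightly future-biased and more patient in
    session 2 (task familiarity).  Magnitudes were fixed once by prospective
    simulation so the signs are reliably expressed at Monte-Carlo scale.
    """
    return TreatmentEffect(
        d_alpha=-0.08, d_beta=0.15, d_delta=-0.004,
        session_drift={"beta": 0.02, "delta": 0.002},
    )


def calibrated_study_config(**overrides) -> StudyConfig:
    """Default study conditions plus the calibrated treatment effects and a
    mild house-money slope (payments between sessions raise session-2 risk
    appetite, as the payment-control analysis expects)."""
    kw = {"treatment": calibrated_treatment(), "payment_risk_slope": 0.0012}
    kw.update(overrides)
    return StudyConfig(**kw)


def _clip_params(df: pd.DataFrame, context: str) -> pd.DataFrame:
    """Truncate parameter columns to their legal ranges, logging clip counts."""
    n_clipped = 0
    for name in PARAM_NAMES:
        lo, hi = _SIM_BOUNDS[name]
        col = df[name]
        bad = (col < lo) | (col > hi)
        n_clipped += int(bad.sum())
        df[name] = col.clip(lo, hi)
    if n_clipped:
        logger.warning("%s: clipped %d parameter values to legal ranges", context, n_clipped)
    return df


def draw_population(config: StudyConfig, seed: int) -> pd.DataFrame:
    """Draw agents and both sessions' parameters (before payment effects).

    Returns one row per participant x session with columns ``participant_id``,
    ``group``, ``session`` and the five parameter columns.  Session-2 values
    are session-1 values plus the common session drift, plus the treatment
    shifts for the probiotics group, truncated to legal ranges.
    """
    n = config.n_probiotics + config.n_placebo
    if n <= 0:
        raise ConfigError("study needs at least one participant")
    rng = np.random.default_rng(seed)
    groups = np.array(["probiotics"] * config.n_probiotics + ["placebo"] * config.n_placebo)
    s1 = pd.DataFrame({"participant_id": np.arange(1, n + 1), "group": groups, "session": 1})
    for name in PARAM_NAMES:
        s1[name] = rng.normal(config.param_means[name], config.param_sds[name], n)
    s1 = _clip_params(s1, "session-1 draws")

    s2 = s1.copy()
    s2["session"] = 2
    drift = config.treatment.session_drift
    for name in PARAM_NAMES:
        s2[name] = s2[name] + drift.get(name, 0.0)
    probi = s2["group"] == "probiotics"
    tr = config.treatment
    s2.loc[probi, "alpha"] += tr.d_alpha
    s2.loc[probi, "beta"] += tr.d_beta
    s2.loc[probi, "delta"] += tr.d_delta
    s2.loc[probi, "temp"] += tr.d_risk_temp
    s2 = _clip_params(s2, "session-2 shifts")
    return pd.concat([s1, s2], ignore_index=True)


def optimal_allocation(params: AgentParams, trial, endowment: float = 100.0,
                       beta_mode: str = "indicator") -> float:
    """Noiseless utility-maximizing tokens on the earlier option.

    For ``alpha < 1`` this is the interior CTB demand; at the risk-neutral
    boundary ``alpha = 1`` utility is linear and the optimum is a corner:
    everything early iff ``d > B`` (ties go to the later option).
    """
    t, k, d = trial["t_days"], trial["k_days"], trial["discount_factor"]
    if params.alpha >= 1.0:
        B = float(discount_weight(params.beta, params.delta, t, k, beta_mode))
        if d > B:
            return float(endowment)
        if d == B:
            logger.info("linear-utility tie (d == B): allocating to the later option")
        return 0.0
    return float(demand_mean(params.alpha, params.beta, params.delta, t, k, d,
                             endowment, beta_mode))


def _mcg_latent_mean(params: AgentParams, design: pd.DataFrame, endowment: float,
                     beta_mode: str) -> np.ndarray:
    if params.alpha >= 1.0:
        B = discount_weight(params.beta, params.delta,
                            design["t_days"].to_numpy(), design["k_days"].to_numpy(),
                            beta_mode)
        return np.where(design["discount_factor"].to_numpy() > B, endowment, 0.0)
    return np.asarray(demand_mean(
        params.alpha, params.beta, params.delta,
        design["t_days"].to_numpy(), design["k_days"].to_numpy(),
        design["discount_factor"].to_numpy(), endowment, beta_mode))


def _simulate_mcg_table(params: AgentParams, design: pd.DataFrame, rng,
                        endowment: float, rounding: str, box_tokens: int,
                        beta_mode: str) -> pd.DataFrame:
    """Vectorized MCG simulation for one agent over a design table."""
    g = _mcg_latent_mean(params, design, endowment, beta_mode)
    latent = g + params.sigma_alloc * rng.standard_normal(len(design))
    tokens = np.clip(latent, 0.0, endowment)
    if rounding == "grid10":
        tokens = np.round(tokens / box_tokens) * box_tokens
    out = design.copy()
    out["tokens_early"] = tokens
    out["tokens_late"] = endowment - tokens
    out["x_t"] = out["discount_factor"] * tokens
    out["x_tk"] = out["tokens_late"]
    return out


def simulate_mcg_allocation(params: AgentParams, trial, rng,
                            endowment: float = 100.0, rounding: str = "continuous",
                            box_tokens: int = 10, beta_mode: str = "indicator") -> dict:
    """Simulate one MCG trial; returns a single choice record as a dict."""
    design = pd.DataFrame([dict(trial)])
    row = _simulate_mcg_table(params, design, rng, endowment, rounding,
                              box_tokens, beta_mode).iloc[0]
    return row.to_dict()


def _mgt_pink_probability(params: AgentParams, n_pink, payoff_pink, payoff_blue):
    """Softmax-over-CRRA-EU probability of guessing pink."""
    n_pink = np.asarray(n_pink, dtype=float)
    eu_pink = (n_pink / 6.0) * np.asarray(payoff_pink, dtype=float) ** params.alpha
    eu_blue = ((6.0 - n_pink) / 6.0) * np.asarray(payoff_blue, dtype=float) ** params.alpha
    return expit((eu_pink - eu_blue) / params.temp)


def _simulate_mgt_table(params: AgentParams, design: pd.DataFrame, rng) -> pd.DataFrame:
    p_pink = _mgt_pink_probability(params, design["n_pink"],
                                   design["payoff_pink"], design["payoff_blue"])
    pick_pink = rng.random(len(design)) < p_pink
    out = design.copy()
    out["choice"] = np.where(pick_pink, "pink", "blue")
    out["won"] = out["choice"] == out["token_color"]
    payoff_chosen = np.where(pick_pink, out["payoff_pink"], out["payoff_blue"])
    out["points"] = np.where(out["won"], payoff_chosen, 0)
    return out


def simulate_mgt_choice(params: AgentParams, trial, rng) -> dict:
    """Simulate one MGT trial; returns a single choice record as a dict."""
    design = pd.DataFrame([dict(trial)])
    return _simulate_mgt_table(params, design, rng).iloc[0].to_dict()


def simulate_study(config: StudyConfig, seed: int
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the full two-session study.

    Returns ``(mcg_table, mgt_table, payments_table)``.  Payments: every
    participant earns a participation fee (hourly rate x session hours); the
    immediate MCG payment comes from one seed-selected session-1 trial and is
    nonzero only when that trial's earlier date is immediate (t = 0), in which
    case it pays ``x_t x token_to_eur``.  When ``payment_risk_slope`` is
    nonzero, session-2 curvature rises with the money received between
    sessions (house-money analogue).
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    pop = draw_population(config, seeds[0])
    design_cfg = config.design
    mcg_designs = {s: build_mcg_design(design_cfg, seeds[1] + s) for s in (1, 2)}
    mgt_designs = {s: build_mgt_design(design_cfg, seeds[2] + s) for s in (1, 2)}
    rng = np.random.default_rng(seeds[3])
    pay_rng = np.random.default_rng(seeds[4])

    participants = pop[pop["session"] == 1][["participant_id", "group"]]
    endow = float(design_cfg.endowment_tokens)

    # ---- session 1 ----
    mcg_rows, mgt_rows = [], []
    session1_mcg: dict[int, pd.DataFrame] = {}
    for _, prow in pop[pop["session"] == 1].iterrows():
        params = AgentParams(**{k: prow[k] for k in PARAM_NAMES})
        mcg = _simulate_mcg_table(params, mcg_designs[1], rng, endow,
                                  config.rounding, design_cfg.box_tokens, config.beta_mode)
        mgt = _simulate_mgt_table(params, mgt_designs[1], rng)
        for df in (mcg, mgt):
            df.insert(0, "participant_id", prow["participant_id"])
            df.insert(1, "group", prow["group"])
            df.insert(2, "session", 1)
        session1_mcg[prow["participant_id"]] = mcg
        mcg_rows.append(mcg)
        mgt_rows.append(mgt)

    # ---- payments between sessions ----
    hours = np.clip(pay_rng.normal(config.session_hours_mean, config.session_hours_sd,
                                   len(participants)), 0.5, None)
    pay_rows = []
    for (pid, grp), hrs in zip(participants.itertuples(index=False), hours):
        mcg1 = session1_mcg[pid]
        sel = mcg1.iloc[pay_rng.integers(len(mcg1))]
        immediate = float(sel["x_t"]) * config.token_to_eur if sel["t_days"] == 0 else 0.0
        pay_rows.append({"participant_id": pid, "group": grp,
                         "payment_eur": immediate,
                         "participation_eur": config.participation_fee_eur * hrs})
    payments = pd.DataFrame(pay_rows)

    # ---- session 2 (house-money shift applied on top of drift/treatment) ----
    pop2 = pop[pop["session"] == 2].merge(
        payments[["participant_id", "payment_eur", "participation_eur"]],
        on="participant_id")
    if config.payment_risk_slope:
        pop2["alpha"] = pop2["alpha"] + config.payment_risk_slope * (
            pop2["payment_eur"] + pop2["participation_eur"])
        pop2 = _clip_params(pop2, "house-money shift")
    for _, prow in pop2.iterrows():
        params = AgentParams(**{k: prow[k] for k in PARAM_NAMES})
        mcg = _simulate_mcg_table(params, mcg_designs[2], rng, endow,
                                  config.rounding, design_cfg.box_tokens, config.beta_mode)
        mgt = _simulate_mgt_table(params, mgt_designs[2], rng)
        for df in (mcg, mgt):
            df.insert(0, "participant_id", prow["participant_id"])
            df.insert(1, "group", prow["group"])
            df.insert(2, "session", 2)
        mcg_rows.append(mcg)
        mgt_rows.append(mgt)

    mcg_table = pd.concat(mcg_rows, ignore_index=True)
    mgt_table = pd.concat(mgt_rows, ignore_index=True)
    return mcg_table, mgt_table, payments
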