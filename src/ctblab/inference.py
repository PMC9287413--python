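"""Group x time treatment inference with linear mixed models.

The treatment question is a classic randomized two-group, two-session
contrast: outcome ~ group + time + group:time with a participant random
intercept (optionally a crossed trial random intercept), fit by REML.  With
treatment (dummy) coding - placebo and session 1 as references - the
interaction coefficient estimates the treatment-specific session-2 shift.

The REML solve is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
this module owns the coding, the covariate handling (house-money payment
controls), the reporting contract, and the Monte-Carlo calibration harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .risk import score_trials
from .simulate import StudyConfig, simulate_study
from .tobit import FitOptions, estimate_all

__all__ = [
    "LMMResult",
    "fit_group_time_lmm",
    "fit_payment_control_lmm",
    "null_and_power",
]

_TERM_LABELS = {
    "Intercept": "intercept",
    "group_probiotics": "group",
    "time2": "time",
    "group_probiotics:time2": "group_time",
    "payment": "payment",
    "participation": "participation",
}


@dataclass
class LMMResult:
    """Fixed-effect table plus variance components from one REML fit."""

    fe_table: pd.DataFrame  # index: term; columns: coef, se, tstat, df, pvalue
    vc: dict
    converged: bool
    formula: str
    notes: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.fe_table.loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.fe_table.loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.fe_table.loc[term, "pvalue"])

    def summary(self) -> str:
        lines = [f"Linear mixed model (REML): {self.formula}",
                 f"  converged: {self.converged}"]
        lines.append(self.fe_table.to_string(float_format=lambda v: f"{v: .4f}"))
        lines.append("  variance components: " +
                     ", ".join(f"{k}={v:.4g}" for k, v in self.vc.items()))
        for k, v in self.notes.items():
            lines.append(f"  note[{k}]: {v}")
        return "\n".join(lines)


def _prepare(data: pd.DataFrame, outcome: str) -> pd.DataFrame:
    for col in (outcome, "group", "session", "participant_id"):
        if col not in data.columns:
            raise KeyError(f"data missing required column: {col}")
    df = data.copy()
    df["group_probiotics"] = (df["group"] == "probiotics").astype(float)
    df["time2"] = (df["session"].astype(int) == 2).astype(float)
    df = df.dropna(subset=[outcome])
    if df.empty:
        raise ValueError(f"no non-missing values of outcome {outcome!r}")
    return df


def _constant_outcome_result(df: pd.DataFrame, outcome: str, terms: list[str],
                             formula: str) -> LMMResult:
    # degenerate case: zero-variance outcome carries no information beyond its level
    fe = pd.DataFrame(
        {"coef": [float(df[outcome].iloc[0])] + [0.0] * (len(terms) - 1),
         "se": 0.0, "tstat": np.nan, "df": np.nan, "pvalue": np.nan},
        index=pd.Index(terms, name="term"))
    return LMMResult(fe, {"participant": 0.0, "residual": 0.0}, True, formula,
                     notes={"degenerate": "constant outcome"})


def fit_group_time_lmm(data: pd.DataFrame, outcome: str,
                       extra_fe: tuple[str, ...] = (),
                       include_trial_re: bool = False,
                       reml: bool = True) -> LMMResult:
    """REML fit of ``outcome ~ group + time + group:time`` (+ covariates).

    Treatment coding with placebo / session-1 references, participant random
    intercept; ``include_trial_re`` adds a crossed trial random intercept via
    variance components (requires a ``trial_id`` column; intended for
    moderate-sized tables).  Zero-variance covariates in ``extra_fe`` are
    dropped (logged in ``notes``), so nested models agree exactly.
    """
    df = _prepare(data, outcome)
    dropped = [c for c in extra_fe if c in df.columns and float(df[c].std()) == 0.0]
    kept = [c for c in extra_fe if c not in dropped]
    for c in kept:
        if c not in df.columns:
            raise KeyError(f"data missing covariate column: {c}")
    rhs = "group_probiotics + time2 + group_probiotics:time2"
    if kept:
        rhs += " + " + " + ".join(kept)
    formula = f"{outcome} ~ {rhs}"
    terms = ["intercept", "group", "time", "group_time"] + kept

    if float(df[outcome].std()) == 0.0:
        res = _constant_outcome_result(df, outcome, terms, formula)
        if dropped:
            res.notes["dropped_covariates"] = dropped
        return res

    if include_trial_re:
        if "trial_id" not in df.columns:
            raise KeyError("include_trial_re requires a trial_id column")
        df["_one"] = 1
        vcf = {"participant": "0 + C(participant_id)", "trial": "0 + C(trial_id)"}
        model = sm.MixedLM.from_formula(formula, groups="_one", vc_formula=vcf, data=df)
    else:
        model = sm.MixedLM.from_formula(formula, groups="participant_id",
                                        re_formula="1", data=df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml)
    fe = fit.fe_params
    se = fit.bse_fe
    n_fe = len(fe)
    resid_df = max(int(fit.nobs) - n_fe, 1)
    raw_terms = list(fe.index)
    labels = [_TERM_LABELS.get(t, t) for t in raw_terms]
    tvals = fe.values / se.values
    table = pd.DataFrame(
        {"coef": fe.values, "se": se.values, "tstat": tvals,
         "df": float(resid_df),
         "pvalue": 2.0 * stats.t.sf(np.abs(tvals), resid_df)},
        index=pd.Index(labels, name="term"))
    if include_trial_re:
        vc = dict(zip(list(model.exog_vc.names), [float(v) for v in fit.vcomp]))
    else:
        vc = {"participant": float(fit.cov_re.iloc[0, 0])}
    vc["residual"] = float(fit.scale)
    notes: dict = {}
    if dropped:
        notes["dropped_covariates"] = dropped
    return LMMResult(table, vc, bool(fit.converged), formula, notes)


def fit_payment_control_lmm(data: pd.DataFrame, payments: pd.DataFrame,
                            outcome: str, reml: bool = True) -> LMMResult:
    """House-money control model: adds between-session payment covariates.

    Payments are received between sessions, so each covariate is coded as the
    euro amount in session-2 rows and zero in session-1 rows; a
    participant-constant coding would be absorbed by the random intercept.
    ``notes`` records whether the time main effect attenuates relative to the
    uncontrolled model.
    """
    for col in ("participant_id", "payment_eur", "participation_eur"):
        if col not in payments.columns:
            raise KeyError(f"payments table missing required column: {col}")
    df = data.merge(payments[["participant_id", "payment_eur", "participation_eur"]],
                    on="participant_id", how="left", validate="many_to_one")
    if df["payment_eur"].isna().any():
        missing = sorted(df.loc[df["payment_eur"].isna(), "participant_id"].unique())
        raise KeyError(f"payments table missing participants: {missing[:5]}")
    s2 = (df["session"].astype(int) == 2).astype(float)
    df["payment"] = df["payment_eur"] * s2
    df["participation"] = df["participation_eur"] * s2
    base = fit_group_time_lmm(df, outcome, reml=reml)
    controlled = fit_group_time_lmm(df, outcome, extra_fe=("payment", "participation"),
                                    reml=reml)
    p_before = base.pvalue("time")
    p_after = (controlled.pvalue("time")
               if "time" in controlled.fe_table.index else np.nan)
    controlled.notes.update({
        "time_p_uncontrolled": p_before,
        "time_p_controlled": p_after,
        "time_attenuated": bool(np.isnan(p_after) or
                                (p_after > p_before and p_after > 0.05)),
    })
    return controlled


def _beta_fit_options(seed: int) -> FitOptions:
    # light options for the Monte-Carlo harness: the likelihood is smooth and
    # unimodal under the simulator's DGP, so few starts suffice
    return FitOptions(n_starts=2, start_jitter_seed=seed)


def _one_replicate(config: StudyConfig, seed: int, outcome: str) -> tuple[float, float]:
    """Simulate one study, run the pipeline, return (interaction coef, p)."""
    mcg, mgt, _ = simulate_study(config, seed)
    if outcome == "risk":
        scored = score_trials(mgt)
        res = fit_group_time_lmm(scored, "risk_sd")
    elif outcome == "beta":
        est = estimate_all(mcg, _beta_fit_options(seed))
        est = est[est["converged"] & est["beta_identified"]]
        res = fit_group_time_lmm(est, "beta_hat")
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return res.coef("group_time"), res.pvalue("group_time")


def _with_effect(config: StudyConfig, outcome: str, effect: float) -> StudyConfig:
    tr = config.treatment
    if outcome == "risk":
        tr = replace(tr, d_alpha=effect)
    else:
        tr = replace(tr, d_beta=effect)
    return replace(config, treatment=tr)


def null_and_power(config: StudyConfig, effect_grid, n_reps: int, seed: int,
                   outcome: str = "risk", alpha_level: float = 0.05,
                   min_reps_for_rates: int = 100) -> pd.DataFrame:
    """Monte-Carlo type-I error / power of the interaction test.

    For each effect size (0 = null) simulates ``n_reps`` studies under
    ``config`` with the treatment shift set on the outcome's natural parameter
    (curvature for risk, present bias for beta), runs the full pipeline, and
    reports the rejection rate of the group x time interaction with its
    Monte-Carlo SE.  Rates are withheld (NaN) below ``min_reps_for_rates``.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for effect in effect_grid:
        cfg = _with_effect(config, outcome, float(effect))
        child = ss.spawn(1)[0]
        rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(n_reps)]
        coefs, pvals = [], []
        for rs in rep_seeds:
            c, p = _one_replicate(cfg, rs, outcome)
            coefs.append(c)
            pvals.append(p)
        pvals = np.asarray(pvals)
        coefs = np.asarray(coefs)
        n_reject = int(np.sum(pvals < alpha_level))
        if n_reps >= min_reps_for_rates:
            rate = n_reject / n_reps
            mc_se = float(np.sqrt(rate * (1 - rate) / n_reps)) if 0 < rate < 1 else \
                float(np.sqrt(alpha_level * (1 - alpha_level) / n_reps))
        else:
            rate, mc_se = np.nan, np.nan
        rows.append({"effect": float(effect), "outcome": outcome, "n_reps": n_reps,
                     "n_reject": n_reject, "rejection_rate": rate, "mc_se": mc_se,
                     "mean_coef": float(np.mean(coefs)),
                     "prop_coef_negative": float(np.mean(coefs < 0)),
                     "prop_coef_positive": float(np.mean(coefs > 0))})
    return pd.DataFrame(rows)
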