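"""Concurrent progressive-ratio co-administration analysis.

Session-level total active responses for a primary substance, recorded
under different secondary-substance conditions (none, FR1, noncontingent,
PR), are compared with random-intercept linear mixed models: one model per
primary substance plus a two-factor omnibus (substance x condition).
Effects are tested by likelihood-ratio chi-square against nested nulls,
with models fitted by maximum likelihood since they differ in fixed
effects.  Breakpoints derived from response totals are available as a
secondary measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .simulate import PRICE_LADDER, VALID_PR_COMBINATIONS

__all__ = [
    "ConditionEffectResult",
    "OmnibusResult",
    "breakpoint_from_responses",
    "condition_means",
    "compare_conditions",
    "omnibus_substance_by_condition",
    "validate_pr_records",
]

BASELINE_CONDITION = "none"


class DegenerateDesignError(ValueError):
    """The condition design cannot support the requested comparison."""


def breakpoint_from_responses(
    total_responses: int, ratio_sequence=PRICE_LADDER
) -> tuple[int, int]:
    """Breakpoint implied by a session's total active responses.

    Responses are consumed greedily by the successive ratio requirements;
    returns ``(last_completed_ratio, reinforcers_earned)`` with a
    breakpoint of 0 when not even the first ratio was completed.
    """
    if total_responses < 0:
        raise ValueError("total_responses must be >= 0")
    seq = list(ratio_sequence)
    if any(b <= a for a, b in zip(seq, seq[1:])) or seq[0] <= 0:
        raise ValueError("ratio_sequence must be increasing positive integers")
    remaining = int(total_responses)
    last = 0
    earned = 0
    for ratio in seq:
        if remaining < ratio:
            break
        remaining -= ratio
        last = ratio
        earned += 1
    return last, earned


def validate_pr_records(records: pd.DataFrame) -> None:
    """Reject combinations outside the seven-cell concurrent design."""
    combos = set(
        zip(records["primary"].astype(str), records["secondary_condition"].astype(str))
    )
    bad = combos - set(VALID_PR_COMBINATIONS)
    if bad:
        raise ValueError(f"invalid primary/secondary combinations: {sorted(bad)}")
    if (records["active_responses"] < 0).any():
        raise ValueError("active_responses must be >= 0")


def condition_means(
    records: pd.DataFrame, last_n_sessions: int = 2
) -> pd.DataFrame:
    """Per subject x combination mean of the last ``last_n_sessions``.

    The first sessions of each combination are protocol acclimation; the
    analysis window is the mean of the final two by default.
    """
    records = records.sort_values("session_index")

    def tail_mean(g):
        return g["active_responses"].tail(last_n_sessions).mean()

    out = (
        records.groupby(["subject", "primary", "secondary_condition"], sort=True)
        .apply(tail_mean, include_groups=False)
        .rename("response")
        .reset_index()
    )
    return out


@dataclass
class ConditionEffectResult:
    """Likelihood-ratio test of a secondary-condition effect on responding."""

    substance: str
    chi_sq: float
    df: int
    p_value: float
    n_subjects: int
    condition_means: pd.Series  # model-implied mean per condition
    contrasts: pd.DataFrame  # vs baseline: estimate, se, z, p, p_holm

    def summary(self) -> str:
        lines = [
            f"Condition effect on responding for {self.substance}",
            f"LRT chi2({self.df}) = {self.chi_sq:.2f}, p = {self.p_value:.4g} "
            f"(n = {self.n_subjects} subjects)",
            "condition means: "
            + ", ".join(f"{k}={v:.1f}" for k, v in self.condition_means.items()),
            "contrasts vs baseline (Holm-adjusted p in last column):",
            self.contrasts.to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)


@dataclass
class OmnibusResult:
    """Sequential LRTs for substance, condition and their interaction."""

    chi_sq_substance: float
    df_substance: int
    p_substance: float
    chi_sq_condition: float
    df_condition: int
    p_condition: float
    chi_sq_interaction: float
    df_interaction: int
    p_interaction: float


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def _fit_ml(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["subject"])
        return model.fit(reml=False)


def _lrt(full, null) -> tuple[float, int, float]:
    chi = max(0.0, 2.0 * (full.llf - null.llf))
    df = int(len(full.fe_params) - len(null.fe_params))
    p = float(stats.chi2.sf(chi, df)) if df > 0 else np.nan
    return float(chi), df, p


def compare_conditions(
    records: pd.DataFrame,
    substance: str,
    baseline: str = BASELINE_CONDITION,
    log1p: bool = False,
    last_n_sessions: int = 2,
) -> ConditionEffectResult:
    """Random-intercept LRT for a condition effect on one substance.

    Fits ``response ~ condition`` with a per-subject random intercept by
    maximum likelihood and compares it to the intercept-only null; reports
    the chi-square with df = #conditions - 1 and Wald contrasts of each
    condition against the substance-alone baseline (raw and Holm-adjusted
    p-values).
    """
    validate_pr_records(records)
    data = condition_means(records, last_n_sessions=last_n_sessions)
    data = data[data["primary"] == substance].copy()
    conditions = sorted(data["secondary_condition"].unique())
    if len(conditions) < 2 or data["subject"].nunique() < 2:
        raise DegenerateDesignError(
            f"need >= 2 conditions and >= 2 subjects for {substance!r}"
        )
    if baseline not in conditions:
        raise DegenerateDesignError(f"baseline condition {baseline!r} absent")
    if log1p:
        data["response"] = np.log1p(data["response"])

    full = _fit_ml(
        f"response ~ C(secondary_condition, Treatment('{baseline}'))", data
    )
    null = _fit_ml("response ~ 1", data)
    chi, df, p = _lrt(full, null)

    rows = []
    for name in full.fe_params.index:
        if name == "Intercept":
            continue
        level = name.split("[T.")[-1].rstrip("]")
        rows.append(
            {
                "condition": level,
                "estimate": full.fe_params[name],
                "se": full.bse_fe[name],
                "z": full.fe_params[name] / full.bse_fe[name],
                "p": 2 * stats.norm.sf(abs(full.fe_params[name] / full.bse_fe[name])),
            }
        )
    contrasts = pd.DataFrame(rows)
    contrasts["p_holm"] = _holm(contrasts["p"].to_numpy())

    intercept = full.fe_params["Intercept"]
    means = {baseline: intercept}
    for row in rows:
        means[row["condition"]] = intercept + row["estimate"]
    means = pd.Series(means).loc[conditions]

    return ConditionEffectResult(
        substance=substance,
        chi_sq=chi,
        df=df,
        p_value=p,
        n_subjects=int(data["subject"].nunique()),
        condition_means=means,
        contrasts=contrasts,
    )


def omnibus_substance_by_condition(
    records: pd.DataFrame, log1p: bool = False, last_n_sessions: int = 2
) -> OmnibusResult:
    """Two-factor sequential LRTs: substance, condition, interaction.

    Models are random-intercept-per-subject, fitted by ML, and compared
    sequentially (null -> +substance -> +condition -> +interaction).
    Degrees of freedom come from the rank of each design, which handles the
    structurally empty ethanol-primary/PR-secondary cell.
    """
    validate_pr_records(records)
    data = condition_means(records, last_n_sessions=last_n_sessions)
    if log1p:
        data["response"] = np.log1p(data["response"])
    # the interaction model is the free seven-cell-mean model
    data["cell"] = data["primary"] + "/" + data["secondary_condition"]

    m0 = _fit_ml("response ~ 1", data)
    m1 = _fit_ml("response ~ C(primary)", data)
    m2 = _fit_ml("response ~ C(primary) + C(secondary_condition)", data)
    m3 = _fit_ml("response ~ C(cell)", data)

    chi_s, df_s, p_s = _lrt(m1, m0)
    chi_c, df_c, p_c = _lrt(m2, m1)
    chi_i, df_i, p_i = _lrt(m3, m2)
    return OmnibusResult(
        chi_sq_substance=chi_s,
        df_substance=df_s,
        p_substance=p_s,
        chi_sq_condition=chi_c,
        df_condition=df_c,
        p_condition=p_c,
        chi_sq_interaction=chi_i,
        df_interaction=df_i,
        p_interaction=p_i,
    )
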