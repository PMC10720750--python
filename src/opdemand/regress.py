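"""Regression tables linking demand indices to each other and to outcomes.

Four analysis families, each returning tidy result tables:

* cross-substance prediction of each demand index from the index of an
  earlier-phase substance (simple standardized regressions, 6 ordered
  substance pairs x 5 indices);
* association of the 10 withdrawal behavioral indices with the essential
  value of ethanol;
* paired baseline-versus-withdrawal t-tests per behavioral metric;
* blood-ethanol-concentration on consumed volume (random-intercept LRT);
* prediction of baseline progressive-ratio responding from demand
  parameters (simple regressions plus an all-parameter multiple OLS).

Simple regressions are computed in closed form on z-scored variables, so
the slope equals the Pearson correlation and F = t^2 with (1, n-2) df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .simulate import STRESS_METRICS

__all__ = [
    "RegressionResult",
    "PairedTestResult",
    "simple_standardized_regression",
    "cross_index_table",
    "stress_association_table",
    "paired_withdrawal_tests",
    "bec_regression",
    "pr_prediction_from_demand",
    "holm_adjust",
]

logger = logging.getLogger(__name__)

DEMAND_INDICES = ("EV", "alpha", "Q0", "Omax", "Pmax")

# ordered pairs: the earlier-phase substance predicts the later one
SUBSTANCE_PAIRS = (
    ("sucrose", "sweetened_ethanol"),
    ("sucrose", "ethanol"),
    ("sucrose", "nicotine"),
    ("sweetened_ethanol", "ethanol"),
    ("sweetened_ethanol", "nicotine"),
    ("ethanol", "nicotine"),
)


@dataclass
class RegressionResult:
    """One predictor -> outcome simple (or multiple) regression row."""

    predictor: str
    outcome: str
    beta: float
    r_squared: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n: int

    def as_row(self) -> dict:
        return {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "beta": self.beta,
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "n": self.n,
        }


@dataclass
class PairedTestResult:
    """Paired t-test per metric; difference is baseline - withdrawal."""

    metric: str
    t_stat: float
    df: int
    p_value: float
    mean_difference: float
    n_pairs: int


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjustment of a p-value vector."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def simple_standardized_regression(
    x, y, predictor: str = "x", outcome: str = "y"
) -> RegressionResult:
    """Closed-form OLS of z-scored y on z-scored x.

    With both variables standardized the slope is the Pearson correlation,
    R^2 its square, and F = t^2 on (1, n-2) df.  Incomplete pairs are
    dropped pairwise; constant input is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    beta = float(np.dot(zx, zy) / (n - 1))  # Pearson r
    r2 = beta**2
    df2 = n - 2
    if 1.0 - r2 < np.finfo(float).tiny:
        f = np.inf
        p = 0.0
    else:
        f = r2 * df2 / (1.0 - r2)
        p = float(stats.f.sf(f, 1, df2))
    return RegressionResult(predictor, outcome, beta, r2, float(f), 1, df2, p, n)


def cross_index_table(
    indices: pd.DataFrame,
    substance_pairs=SUBSTANCE_PAIRS,
    index_names=DEMAND_INDICES,
    min_n: int = 3,
) -> pd.DataFrame:
    """Cross-substance prediction of demand indices.

    For each demand index and each ordered substance pair, regress the
    later-phase substance's index on the earlier one across subjects
    (pairwise-complete; failed fits excluded via ``fit_ok``).  Returns one
    tidy row per (index, pair) — 5 x 6 = 30 with the default design —
    with a Holm-adjusted p column appended per index block.
    """
    ok = indices[indices["fit_ok"].astype(bool)]
    rows = []
    for index_name in index_names:
        wide = ok.pivot(index="subject", columns="substance", values=index_name)
        block = []
        for pred_s, out_s in substance_pairs:
            if pred_s not in wide or out_s not in wide:
                logger.warning("substance missing for pair (%s, %s)", pred_s, out_s)
                continue
            pair = wide[[pred_s, out_s]].dropna()
            if len(pair) < min_n:
                logger.warning(
                    "skipping %s %s->%s: only %d complete subjects",
                    index_name, pred_s, out_s, len(pair),
                )
                continue
            res = simple_standardized_regression(
                pair[pred_s], pair[out_s], predictor=pred_s, outcome=out_s
            )
            row = res.as_row()
            row["index"] = index_name
            block.append(row)
        if block:
            ps = holm_adjust([r["p_value"] for r in block])
            for r, ph in zip(block, ps):
                r["p_holm"] = ph
            rows.extend(block)
    cols = ["index", "predictor", "outcome", "beta", "r_squared",
            "f_stat", "df1", "df2", "p_value", "p_holm", "n"]
    return pd.DataFrame(rows)[cols] if rows else pd.DataFrame(columns=cols)


def stress_association_table(
    ev: pd.Series, stress: pd.DataFrame, metrics=STRESS_METRICS
) -> pd.DataFrame:
    """Regress each withdrawal behavioral index on ethanol essential value.

    ``ev`` is indexed by subject; ``stress`` has a subject column plus one
    column per metric.  Returns 10 tidy rows with raw and Holm-adjusted
    p-values.
    """
    merged = stress.set_index("subject").join(ev.rename("EV"), how="inner")
    rows = []
    for metric in metrics:
        res = simple_standardized_regression(
            merged["EV"], merged[metric], predictor="ethanol_EV", outcome=metric
        )
        rows.append(res.as_row())
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_value"])
    return out


def paired_withdrawal_tests(
    baseline: pd.DataFrame, withdrawal: pd.DataFrame, metrics=STRESS_METRICS
) -> list[PairedTestResult]:
    """Classical paired t-test per metric, difference = baseline - withdrawal."""
    b = baseline.set_index("subject")
    w = withdrawal.set_index("subject")
    common = b.index.intersection(w.index)
    if len(common) < 2:
        raise ValueError("need >= 2 matched subjects")
    results = []
    for metric in metrics:
        d = (b.loc[common, metric] - w.loc[common, metric]).to_numpy(float)
        n = len(d)
        se = d.std(ddof=1) / np.sqrt(n)
        if se > 0:
            t = float(d.mean() / se)
        else:  # constant difference: t degenerates to 0 or +-inf
            t = 0.0 if d.mean() == 0 else float(np.inf * np.sign(d.mean()))
        p = float(2 * stats.t.sf(abs(t), n - 1))
        results.append(PairedTestResult(metric, t, n - 1, p, float(d.mean()), n))
    return results


def bec_regression(bec: pd.DataFrame) -> dict:
    """Blood ethanol concentration regressed on consumed volume.

    Fits a per-subject random-intercept model (ML) and reports the
    likelihood-ratio chi-square(1) for the volume slope against the
    intercept-only null, plus the marginal R^2 (variance of the fixed-
    effect prediction over total variance).  When every subject has a
    single measurement the random intercept is unidentified and the
    function falls back to OLS with a logged notice.
    """
    repeated = bec.groupby("subject").size().max() >= 2
    if repeated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm(
                "concentration ~ volume", bec, groups=bec["subject"]
            ).fit(reml=False)
            null = smf.mixedlm(
                "concentration ~ 1", bec, groups=bec["subject"]
            ).fit(reml=False)
        chi = max(0.0, 2.0 * (full.llf - null.llf))
        p = float(stats.chi2.sf(chi, 1))
        fixed_pred = full.fe_params["Intercept"] + full.fe_params["volume"] * bec["volume"]
        var_f = float(np.var(fixed_pred, ddof=0))
        var_u = float(full.cov_re.iloc[0, 0])
        var_e = float(full.scale)
        r2_marginal = var_f / (var_f + var_u + var_e)
        slope = float(full.fe_params["volume"])
        method = "mixed_lrt"
    else:
        logger.info("single measurement per subject; falling back to OLS")
        ols = smf.ols("concentration ~ volume", bec).fit()
        null = smf.ols("concentration ~ 1", bec).fit()
        chi = max(0.0, 2.0 * (ols.llf - null.llf))
        p = float(stats.chi2.sf(chi, 1))
        r2_marginal = float(ols.rsquared)
        slope = float(ols.params["volume"])
        method = "ols_fallback"
    return {
        "chi_sq": float(chi),
        "df": 1,
        "p_value": p,
        "r_squared_marginal": float(r2_marginal),
        "slope": slope,
        "n_obs": int(len(bec)),
        "n_subjects": int(bec["subject"].nunique()),
        "method": method,
    }


def pr_prediction_from_demand(
    indices: pd.DataFrame,
    pr_baseline: pd.DataFrame,
    substance: str,
    index_names=DEMAND_INDICES,
) -> tuple[pd.DataFrame, dict]:
    """Predict baseline PR responding from demand parameters.

    ``pr_baseline`` has columns subject, response (total active responses
    at the substance-alone PR baseline).  Each demand parameter is tested
    in a simple standardized regression; a multiple OLS with all
    parameters gives the joint R^2.  A large design condition number is
    reported as a warning flag rather than an error.
    """
    ok = indices[(indices["substance"] == substance) & indices["fit_ok"].astype(bool)]
    merged = ok.set_index("subject").join(
        pr_baseline.set_index("subject")["response"], how="inner"
    )
    rows = []
    for name in index_names:
        res = simple_standardized_regression(
            merged[name], merged["response"],
            predictor=f"{substance}_{name}", outcome="pr_response",
        )
        rows.append(res.as_row())
    simple = pd.DataFrame(rows)
    simple["p_holm"] = holm_adjust(simple["p_value"])

    X = merged[list(index_names)].apply(
        lambda c: (c - c.mean()) / c.std(ddof=1)
    )
    y = (merged["response"] - merged["response"].mean()) / merged["response"].std(ddof=1)
    cond = float(np.linalg.cond(X.to_numpy()))
    if cond > 1e6:
        logger.warning("ill-conditioned demand-parameter design (cond=%.3g)", cond)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    multiple = {
        "substance": substance,
        "r_squared": float(fit.rsquared),
        "f_stat": float(fit.fvalue),
        "df1": int(fit.df_model),
        "df2": int(fit.df_resid),
        "p_value": float(fit.f_pvalue),
        "condition_number": cond,
        "n": int(len(merged)),
    }
    return simple, multiple
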