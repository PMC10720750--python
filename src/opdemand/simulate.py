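"""Synthetic study generator.

Emulates a long-access rodent self-administration study of sucrose,
sweetened ethanol, ethanol and nicotine: per-subject demand curves on the
15-step between-session fixed-ratio ladder with the "failing to earn at
least one reinforcer" stopping rule, lognormal individual variation in Q0
and alpha with configurable cross-substance correlation of log-alpha,
withdrawal behavioral indices (elevated plus-maze and open field) linearly
coupled to the true essential value of ethanol, blood-ethanol-concentration
measurements with a per-subject random intercept, and concurrent
progressive-ratio co-administration sessions with multiplicative condition
effects.

The generator keeps its ground truth, so parameter-recovery and calibration
checks can close the loop on every downstream analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .demand import DemandCurveData, DemandParams, essential_value, predict_log_consumption

__all__ = [
    "PRICE_LADDER",
    "SUBSTANCES",
    "VALID_PR_COMBINATIONS",
    "EPM_METRICS",
    "OF_METRICS",
    "STRESS_METRICS",
    "CohortSpec",
    "StudyBundle",
    "default_price_ladder",
    "simulate_demand_curve",
    "simulate_cohort",
]

# Between-session FR escalation ladder; also the PR sequence used in
# concurrent sessions.
PRICE_LADDER = (1, 3, 5, 8, 12, 18, 26, 38, 58, 86, 130, 195, 292, 438, 657)

SUBSTANCES = ("sucrose", "sweetened_ethanol", "ethanol", "nicotine")

# The seven valid (primary substance, secondary condition) combinations of
# the concurrent design: nicotine-primary sessions add a PR-secondary
# ethanol condition that has no ethanol-primary counterpart.
VALID_PR_COMBINATIONS = (
    ("nicotine", "none"),
    ("nicotine", "FR1"),
    ("nicotine", "noncontingent"),
    ("nicotine", "PR"),
    ("ethanol", "none"),
    ("ethanol", "FR1"),
    ("ethanol", "noncontingent"),
)

EPM_METRICS = (
    "epm_distance",
    "epm_speed",
    "epm_freezing_episodes",
    "epm_freezing_time",
    "epm_open_arm_time",
)
OF_METRICS = (
    "of_distance",
    "of_speed",
    "of_freezing_episodes",
    "of_freezing_time",
    "of_center_time",
)
STRESS_METRICS = EPM_METRICS + OF_METRICS


def default_price_ladder() -> tuple[int, ...]:
    """The 15-step FR/PR requirement sequence."""
    return PRICE_LADDER


def _default_alpha_corr() -> np.ndarray:
    """Cross-substance correlation of log-alpha.

    Nonzero entries mirror the coupled elasticity pattern the analyses are
    meant to detect: sucrose with sweetened ethanol, sweetened ethanol with
    ethanol, ethanol with nicotine.
    """
    corr = np.eye(4)
    pairs = {(0, 1): 0.45, (1, 2): 0.60, (2, 3): 0.70}
    for (i, j), r in pairs.items():
        corr[i, j] = corr[j, i] = r
    return corr


# Withdrawal indices: (baseline mean, baseline sd, withdrawal mean,
# correlation with true ethanol EV, marginal sd in withdrawal).  Locomotor
# measures drop in withdrawal and correlate negatively with EV; freezing
# measures rise and correlate positively; open-arm/center time is weakly
# coupled.
_DEFAULT_WITHDRAWAL = {
    "epm_distance": (25.0, 4.0, 21.0, -0.67, 4.0),
    "epm_speed": (4.2, 0.7, 3.6, -0.67, 0.7),
    "epm_freezing_episodes": (8.0, 3.0, 12.0, 0.65, 3.0),
    "epm_freezing_time": (40.0, 15.0, 60.0, 0.70, 15.0),
    "epm_open_arm_time": (60.0, 20.0, 45.0, 0.31, 20.0),
    "of_distance": (30.0, 5.0, 26.0, -0.49, 5.0),
    "of_speed": (5.0, 0.8, 4.4, -0.50, 0.8),
    "of_freezing_episodes": (6.0, 2.5, 8.0, 0.20, 2.5),
    "of_freezing_time": (30.0, 12.0, 42.0, 0.46, 12.0),
    "of_center_time": (50.0, 18.0, 42.0, 0.10, 18.0),
}

# Multiplicative condition effects on PR responding for the primary
# substance: nicotine at low cost (FR1) or noncontingently boosts ethanol
# responding; low-cost ethanol suppresses nicotine responding.
_DEFAULT_CONDITION_EFFECTS = {
    ("ethanol", "none"): 1.0,
    ("ethanol", "FR1"): 1.5,
    ("ethanol", "noncontingent"): 1.4,
    ("nicotine", "none"): 1.0,
    ("nicotine", "FR1"): 0.6,
    ("nicotine", "noncontingent"): 1.0,
    ("nicotine", "PR"): 1.0,
}


@dataclass
class CohortSpec:
    """Full generative description of one synthetic study.

    Lognormal parameters are natural-log location/scale of Q0 (dose units
    per 12-h session) and alpha.  ``dose_per_reinforcer`` converts model
    consumption to earned reinforcers for the stopping rule (g/kg per
    5-s sipper access for the liquid reinforcers; 0.03 mg/kg per infusion
    for nicotine).  ``n_missing`` drops that many subjects from a
    substance's data (catheter-failure analogue), reproducing unequal n
    across analyses.
    """

    n_subjects: int = 19
    substances: tuple[str, ...] = SUBSTANCES
    price_ladder: tuple[int, ...] = PRICE_LADDER
    k_true: float = 2.0
    mu_log_q0: dict = field(
        default_factory=lambda: {
            "sucrose": np.log(3.0),
            "sweetened_ethanol": np.log(1.5),
            "ethanol": np.log(1.0),
            "nicotine": np.log(1.5),
        }
    )
    sd_log_q0: dict = field(
        default_factory=lambda: {s: 0.30 for s in SUBSTANCES}
    )
    mu_log_alpha: dict = field(
        default_factory=lambda: {
            "sucrose": np.log(5e-4),
            "sweetened_ethanol": np.log(2e-3),
            "ethanol": np.log(5e-3),
            "nicotine": np.log(1e-3),
        }
    )
    sd_log_alpha: dict = field(
        default_factory=lambda: {s: 0.50 for s in SUBSTANCES}
    )
    alpha_corr: np.ndarray = field(default_factory=_default_alpha_corr)
    noise_sd_log10: float = 0.05
    dose_per_reinforcer: dict = field(
        default_factory=lambda: {
            "sucrose": 0.06,
            "sweetened_ethanol": 0.03,
            "ethanol": 0.02,
            "nicotine": 0.03,
        }
    )
    n_missing: dict = field(default_factory=lambda: {"nicotine": 4})
    withdrawal_model: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_WITHDRAWAL.items()}
    )
    bec_intercept: float = 10.0
    bec_slope: float = 60.0  # mg/dl per g/kg consumed
    bec_subject_sd: float = 12.0
    bec_noise_sd: float = 28.0
    bec_tests_per_subject: int = 2
    condition_effects: dict = field(
        default_factory=lambda: dict(_DEFAULT_CONDITION_EFFECTS)
    )
    pr_base_responses: dict = field(
        default_factory=lambda: {"ethanol": 200.0, "nicotine": 250.0}
    )
    pr_ev_coupling: float = 1.0  # d log(responses) / d log(EV)
    pr_subject_sd: float = 0.30  # log-scale subject effect beyond EV
    pr_session_sd: float = 0.20  # log-scale session-to-session noise
    n_sessions_per_condition: int = 5
    seed: int = 0

    def __post_init__(self):
        self.alpha_corr = np.asarray(self.alpha_corr, dtype=float)
        m = len(self.substances)
        if self.alpha_corr.shape != (m, m):
            raise ValueError("alpha_corr must be square over substances")
        if not np.allclose(self.alpha_corr, self.alpha_corr.T):
            raise ValueError("alpha_corr must be symmetric")
        if not np.allclose(np.diag(self.alpha_corr), 1.0):
            raise ValueError("alpha_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.alpha_corr).min() < -1e-10:
            raise ValueError("alpha_corr must be positive semi-definite")
        if np.any(np.diff(np.asarray(self.price_ladder)) <= 0):
            raise ValueError("price_ladder must be strictly increasing")
        if self.noise_sd_log10 < 0:
            raise ValueError("noise_sd_log10 must be >= 0")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["alpha_corr"] = self.alpha_corr.tolist()
        d["substances"] = list(self.substances)
        d["price_ladder"] = list(self.price_ladder)
        d["withdrawal_model"] = {k: list(v) for k, v in self.withdrawal_model.items()}
        d["condition_effects"] = {
            f"{p}|{s}": v for (p, s), v in self.condition_effects.items()
        }
        for key in ("mu_log_q0", "sd_log_q0", "mu_log_alpha", "sd_log_alpha"):
            d[key] = {k: float(v) for k, v in d[key].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "seed" not in d:
            raise ValueError("cohort spec file must state a seed")
        d["substances"] = tuple(d["substances"])
        d["price_ladder"] = tuple(d["price_ladder"])
        d["alpha_corr"] = np.asarray(d["alpha_corr"], dtype=float)
        d["withdrawal_model"] = {k: tuple(v) for k, v in d["withdrawal_model"].items()}
        d["condition_effects"] = {
            tuple(k.split("|")): v for k, v in d["condition_effects"].items()
        }
        return cls(**d)


@dataclass
class StudyBundle:
    """All tables of one simulated study plus the generating truth."""

    spec: CohortSpec
    demand: pd.DataFrame          # subject, substance, price, reinforcers, consumption
    truth: pd.DataFrame           # subject, substance, Q0_true, alpha_true, EV_true
    stress_baseline: pd.DataFrame  # subject + 10 metric columns
    stress_withdrawal: pd.DataFrame
    bec: pd.DataFrame             # subject, test, volume, concentration
    pr_sessions: pd.DataFrame     # subject, primary, secondary_condition, session_index, active_responses

    TABLE_NAMES = (
        "demand",
        "truth",
        "stress_baseline",
        "stress_withdrawal",
        "bec",
        "pr_sessions",
    )

    def to_csvs(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in self.TABLE_NAMES:
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def simulate_demand_curve(
    truth: DemandParams,
    ladder=PRICE_LADDER,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    dose_per_reinforcer: float | None = None,
    subject_id: str = "sim",
    substance: str = "sim",
) -> tuple[DemandCurveData, np.ndarray]:
    """Simulate one between-session demand series.

    Returns the series and the aligned earned-reinforcer counts (NaN when
    no dose conversion is given).

    Consumption at each price is ``10**(predicted log10 + N(0, noise_sd))``.
    When ``dose_per_reinforcer`` is given, earned reinforcers are
    ``floor(consumption / dose)`` and the ladder stops at the first price
    where fewer than one reinforcer is earned; that terminal session is
    recorded with zero consumption (the stopping-rule session exists in the
    data and is handled downstream by the fit's zero policy).
    """
    rng = rng or np.random.default_rng()
    ladder = np.asarray(ladder, dtype=float)
    # draw the full noise vector up front so truncation does not perturb
    # the stream for later prices of other curves
    eps = rng.normal(0.0, noise_sd, size=len(ladder)) if noise_sd > 0 else np.zeros(len(ladder))
    prices, cons, reinf = [], [], []
    for i, price in enumerate(ladder):
        q = 10.0 ** (predict_log_consumption(truth, price) + eps[i])
        if dose_per_reinforcer is not None:
            n = int(np.floor(q / dose_per_reinforcer))
            if n < 1:
                prices.append(price)
                cons.append(0.0)
                reinf.append(0)
                break
            reinf.append(n)
        else:
            reinf.append(np.nan)
        prices.append(price)
        cons.append(q)
    return DemandCurveData(
        subject_id=subject_id,
        substance=substance,
        prices=np.asarray(prices),
        consumption=np.asarray(cons),
        responses=None,
    ), np.asarray(reinf, dtype=float)


def _draw_parameters(spec: CohortSpec, rng: np.random.Generator):
    m = len(spec.substances)
    sd = np.array([spec.sd_log_alpha[s] for s in spec.substances])
    mu = np.array([spec.mu_log_alpha[s] for s in spec.substances])
    cov = spec.alpha_corr * np.outer(sd, sd)
    log_alpha = rng.multivariate_normal(mu, cov, size=spec.n_subjects, method="svd")
    log_q0 = np.column_stack(
        [
            rng.normal(spec.mu_log_q0[s], spec.sd_log_q0[s], size=spec.n_subjects)
            for s in spec.substances
        ]
    )
    return np.exp(log_q0), np.exp(log_alpha)


def _missing_subjects(spec: CohortSpec, rng: np.random.Generator) -> dict[str, set]:
    out: dict[str, set] = {s: set() for s in spec.substances}
    for subst, n_miss in spec.n_missing.items():
        if subst in out and n_miss > 0:
            idx = rng.choice(spec.n_subjects, size=min(n_miss, spec.n_subjects), replace=False)
            out[subst] = set(int(i) for i in idx)
    return out


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> StudyBundle:
    """Generate a full study bundle from a cohort specification.

    A single seed governs every stochastic stage through independent child
    streams (parameters, demand noise, missingness, withdrawal, BEC, PR),
    so identical spec + seed yields byte-identical tables.
    """
    seed = spec.seed if seed is None else seed
    children = np.random.SeedSequence(seed).spawn(6)
    rng_par, rng_dem, rng_miss, rng_wd, rng_bec, rng_pr = (
        np.random.default_rng(c) for c in children
    )

    subjects = [f"R{i+1:03d}" for i in range(spec.n_subjects)]
    q0s, alphas = _draw_parameters(spec, rng_par)
    missing = _missing_subjects(spec, rng_miss)

    truth_rows, demand_rows = [], []
    ev_true = {}  # (subject_idx, substance) -> EV
    for j, subst in enumerate(spec.substances):
        for i, subj in enumerate(subjects):
            q0, alpha = q0s[i, j], alphas[i, j]
            ev = essential_value(alpha, spec.k_true)
            ev_true[(i, subst)] = ev
            if i in missing[subst]:
                continue
            truth_rows.append(
                {"subject": subj, "substance": subst, "Q0_true": q0,
                 "alpha_true": alpha, "EV_true": ev}
            )
            curve, reinf = simulate_demand_curve(
                DemandParams(q0, alpha, spec.k_true),
                ladder=spec.price_ladder,
                noise_sd=spec.noise_sd_log10,
                rng=rng_dem,
                dose_per_reinforcer=spec.dose_per_reinforcer[subst],
                subject_id=subj,
                substance=subst,
            )
            for p, c, r in zip(curve.prices, curve.consumption, reinf):
                demand_rows.append(
                    {"subject": subj, "substance": subst, "price": p,
                     "reinforcers": r, "consumption": c}
                )

    demand = pd.DataFrame(demand_rows)
    truth = pd.DataFrame(truth_rows)

    # -- withdrawal behavioral indices (coupled to true ethanol EV) ---------
    ev_eth = np.array([ev_true[(i, "ethanol")] for i in range(spec.n_subjects)])
    # moments of EV implied by the lognormal alpha model, used to convert
    # target correlations into slopes on the EV scale
    sd_la = spec.sd_log_alpha["ethanol"]
    ev_med = essential_value(np.exp(spec.mu_log_alpha["ethanol"]), spec.k_true)
    ev_mean = ev_med * np.exp(sd_la**2 / 2.0)
    ev_sd = ev_mean * np.sqrt(np.expm1(sd_la**2))

    base_rows, wd_rows = [], []
    for i, subj in enumerate(subjects):
        brow, wrow = {"subject": subj}, {"subject": subj}
        for metric, (b_mean, b_sd, w_mean, rho, w_sd) in spec.withdrawal_model.items():
            brow[metric] = rng_wd.normal(b_mean, b_sd)
            slope = rho * w_sd / ev_sd
            resid_sd = w_sd * np.sqrt(max(0.0, 1.0 - rho**2))
            mu = w_mean + slope * (ev_eth[i] - ev_mean)
            wrow[metric] = mu + rng_wd.normal(0.0, resid_sd)
        base_rows.append(brow)
        wd_rows.append(wrow)
    stress_baseline = pd.DataFrame(base_rows)
    stress_withdrawal = pd.DataFrame(wd_rows)

    # -- blood ethanol concentration ---------------------------------------
    bec_rows = []
    for i, subj in enumerate(subjects):
        u = rng_bec.normal(0.0, spec.bec_subject_sd)
        for t in range(spec.bec_tests_per_subject):
            vol = rng_bec.uniform(0.3, 2.0)  # g/kg consumed before sampling
            conc = (
                spec.bec_intercept
                + spec.bec_slope * vol
                + u
                + rng_bec.normal(0.0, spec.bec_noise_sd)
            )
            bec_rows.append(
                {"subject": subj, "test": t + 1, "volume": vol,
                 "concentration": max(conc, 0.0)}
            )
    bec = pd.DataFrame(bec_rows)

    # -- concurrent PR co-administration sessions --------------------------
    log_ev_mean = {
        subst: np.log(essential_value(np.exp(spec.mu_log_alpha[subst]), spec.k_true))
        for subst in ("ethanol", "nicotine")
    }
    pr_rows = []
    for i, subj in enumerate(subjects):
        subj_eff = {
            subst: rng_pr.normal(0.0, spec.pr_subject_sd)
            for subst in ("ethanol", "nicotine")
        }
        for primary, secondary in VALID_PR_COMBINATIONS:
            involves_nicotine = primary == "nicotine" or secondary != "none"
            if involves_nicotine and i in missing.get("nicotine", set()):
                # catheter failure removes every nicotine-involving session
                continue
            mult = spec.condition_effects[(primary, secondary)]
            base = np.log(spec.pr_base_responses[primary])
            coupling = spec.pr_ev_coupling * (
                np.log(ev_true[(i, primary)]) - log_ev_mean[primary]
            )
            for sess in range(1, spec.n_sessions_per_condition + 1):
                mu = base + coupling + subj_eff[primary] + np.log(mult)
                resp = np.exp(mu + rng_pr.normal(0.0, spec.pr_session_sd))
                pr_rows.append(
                    {
                        "subject": subj,
                        "primary": primary,
                        "secondary_condition": secondary,
                        "session_index": sess,
                        "active_responses": int(np.round(resp)),
                    }
                )
    pr_sessions = pd.DataFrame(pr_rows)

    return StudyBundle(
        spec=spec,
        demand=demand,
        truth=truth,
        stress_baseline=stress_baseline,
        stress_withdrawal=stress_withdrawal,
        bec=bec,
        pr_sessions=pr_sessions,
    )
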