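"""Monte-Carlo calibration and power utilities.

Each routine simulates many small studies from the generator and pushes
them through the corresponding analysis, measuring operating
characteristics: type-I error of the condition likelihood-ratio test under
a null generator, power to detect a condition effect of known size, and
detection/false-positive rates of the cross-substance elasticity
regression.  They are used by the test suite and the acceptance script;
all randomness flows from the supplied seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demand import DemandParams
from .pr import compare_conditions
from .regress import simple_standardized_regression
from .simulate import CohortSpec, simulate_cohort

__all__ = [
    "null_condition_spec",
    "lrt_type1_rate",
    "condition_contrast_power",
    "alpha_correlation_detection_rate",
]


def _pr_only_spec(n_subjects: int, condition_effects: dict | None, seed: int) -> CohortSpec:
    spec = CohortSpec(n_subjects=n_subjects, seed=seed, n_missing={})
    if condition_effects is not None:
        spec.condition_effects = condition_effects
    return spec


def null_condition_spec(n_subjects: int = 20, seed: int = 0) -> CohortSpec:
    """Generator with every condition multiplier at 1 (no condition effect)."""
    effects = {k: 1.0 for k in CohortSpec().condition_effects}
    return _pr_only_spec(n_subjects, effects, seed)


def lrt_type1_rate(
    n_sims: int = 500,
    n_subjects: int = 20,
    substance: str = "nicotine",
    alpha_level: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the condition LRT under the null generator."""
    root = np.random.SeedSequence(seed)
    rejections = 0
    for child in root.spawn(n_sims):
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        spec = null_condition_spec(n_subjects, seed=sim_seed)
        bundle = simulate_cohort(spec)
        res = compare_conditions(bundle.pr_sessions, substance)
        rejections += res.p_value < alpha_level
    return rejections / n_sims


def condition_contrast_power(
    n_sims: int = 200,
    n_subjects: int = 15,
    substance: str = "ethanol",
    condition: str = "FR1",
    effect: float = 1.5,
    alpha_level: float = 0.05,
    seed: int = 0,
) -> float:
    """Power of the baseline contrast for one boosted condition.

    The generator applies a multiplicative ``effect`` to responding for
    ``substance`` under ``condition`` (all other multipliers 1); success is
    a positive contrast with p < alpha_level.
    """
    root = np.random.SeedSequence(seed)
    hits = 0
    for child in root.spawn(n_sims):
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        effects = {k: 1.0 for k in CohortSpec().condition_effects}
        effects[(substance, condition)] = effect
        spec = _pr_only_spec(n_subjects, effects, sim_seed)
        bundle = simulate_cohort(spec)
        res = compare_conditions(bundle.pr_sessions, substance)
        row = res.contrasts[res.contrasts["condition"] == condition].iloc[0]
        sign_ok = row["estimate"] > 0 if effect > 1 else row["estimate"] < 0
        hits += sign_ok and row["p"] < alpha_level
    return hits / n_sims


def alpha_correlation_detection_rate(
    n_sims: int = 200,
    n_subjects: int = 19,
    rho: float = 0.8,
    pair: tuple[str, str] = ("ethanol", "nicotine"),
    alpha_level: float = 0.05,
    seed: int = 0,
) -> float:
    """Detection rate of an imposed cross-substance log-alpha correlation.

    Simulates cohorts whose log-alpha correlation between the two
    substances is ``rho`` (all other off-diagonals 0), fits nothing —
    the regression runs on the true alphas, isolating the statistical step
    from fit error — and counts significant simple regressions.  With
    ``rho=0`` this measures the false-positive rate.
    """
    substances = list(CohortSpec().substances)
    i, j = substances.index(pair[0]), substances.index(pair[1])
    corr = np.eye(len(substances))
    corr[i, j] = corr[j, i] = rho
    root = np.random.SeedSequence(seed)
    hits = 0
    for child in root.spawn(n_sims):
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        spec = CohortSpec(n_subjects=n_subjects, seed=sim_seed, n_missing={})
        spec.alpha_corr = corr
        bundle = simulate_cohort(spec)
        wide = bundle.truth.pivot(index="subject", columns="substance", values="alpha_true")
        res = simple_standardized_regression(wide[pair[0]], wide[pair[1]])
        hits += res.p_value < alpha_level
    return hits / n_sims
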