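"""End-to-end orchestration: simulate or ingest, fit, and tabulate.

``run`` executes the full analysis under one configuration and seed:
generate (or read) the study tables, choose the shared span constant k,
fit every demand curve, then produce the cross-index, stress-association,
paired-withdrawal, BEC and PR condition/prediction tables.  Every output
is a CSV; a JSON manifest records the seed, the chosen k, row counts,
SHA-256 checksums and any skipped stages, so a rerun with the same
configuration is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import choose_k, demand_table_to_curves, fit_cohort
from .demand import FitConfig
from .pr import compare_conditions, condition_means, omnibus_substance_by_condition
from .regress import (
    bec_regression,
    cross_index_table,
    paired_withdrawal_tests,
    pr_prediction_from_demand,
    stress_association_table,
)
from .simulate import STRESS_METRICS, CohortSpec, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run", "validate_inputs"]

logger = logging.getLogger(__name__)

DEMAND_SCHEMA = ["subject", "substance", "price", "reinforcers", "consumption"]
STRESS_SCHEMA = ["subject", *STRESS_METRICS]
BEC_SCHEMA = ["subject", "test", "volume", "concentration"]
PR_SCHEMA = ["subject", "primary", "secondary_condition", "session_index", "active_responses"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass
class RunConfig:
    """One pipeline run: simulate a cohort or analyze supplied CSVs."""

    mode: str = "simulate"  # 'simulate' | 'analyze'
    outdir: str | Path = "opdemand_run"
    seed: int = 0
    cohort_spec: CohortSpec | None = None  # simulate mode
    demand_csv: str | Path | None = None  # analyze mode inputs
    stress_baseline_csv: str | Path | None = None
    stress_withdrawal_csv: str | Path | None = None
    bec_csv: str | Path | None = None
    pr_csv: str | Path | None = None
    fit_config: FitConfig = field(default_factory=FitConfig)
    k_policy: str = "span_plus_half"
    k_value: float | None = None

    def __post_init__(self):
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.mode == "simulate" and self.cohort_spec is None:
            self.cohort_spec = CohortSpec(seed=self.seed)
        if self.mode == "analyze" and self.demand_csv is None:
            raise ValueError("analyze mode requires at least a demand CSV")


@dataclass
class ValidationReport:
    violations: list  # (table, row index or None, message)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(tables: dict[str, pd.DataFrame]) -> ValidationReport:
    """Schema, type, monotone-price and duplicate-key checks.

    Hard schema violations (missing columns) raise; soft violations are
    listed with the offending row index.
    """
    schemas = {
        "demand": DEMAND_SCHEMA,
        "stress_baseline": STRESS_SCHEMA,
        "stress_withdrawal": STRESS_SCHEMA,
        "bec": BEC_SCHEMA,
        "pr_sessions": PR_SCHEMA,
    }
    violations = []
    for name, df in tables.items():
        want = schemas.get(name)
        if want is None:
            continue
        missing = [c for c in want if c not in df.columns]
        if missing:
            raise PipelineError(f"[validate:{name}] missing columns {missing}")
    demand = tables.get("demand")
    if demand is not None:
        for i in demand.index[demand["consumption"] < 0]:
            violations.append(("demand", int(i), "negative consumption"))
        for i in demand.index[demand["price"] < 1]:
            violations.append(("demand", int(i), "price below 1"))
        for (subj, subst), g in demand.groupby(["subject", "substance"]):
            p = g["price"].to_numpy()
            if np.any(np.diff(p) <= 0):
                violations.append(
                    ("demand", int(g.index[0]),
                     f"non-monotone or duplicate prices for {subj}/{subst}")
                )
    bec = tables.get("bec")
    if bec is not None:
        dup = bec.duplicated(["subject", "test"])
        for i in bec.index[dup]:
            violations.append(("bec", int(i), "duplicate subject/test key"))
        for i in bec.index[bec["volume"] < 0]:
            violations.append(("bec", int(i), "negative volume"))
    pr = tables.get("pr_sessions")
    if pr is not None:
        for i in pr.index[pr["active_responses"] < 0]:
            violations.append(("pr_sessions", int(i), "negative responses"))
    return ValidationReport(violations)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "opdemand_version": __version__,
        "stages": [],
        "skipped": [],
        "warnings": [],
        "outputs": {},
        "counts": {},
    }

    # -- stage: obtain tables ----------------------------------------------
    tables: dict[str, pd.DataFrame | None] = {}
    if config.mode == "simulate":
        spec = config.cohort_spec
        bundle = simulate_cohort(spec, seed=config.seed)
        datadir = outdir / "data"
        bundle.to_csvs(datadir)
        for name in bundle.TABLE_NAMES:
            tables[name] = getattr(bundle, name)
        manifest["stages"].append("simulate")
    else:
        readers = {
            "demand": config.demand_csv,
            "stress_baseline": config.stress_baseline_csv,
            "stress_withdrawal": config.stress_withdrawal_csv,
            "bec": config.bec_csv,
            "pr_sessions": config.pr_csv,
        }
        for name, path in readers.items():
            if path is None or not Path(path).exists():
                tables[name] = None
                if path is not None:
                    manifest["warnings"].append(f"input {name} not found: {path}")
            else:
                tables[name] = pd.read_csv(path)
        manifest["stages"].append("ingest")

    report = validate_inputs({k: v for k, v in tables.items() if v is not None})
    manifest["validation_violations"] = [
        {"table": t, "row": r, "message": m} for t, r, m in report.violations
    ]
    manifest["stages"].append("validate")

    # -- stage: shared k and demand fits -----------------------------------
    demand = tables.get("demand")
    if demand is None:
        raise PipelineError("[fit] no demand table available")
    try:
        curves = demand_table_to_curves(demand)
        k = choose_k(curves, policy=config.k_policy, value=config.k_value)
        indices = fit_cohort(curves, k=k, config=config.fit_config)
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError(f"[fit] {exc}") from exc
    manifest["k"] = k
    manifest["counts"]["demand_rows"] = int(len(demand))
    manifest["counts"]["curves_fit"] = int(len(indices))
    manifest["counts"]["fit_failures"] = int((~indices["fit_ok"].astype(bool)).sum())
    _write_csv(indices, outdir / "indices.csv")
    manifest["stages"].append("fit")

    # -- stage: cross-index table ------------------------------------------
    cross = cross_index_table(indices)
    _write_csv(cross, outdir / "cross_indices.csv")
    manifest["counts"]["cross_index_rows"] = int(len(cross))
    manifest["stages"].append("cross_indices")

    # -- stage: withdrawal analyses ----------------------------------------
    sb, sw = tables.get("stress_baseline"), tables.get("stress_withdrawal")
    ev = (
        indices[(indices["substance"] == "ethanol") & indices["fit_ok"].astype(bool)]
        .set_index("subject")["EV"]
    )
    if sw is not None and not ev.empty:
        stress = stress_association_table(ev, sw)
        _write_csv(stress, outdir / "stress_associations.csv")
        manifest["counts"]["stress_rows"] = int(len(stress))
        manifest["stages"].append("stress_associations")
    else:
        manifest["skipped"].append("stress_associations")
    if sb is not None and sw is not None:
        paired = paired_withdrawal_tests(sb, sw)
        _write_csv(
            pd.DataFrame([dataclasses.asdict(r) for r in paired]),
            outdir / "withdrawal_paired_tests.csv",
        )
        manifest["stages"].append("withdrawal_paired_tests")
    else:
        manifest["skipped"].append("withdrawal_paired_tests")

    # -- stage: BEC ---------------------------------------------------------
    bec = tables.get("bec")
    if bec is not None:
        res = bec_regression(bec)
        _write_csv(pd.DataFrame([res]), outdir / "bec_regression.csv")
        manifest["stages"].append("bec_regression")
    else:
        manifest["skipped"].append("bec_regression")

    # -- stage: PR condition effects and demand prediction ------------------
    pr = tables.get("pr_sessions")
    if pr is not None:
        cond_rows = []
        for substance in ("ethanol", "nicotine"):
            try:
                res = compare_conditions(pr, substance)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"[pr_conditions:{substance}] {exc}") from exc
            for _, crow in res.contrasts.iterrows():
                cond_rows.append(
                    {
                        "substance": substance,
                        "chi_sq": res.chi_sq,
                        "df": res.df,
                        "p_value": res.p_value,
                        "condition": crow["condition"],
                        "contrast_estimate": crow["estimate"],
                        "contrast_p": crow["p"],
                        "contrast_p_holm": crow["p_holm"],
                        "n_subjects": res.n_subjects,
                    }
                )
        _write_csv(pd.DataFrame(cond_rows), outdir / "pr_condition_effects.csv")
        omni = omnibus_substance_by_condition(pr)
        _write_csv(pd.DataFrame([dataclasses.asdict(omni)]), outdir / "pr_omnibus.csv")
        manifest["stages"].append("pr_conditions")

        baseline = condition_means(pr)
        simple_rows, multi_rows = [], []
        for substance in ("ethanol", "nicotine"):
            base = baseline[
                (baseline["primary"] == substance)
                & (baseline["secondary_condition"] == "none")
            ][["subject", "response"]]
            try:
                simple, multiple = pr_prediction_from_demand(indices, base, substance)
            except ValueError as exc:
                manifest["warnings"].append(f"pr_prediction {substance}: {exc}")
                continue
            simple_rows.append(simple)
            multi_rows.append(multiple)
        if simple_rows:
            _write_csv(pd.concat(simple_rows), outdir / "pr_demand_prediction.csv")
            _write_csv(pd.DataFrame(multi_rows), outdir / "pr_demand_prediction_multiple.csv")
            manifest["stages"].append("pr_prediction")
    else:
        manifest["skipped"].extend(["pr_conditions", "pr_prediction"])

    # -- manifest ------------------------------------------------------------
    for p in sorted(outdir.rglob("*.csv")):
        manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
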