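"""Cohort-level demand fitting: shared-k selection and index tabulation.

Essential values are only comparable across substances when every curve is
fitted under the same span constant ``k``, so ``k`` is chosen once from the
pooled study and reused for every fit.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .demand import (
    DemandCurveData,
    DemandError,
    DemandModel,
    FitConfig,
    InsufficientDataError,
)

__all__ = ["choose_k", "fit_cohort", "demand_table_to_curves"]

INDEX_COLUMNS = [
    "subject",
    "substance",
    "Q0",
    "alpha",
    "EV",
    "Omax",
    "Pmax",
    "r_squared",
    "fit_ok",
    "flags",
    "n_points",
]


def demand_table_to_curves(df: pd.DataFrame) -> list[DemandCurveData]:
    """Split a long demand table into per-(subject, substance) series."""
    curves = []
    for (subj, subst), g in df.groupby(["subject", "substance"], sort=True):
        g = g.sort_values("price")
        curves.append(
            DemandCurveData(
                subject_id=str(subj),
                substance=str(subst),
                prices=g["price"].to_numpy(float),
                consumption=g["consumption"].to_numpy(float),
            )
        )
    return curves


def choose_k(
    datasets: Iterable[DemandCurveData],
    policy: str = "span_plus_half",
    value: float | None = None,
) -> float:
    """Select the shared log10-consumption span constant ``k``.

    Policies
    --------
    ``'span_plus_half'`` (default)
        k = [max - min of log10 mean consumption, pooled over all
        (substance, price) cells with positive mean] + 0.5.  Averaging
        across subjects first keeps one noisy session from dictating the
        span.
    ``'fixed'``
        Echo ``value``.
    ``'shared_nls'``
        Estimate k as one extra parameter shared across all curves in a
        joint nonlinear least-squares problem (per-curve Q0 and alpha).
    """
    if policy == "fixed":
        if value is None or not (np.isfinite(value) and value > 0):
            raise DemandError("fixed k policy requires a positive value")
        return float(value)

    curves = list(datasets)
    if not curves:
        raise DemandError("no datasets supplied")

    if policy == "span_plus_half":
        rows = []
        for c in curves:
            for p, q in zip(c.prices, c.consumption):
                rows.append((c.substance, p, q))
        tab = pd.DataFrame(rows, columns=["substance", "price", "consumption"])
        means = tab.groupby(["substance", "price"])["consumption"].mean()
        means = means[means > 0]
        if means.empty:
            raise DemandError("all consumption zero; cannot choose k")
        logm = np.log10(means.to_numpy())
        return float(logm.max() - logm.min() + 0.5)

    if policy == "shared_nls":
        usable = []
        for c in curves:
            keep = c.consumption > 0
            if keep.sum() >= 3:
                usable.append((c.prices[keep], np.log10(c.consumption[keep])))
        if not usable:
            raise DemandError("no curve with >= 3 positive points")
        n = len(usable)

        # parameters: log q0_i (n), log alpha_i (n), log k (1)
        def resid(theta):
            lq0, lal, lk = theta[:n], theta[n : 2 * n], theta[-1]
            k = np.exp(lk)
            out = []
            for i, (prices, logq) in enumerate(usable):
                q0, al = np.exp(lq0[i]), np.exp(lal[i])
                pred = np.log10(q0) + k * (np.exp(-al * q0 * prices) - 1.0)
                out.append(pred - logq)
            return np.concatenate(out)

        x0 = np.concatenate(
            [
                [lq[0] * np.log(10) for _, lq in usable],  # q0 ~ first point
                np.full(n, np.log(1e-3)),
                [np.log(2.0)],
            ]
        )
        sol = optimize.least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise DemandError("shared-k joint fit did not converge")
        return float(np.exp(sol.x[-1]))

    raise DemandError(f"unknown k policy {policy!r}")


def fit_cohort(
    data: pd.DataFrame | Sequence[DemandCurveData],
    k: float | None = None,
    k_policy: str = "span_plus_half",
    k_value: float | None = None,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Fit every subject x substance demand curve under one shared ``k``.

    Returns one row per series with the fitted parameters and derived
    indices (columns: subject, substance, Q0, alpha, EV, Omax, Pmax,
    r_squared, fit_ok, flags, n_points).  Series that cannot be fitted
    (too few usable points, solver failure) are carried as flagged rows
    with ``fit_ok=False`` rather than dropped.

    The chosen ``k`` is attached as ``result.attrs['k']``.
    """
    curves = data if not isinstance(data, pd.DataFrame) else demand_table_to_curves(data)
    curves = list(curves)
    if k is None:
        k = choose_k(curves, policy=k_policy, value=k_value)
    config = config or FitConfig()

    rows = []
    for c in curves:
        try:
            res = DemandModel(c, k=k, config=config).fit()
            rows.append(res.indices())
        except InsufficientDataError:
            omax = float(np.max(c.prices * c.consumption))
            pmax = float(c.prices[int(np.argmax(c.prices * c.consumption))])
            rows.append(
                {
                    "subject": c.subject_id,
                    "substance": c.substance,
                    "Q0": np.nan,
                    "alpha": np.nan,
                    "EV": np.nan,
                    "Omax": omax,
                    "Pmax": pmax,
                    "r_squared": np.nan,
                    "fit_ok": False,
                    "flags": "insufficient_data",
                    "n_points": int(np.sum(c.consumption > 0)),
                }
            )
    out = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    out.attrs["k"] = float(k)
    return out
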