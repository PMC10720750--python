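"""Exponential operant demand model.

Implements the Hursh–Silberberg exponential demand equation

    log10 Q = log10 Q0 + k * (exp(-alpha * Q0 * C) - 1)

where ``Q`` is consumption at unit price ``C`` (the fixed-ratio response
requirement per reinforcer), ``Q0`` is demand intensity (consumption at zero
price), ``alpha`` is demand elasticity (rate of decline of log consumption
with price) and ``k`` is a constant fixing the log10 span of consumption.
``k`` must be shared across every fit whose essential values will be
compared.

The model is fitted by nonlinear least squares on log10-transformed
consumption.  A fitted curve yields the standard behavioral-economic
indices: essential value ``EV = 1/(100 * alpha * k**1.5)``, maximum
expenditure ``Omax`` and the price of maximum expenditure ``Pmax``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LN10",
    "DemandCurveData",
    "DemandParams",
    "FitConfig",
    "DemandModel",
    "DemandFitResults",
    "DemandError",
    "InsufficientDataError",
    "predict_log_consumption",
    "predict_consumption",
    "elasticity",
    "essential_value",
    "empirical_omax_pmax",
    "analytic_pmax",
]

LN10 = np.log(10.0)


class DemandError(ValueError):
    """Invalid demand-model input."""


class InsufficientDataError(DemandError):
    """Fewer usable price/consumption points than parameters require."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemandCurveData:
    """One subject x substance consumption-versus-price series.

    Prices are fixed-ratio requirements (responses per reinforcer) and must
    be strictly increasing and >= 1.  Consumption is the dose earned per
    session (g/kg or mg/kg), aligned with ``prices``.  ``responses`` is the
    optional active-manipulandum count per session.
    """

    subject_id: str
    substance: str
    prices: np.ndarray
    consumption: np.ndarray
    responses: np.ndarray | None = None

    def __post_init__(self):
        prices = np.asarray(self.prices, dtype=float)
        consumption = np.asarray(self.consumption, dtype=float)
        object.__setattr__(self, "prices", prices)
        object.__setattr__(self, "consumption", consumption)
        if prices.ndim != 1 or consumption.shape != prices.shape:
            raise DemandError("prices and consumption must be 1-D and aligned")
        if len(prices) == 0:
            raise DemandError("empty demand series")
        if not np.all(np.isfinite(prices)) or not np.all(np.isfinite(consumption)):
            raise DemandError("non-finite price or consumption")
        if np.any(np.diff(prices) <= 0):
            raise DemandError("prices must be strictly increasing")
        if np.any(prices < 1):
            raise DemandError("all prices must be >= 1 (FR requirement)")
        if np.any(consumption < 0):
            raise DemandError("consumption must be nonnegative")
        if self.responses is not None:
            responses = np.asarray(self.responses, dtype=float)
            if responses.shape != prices.shape or np.any(responses < 0):
                raise DemandError("responses must align with prices and be >= 0")
            object.__setattr__(self, "responses", responses)

    def __len__(self) -> int:
        return len(self.prices)


@dataclass(frozen=True)
class DemandParams:
    """Parameters of one exponential demand curve (positive Q0, alpha, k)."""

    q0: float
    alpha: float
    k: float

    def __post_init__(self):
        for name in ("q0", "alpha", "k"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DemandError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class FitConfig:
    """Solver and preprocessing controls for demand-curve fitting.

    zero_policy: 'drop' removes zero-consumption sessions (the terminal
    session under the stopping rule) before the log transform; a positive
    float replaces zeros with that value instead.
    """

    zero_policy: str | float = "drop"
    alpha_init: float = 1e-3
    q0_init: float | None = None  # default: consumption at lowest price
    max_iter: int = 10000
    tol: float = 1e-12
    q0_bound: float = 1e-12
    alpha_bound: float = 1e-12

    def __post_init__(self):
        if isinstance(self.zero_policy, str):
            if self.zero_policy != "drop":
                raise DemandError("zero_policy must be 'drop' or a positive float")
        elif not (np.isfinite(self.zero_policy) and self.zero_policy > 0):
            raise DemandError("zero replacement value must be > 0")
        if self.tol <= 0:
            raise DemandError("tol must be > 0")


# ---------------------------------------------------------------------------
# model function and closed-form indices
# ---------------------------------------------------------------------------


def predict_log_consumption(params: DemandParams, price) -> np.ndarray | float:
    """log10 predicted consumption at the given price(s).

    Strictly decreasing in price; equals ``log10 Q0`` at price 0 and tends
    to ``log10 Q0 - k`` as price grows without bound.
    """
    c = np.asarray(price, dtype=float)
    if not np.all(np.isfinite(c)) or np.any(c < 0):
        raise DemandError("price must be finite and >= 0")
    out = np.log10(params.q0) + params.k * (
        np.exp(-params.alpha * params.q0 * c) - 1.0
    )
    return out if out.ndim else float(out)


def predict_consumption(params: DemandParams, price):
    """Predicted consumption (raw scale) at the given price(s)."""
    return 10.0 ** np.asarray(predict_log_consumption(params, price))


def elasticity(params: DemandParams, price):
    """Point elasticity d(log10 Q)/d(log10 C) of the demand curve.

    Equals -k*ln(10)*alpha*Q0*C*exp(-alpha*Q0*C); demand is inelastic
    (elasticity > -1) at low prices and crosses -1 at Pmax.
    """
    c = np.asarray(price, dtype=float)
    u = params.alpha * params.q0 * c
    out = -params.k * LN10 * u * np.exp(-u)
    return out if out.ndim else float(out)


def essential_value(params_or_alpha, k: float | None = None) -> float:
    """Essential value EV = 1/(100 * alpha * k**1.5).

    EV is inversely proportional to elasticity alpha and quantifies a
    reinforcer's capacity to maintain responding as its price rises.  Only
    EVs computed under the same k are comparable.
    """
    if isinstance(params_or_alpha, DemandParams):
        alpha, k = params_or_alpha.alpha, params_or_alpha.k
    else:
        alpha = params_or_alpha
        if k is None:
            raise DemandError("k required when alpha passed as a scalar")
    if not (np.isfinite(alpha) and alpha > 0):
        raise DemandError("alpha must be > 0")
    if not (np.isfinite(k) and k > 0):
        raise DemandError("k must be > 0")
    return 1.0 / (100.0 * alpha * k**1.5)


def empirical_omax_pmax(data: DemandCurveData) -> tuple[float, float, bool]:
    """Maximum observed expenditure and its price.

    Expenditure at each price is price x consumption; ``Omax`` is the
    largest expenditure and ``Pmax`` the price at which it occurs.  Ties
    resolve toward the lower price (conservative estimate of the inelastic
    range).  Returns ``(omax, pmax, degenerate)`` where ``degenerate`` marks
    an all-zero series (Omax 0 at the lowest price).
    """
    expenditure = data.prices * data.consumption
    i = int(np.argmax(expenditure))  # first max = lowest price on ties
    degenerate = bool(np.all(data.consumption == 0))
    return float(expenditure[i]), float(data.prices[i]), degenerate


def analytic_pmax(params: DemandParams) -> float:
    """Model-based Pmax: the price where elasticity first reaches -1.

    With u = alpha*Q0*C the unit-elasticity condition is
    k*ln(10)*u*exp(-u) = 1, solved on u in (0, 1] (the ascending branch of
    u*exp(-u), where expenditure peaks).  Requires k*ln(10) > e, i.e. a
    model that actually becomes elastic; otherwise raises.
    """
    a = params.k * LN10
    f = lambda u: a * u * np.exp(-u) - 1.0
    if f(1.0) <= 0:  # peak of u*exp(-u) never reaches 1/(k ln10)
        raise DemandError(
            f"no unit-elasticity point: k={params.k} too small (k*ln10 <= e)"
        )
    u = optimize.brentq(f, 1e-14, 1.0, xtol=1e-14, rtol=8.9e-16)
    return u / (params.alpha * params.q0)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class DemandModel:
    """Exponential demand model for one consumption-versus-price series.

    Parameters
    ----------
    data : DemandCurveData
        The observed series.
    k : float
        Fixed log10-consumption span shared across the analysis (see
        :func:`opdemand.cohort.choose_k`).
    config : FitConfig, optional
        Preprocessing and solver controls.

    ``fit()`` estimates ``(Q0, alpha)`` by least squares on log10
    consumption with ``k`` held fixed and returns :class:`DemandFitResults`.
    """

    def __init__(self, data: DemandCurveData, k: float, config: FitConfig | None = None):
        if not (np.isfinite(k) and k > 0):
            raise DemandError("k must be finite and > 0")
        self.data = data
        self.k = float(k)
        self.config = config or FitConfig()
        self._prices, self._logq = self._prepare()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        k: float,
        subject: str | None = None,
        substance: str | None = None,
        config: FitConfig | None = None,
    ) -> "DemandModel":
        """Build from a long demand table (columns subject, substance, price,
        consumption); optionally select one subject x substance series."""
        sub = df
        if subject is not None:
            sub = sub[sub["subject"].astype(str) == str(subject)]
        if substance is not None:
            sub = sub[sub["substance"] == substance]
        if sub.empty:
            raise DemandError("no rows for requested subject/substance")
        sub = sub.sort_values("price")
        data = DemandCurveData(
            subject_id=str(sub["subject"].iloc[0]),
            substance=str(sub["substance"].iloc[0]),
            prices=sub["price"].to_numpy(float),
            consumption=sub["consumption"].to_numpy(float),
        )
        return cls(data, k=k, config=config)

    def _prepare(self) -> tuple[np.ndarray, np.ndarray]:
        prices = self.data.prices
        cons = self.data.consumption.copy()
        if isinstance(self.config.zero_policy, str):  # 'drop'
            keep = cons > 0
            prices, cons = prices[keep], cons[keep]
        else:
            cons[cons == 0] = float(self.config.zero_policy)
        return prices, np.log10(cons) if len(cons) else np.empty(0)

    @property
    def nobs(self) -> int:
        """Number of usable points after the zero policy."""
        return len(self._prices)

    def loglike_profile_sse(self, q0: float, alpha: float) -> float:
        """Sum of squared log10 residuals at the given parameters."""
        pred = predict_log_consumption(DemandParams(q0, alpha, self.k), self._prices)
        return float(np.sum((self._logq - pred) ** 2))

    def fit(self) -> "DemandFitResults":
        """Nonlinear least-squares fit of (Q0, alpha) on the log10 scale.

        Raises :class:`InsufficientDataError` below 3 usable points; solver
        non-convergence is returned as a flagged (``converged=False``)
        result, never as silent NaN.
        """
        if self.nobs < 3:
            raise InsufficientDataError(
                f"need >= 3 usable points, have {self.nobs} "
                f"(subject={self.data.subject_id!r}, substance={self.data.substance!r})"
            )
        cfg = self.config
        q0_init = cfg.q0_init
        if q0_init is None:
            q0_init = max(10.0 ** self._logq[0], cfg.q0_bound * 10)
        k = self.k

        def f(c, q0, alpha):
            return np.log10(q0) + k * (np.exp(-alpha * q0 * c) - 1.0)

        flags: set[str] = set()
        converged = True
        popt = np.array([np.nan, np.nan])
        pcov = np.full((2, 2), np.nan)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    f,
                    self._prices,
                    self._logq,
                    p0=[q0_init, cfg.alpha_init],
                    bounds=([cfg.q0_bound, cfg.alpha_bound], [np.inf, np.inf]),
                    maxfev=cfg.max_iter,
                    xtol=cfg.tol,
                    ftol=cfg.tol,
                    gtol=cfg.tol,
                    method="trf",
                )
            if not np.all(np.isfinite(popt)):
                converged = False
        except RuntimeError:
            converged = False

        sst = float(np.sum((self._logq - self._logq.mean()) ** 2))
        if converged:
            params = DemandParams(float(popt[0]), float(popt[1]), k)
            sse = self.loglike_profile_sse(params.q0, params.alpha)
            if sst < 1e-10:
                # flat series: alpha collapses to its bound, the fit is exact
                flags.add("flat")
                rsq = 1.0 if sse < 1e-10 else -np.inf
            else:
                rsq = 1.0 - sse / sst
            if popt[1] <= cfg.alpha_bound * 10:
                flags.add("alpha_at_bound")
        else:
            params = None
            rsq = np.nan
            flags.add("not_converged")
        return DemandFitResults(self, params, pcov, rsq, converged, flags)


class DemandFitResults:
    """Results of an exponential demand fit.

    Exposes the fitted parameters (``params``), their standard errors on the
    fitted scale (``bse``), the log-scale ``rsquared``, the derived demand
    indices (``ev``, ``omax``, ``pmax``, ``pmax_analytic``), convergence
    flags, and a ``summary()`` table.
    """

    def __init__(self, model, params, pcov, rsquared, converged, flags):
        self.model = model
        self.demand_params: DemandParams | None = params
        self.cov_params = np.asarray(pcov, dtype=float)
        self.rsquared = rsquared
        self.converged = bool(converged)
        self.flags = frozenset(flags)

    # -- parameter accessors ------------------------------------------------
    @property
    def params(self) -> pd.Series:
        p = self.demand_params
        vals = [np.nan, np.nan] if p is None else [p.q0, p.alpha]
        return pd.Series(vals, index=["Q0", "alpha"])

    @property
    def bse(self) -> pd.Series:
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(self.cov_params))
        return pd.Series(se, index=["Q0", "alpha"])

    @property
    def nobs(self) -> int:
        return self.model.nobs

    # -- derived indices ----------------------------------------------------
    @property
    def ev(self) -> float:
        if self.demand_params is None:
            return np.nan
        return essential_value(self.demand_params)

    @property
    def omax(self) -> float:
        return empirical_omax_pmax(self.model.data)[0]

    @property
    def pmax(self) -> float:
        return empirical_omax_pmax(self.model.data)[1]

    @property
    def pmax_analytic(self) -> float:
        if self.demand_params is None:
            return np.nan
        return analytic_pmax(self.demand_params)

    def predict(self, price, log=True):
        """Model prediction at the given price(s) (log10 scale by default)."""
        if self.demand_params is None:
            raise DemandError("no converged parameters to predict from")
        fn = predict_log_consumption if log else predict_consumption
        return fn(self.demand_params, price)

    def indices(self) -> dict:
        """One tidy row of demand indices for this subject x substance."""
        omax, pmax, degenerate = empirical_omax_pmax(self.model.data)
        p = self.params
        return {
            "subject": self.model.data.subject_id,
            "substance": self.model.data.substance,
            "Q0": p["Q0"],
            "alpha": p["alpha"],
            "EV": self.ev,
            "Omax": omax,
            "Pmax": pmax,
            "r_squared": self.rsquared,
            "fit_ok": self.converged and not degenerate,
            "flags": ";".join(sorted(self.flags)) or "",
            "n_points": self.nobs,
        }

    def summary(self) -> str:
        d = self.model.data
        buf = io.StringIO()
        w = buf.write
        w("Exponential Demand Fit\n")
        w("=" * 58 + "\n")
        w(f"subject: {d.subject_id}    substance: {d.substance}\n")
        w(f"n points (used/total): {self.nobs}/{len(d)}    k: {self.model.k:g}\n")
        w(f"converged: {self.converged}    flags: {sorted(self.flags)}\n")
        w("-" * 58 + "\n")
        w(f"{'param':>8} {'estimate':>14} {'std err':>12}\n")
        for name in ("Q0", "alpha"):
            w(f"{name:>8} {self.params[name]:>14.6g} {self.bse[name]:>12.4g}\n")
        w("-" * 58 + "\n")
        w(f"R^2 (log10 scale): {self.rsquared:.4f}\n")
        w(f"EV: {self.ev:.6g}    Omax: {self.omax:.6g}    Pmax: {self.pmax:g}\n")
        return buf.getvalue()

    def plot(self, ax=None, n_grid: int = 200):
        """Observed consumption and the fitted curve on log-log axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        pos = d.consumption > 0
        ax.scatter(d.prices[pos], d.consumption[pos], color="k", zorder=3)
        if self.demand_params is not None:
            grid = np.geomspace(d.prices[0], d.prices[-1], n_grid)
            ax.plot(grid, self.predict(grid, log=False), color="C0")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("price (FR requirement)")
        ax.set_ylabel("consumption (dose/kg)")
        ax.set_title(f"{d.subject_id} / {d.substance}")
        return ax
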