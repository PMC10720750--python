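"""Unit and property tests for the exponential demand model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opdemand import (
    DemandCurveData,
    DemandModel,
    DemandParams,
    FitConfig,
    analytic_pmax,
    choose_k,
    elasticity,
    empirical_omax_pmax,
    essential_value,
    fit_cohort,
    predict_log_consumption,
    simulate_demand_curve,
)
from opdemand.demand import DemandError, InsufficientDataError

LADDER = np.array([1, 3, 5, 8, 12, 18, 26, 38, 58, 86, 130, 195, 292, 438, 657])


def make_curve(q0, alpha, k, prices=LADDER, noise_sd=0.0, rng=None, **kw):
    curve, _ = simulate_demand_curve(
        DemandParams(q0, alpha, k), ladder=prices, noise_sd=noise_sd, rng=rng, **kw
    )
    return curve


class TestPredict:
    @pytest.mark.parametrize(
        "price,expected",
        [
            (0.0, 2.0),  # log10 Q0 at zero price
            (1.0, 2.0 + 2.0 * (np.exp(-1.0) - 1.0)),
            (1e9, 0.0),  # limit log10 Q0 - k
        ],
    )
    def test_closed_form_points(self, price, expected):
        p = DemandParams(q0=100, alpha=0.01, k=2)
        assert predict_log_consumption(p, price) == pytest.approx(expected, abs=1e-9)

    @given(
        q0=st.floats(0.1, 1e4),
        alpha=st.floats(1e-5, 1.0),
        k=st.floats(0.5, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_price(self, q0, alpha, k):
        p = DemandParams(q0, alpha, k)
        prices = np.linspace(0, 1.0 / (alpha * q0) * 5, 50)
        vals = predict_log_consumption(p, prices)
        assert np.all(np.diff(vals) < 0)

    def test_rejects_bad_inputs(self):
        p = DemandParams(100, 0.01, 2)
        with pytest.raises(DemandError):
            predict_log_consumption(p, -1.0)
        with pytest.raises(DemandError):
            predict_log_consumption(p, np.nan)
        with pytest.raises(DemandError):
            DemandParams(-1, 0.01, 2)


class TestEssentialValue:
    def test_printed_value(self):
        assert essential_value(0.01, 2.0) == pytest.approx(
            1.0 / (100 * 0.01 * 2**1.5), rel=1e-12
        )
        assert essential_value(0.01, 2.0) == pytest.approx(0.353553, abs=5e-7)

    def test_reciprocal_in_alpha(self):
        assert essential_value(0.02, 2.0) == pytest.approx(
            essential_value(0.01, 2.0) / 2, rel=1e-12
        )

    def test_algebraic_inversion(self):
        k = 3.7
        alpha = 1.0 / (100 * k**1.5)
        assert essential_value(alpha, k) == pytest.approx(1.0, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(DemandError):
            essential_value(0.0, 2.0)
        with pytest.raises(DemandError):
            essential_value(0.01, -1.0)


class TestEmpiricalOmaxPmax:
    def test_hand_example(self):
        d = DemandCurveData("s", "x", [1, 3, 5], [10, 4, 1])
        omax, pmax, degenerate = empirical_omax_pmax(d)
        assert (omax, pmax, degenerate) == (12.0, 3.0, False)

    def test_singleton(self):
        d = DemandCurveData("s", "x", [1], [7])
        assert empirical_omax_pmax(d)[:2] == (7.0, 1.0)

    def test_all_zero_flagged_degenerate(self):
        d = DemandCurveData("s", "x", [1, 3, 5], [0, 0, 0])
        omax, pmax, degenerate = empirical_omax_pmax(d)
        assert omax == 0.0 and pmax == 1.0 and degenerate

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(50):
            n = rng.integers(1, 12)
            prices = np.sort(rng.choice(np.arange(1, 1000), size=n, replace=False))
            cons = rng.uniform(0, 50, size=n)
            d = DemandCurveData("s", "x", prices, cons)
            omax, pmax, _ = empirical_omax_pmax(d)
            # brute force over all observed prices, lower price on ties
            best = max(
                ((p * c, -p) for p, c in zip(prices, cons)),
                key=lambda t: (t[0], t[1]),
            )
            assert omax == pytest.approx(best[0], rel=1e-15)
            assert pmax == -best[1]


class TestAnalyticPmax:
    def test_matches_grid_oracle(self):
        p = DemandParams(100, 0.003, 2)
        pm = analytic_pmax(p)
        # dense grid over the ascending elasticity branch
        grid = np.linspace(1e-6, 1.0 / (p.alpha * p.q0), 2_000_001)
        oracle = grid[np.argmin(np.abs(elasticity(p, grid) + 1.0))]
        assert pm == pytest.approx(oracle, rel=1e-3)

    def test_elasticity_at_root_is_minus_one(self):
        p = DemandParams(7.5, 0.02, 3.1)
        assert elasticity(p, analytic_pmax(p)) == pytest.approx(-1.0, abs=1e-10)

    def test_scaling_invariance(self):
        base = DemandParams(100, 0.003, 2)
        for s in (0.5, 10.0):
            scaled = DemandParams(100 * s, 0.003 / s, 2)
            assert analytic_pmax(scaled) == pytest.approx(
                analytic_pmax(base), rel=1e-12
            )

    def test_no_root_for_small_k(self):
        with pytest.raises(DemandError):
            analytic_pmax(DemandParams(100, 0.003, 1.0))


class TestFit:
    def test_noise_free_round_trip(self):
        curve = make_curve(100, 0.003, 2)
        res = DemandModel(curve, k=2).fit()
        assert res.converged
        assert res.params["Q0"] == pytest.approx(100, rel=1e-6)
        assert res.params["alpha"] == pytest.approx(0.003, rel=1e-6)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_flat_series_flagged(self):
        d = DemandCurveData("s", "x", LADDER[:5], np.full(5, 50.0))
        res = DemandModel(d, k=2).fit()
        assert "flat" in res.flags or "alpha_at_bound" in res.flags
        assert res.rsquared == pytest.approx(1.0, abs=1e-8)

    def test_insufficient_data_raises(self):
        d = DemandCurveData("s", "x", [1, 3, 5], [10.0, 5.0, 0.0])
        with pytest.raises(InsufficientDataError):
            DemandModel(d, k=2).fit()  # zero dropped -> 2 points

    def test_zero_replacement_policy(self):
        d = DemandCurveData("s", "x", [1, 3, 5, 8], [10.0, 5.0, 1.0, 0.0])
        m = DemandModel(d, k=2, config=FitConfig(zero_policy=0.01))
        assert m.nobs == 4
        assert m.fit().converged

    def test_noisy_recovery_median_error(self, rng):
        errs_a, errs_q = [], []
        for _ in range(200):
            curve = make_curve(100, 0.003, 2, noise_sd=0.05, rng=rng)
            res = DemandModel(curve, k=2).fit()
            errs_a.append(abs(res.params["alpha"] - 0.003) / 0.003)
            errs_q.append(abs(res.params["Q0"] - 100) / 100)
        assert np.median(errs_a) < 0.10
        assert np.median(errs_q) < 0.05

    @pytest.mark.parametrize("s", [0.5, 10.0])
    def test_unit_scaling_covariance(self, s):
        base = make_curve(100, 0.003, 2)
        scaled = DemandCurveData(
            "s", "x", base.prices, base.consumption * s
        )
        res = DemandModel(scaled, k=2).fit()
        assert res.params["Q0"] == pytest.approx(100 * s, rel=1e-6)
        assert res.params["alpha"] == pytest.approx(0.003 / s, rel=1e-6)
        assert res.ev == pytest.approx(
            essential_value(0.003, 2) * s, rel=1e-5
        )

    def test_rsquared_decreases_with_noise(self, rng):
        r2 = []
        for sd in (0.0, 0.05, 0.2):
            vals = [
                DemandModel(make_curve(100, 0.003, 2, noise_sd=sd, rng=rng), k=2)
                .fit().rsquared
                for _ in range(30)
            ]
            r2.append(np.mean(vals))
        assert r2[0] > r2[1] > r2[2]

    def test_summary_renders(self):
        res = DemandModel(make_curve(100, 0.003, 2), k=2).fit()
        s = res.summary()
        assert "Q0" in s and "EV" in s and "R^2" in s


class TestChooseK:
    def test_span_plus_half(self):
        d = DemandCurveData("s", "x", [1, 3], [100.0, 1.0])
        assert choose_k([d], "span_plus_half") == pytest.approx(2.5)

    def test_fixed_echo(self):
        assert choose_k([], "fixed", value=2.0) == 2.0

    def test_all_zero_errors(self):
        d = DemandCurveData("s", "x", [1, 3], [0.0, 0.0])
        with pytest.raises(DemandError):
            choose_k([d], "span_plus_half")

    def test_shared_nls_recovers_k(self):
        curves = [
            make_curve(100, 0.003, 2, subject_id="a"),
            make_curve(30, 0.01, 2, subject_id="b"),
        ]
        assert choose_k(curves, "shared_nls") == pytest.approx(2.0, abs=1e-4)


class TestFitCohort:
    def test_cardinality_and_identity(self, small_spec):
        from opdemand import simulate_cohort

        bundle = simulate_cohort(small_spec)
        table = fit_cohort(bundle.demand, k=small_spec.k_true)
        assert len(table) == 8 * 4  # one row per subject x substance
        ok = table[table.fit_ok]
        # EV identity propagates through every row
        np.testing.assert_allclose(
            ok["EV"], 1.0 / (100 * ok["alpha"] * small_spec.k_true**1.5), rtol=1e-10
        )

    def test_failed_fit_kept_as_flagged_row(self):
        import pandas as pd

        good = make_curve(100, 0.003, 2)
        df = pd.DataFrame(
            {
                "subject": ["a"] * len(good.prices) + ["b", "b", "b"],
                "substance": "x",
                "price": list(good.prices) + [1, 3, 5],
                "consumption": list(good.consumption) + [5.0, 0.0, 0.0],
            }
        )
        table = fit_cohort(df, k=2.0)
        assert len(table) == 2
        bad = table[table.subject == "b"].iloc[0]
        assert not bad.fit_ok and bad["flags"] == "insufficient_data"
        assert np.isnan(bad.Q0)
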