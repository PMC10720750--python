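"""Tests for the regression-table analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from opdemand import (
    CohortSpec,
    bec_regression,
    cross_index_table,
    fit_cohort,
    paired_withdrawal_tests,
    pr_prediction_from_demand,
    simple_standardized_regression,
    simulate_cohort,
    stress_association_table,
)
from opdemand.regress import holm_adjust
from opdemand.simulate import STRESS_METRICS


class TestSimpleStandardizedRegression:
    def test_identity_line(self):
        x = np.arange(10.0)
        res = simple_standardized_regression(x, x)
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == 0.0

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = simple_standardized_regression(x, y)
        assert res.beta == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_pearson_and_f_oracles(self, rng):
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        res = simple_standardized_regression(x, y)
        r, p = stats.pearsonr(x, y)
        assert res.beta == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-9)
        # F = t^2 with t from the correlation test
        t = r * np.sqrt((len(x) - 2) / (1 - r**2))
        assert res.f_stat == pytest.approx(t**2, rel=1e-12)
        assert (res.df1, res.df2) == (1, 38)

    def test_pairwise_deletion_and_errors(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.1, 6.0, 8.2, np.nan])
        res = simple_standardized_regression(x, y)
        assert res.n == 3
        with pytest.raises(ValueError, match="zero variance"):
            simple_standardized_regression(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match="complete pairs"):
            simple_standardized_regression([1, 2], [3, 4])


class TestHolm:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=12)
        np.testing.assert_allclose(
            holm_adjust(p), multipletests(p, method="holm")[1], rtol=1e-12
        )


class TestCrossIndexTable:
    def test_thirty_rows_and_df_pattern(self, default_bundle):
        indices = fit_cohort(default_bundle.demand, k=default_bundle.spec.k_true)
        table = cross_index_table(indices)
        assert len(table) == 30  # 6 ordered pairs x 5 indices
        # nicotine rows lose the missing subjects: df2 = n - 2
        nic = table[table.outcome == "nicotine"]
        assert (nic["df2"] == 13).all()
        non_nic = table[table.outcome != "nicotine"]
        assert (non_nic["df2"] == 17).all()

    def test_sparse_substance_skipped(self, default_bundle):
        indices = fit_cohort(default_bundle.demand, k=2.0)
        # keep only two nicotine subjects: every nicotine pair drops out
        nic = indices["substance"] == "nicotine"
        drop = indices[nic].index[2:]
        table = cross_index_table(indices.drop(drop))
        assert len(table) == 15  # 3 remaining pairs x 5 indices
        assert not (table["outcome"] == "nicotine").any()


class TestStressAssociation:
    def test_ten_rows(self, default_bundle):
        indices = fit_cohort(default_bundle.demand, k=default_bundle.spec.k_true)
        ev = (
            indices[(indices.substance == "ethanol") & indices.fit_ok]
            .set_index("subject")["EV"]
        )
        table = stress_association_table(ev, default_bundle.stress_withdrawal)
        assert len(table) == 10
        assert set(table["outcome"]) == set(STRESS_METRICS)

    def test_zero_noise_linear_map_gives_r2_one(self):
        # withdrawal indices an exact linear function of EV
        model = {m: (0.0, 1.0, 50.0, 1.0 if i % 2 else -1.0, 1.0)
                 for i, m in enumerate(STRESS_METRICS)}
        # rho = +-1 makes the residual sd zero in the generator
        spec = CohortSpec(n_subjects=12, seed=3, n_missing={},
                          withdrawal_model={m: (50.0, 5.0, 40.0, 1.0 if i % 2 else -1.0, 8.0)
                                            for i, m in enumerate(STRESS_METRICS)})
        bundle = simulate_cohort(spec)
        ev = bundle.truth.query("substance == 'ethanol'").set_index("subject")["EV_true"]
        table = stress_association_table(ev, bundle.stress_withdrawal)
        np.testing.assert_allclose(table["r_squared"], 1.0, atol=1e-9)
        signs = np.sign(table.set_index("outcome")["beta"])
        for i, m in enumerate(STRESS_METRICS):
            assert signs[m] == (1.0 if i % 2 else -1.0)


class TestPairedTests:
    def test_null_and_sign_convention(self, default_bundle):
        b = default_bundle.stress_baseline
        res = paired_withdrawal_tests(b, b.copy())
        for r in res:
            assert r.mean_difference == 0.0 and r.p_value == 1.0
        shifted = b.copy()
        shifted["epm_freezing_time"] = shifted["epm_freezing_time"] + 10.0
        res = paired_withdrawal_tests(b, shifted)
        freeze = next(r for r in res if r.metric == "epm_freezing_time")
        assert freeze.t_stat == -np.inf or freeze.t_stat < 0
        assert freeze.mean_difference == pytest.approx(-10.0)

    def test_matches_one_sample_t_oracle(self, default_bundle):
        res = paired_withdrawal_tests(
            default_bundle.stress_baseline, default_bundle.stress_withdrawal
        )
        b = default_bundle.stress_baseline.set_index("subject")
        w = default_bundle.stress_withdrawal.set_index("subject")
        for r in res:
            t, p = stats.ttest_1samp(b[r.metric] - w[r.metric], 0.0)
            assert r.t_stat == pytest.approx(t, rel=1e-12)
            assert r.p_value == pytest.approx(p, rel=1e-12)
            assert r.df == len(b) - 1

    def test_too_few_pairs_rejected(self, default_bundle):
        b = default_bundle.stress_baseline.iloc[:1]
        with pytest.raises(ValueError):
            paired_withdrawal_tests(b, b)


class TestBecRegression:
    def test_detects_generated_slope(self, default_bundle):
        res = bec_regression(default_bundle.bec)
        assert res["method"] == "mixed_lrt"
        assert res["p_value"] < 0.05
        assert res["slope"] > 0
        assert 0 < res["r_squared_marginal"] < 1

    def test_noiseless_r2_near_one(self):
        spec = CohortSpec(n_subjects=15, seed=2, n_missing={},
                          bec_subject_sd=0.0, bec_noise_sd=1e-6)
        res = bec_regression(simulate_cohort(spec).bec)
        assert res["r_squared_marginal"] > 0.999

    def test_unit_change_rescales_slope(self, default_bundle):
        bec = default_bundle.bec.copy()
        res_a = bec_regression(bec)
        bec["volume"] = bec["volume"] * 10.0  # e.g. per 100 g instead of per kg
        res_b = bec_regression(bec)
        assert res_b["slope"] == pytest.approx(res_a["slope"] / 10.0, rel=1e-4)
        assert res_b["chi_sq"] == pytest.approx(res_a["chi_sq"], rel=1e-4)

    def test_single_measurement_falls_back_to_ols(self, default_bundle):
        one = default_bundle.bec.groupby("subject", as_index=False).first()
        res = bec_regression(one)
        assert res["method"] == "ols_fallback"
        assert np.isfinite(res["chi_sq"])


@pytest.fixture(scope="module")
def inputs(default_bundle):
    from opdemand.pr import condition_means

    indices = fit_cohort(default_bundle.demand, k=default_bundle.spec.k_true)
    means = condition_means(default_bundle.pr_sessions)
    base = means[
        (means.primary == "ethanol") & (means.secondary_condition == "none")
    ][["subject", "response"]]
    return indices, base


class TestPRPrediction:
    def test_multiple_r2_dominates_simple(self, inputs):
        indices, base = inputs
        simple, multiple = pr_prediction_from_demand(indices, base, "ethanol")
        assert len(simple) == 5
        assert multiple["r_squared"] >= simple["r_squared"].max() - 1e-12

    def test_ev_predicts_responding(self, inputs):
        indices, base = inputs
        simple, _ = pr_prediction_from_demand(indices, base, "ethanol")
        ev_row = simple[simple.predictor == "ethanol_EV"].iloc[0]
        assert ev_row["beta"] > 0 and ev_row["p_value"] < 0.05

    def test_permuted_outcome_kills_r2(self, inputs, rng):
        indices, base = inputs
        r2 = []
        for _ in range(20):
            shuffled = base.copy()
            shuffled["response"] = rng.permutation(shuffled["response"].to_numpy())
            _, multiple = pr_prediction_from_demand(indices, shuffled, "ethanol")
            r2.append(multiple["r_squared"])
        # with 5 spurious predictors on ~19 subjects E[R^2] ~ p/(n-1)
        assert np.mean(r2) < 0.45
        _, real = pr_prediction_from_demand(indices, base, "ethanol")
        assert real["r_squared"] > np.mean(r2)
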