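"""Tests of the stratified Cox engine, Lexis expansion, floated risks,
dilution correction and subgroup tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alcophewas._errors import (ConfigurationError, EstimationError,
                                ValidationError)
from alcophewas.coxfit import (StratifiedCoxModel, dose_response_corrected,
                               fit_categorical_profile, float_absolute_risks,
                               lexis_expand, subgroup_heterogeneity_trend)
from _oracles import efron_partial_loglik, maximize_efron_oracle
from conftest import random_tiny_survival


class TestLexisExpand:
    def test_hand_traced_split(self):
        df = pd.DataFrame({"entry_age": [52.0], "exit_age": [61.0],
                           "event": [1], "area": [3]})
        out = lexis_expand(df)
        assert list(out["entry_age"]) == [52.0, 55.0, 60.0]
        assert list(out["exit_age"]) == [55.0, 60.0, 61.0]
        assert list(out["event"]) == [0, 0, 1]
        assert list(out["age_band"]) == [3, 4, 5]
        assert (out["area"] == 3).all()

    def test_single_band_stays_single(self):
        df = pd.DataFrame({"entry_age": [41.0], "exit_age": [44.0], "event": [0]})
        out = lexis_expand(df)
        assert len(out) == 1

    def test_person_time_and_events_conserved(self, cohort):
        p = cohort.participants.head(2000)
        df = pd.DataFrame({
            "entry_age": np.maximum(p["age_baseline"], 35.0),
            "exit_age": np.minimum(np.minimum(p["death_age"], p["censor_age"]),
                                   85.0),
            "event": (np.arange(len(p)) % 7 == 0).astype(int),
        })
        df = df[df["exit_age"] > df["entry_age"]]
        out = lexis_expand(df)
        time_in = (df["exit_age"] - df["entry_age"]).sum()
        time_out = (out["exit_age"] - out["entry_age"]).sum()
        assert time_out == pytest.approx(time_in)
        assert out["event"].sum() == df["event"].sum()

    def test_window_validation(self):
        df = pd.DataFrame({"entry_age": [40.0], "exit_age": [50.0], "event": [0]})
        with pytest.raises(ConfigurationError):
            lexis_expand(df, window=(30.0, 85.0))


class TestCoxEngine:
    def test_matches_bruteforce_oracle_on_tiny_data(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 20:
            entry, exit_, event, x = random_tiny_survival(rng)
            try:
                m = StratifiedCoxModel(entry, exit_, event, x[:, None])
                res = m.fit()
            except EstimationError:
                continue
            if abs(m.loglik([1.5]) - m.loglik([0.0])) < 1e-9:
                continue  # flat likelihood: any value is an argmax
            oracle = maximize_efron_oracle(entry, exit_, event, x)
            if abs(oracle) > 3:  # near-separated draws
                continue
            assert res.params.iloc[0] == pytest.approx(oracle, abs=1e-6)
            checked += 1

    def test_loglik_agrees_with_handwritten_formula(self):
        rng = np.random.default_rng(5)
        entry, exit_, event, x = random_tiny_survival(rng)
        m = StratifiedCoxModel(entry, exit_, event, x[:, None])
        for b in (-1.0, 0.0, 0.7):
            assert m.loglik([b]) == pytest.approx(
                efron_partial_loglik(b, entry, exit_, event, x), rel=1e-12)

    def test_matches_lifelines_with_ties_and_delayed_entry(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(8)
        n = 500
        entry = rng.uniform(35, 50, n)
        exit_ = entry + rng.integers(1, 20, n)  # integer gaps force ties
        event = rng.random(n) < 0.4
        X = rng.normal(0, 1, (n, 3))
        res = StratifiedCoxModel(entry, exit_, event, X).fit()
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["entry"], df["T"], df["E"] = entry, exit_, event
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E",
                                entry_col="entry")
        np.testing.assert_allclose(res.params.to_numpy(),
                                   cph.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(res.bse.to_numpy(),
                                   cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_duplicating_records_halves_variance(self):
        # duplication creates ties, so under the Efron correction the
        # point estimate is preserved only approximately
        rng = np.random.default_rng(3)
        n = 300
        entry = np.zeros(n)
        exit_ = rng.uniform(1, 10, n)
        event = rng.random(n) < 0.5
        x = rng.normal(0, 1, (n, 1))
        r1 = StratifiedCoxModel(entry, exit_, event, x).fit()
        r2 = StratifiedCoxModel(np.tile(entry, 2), np.tile(exit_, 2),
                                np.tile(event, 2), np.tile(x, (2, 1))).fit()
        assert r2.params.iloc[0] == pytest.approx(r1.params.iloc[0], abs=5e-3)
        assert r2.cov.iloc[0, 0] == pytest.approx(r1.cov.iloc[0, 0] / 2,
                                                  rel=5e-2)

    def test_invariant_to_within_stratum_time_shift(self):
        rng = np.random.default_rng(4)
        n = 200
        entry = rng.uniform(0, 2, n)
        exit_ = entry + rng.uniform(0.5, 8, n)
        event = rng.random(n) < 0.5
        x = rng.normal(0, 1, (n, 2))
        strata = rng.integers(0, 3, n)
        r1 = StratifiedCoxModel(entry, exit_, event, x, strata=strata).fit()
        shift = strata * 13.0  # common shift within each stratum
        r2 = StratifiedCoxModel(entry + shift, exit_ + shift, event, x,
                                strata=strata).fit()
        np.testing.assert_allclose(r1.params, r2.params, atol=1e-8)

    def test_null_wald_rejection_rate_nominal(self):
        """Exposure independent of hazard: Wald test rejects at ~5%."""
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 200
        for _ in range(reps):
            n = 300
            exit_ = rng.exponential(5, n)
            event = exit_ < 8
            exit_ = np.minimum(exit_, 8)
            x = rng.normal(0, 1, (n, 1))
            res = StratifiedCoxModel(np.zeros(n), exit_, event, x).fit()
            rejections += res.pvalues.iloc[0] < 0.05
        assert rejections <= stats.binom.ppf(0.999, reps, 0.05)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        n = 100
        exit_ = rng.uniform(1, 5, n)
        event = rng.random(n) < 0.5
        X = np.column_stack([rng.normal(size=n), np.ones(n)])
        with pytest.warns(UserWarning, match="constant"):
            m = StratifiedCoxModel(np.zeros(n), exit_, event, X,
                                   names=["x", "flat"])
        assert m.names == ["x"]

    def test_no_events_rejected(self):
        with pytest.raises(EstimationError):
            StratifiedCoxModel(np.zeros(3), np.ones(3), np.zeros(3),
                               np.ones((3, 1)))


class TestFloatedRisks:
    def _sim_fit(self, seed, k=6, n=4000):
        """Fit a k-level categorical model on simulated data."""
        rng = np.random.default_rng(seed)
        level = rng.integers(0, k, n)
        beta = np.linspace(0, 0.8, k)
        lam = 0.1 * np.exp(beta[level])
        t = rng.standard_exponential(n) / lam
        event = t < 8
        exit_ = np.minimum(t, 8)
        X = np.zeros((n, k - 1))
        for j in range(1, k):
            X[:, j - 1] = level == j
        res = StratifiedCoxModel(np.zeros(n), exit_, event, X,
                                 names=[f"l{j}" for j in range(1, k)]).fit()
        sizes = {f"l{j}": int((level == j).sum()) for j in range(1, k)}
        sizes["ref"] = int((level == 0).sum())
        return res, sizes

    def test_equal_offdiagonal_closed_form(self):
        V = np.array([[0.05, 0.02, 0.02],
                      [0.02, 0.07, 0.02],
                      [0.02, 0.02, 0.06]])
        fl = float_absolute_risks(pd.Series([0.1, 0.2, 0.3],
                                            index=["a", "b", "c"]), V, "ref")
        assert fl.var_floated[0] == pytest.approx(0.02)
        np.testing.assert_allclose(fl.var_floated[1:], np.diag(V) - 0.02)

    def test_diagonal_covariance_limit(self):
        V = np.diag([0.04, 0.05, 0.06])
        fl = float_absolute_risks(pd.Series([0.0, 0.1, 0.2],
                                            index=list("abc")), V, "ref")
        assert fl.var_floated[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fl.var_floated[1:], np.diag(V))

    def test_reconstruction_within_ten_percent_on_simulated_fits(self):
        worst = 0.0
        for seed in range(8):
            res, sizes = self._sim_fit(seed)
            fl = float_absolute_risks(res.params, res.cov, "ref",
                                      level_sizes=sizes)
            worst = max(worst, fl.reconstruction_error())
        assert worst <= 0.10

    def test_reference_ci_has_positive_width(self):
        res, sizes = self._sim_fit(1)
        fl = float_absolute_risks(res.params, res.cov, "ref")
        ci = fl.conf_int()
        ref_row = ci[ci["level"] == "ref"].iloc[0]
        assert ref_row["hr_upper"] > ref_row["hr_lower"] > 0

    def test_two_level_split_proportional_to_sizes(self):
        V = np.array([[0.06]])
        fl = float_absolute_risks(pd.Series([0.4], index=["b"]), V, "a",
                                  level_sizes={"a": 100, "b": 300})
        # reference variance share = (1/100) / (1/100 + 1/300)
        assert fl.var_floated[0] == pytest.approx(0.06 * 0.75)
        assert fl.var_floated.sum() == pytest.approx(0.06)


class TestDoseResponse:
    def test_identity_when_rdr_one(self):
        d = dose_response_corrected(0.3, 0.1, 1.0)
        assert d.log_hr == pytest.approx(0.3) and d.se == pytest.approx(0.1)

    def test_known_correction(self):
        d = dose_response_corrected(np.log(1.10), 0.05, 0.53)
        assert d.hr == pytest.approx(np.exp(np.log(1.10) / 0.53), rel=1e-12)
        assert d.hr == pytest.approx(1.197, abs=5e-4)

    def test_ci_width_scales_inversely_with_rdr(self):
        d1 = dose_response_corrected(0.2, 0.05, 1.0)
        d2 = dose_response_corrected(0.2, 0.05, 0.5)
        w1 = np.log(d1.ci_upper) - np.log(d1.ci_lower)
        w2 = np.log(d2.ci_upper) - np.log(d2.ci_lower)
        assert w2 == pytest.approx(2 * w1)

    def test_invalid_rdr_rejected(self):
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValidationError):
                dose_response_corrected(0.1, 0.05, bad)


class TestSubgroupTests:
    def test_identical_estimates(self):
        out = subgroup_heterogeneity_trend([0.2, 0.2, 0.2], [0.1, 0.2, 0.1])
        assert out.chi2_heterogeneity == pytest.approx(0.0)
        assert out.p_heterogeneity == pytest.approx(1.0)

    def test_two_group_identity(self):
        b, se = [0.1, 0.4], [0.05, 0.08]
        out = subgroup_heterogeneity_trend(b, se)
        expected = (0.1 - 0.4) ** 2 / (0.05 ** 2 + 0.08 ** 2)
        assert out.chi2_heterogeneity == pytest.approx(expected)

    def test_p_uniform_under_common_effect(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(400):
            se = rng.uniform(0.05, 0.2, 4)
            b = 0.3 + rng.normal(0, se)
            ps.append(subgroup_heterogeneity_trend(b, se).p_heterogeneity)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_trend_detects_ordered_effect(self):
        out = subgroup_heterogeneity_trend([0.0, 0.2, 0.4], [0.05] * 3,
                                           scores=[0, 1, 2])
        assert out.p_trend < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(EstimationError):
            subgroup_heterogeneity_trend([0.1], [0.05])


class TestCategoricalProfile:
    def test_j_shape_recovered(self):
        """Planted category hazards (elevated at both ends) are reproduced
        in the floated profile ordering."""
        rng = np.random.default_rng(10)
        n = 30_000
        levels = np.array(["non", "ex", "occasional", "moderate", "heavy"])
        lv = rng.choice(5, n, p=[0.2, 0.1, 0.4, 0.2, 0.1])
        true_lhr = np.array([0.35, 0.5, 0.0, 0.05, 0.6])
        entry = rng.uniform(40, 60, n)
        lam = 0.02 * np.exp(true_lhr[lv])
        gap = rng.standard_exponential(n) / lam
        exit_ = np.minimum(entry + gap, entry + 12)
        event = (gap < 12).astype(int)
        exit_ = np.minimum(exit_, 85.0)
        df = pd.DataFrame({"entry_age": entry, "exit_age": exit_,
                           "event": event, "category": levels[lv],
                           "area": rng.integers(0, 3, n)})
        df = df[df.exit_age > df.entry_age]
        sl = lexis_expand(df)
        fl, res = fit_categorical_profile(sl, "category", "occasional")
        est = dict(zip(fl.levels, fl.log_hr))
        assert est["heavy"] > est["moderate"]
        assert est["ex"] > est["occasional"] == 0.0
        assert est["non"] > est["moderate"]
        # floated intervals cover the planted values
        se = dict(zip(fl.levels, fl.se_floated()))
        truth = dict(zip(levels, true_lhr))
        for lev in ("non", "ex", "heavy"):
            assert abs(est[lev] - truth[lev]) < 3.5 * se[lev]
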