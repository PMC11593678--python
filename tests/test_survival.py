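import numpy as np
import pandas as pd
import pytest

from folrsig.survival import (
    cox_fit,
    cox_time_stratified,
    episode_split,
    km_estimate,
    logrank_test,
    multivariate_screen,
)


def km_product_oracle(time, event):
    """Hand-rolled product-limit estimator at each distinct event time."""
    time, event = np.asarray(time, float), np.asarray(event, int)
    s, out = 1.0, {}
    for t in sorted(set(time[event == 1])):
        n_at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        est = km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
        assert (est.survival["S"] == 1.0).all()
        assert np.isnan(est.median)

    def test_three_events_closed_form(self):
        est = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        surv = est.survival["S"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)
        assert est.median == pytest.approx(2.0)

    def test_censored_data_matches_product_oracle(self, rng):
        time = rng.exponential(10, 40).round(2) + 0.01
        event = rng.integers(0, 2, 40)
        event[0] = 1
        est = km_estimate(time, event)
        for t, s in km_product_oracle(time, event).items():
            assert est.survival.loc[t, "S"] == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = rng.exponential(5, 30) + 0.01
        est = km_estimate(time, np.ones(30, dtype=int))
        for t in time:
            empirical = (time > t).mean()
            assert est.survival.loc[t, "S"] == pytest.approx(empirical, abs=1e-12)

    def test_rate_at_horizon_with_greenwood_ci(self):
        est = km_estimate([10.0, 70.0, 80.0, 90.0], [1, 0, 0, 0],
                          rate_times=(60.0,))
        s, lo, hi = est.rates[60.0]
        assert s == pytest.approx(0.75)
        assert lo < s < hi

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogRank:
    def test_duplicated_groups_statistic_zero(self):
        time = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = ["a"] * 4 + ["b"] * 4
        chi2, p = logrank_test(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_manual_table(self):
        # subjects: A group times 1,3,5 (all events); B group 2,4,6 (all events)
        time = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
        event = [1] * 6
        groups = ["A"] * 3 + ["B"] * 3
        # manual O-E with hypergeometric variance, computed by hand:
        # t=1: nA=3 n=6 dA=1 E=.5 V=.25 ; t=2: nA=2 n=5 dB=1 E=.4 V=.24
        # t=3: nA=2 n=4 dA=1 E=.5 V=.25 ; t=4: nA=1 n=3 dB=1 E=1/3 V=2/9
        # t=5: nA=1 n=2 dA=1 E=.5 V=.25 ; t=6: last subject, V=0
        o_minus_e = (1 - 0.5) + (0 - 0.4) + (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5) - 0
        var = 0.25 + 0.24 + 0.25 + 2 / 9 + 0.25 + 0.0
        expected_chi2 = o_minus_e**2 / var
        chi2, _ = logrank_test(time, event, groups)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-10)

    def test_symmetric_under_group_relabeling(self, rng):
        time = rng.exponential(10, 30) + 0.01
        event = rng.integers(0, 2, 30)
        event[:2] = 1
        groups = rng.integers(0, 2, 30)
        chi2_a, _ = logrank_test(time, event, groups)
        chi2_b, _ = logrank_test(time, event, 1 - groups)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            logrank_test([1.0, 2.0], [0, 0], ["a", "b"])

    def test_power_against_planted_hazard(self, rng):
        # HR 0.71, n = 1500: the test should reject at 5% nearly always
        rejections = 0
        for _ in range(10):
            x = rng.integers(0, 2, 1500)
            lam = 0.015 * np.where(x == 1, 0.71, 1.0)
            t = rng.exponential(1 / lam)
            c = rng.exponential(1 / (0.006), 1500)
            time = np.minimum(t, c).clip(0.01)
            event = (t <= c).astype(int)
            _, p = logrank_test(time, event, x)
            rejections += p < 0.05
        assert rejections >= 9


class TestCoxFit:
    def _planted(self, rng, n=1500, hr=0.71):
        x = rng.integers(0, 2, n)
        lam = 0.015 * np.where(x == 1, hr, 1.0)
        t = rng.exponential(1 / lam)
        c = rng.exponential(1 / 0.006, n)
        return pd.DataFrame({
            "time": np.minimum(t, c).clip(0.01),
            "event": (t <= c).astype(int),
            "x": x,
        })

    def test_recovers_planted_hazard_ratio(self, rng):
        fit = cox_fit(self._planted(rng), "time", "event", ["x"])
        assert fit.hr("x") == pytest.approx(0.71, rel=0.15)
        lo, hi = fit.summary.loc["x", ["ci_low", "ci_high"]]
        assert lo < fit.hr("x") < hi

    def test_collinear_covariates_rejected(self, rng):
        df = self._planted(rng, n=100)
        df["x2"] = df["x"]
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(df, "time", "event", ["x", "x2"])

    def test_no_events_rejected(self, rng):
        df = self._planted(rng, n=50)
        df["event"] = 0
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, "time", "event", ["x"])

    def test_categorical_covariate_dummy_coded(self, rng):
        df = self._planted(rng, n=300)
        df["grp"] = np.where(df["x"] == 1, "high", "low")
        fit = cox_fit(df, "time", "event", ["grp"])
        assert any(c.startswith("grp_") for c in fit.summary.index)

    def test_interaction_terms_expand(self, rng):
        df = self._planted(rng, n=400)
        df["z"] = rng.integers(0, 2, 400)
        fit = cox_fit(df, "time", "event", ["x", "z"], interactions=[("x", "z")])
        assert "x:z" in fit.summary.index


class TestTimeStratified:
    def test_episode_split_structure(self):
        df = pd.DataFrame({"t": [4.0, 10.0, 30.0], "e": [1, 0, 1], "x": [1, 0, 1]},
                          index=["a", "b", "c"])
        long = episode_split(df, "t", "e", (6.0, 12.0))
        # a: one episode (0,4]; b: (0,6](6,10]; c: (0,6](6,12](12,30]
        assert len(long) == 6
        a = long[long["subject_id"] == "a"]
        assert a["event"].tolist() == [1]
        c = long[long["subject_id"] == "c"]
        assert c["stop"].tolist() == [6.0, 12.0, 30.0]
        assert c["event"].tolist() == [0, 0, 1]

    def test_unordered_cutpoints_rejected(self):
        df = pd.DataFrame({"t": [4.0], "e": [1], "x": [1]})
        with pytest.raises(ValueError, match="increasing"):
            episode_split(df, "t", "e", (12.0, 6.0))

    def test_interval_without_events_reported_nan(self, rng):
        # all events after month 6: first interval has no information
        n = 300
        x = rng.integers(0, 2, n)
        t = 6.5 + rng.exponential(20, n)
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        table = cox_time_stratified(df, "time", "event", "x")
        assert np.isnan(table.loc["(0,6]", "hr"])
        assert table.loc["(0,6]", "n_events"] == 0

    def test_time_constant_effect_indistinguishable_across_intervals(self, rng):
        n = 2000
        x = rng.integers(0, 2, n)
        lam = 0.05 * np.where(x == 1, 0.6, 1.0)
        t = rng.exponential(1 / lam)
        c = rng.exponential(40, n)
        df = pd.DataFrame({"time": np.minimum(t, c).clip(0.01),
                           "event": (t <= c).astype(int), "x": x})
        table = cox_time_stratified(df, "time", "event", "x")
        # every interval's CI covers every other interval's point estimate
        hrs = table["hr"].dropna()
        for _, row in table.dropna().iterrows():
            assert (hrs >= row["ci_low"]).all() and (hrs <= row["ci_high"]).all()


class TestMultivariateScreen:
    def _data(self, rng, n=600):
        x = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n)  # null covariate
        lam = 0.03 * np.where(x == 1, 0.5, 1.0)
        t = rng.exponential(1 / lam)
        c = rng.exponential(50, n)
        return pd.DataFrame({"time": np.minimum(t, c).clip(0.01),
                             "event": (t <= c).astype(int), "x": x, "z": z})

    def test_only_informative_covariate_enters(self, rng):
        res = multivariate_screen(self._data(rng), "time", "event", ["x", "z"])
        assert res.entered == ["x"]
        assert res.multivariate.hr("x") == pytest.approx(0.5, rel=0.25)

    def test_single_passing_candidate_equals_univariate(self, rng):
        df = self._data(rng)
        res = multivariate_screen(df, "time", "event", ["x"])
        assert res.entered == ["x"]
        assert res.multivariate.summary.loc["x", "coef"] == pytest.approx(
            res.univariate["x"].summary.loc["x", "coef"]
        )

    def test_all_null_skips_multivariate(self, rng):
        n = 300
        df = pd.DataFrame({
            "time": rng.exponential(20, n).clip(0.01),
            "event": rng.integers(0, 2, n),
            "z1": rng.integers(0, 2, n),
        })
        res = multivariate_screen(df, "time", "event", ["z1"])
        if res.entered:  # a null can pass by chance; then multivariate runs
            assert res.multivariate is not None
        else:
            assert res.multivariate is None
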