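import math

import numpy as np
import pandas as pd
import pytest

from spatialtme.quantification import density_wide
from spatialtme.quantification import build_metric_table
from spatialtme.survival import (
    cox_fit,
    encode_clinical_covariates,
    km_estimate,
    logrank,
    median_split,
    run_survival_analysis,
    select_multivariate,
)


def naive_km(times, events):
    """Product-limit oracle by explicit loop."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times, float)[order], np.asarray(events, bool)[order]
    s = 1.0
    out = {}
    for t in np.unique(times):
        at_risk = int((times >= t).sum())
        d = int(events[times == t].sum())
        if d:
            s *= 1 - d / at_risk
        out[float(t)] = s
    return out


def naive_logrank(times_a, events_a, times_b, events_b):
    """Mantel-Cox O-E table oracle."""
    times = np.concatenate([times_a, times_b]).astype(float)
    events = np.concatenate([events_a, events_b]).astype(bool)
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestMedianSplit:
    def test_even_count(self):
        groups, cutoff = median_split(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert cutoff == 2.5
        assert set(groups[groups == "high"].index) == {"c", "d"}
        assert set(groups[groups == "low"].index) == {"a", "b"}

    def test_ties_go_low(self):
        groups, cutoff = median_split(pd.Series([1, 2, 2, 5], index=list("abcd")))
        assert cutoff == 2.0
        assert set(groups[groups == "high"].index) == {"d"}
        assert set(groups[groups == "low"].index) == {"a", "b", "c"}

    @pytest.mark.parametrize("seed", range(5))
    def test_balance_bounded_by_ties(self, seed):
        rng = np.random.default_rng(seed)
        v = pd.Series(rng.integers(0, 10, 31).astype(float))
        groups, cutoff = median_split(v)
        n_tied = int((v == cutoff).sum())
        # ties at the cutoff all go to "low": the worst-case imbalance is
        # 2*ties - 1 (odd n, median inside a tied block), not ties itself
        imbalance = abs((groups == "high").sum() - (groups == "low").sum())
        assert imbalance <= max(2 * n_tied - 1, 1)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(pd.Series([3.0, 3.0, 3.0]))

    def test_missing_excluded(self):
        groups, _ = median_split(pd.Series([1.0, np.nan, 3.0, 4.0]))
        assert len(groups) == 3


class TestKM:
    def test_all_events_by_hand(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert list(km["time"]) == [1, 2, 3]
        assert list(km["survival"]) == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censoring_reduces_risk_set_without_step(self):
        km = km_estimate([1, 2, 3], [1, 0, 1]).set_index("time")
        assert km.loc[1, "survival"] == pytest.approx(2 / 3)
        assert km.loc[2, "survival"] == pytest.approx(2 / 3)  # no step at censor
        assert km.loc[2, "n_events"] == 0
        assert km.loc[3, "survival"] == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_naive_product_limit(self, rng):
        times = rng.exponential(5, 40).round(1) + 0.1
        events = rng.integers(0, 2, 40).astype(bool)
        km = km_estimate(times, events).set_index("time")["survival"]
        oracle = naive_km(times, events)
        for t, s in oracle.items():
            assert km.loc[t] == pytest.approx(s)

    def test_monotone_non_increasing(self, rng):
        times = rng.exponential(3, 60) + 0.01
        events = rng.integers(0, 2, 60).astype(bool)
        km = km_estimate(times, events)
        assert (np.diff(km["survival"]) <= 1e-12).all()
        assert km["survival"].between(0, 1).all()


class TestLogrank:
    def test_identical_groups_null(self):
        t, e = [1.0, 2.0, 3.0], [1, 1, 0]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_example(self):
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 1, 1])
        chi2, p = logrank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(naive_logrank(ta, ea, tb, eb), rel=1e-9)

    def test_matches_oracle_random(self, rng):
        ta, tb = rng.exponential(4, 25), rng.exponential(2, 30)
        ea, eb = rng.integers(0, 2, 25), rng.integers(0, 2, 30)
        chi2, _ = logrank(ta, ea, tb, eb)
        assert chi2 == pytest.approx(naive_logrank(ta, ea, tb, eb), rel=1e-9)


class TestCox:
    @staticmethod
    def simulate_ph(n, beta, rng, censor_rate=0.1, h0=0.1):
        x = (rng.uniform(size=n) < 0.5).astype(float)
        t = rng.exponential(1 / (h0 * np.exp(beta * x)))
        c = rng.exponential(1 / censor_rate, n)
        return pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int),
                             "x": x})

    def test_null_hr_near_one(self, rng):
        df = self.simulate_ph(400, 0.0, rng)
        res = cox_fit(df, "time", "event", ["x"])
        row = res.summary.iloc[0]
        assert row["ci_low"] < 1.0 < row["ci_high"]
        assert res.converged

    def test_recovers_planted_effect(self, rng):
        beta = math.log(0.5)
        df = self.simulate_ph(600, beta, rng)
        res = cox_fit(df, "time", "event", ["x"])
        row = res.summary.iloc[0]
        assert row["hr"] == pytest.approx(0.5, rel=0.25)
        assert row["ci_low"] <= 0.5 <= row["ci_high"]
        assert row["p"] < 0.05

    def test_ci_consistent_with_coef(self, rng):
        df = self.simulate_ph(200, 0.7, rng)
        res = cox_fit(df, "time", "event", ["x"])
        row = res.summary.iloc[0]
        assert row["ci_low"] == pytest.approx(math.exp(row["coef"] - 1.96 * row["se"]), rel=1e-3)
        assert row["ci_high"] == pytest.approx(math.exp(row["coef"] + 1.96 * row["se"]), rel=1e-3)

    def test_duplicated_covariate_flagged(self, rng):
        df = self.simulate_ph(100, 0.5, rng)
        df["x2"] = df["x"]
        res = cox_fit(df, "time", "event", ["x", "x2"])
        assert "collinear_covariates" in res.flags

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 1],
                           "x": [0.0, 1.0, 0.5]})
        with pytest.raises(ValueError, match="too few events"):
            cox_fit(df, "time", "event", ["x"])


class TestSelection:
    def test_strict_alpha(self):
        uni = pd.DataFrame({"covariate": ["a", "b", "c"], "p": [0.04, 0.06, 0.05]})
        assert select_multivariate(uni) == ["a"]  # boundary 0.05 excluded

    def test_none_selected(self):
        uni = pd.DataFrame({"covariate": ["a"], "p": [0.5]})
        assert select_multivariate(uni) == []


class TestCohortAnalysis:
    def test_structure_and_partition(self, small_cohort, small_gated):
        density, _ = build_metric_table(small_gated, small_cohort.fields)
        wide = density_wide(density)
        res = run_survival_analysis(
            wide, small_cohort.clinical, ["density_Th_stroma"], endpoint="os"
        )
        km = res["km"]["density_Th_stroma"]
        n_nonmissing = wide["density_Th_stroma"].notna().sum()
        assert km["n_high"] + km["n_low"] == n_nonmissing
        assert 0 <= km["logrank_p"] <= 1
        assert {"covariate", "hr", "ci_low", "ci_high", "p"} <= set(res["univariate"].columns)
        # every clinical covariate plus the metric indicator was tested
        assert "density_Th_stroma_high" in set(res["univariate"]["covariate"])

    def test_covariate_encoding(self, small_cohort):
        enc = encode_clinical_covariates(small_cohort.clinical)
        assert set(enc.columns) >= {"age", "sex_male", "side_right", "adjuvant_yes",
                                    "ajcc_III_IV", "msi_high", "icr_medium_high"}
        assert enc.drop(columns="age").isin([0.0, 1.0]).all().all()
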