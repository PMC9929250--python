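import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from multiprot.clinical import (
    cis_trans_fisher,
    cox_hr,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
)
from multiprot.datamodel import MutationTable, ValidationError


def km_product_limit_oracle(times, events):
    """Hand product-limit estimator at each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


def logrank_oracle(times, events, groups):
    """Independent two-group O/E/V tally; returns the chi-square."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    g1 = groups == np.unique(groups)[0]
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKM:
    def test_no_events_gives_flat_one(self):
        fit = km_estimate([5, 8, 10], [0, 0, 0])
        curve = fit.curves[0]
        assert (curve["survival"] == 1.0).all()

    def test_three_events_hand_product_limit(self):
        fit = km_estimate([1, 2, 3], [1, 1, 1])
        curve = fit.curves[0].set_index("time")["survival"]
        assert curve[1.0] == pytest.approx(2 / 3)
        assert curve[2.0] == pytest.approx(1 / 3)
        assert curve[3.0] == pytest.approx(0.0)

    def test_matches_oracle_with_censoring(self, rng):
        times = rng.exponential(10, 40).round(2)
        events = (rng.random(40) < 0.7).astype(int)
        fit = km_estimate(times, events)
        curve = fit.curves[0].set_index("time")["survival"]
        for t, s in km_product_limit_oracle(times, events).items():
            assert curve[t] == pytest.approx(s, abs=1e-10)

    def test_trailing_censor_matches_oracle(self):
        ext = km_estimate([1, 2, 3, 9], [1, 1, 1, 0]).curves[0].set_index("time")["survival"]
        oracle = km_product_limit_oracle([1, 2, 3, 9], [1, 1, 1, 0])
        for t, s in oracle.items():
            assert ext[t] == pytest.approx(s, abs=1e-12)

    def test_monotone_nonincreasing(self, rng):
        times = rng.exponential(5, 30)
        events = (rng.random(30) < 0.6).astype(int)
        curve = km_estimate(times, events).curves[0]["survival"].to_numpy()
        assert (np.diff(curve) <= 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1] * 2
        groups = [0] * 4 + [1] * 4
        out = logrank_test(times, events, groups)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert out["p"] == pytest.approx(1.0)

    def test_textbook_fixture_matches_tally_oracle(self):
        times = [3, 5, 7, 2, 4, 6]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        out = logrank_test(times, events, groups)
        assert out["chi2"] == pytest.approx(logrank_oracle(times, events, groups), abs=1e-10)

    def test_random_fixture_matches_oracle(self, rng):
        times = rng.exponential(10, 30).round(1)
        events = (rng.random(30) < 0.8).astype(int)
        groups = rng.integers(0, 2, 30)
        if events.sum() == 0 or len(np.unique(groups)) < 2:
            pytest.skip("degenerate draw")
        out = logrank_test(times, events, groups)
        assert out["chi2"] == pytest.approx(logrank_oracle(times, events, groups), abs=1e-8)

    def test_time_rescaling_invariance(self, rng):
        times = rng.exponential(10, 30)
        events = (rng.random(30) < 0.7).astype(int)
        groups = rng.integers(0, 2, 30)
        a = logrank_test(times, events, groups)
        b = logrank_test(np.exp(times / 10), events, groups)  # strictly increasing
        assert a["chi2"] == pytest.approx(b["chi2"], abs=1e-9)

    def test_planted_hazard_ratio_detected(self):
        rng = np.random.default_rng(42)
        rejections = 0
        for s in range(20):
            t1 = rng.exponential(10, 100)
            t2 = rng.exponential(10 / 3, 100)
            times = np.concatenate([t1, t2])
            cens = rng.uniform(0, 25, 200)
            events = (times <= cens).astype(int)
            obs = np.minimum(times, cens)
            groups = np.array([0] * 100 + [1] * 100)
            if logrank_test(obs, events, groups)["p"] < 0.05:
                rejections += 1
        assert rejections >= 18  # >= 90% power at HR = 3

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [0, 0], [0, 1])


def cox_newton_oracle(times, events, x, ties="efron"):
    """One-covariate Cox partial-likelihood Newton-Raphson, coded from the
    Efron tie-corrected score directly."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    beta = 0.0
    for _ in range(50):
        U = 0.0
        I = 0.0
        for t in np.unique(times[events == 1]):
            risk = times >= t
            dead = (times == t) & (events == 1)
            d = dead.sum()
            eta = np.exp(beta * x)
            s0 = eta[risk].sum()
            s1 = (x * eta)[risk].sum()
            s2 = (x * x * eta)[risk].sum()
            d0 = eta[dead].sum()
            d1 = (x * eta)[dead].sum()
            d2 = (x * x * eta)[dead].sum()
            for l in range(d):
                f = l / d
                den = s0 - f * d0
                num1 = s1 - f * d1
                num2 = s2 - f * d2
                U += (x * dead).sum() / d - num1 / den
                I += num2 / den - (num1 / den) ** 2
        step = U / I
        step = np.clip(step, -1.0, 1.0)  # damped Newton for stability
        beta += step
        if abs(step) < 1e-12:
            break
    return beta


class TestCox:
    def test_identical_arms_hr_near_one(self, rng):
        times = rng.exponential(10, 80)
        events = (rng.random(80) < 0.8).astype(int)
        cov = pd.DataFrame({"arm": [0] * 40 + [1] * 40})
        out = cox_hr(times, events, cov)
        assert out.loc["arm", "hr_ci_lower"] < 1 < out.loc["arm", "hr_ci_upper"]

    def test_tiny_fixture_matches_newton_oracle(self):
        times = [5, 4, 3, 2, 1]
        events = [1, 0, 1, 1, 1]
        x = [1, 0, 1, 0, 0]
        out = cox_hr(times, events, pd.DataFrame({"x": x}))
        beta = cox_newton_oracle(times, events, x)
        # agreement bounded by the fitter's convergence tolerance
        assert out.loc["x", "coef"] == pytest.approx(beta, abs=1e-4)

    def test_random_fixture_matches_newton_oracle(self, rng):
        times = rng.exponential(5, 25).round(2)
        events = (rng.random(25) < 0.8).astype(int)
        x = rng.normal(0, 1, 25)
        out = cox_hr(times, events, pd.DataFrame({"x": x}))
        beta = cox_newton_oracle(times, events, x)
        assert out.loc["x", "coef"] == pytest.approx(beta, abs=1e-4)

    def test_true_hazard_ratio_coverage(self):
        rng = np.random.default_rng(7)
        covered = 0
        n_sims = 30
        for _ in range(n_sims):
            arm = np.array([0] * 100 + [1] * 100)
            lam = 0.1 * np.exp(np.log(2) * arm)
            t = rng.exponential(1 / lam)
            c = rng.uniform(0, 25, 200)
            times = np.minimum(t, c)
            events = (t <= c).astype(int)
            out = cox_hr(times, events, pd.DataFrame({"arm": arm}))
            if out.loc["arm", "hr_ci_lower"] <= 2 <= out.loc["arm", "hr_ci_upper"]:
                covered += 1
        assert covered / n_sims >= 0.93

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValidationError):
            cox_hr([1, 2, 3, 4], [1, 1, 1, 0], pd.DataFrame({"x": [1, 1, 1, 1]}))


class TestOptimalCutpoint:
    def test_perfect_separation_recovered(self):
        # early events below marker 10; the late group survives to study end
        marker = np.arange(1, 21, dtype=float)
        times = np.where(marker <= 10, 2.0 + marker * 0.01, 30.0)
        events = (marker <= 10).astype(int)
        out = optimal_cutpoint(marker, times, events)
        assert 10 <= out["cutpoint"] < 11

    def test_uninformative_marker_flagged_by_permutation(self, rng):
        marker = rng.normal(0, 1, 40)
        times = rng.exponential(10, 40)
        events = (rng.random(40) < 0.8).astype(int)
        out = optimal_cutpoint(marker, times, events, n_permutations=100, seed=4)
        assert out["permutation_p"] > 0.05

    def test_planted_step_at_40th_percentile(self):
        r = np.random.default_rng(0)
        n = 50
        marker = np.sort(r.normal(0, 1, n))
        step = marker[int(0.4 * n) - 1]
        lam = np.where(marker <= step, 1.0, 0.02)
        t = r.exponential(1 / lam)
        times = np.minimum(t, 12.0)
        events = (t <= 12.0).astype(int)
        out = optimal_cutpoint(marker, times, events)
        idx = np.searchsorted(marker, out["cutpoint"])
        assert abs(idx - int(0.4 * n)) <= 1

    def test_monotone_transform_invariance(self, rng):
        marker = rng.normal(0, 1, 30)
        times = rng.exponential(10, 30)
        events = (rng.random(30) < 0.7).astype(int)
        a = optimal_cutpoint(marker, times, events)
        b = optimal_cutpoint(np.exp(marker), times, events)
        assert a["max_statistic"] == pytest.approx(b["max_statistic"], abs=1e-9)

    def test_constant_marker_rejected(self):
        with pytest.raises(ValidationError):
            optimal_cutpoint(np.ones(12), np.arange(12.0), np.ones(12, int))


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    n1, m1 = a + b, a + c
    N = a + b + c + d
    pmf_obs = hypergeom.pmf(a, N, m1, n1)
    total = 0.0
    for x in range(max(0, m1 - (N - n1)), min(m1, n1) + 1):
        px = hypergeom.pmf(x, N, m1, n1)
        if px <= pmf_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestCisTransFisher:
    def _tables(self, pattern):
        patients = [f"p{i}" for i in range(6)]
        mut = MutationTable(
            pd.DataFrame({"G1": [True] * 3 + [False] * 3}, index=patients)
        )
        status = pd.DataFrame({"G1": pattern, "OTHER": [True, False] * 3}, index=patients)
        return mut, status

    def test_diagonal_table_enumeration(self):
        mut, status = self._tables([True] * 3 + [False] * 3)
        out = cis_trans_fisher(mut, status)
        row = out[(out.mutated_gene == "G1") & (out.protein == "G1")].iloc[0]
        assert row["p"] == pytest.approx(0.1, abs=1e-12)  # [[3,0],[0,3]]
        assert row["effect_class"] == "cis"

    def test_balanced_table_null(self):
        mut, status = self._tables([True, False, True, False, True, False])
        out = cis_trans_fisher(mut, status)
        row = out[(out.mutated_gene == "G1") & (out.protein == "G1")].iloc[0]
        assert row["p"] == pytest.approx(1.0)

    def test_matches_enumeration_for_random_tables(self, rng):
        patients = [f"p{i}" for i in range(12)]
        mut = MutationTable(pd.DataFrame(
            {"G1": rng.random(12) < 0.5}, index=patients
        ))
        status = pd.DataFrame({"P1": rng.random(12) < 0.5}, index=patients)
        out = cis_trans_fisher(mut, status).iloc[0]
        m = mut.table["G1"].to_numpy()
        u = status["P1"].to_numpy()
        a, b = int((m & u).sum()), int((m & ~u).sum())
        c, d = int((~m & u).sum()), int((~m & ~u).sum())
        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
            assert out["p"] == 1.0
        else:
            assert out["p"] == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-10)

    def test_zero_margin_degenerate(self):
        patients = [f"p{i}" for i in range(4)]
        mut = MutationTable(pd.DataFrame({"G1": [False] * 4}, index=patients))
        status = pd.DataFrame({"G1": [True, False, True, False]}, index=patients)
        out = cis_trans_fisher(mut, status).iloc[0]
        assert out["p"] == 1.0 and bool(out["degenerate"])

    def test_planted_cis_effect_is_top_hit(self, small_cohort, small_prepared):
        c = small_cohort
        prot = small_prepared["proteome"]
        pairs = c.samples.complete_pairs()
        tum = prot.data[list(pairs["tumor"])]
        tum.columns = list(pairs.index)
        status = tum.T.gt(tum.median(axis=1), axis=1)
        res = cis_trans_fisher(c.mutations, status)
        cis = res[res.effect_class == "cis"].sort_values("p")
        planted = set(c.truth.mutated_gene_effects)
        assert set(cis.head(len(planted))["mutated_gene"]) == planted
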