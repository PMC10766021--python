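import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from ki67cl.errors import EmptyFoldError, NoFeasibleCutoffError
from ki67cl.survival import (
    SurvivalRecord,
    combine_fold_stats,
    concordance_index,
    cox_fit,
    cross_validate_marker,
    find_optimal_cutoff,
    kaplan_meier,
    logrank_test,
    records_to_frame,
    stratify_at_cutoff,
)
from ki67cl.synth import CohortSimConfig, simulate_cohort


def frame(times, events, markers=None, **cov):
    df = pd.DataFrame({"time": times, "event": events})
    df["marker"] = markers if markers is not None else 0.0
    for k, v in cov.items():
        df[k] = v
    return df


# ---------------------------------------------------------------- KM


class TestKaplanMeier:
    def test_all_censored_is_constant_one(self):
        km = kaplan_meier(frame([3, 5, 8], [0, 0, 0]))
        assert np.all(km.survival == 1.0)

    def test_three_events_product_limit(self):
        km = kaplan_meier(frame([1, 2, 3], [1, 1, 1]))
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(2) == pytest.approx(1 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_censoring_in_risk_set(self):
        km = kaplan_meier(frame([5, 10], [1, 0]))
        assert km.at(5) == pytest.approx(0.5)
        assert km.at(10) == pytest.approx(0.5)

    def test_curve_monotone_and_starts_at_one(self):
        rng = np.random.default_rng(1)
        km = kaplan_meier(frame(rng.exponential(10, 50) + 0.1,
                                rng.integers(0, 2, 50)))
        assert km.at(0) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_invariant_to_record_order(self):
        df = frame([4, 1, 9, 2, 7], [1, 0, 1, 1, 0])
        a = kaplan_meier(df)
        b = kaplan_meier(df.sample(frac=1, random_state=0))
        assert np.array_equal(a.times, b.times)
        assert np.allclose(a.survival, b.survival)


# ---------------------------------------------------------------- log-rank


def logrank_oracle(a, b):
    """Per-event-time O-E and hypergeometric variance arithmetic."""
    times = sorted(set(a.loc[a.event == 1, "time"]) | set(b.loc[b.event == 1, "time"]))
    O_minus_E = 0.0
    V = 0.0
    for t in times:
        n1 = (a.time >= t).sum()
        n2 = (b.time >= t).sum()
        d1 = ((a.time == t) & (a.event == 1)).sum()
        d2 = ((b.time == t) & (b.event == 1)).sum()
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        O_minus_E += d1 - d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    stat = O_minus_E**2 / V
    return stat, chi2.sf(stat, 1)


class TestLogrank:
    def test_identical_groups(self):
        g = frame([1, 2, 3, 4], [1, 1, 0, 1])
        stat, p = logrank_test(g, g.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_anywhere(self):
        stat, p = logrank_test(frame([1, 2], [0, 0]), frame([3], [0]))
        assert (stat, p) == (0.0, 1.0)

    def test_matches_per_event_time_arithmetic(self):
        a = frame([6, 13, 21, 30, 37, 38], [1, 1, 1, 1, 0, 1])
        b = frame([10, 10, 12, 28, 35, 40], [1, 0, 1, 1, 1, 0])
        stat, p = logrank_test(a, b)
        o_stat, o_p = logrank_oracle(a, b)
        assert stat == pytest.approx(o_stat, rel=1e-9)
        assert p == pytest.approx(o_p, rel=1e-9)

    def test_symmetric_under_group_swap(self):
        a = frame([1, 4, 6, 9], [1, 1, 0, 1])
        b = frame([2, 3, 8], [1, 0, 1])
        sa, pa = logrank_test(a, b)
        sb, pb = logrank_test(b, a)
        assert sa == pytest.approx(sb) and pa == pytest.approx(pb)

    def test_null_type_one_error_rate(self):
        # under the null (one population split at random), p < 0.05 ~ 5%
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            t = rng.exponential(50, 60) + 0.01
            e = (rng.random(60) < 0.7).astype(int)
            half = 30
            _, p = logrank_test(frame(t[:half], e[:half]), frame(t[half:], e[half:]))
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


# ---------------------------------------------------------------- C-index


def cindex_oracle(times, events, markers):
    """Exhaustive Harrell pair enumeration, higher marker = worse."""
    num = den = 0.0
    for i, j in itertools.combinations(range(len(times)), 2):
        if times[i] == times[j]:
            continue  # only pairs orderable in time
        first, second = (i, j) if times[i] < times[j] else (j, i)
        if not events[first]:
            continue  # earlier-time patient censored: not comparable
        den += 1
        if markers[first] > markers[second]:
            num += 1
        elif markers[first] == markers[second]:
            num += 0.5
    return num / den if den else float("nan")


class TestConcordance:
    def test_perfect_anti_ordering(self):
        df = frame([1, 2, 3, 4], [1, 1, 1, 1], markers=[4, 3, 2, 1])
        assert concordance_index(df) == 1.0

    def test_all_markers_equal(self):
        df = frame([1, 2, 3], [1, 1, 1], markers=[2, 2, 2])
        assert concordance_index(df) == 0.5

    def test_five_record_brute_force(self):
        df = frame([3, 1, 8, 5, 2], [1, 1, 0, 1, 0], markers=[0.6, 0.9, 0.1, 0.4, 0.5])
        expected = cindex_oracle(df.time.to_numpy(), df.event.to_numpy(),
                                 df.marker.to_numpy())
        assert concordance_index(df) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_sets_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        df = frame(rng.exponential(10, n) + 0.1, rng.integers(0, 2, n),
                   markers=rng.random(n))
        expected = cindex_oracle(df.time.to_numpy(), df.event.to_numpy(),
                                 df.marker.to_numpy())
        got = concordance_index(df)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_negated_marker_complements(self):
        rng = np.random.default_rng(9)
        df = frame(rng.exponential(10, 12) + 0.1, rng.integers(0, 2, 12),
                   markers=rng.random(12))
        c = concordance_index(df)
        neg = df.assign(marker=-df.marker)
        assert c + concordance_index(neg) == pytest.approx(1.0)


# ---------------------------------------------------------------- cutoff


class TestFindOptimalCutoff:
    def _separated_cohort(self):
        rng = np.random.default_rng(2)
        low = frame(rng.exponential(120, 50) + 0.1, np.ones(50, int),
                    markers=rng.uniform(0.0, 0.3, 50))
        high = frame(rng.exponential(20, 50) + 0.1, np.ones(50, int),
                     markers=rng.uniform(0.7, 1.0, 50))
        return pd.concat([low, high], ignore_index=True)

    def test_cutoff_falls_in_the_gap(self):
        cutoff = find_optimal_cutoff(self._separated_cohort())
        assert 0.3 <= cutoff <= 0.7

    def test_group_size_constraint_excludes_extremes(self):
        df = self._separated_cohort().iloc[:20]
        candidates = np.quantile(df.marker, [0.02, 0.5, 0.98])
        cutoff = find_optimal_cutoff(df, candidates=candidates, min_group_fraction=0.1)
        # extremes leave <2 of 20 in a group and must be excluded
        assert cutoff == pytest.approx(candidates[1])

    def test_matches_exhaustive_grid_evaluation(self):
        df = self._separated_cohort()
        candidates = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
        cutoff = find_optimal_cutoff(df, candidates=candidates)
        best = None
        for c in candidates:
            high = df.marker > c
            if min(high.sum(), (~high).sum()) < 0.1 * len(df):
                continue
            _, p = logrank_test(df[~high], df[high])
            if best is None or p < best[0] or (p == best[0] and c < best[1]):
                best = (p, c)
        assert cutoff == pytest.approx(best[1])

    def test_no_feasible_candidate_errors(self):
        df = frame([1, 2, 3, 4], [1, 1, 1, 1], markers=[0.5] * 4)
        with pytest.raises(NoFeasibleCutoffError):
            find_optimal_cutoff(df)


# ---------------------------------------------------------------- CV


class TestCombinedStatistics:
    def test_combined_p_is_twice_median(self):
        s = combine_fold_stats([(0.4, 0.01, 0.7), (0.4, 0.02, 0.7), (0.4, 0.03, 0.7)])
        assert s.combined_p == pytest.approx(0.04)

    def test_combined_p_capped_at_one(self):
        s = combine_fold_stats([(0.4, 0.6, 0.6), (0.4, 0.9, 0.6), (0.4, 0.8, 0.6)])
        assert s.combined_p == 1.0

    def test_combined_c_mean_and_sd(self):
        s = combine_fold_stats([(0.3, 0.1, 0.7), (0.4, 0.1, 0.7), (0.5, 0.1, 0.7)])
        assert s.combined_c_mean == pytest.approx(0.7)
        assert s.combined_c_sd == pytest.approx(0.0, abs=1e-12)
        assert s.chosen_cutoff == 0.4

    def test_combined_p_never_below_median(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ps = rng.random(3)
            s = combine_fold_stats([(0.5, p, 0.6) for p in ps])
            assert np.median(ps) <= s.combined_p <= 1.0


class TestCrossValidate:
    def _cohort(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        markers = rng.uniform(0, 1, n)
        recs = simulate_cohort(markers, CohortSimConfig(n_patients=n, seed=seed))
        return records_to_frame(recs)

    def test_three_folds_reported(self):
        s = cross_validate_marker(self._cohort(), k=3, seed=1)
        assert len(s.per_fold) == 3
        assert 0 < s.combined_p <= 1.0

    def test_deterministic_under_seed(self):
        a = cross_validate_marker(self._cohort(), k=3, seed=4)
        b = cross_validate_marker(self._cohort(), k=3, seed=4)
        assert a.per_fold == b.per_fold

    def test_event_free_fold_raises(self):
        df = frame([1, 2, 3, 4, 5, 6], [1, 0, 0, 0, 0, 0],
                   markers=[0.1, 0.9, 0.2, 0.8, 0.3, 0.7])
        with pytest.raises(EmptyFoldError):
            cross_validate_marker(df, k=3, seed=0, candidates=np.array([0.5]),
                                  min_group_fraction=0.0)

    def test_bad_k(self):
        with pytest.raises(ValueError):
            cross_validate_marker(self._cohort(), k=1)


# ---------------------------------------------------------------- Cox


class TestCoxFit:
    def test_constant_covariate_dropped_to_unit_hr(self):
        df = frame([1, 2, 3, 4], [1, 1, 0, 1], constant=[1, 1, 1, 1])
        res = cox_fit(df, ["constant"])
        t = res.term("constant")
        assert t.hazard_ratio == 1.0 and t.coef == 0.0

    def test_four_record_closed_form(self):
        # events at t=1 (x=1) and t=2 (x=0), censored x=1 and x=0 at t=3:
        # dlogL/db = 0 solves to exp(b) = sqrt(2)
        df = frame([1, 2, 3, 3], [1, 1, 0, 0], x=[1, 0, 1, 0])
        res = cox_fit(df, ["x"])
        assert res.term("x").coef == pytest.approx(math.log(2) / 2, abs=1e-5)
        assert res.term("x").hazard_ratio == pytest.approx(math.sqrt(2), abs=1e-4)

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.01 * np.where(x == 1, 2.0, 1.0)))
        df = frame(np.maximum(t, 1e-6), np.ones(n, int), x=x)
        res = cox_fit(df, ["x"])
        term = res.term("x")
        assert 1.8 <= term.hazard_ratio <= 2.2
        assert term.ci_lower < term.hazard_ratio < term.ci_upper
        assert term.p < 0.001

    def test_univariate_vs_multivariate_layout(self):
        rng = np.random.default_rng(3)
        n = 200
        df = frame(rng.exponential(50, n) + 0.1, rng.integers(0, 2, n),
                   a=rng.random(n), b=rng.random(n))
        uni = cox_fit(df, ["a", "b"], model_type="UNIVARIATE")
        multi = cox_fit(df, ["a", "b"], model_type="MULTIVARIATE")
        assert {t.name for t in uni.terms} == {t.name for t in multi.terms} == {"a", "b"}
        for res in (uni, multi):
            for t in res.terms:
                assert t.ci_lower <= t.hazard_ratio <= t.ci_upper
                assert t.hazard_ratio > 0

    def test_no_events_rejected(self):
        df = frame([1, 2], [0, 0], x=[0, 1])
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])


# ---------------------------------------------------------------- stratify


def test_stratify_at_fixed_cutoff_reports_both_curves():
    rng = np.random.default_rng(5)
    n = 120
    markers = rng.uniform(0, 1, n)
    recs = simulate_cohort(markers, CohortSimConfig(n_patients=n, hazard_ratio_high=3.0,
                                                    score_threshold=0.375, seed=5))
    df = records_to_frame(recs)
    res = stratify_at_cutoff(df, 0.375)
    assert res.group_high.sum() + (~res.group_high).sum() == n
    assert res.logrank_p < 0.05
    assert res.km_low.at(0) == res.km_high.at(0) == 1.0


def test_survival_record_validation():
    with pytest.raises(ValueError):
        SurvivalRecord("p", -1.0, 1, 0.5)
    with pytest.raises(ValueError):
        SurvivalRecord("p", 10.0, 2, 0.5)
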