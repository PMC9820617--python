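"""Kaplan-Meier medians, Cox hazard ratios, pairwise log-rank, risk scores."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glioma_cns5.cohort import CaseAnnotation, ExpressionMatrix
from glioma_cns5.rules import classify_cohort
from glioma_cns5.survival import (
    CNS5_GROUPS,
    LEGACY_GROUPS,
    PairwiseResult,
    RiskScoreModel,
    cox_hr,
    km_curve,
    km_median,
    pairwise_logrank,
    risk_split,
    significant_fraction,
    stars,
    survival_groups,
)


def km_median_oracle(times, events):
    """Hand-rolled product-limit estimate: first t with S(t) <= 0.5."""
    times, events = np.asarray(times, dtype=float), np.asarray(events, dtype=int)
    order = np.lexsort((-events, times))  # at ties, deaths precede censorings
    t, e = times[order], events[order]
    at_risk, s = len(t), 1.0
    for ti, ei in zip(t, e):
        if ei:
            s *= (at_risk - 1) / at_risk
        at_risk -= 1
        if ei and s <= 0.5:
            return ti
    return np.nan


class TestKmMedian:
    def test_uncensored_hand_example(self):
        res = km_median([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert res.median == 3 == km_median_oracle([1, 2, 3, 4, 5], [1] * 5)

    def test_single_censored_observation_is_na(self):
        res = km_median([10.0], [0])
        assert np.isnan(res.median)

    def test_all_censored_is_na(self):
        res = km_median([5, 8, 9], [0, 0, 0])
        assert np.isnan(res.median) and res.n_events == 0

    def test_matches_oracle_on_random_censored_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            t = rng.exponential(10, n).round(2)
            e = rng.integers(0, 2, n)
            got = km_median(t, e).median
            want = km_median_oracle(t, e)
            assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(14.0 / np.log(2), size=5000)
        res = km_median(t, np.ones(5000, dtype=int))
        assert res.median == pytest.approx(14.0, abs=0.5)
        assert res.ci_lower <= res.median <= res.ci_upper

    def test_curve_is_monotone_step_function_from_one(self):
        rng = np.random.default_rng(2)
        sf = km_curve(rng.exponential(5, 50), rng.integers(0, 2, 50))
        vals = sf["survival"].to_numpy()
        assert vals[0] == 1.0
        assert (np.diff(vals) <= 1e-12).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            km_median([], [])
        with pytest.raises(ValueError):
            km_median([-1.0], [1])


class TestCoxHr:
    def exp_two_groups(self, hr=0.32, n=400, seed=0):
        rng = np.random.default_rng(seed)
        lam = np.log(2) / 14.0
        t_ref = rng.exponential(1 / lam, n)
        t_b = rng.exponential(1 / (lam * hr), n)
        groups = ["REF"] * n + ["B"] * n
        times = np.r_[t_ref, t_b]
        events = np.ones(2 * n, dtype=int)
        return groups, times, events

    def test_reference_has_unit_hr(self):
        g, t, e = self.exp_two_groups()
        res = cox_hr(g, t, e, "REF")
        ref = next(r for r in res if r.group == "REF")
        assert ref.hr == 1.0

    def test_recovers_planted_hr(self):
        g, t, e = self.exp_two_groups(hr=0.32, n=400, seed=3)
        res = cox_hr(g, t, e, "REF")
        b = next(r for r in res if r.group == "B")
        assert b.ci_lower < 0.32 < b.ci_upper

    def test_null_ci_contains_one(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 400)
        g = ["A"] * 200 + ["B"] * 200
        res = cox_hr(g, t, np.ones(400, dtype=int), "A")
        b = next(r for r in res if r.group == "B")
        assert b.ci_lower < 1.0 < b.ci_upper

    def test_swapping_reference_inverts_hr(self):
        g, t, e = self.exp_two_groups(hr=0.5, n=150, seed=5)
        hr_ab = next(r for r in cox_hr(g, t, e, "REF") if r.group == "B").hr
        hr_ba = next(r for r in cox_hr(g, t, e, "B") if r.group == "REF").hr
        assert hr_ab == pytest.approx(1.0 / hr_ba, rel=1e-6)

    def test_zero_event_group_flagged_unstable(self):
        g = ["A"] * 30 + ["B"] * 30
        t = np.r_[np.random.default_rng(6).exponential(5, 30), np.full(30, 50.0)]
        e = np.r_[np.ones(30, dtype=int), np.zeros(30, dtype=int)]
        res = cox_hr(g, t, e, "A")
        b = next(r for r in res if r.group == "B")
        assert b.unstable

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            cox_hr(["A", "B"], [1, 2], [1, 1], "Z")


class TestPairwise:
    def grouped_exp(self, medians, n=60, seed=0):
        rng = np.random.default_rng(seed)
        groups, times = [], []
        for name, med in medians.items():
            groups += [name] * n
            times.append(rng.exponential(med / np.log(2), n))
        return groups, np.concatenate(times), np.ones(n * len(medians), dtype=int)

    def test_seven_groups_yield_21_pairs(self):
        g, t, e = self.grouped_exp({f"G{i}": 10 + 5 * i for i in range(7)})
        res = pairwise_logrank(g, t, e)
        assert res.n_pairs == 21
        assert len(res.pair_frame()) == 21

    def test_six_groups_yield_15_pairs(self):
        g, t, e = self.grouped_exp({f"G{i}": 10 + 5 * i for i in range(6)})
        assert pairwise_logrank(g, t, e).n_pairs == 15

    def test_hr_matrix_inverts_symmetrically(self):
        g, t, e = self.grouped_exp({"A": 10, "B": 30, "C": 60}, seed=1)
        res = pairwise_logrank(g, t, e)
        for a, b in itertools.combinations(res.groups, 2):
            assert res.hr.loc[a, b] == pytest.approx(1.0 / res.hr.loc[b, a])
        assert np.allclose(res.p.to_numpy(), res.p.to_numpy().T, equal_nan=True)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 40)
        g = ["A", "B"] * 20  # arbitrary split of one sample set
        res = pairwise_logrank(g, t, np.ones(40, dtype=int))
        assert res.p.loc["A", "B"] > 0.05

    def test_bh_adjustment_is_monotone(self):
        g, t, e = self.grouped_exp({"A": 5, "B": 20, "C": 80, "D": 20.5}, seed=2)
        res = pairwise_logrank(g, t, e, adjust="BH")
        for a, b in itertools.combinations(res.groups, 2):
            assert res.p_adjusted.loc[a, b] >= res.p.loc[a, b] - 1e-15

    def test_stars_thresholds(self):
        assert stars(0.0005) == "***"
        assert stars(0.005) == "**"
        assert stars(0.05) == "*"
        assert stars(0.2) == ""


def synthetic_pairwise(n_groups, sig_pairs):
    """A PairwiseResult carrying a crafted p matrix (for summary arithmetic)."""
    groups = tuple(f"G{i}" for i in range(n_groups))
    p = pd.DataFrame(np.nan, index=groups, columns=groups, dtype=float)
    for j, (a, b) in enumerate(itertools.combinations(groups, 2)):
        val = 0.01 if j < sig_pairs else 0.5
        p.loc[a, b] = p.loc[b, a] = val
    hr = pd.DataFrame(1.0, index=groups, columns=groups)
    return PairwiseResult(groups, p, p.copy(), hr, alpha=0.05, adjust="none")


class TestSignificantFraction:
    @pytest.mark.parametrize("n_groups, n_sig, expected_pct", [
        (7, 12, 57),
        (6, 11, 73),
        (5, 0, 0),
    ])
    def test_percent_rounding(self, n_groups, n_sig, expected_pct):
        res = synthetic_pairwise(n_groups, n_sig)
        frac = significant_fraction(res)
        assert frac["n_sig"] == n_sig
        assert frac["n_pairs"] == n_groups * (n_groups - 1) // 2
        assert frac["percent"] == expected_pct

    def test_invariant_to_group_order(self):
        res = synthetic_pairwise(6, 7)
        rev = PairwiseResult(tuple(reversed(res.groups)), res.p, res.p_adjusted,
                             res.hr, res.alpha, res.adjust)
        assert significant_fraction(res) == significant_fraction(rev)


class TestRiskSplit:
    def planted(self, n=300, log_hr_per_sd=0.7, seed=0):
        rng = np.random.default_rng(seed)
        genes = ["FN1", "ITGA5", "OSMR", "NGFR"]
        log2x = rng.normal(5, 1, size=(4, n))
        vals = pd.DataFrame(np.power(2.0, log2x), index=genes,
                            columns=[f"s{i:03d}" for i in range(n)])
        expr = ExpressionMatrix(vals)
        model = RiskScoreModel({g: 1.0 for g in genes})
        score = vals.sum(axis=0)
        z = (score - score.mean()) / score.std()
        lam = (np.log(2) / 20.0) * np.exp(log_hr_per_sd * z.to_numpy())
        times = rng.exponential(1.0 / lam)
        return model, expr, times, np.ones(n, dtype=int)

    def test_planted_effect_recovered(self):
        model, expr, t, e = self.planted(seed=1)
        res = risk_split(model, expr, t, e)
        assert res.hr_high_vs_low > 1.0
        assert res.p < 0.05
        assert set(res.labels.unique()) == {"high", "low"}

    def test_patient_permutation_invariance(self):
        model, expr, t, e = self.planted(n=120, seed=2)
        res1 = risk_split(model, expr, t, e)
        perm = np.random.default_rng(3).permutation(120)
        expr2 = ExpressionMatrix(expr.values.iloc[:, perm],
                                 {s: s for s in expr.values.columns[perm]})
        res2 = risk_split(model, expr2, np.asarray(t)[perm], np.asarray(e)[perm])
        assert res1.hr_high_vs_low == pytest.approx(res2.hr_high_vs_low, rel=1e-9)

    def test_zero_coefficients_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            RiskScoreModel({"FN1": 0.0})

    def test_missing_genes_listed(self):
        model, expr, t, e = self.planted(n=50, seed=4)
        bad = RiskScoreModel({"FN1": 1.0, "NOT_A_GENE": 2.0})
        with pytest.raises(ValueError, match="NOT_A_GENE"):
            risk_split(bad, expr, t, e)

    def test_identical_scores_rejected(self):
        vals = pd.DataFrame(np.ones((1, 10)), index=["FN1"],
                            columns=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="identical"):
            risk_split(RiskScoreModel({"FN1": 1.0}), ExpressionMatrix(vals),
                       np.ones(10), np.ones(10, dtype=int))


class TestSurvivalGroups:
    def test_legacy_and_cns5_group_labels(self, sim_cohort):
        cases, _ = sim_cohort
        res = classify_cohort(cases)
        gl = survival_groups(cases, grouping="legacy")
        gc = survival_groups(cases, res.diagnoses, grouping="cns5")
        assert set(gl["group"]) <= set(LEGACY_GROUPS)
        assert set(gc["group"]) <= set(CNS5_GROUPS)
        # cases without survival data are dropped
        with_os = [c for c in cases if c.os_time is not None and c.os_event is not None]
        assert len(gl) <= len(with_os)

    def test_cns5_grouping_requires_diagnoses(self, sim_cohort):
        cases, _ = sim_cohort
        with pytest.raises(ValueError, match="diagnoses"):
            survival_groups(cases, grouping="cns5")
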