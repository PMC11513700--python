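"""Contingency, rank, multiple-testing and survival statistics.

The Fisher test is cross-checked against an independent full hypergeometric
enumeration; the chi-square closed form against the generic sum over
observed-vs-expected cells.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from egcstrat.stats import (
    ContingencyTable2x2,
    Kodama,
    TestMethod,
    bh_adjust,
    choose_test,
    clinical_to_frame,
    cox_univariate,
    fisher_exact_2x2,
    km_logrank,
    pearson_chi2_2x2,
    t_test,
    wilcoxon_rank_sum,
)
from egcstrat.stats import ClinicalRecord


def enumerate_fisher_p(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher p by explicit enumeration of all tables with the
    observed margins, summing point probabilities <= the observed one."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.total

    def point_prob(a):
        return (
            math.comb(r1, a) * math.comb(r2, c1 - a) / math.comb(n, c1)
        )

    p_obs = point_prob(t.a)
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = point_prob(a)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def random_survival_frame(rng, n, hazard_ratio, censor_rate=0.4, horizon=120.0):
    """Exponential DFS with a binary covariate scaling the hazard."""
    flag = rng.random(n) < 0.5
    lam = 0.0074 * np.where(flag, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    lam_c = 0.0074 * censor_rate / (1 - censor_rate)
    t_cens = np.minimum(rng.exponential(1.0 / lam_c, size=n), horizon)
    return pd.DataFrame(
        {
            "dfs_time": np.minimum(t_event, t_cens),
            "event": t_event <= t_cens,
            "flag": flag,
        }
    )


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,printed",
        [
            ((6, 7, 0, 14), 0.006),   # ARID1A carriers concentrated in one subtype
            ((3, 11, 1, 12), 0.596),  # lymphovascular invasion split
            ((11, 3, 8, 5), 0.420),   # nodal status split
        ],
    )
    def test_reproduces_reported_two_sided_p(self, table, printed):
        t = ContingencyTable2x2(*table)
        res = fisher_exact_2x2(t)
        assert round(res.p_value, 3) == printed
        assert res.p_value == pytest.approx(enumerate_fisher_p(t), rel=1e-7)

    def test_zero_margin_single_table_p_one(self):
        res = fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 7))
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 0, 0))

    @given(hst.tuples(*[hst.integers(0, 12)] * 4))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle_and_swap_invariance(self, counts):
        a, b, c, d = counts
        if a + b + c + d == 0:
            return
        t = ContingencyTable2x2(a, b, c, d)
        p = fisher_exact_2x2(t).p_value
        assert p == pytest.approx(enumerate_fisher_p(t), rel=1e-7, abs=1e-12)
        swapped = ContingencyTable2x2(d, c, b, a)  # both rows and columns
        assert fisher_exact_2x2(swapped).p_value == pytest.approx(p, rel=1e-9)


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "table,printed",
        [
            ((7, 7, 8, 5), 0.547),  # sex split
            ((8, 6, 5, 8), 0.332),  # tumor-location split
        ],
    )
    def test_reproduces_reported_p(self, table, printed):
        res = pearson_chi2_2x2(ContingencyTable2x2(*table))
        assert round(res.p_value, 3) == printed

    def test_closed_form_statistic(self):
        res = pearson_chi2_2x2(ContingencyTable2x2(7, 7, 8, 5))
        assert res.statistic == pytest.approx(0.3635, abs=5e-4)

    def test_balanced_table_statistic_zero(self):
        res = pearson_chi2_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2(ContingencyTable2x2(0, 0, 3, 5))

    @given(hst.tuples(*[hst.integers(1, 30)] * 4))
    @settings(max_examples=60, deadline=None)
    def test_equals_generic_observed_expected_form(self, counts):
        t = ContingencyTable2x2(*counts)
        obs = t.as_array()
        exp = t.expected()
        generic = float(((obs - exp) ** 2 / exp).sum())
        assert pearson_chi2_2x2(t).statistic == pytest.approx(generic, rel=1e-10)


class TestChooseTest:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((11, 3, 8, 5), TestMethod.FISHER_EXACT),   # min expected 3.85
            ((7, 7, 8, 5), TestMethod.PEARSON_CHI2),    # min expected 5.78
            ((100, 100, 100, 100), TestMethod.PEARSON_CHI2),
        ],
    )
    def test_expected_count_rule(self, table, expected):
        assert choose_test(ContingencyTable2x2(*table)) is expected


class TestWilcoxonRankSum:
    def test_exact_small_sample_p(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 5], [1, 2, 5], exact=True)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 200)
        y = rng.normal(2, 1, 200)
        assert wilcoxon_rank_sum(x, y).p_value < 1e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBhAdjust:
    def test_step_up_small_family(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_capped(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(hst.lists(hst.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_order_equivariant_and_dominating(self, ps):
        adj = bh_adjust(ps)
        perm = list(reversed(range(len(ps))))
        adj_perm = bh_adjust([ps[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(a <= 1.0 + 1e-12 for a in adj)


class TestCoxUnivariate:
    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(11)
        df = random_survival_frame(rng, 500, hazard_ratio=2.0, censor_rate=0.5)
        fit = cox_univariate(df, "flag")
        assert 1.6 <= fit.hazard_ratio <= 2.5
        assert fit.ci_low <= fit.hazard_ratio <= fit.ci_high

    def test_null_covariate_ci_covers_one_in_most_seeds(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            df = random_survival_frame(rng, 300, hazard_ratio=1.0)
            fit = cox_univariate(df, "flag")
            if fit.ci_low <= 1.0 <= fit.ci_high:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"dfs_time": [5.0, 8.0, 10.0], "event": [False, False, False],
             "flag": [True, False, True]}
        )
        with pytest.raises(ValueError, match="events"):
            cox_univariate(df, "flag")

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame(
            {"dfs_time": [5.0, 8.0, 10.0, 3.0], "event": [True, True, False, True],
             "flag": [True, True, True, True]}
        )
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(df, "flag")

    def test_efron_ties_close_to_breslow_without_ties(self):
        rng = np.random.default_rng(3)
        df = random_survival_frame(rng, 300, hazard_ratio=2.0)
        breslow = cox_univariate(df, "flag", ties="breslow")
        efron = cox_univariate(df, "flag", ties="efron")
        assert efron.hazard_ratio == pytest.approx(breslow.hazard_ratio, rel=0.02)


class TestKmLogrank:
    @staticmethod
    def _records(times, events, group_of):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(len(times))],
                "dfs_time": times,
                "event": events,
                "grp": group_of,
            }
        )

    def test_identical_groups_p_one(self):
        times = [5.0, 8.0, 12.0, 20.0, 30.0] * 2
        events = [True, False, True, True, False] * 2
        groups = ["a"] * 5 + ["b"] * 5
        _, res = km_logrank(self._records(times, events, groups), "grp")
        assert res.p_value == pytest.approx(1.0)

    def test_separated_exponentials_detected(self):
        rng = np.random.default_rng(5)
        t1 = rng.exponential(1.0, 200)
        t2 = rng.exponential(1 / 3, 200)
        df = self._records(
            np.concatenate([t1, t2]).tolist(),
            [True] * 400,
            ["a"] * 200 + ["b"] * 200,
        )
        curves, res = km_logrank(df, "grp")
        assert res.p_value < 1e-3
        assert {c.group for c in curves} == {"a", "b"}

    def test_all_censored_group_handled(self):
        df = self._records(
            [5.0, 8.0, 10.0, 4.0, 6.0, 9.0],
            [True, True, False, False, False, False],
            ["a", "a", "a", "b", "b", "b"],
        )
        curves, res = km_logrank(df, "grp")
        b = next(c for c in curves if c.group == "b")
        assert b.n_events == 0
        assert 0.0 <= res.p_value <= 1.0

    def test_single_group_rejected(self):
        df = self._records([5.0, 8.0], [True, True], ["a", "a"])
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(df, "grp")


class TestClinicalRecords:
    def test_frame_roundtrip_and_invariants(self):
        rec = ClinicalRecord(
            "P1", Kodama.PEN_A, 67.0, "F", "lower", "intestinal", "g3",
            "pn0", 0.0, False, 2.0, 48.0, True,
        )
        df = clinical_to_frame([rec])
        assert df.loc[0, "kodama"] == "pen_a"
        with pytest.raises(ValueError):
            ClinicalRecord("P1", Kodama.PEN_A, 67.0, "F", "lower", "intestinal",
                           "g3", "pn0", 1.4, False, 2.0, 48.0, True)

    def test_t_test_matches_pooled_formula(self):
        x = [63.0, 71.0, 58.0, 75.0]
        y = [61.0, 69.0, 77.0, 80.0, 66.0]
        res = t_test(x, y)
        assert 0.0 <= res.p_value <= 1.0
        assert res.method is TestMethod.T_TEST
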