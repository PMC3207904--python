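from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import chromshift as cs
from chromshift.stats import (ContingencyTable, ks_asymptotic_p,
                              ks_rank_enrichment, transition_expression_report)


def _ranked(n):
    return pd.DataFrame({"rank": range(1, n + 1)},
                        index=[f"g{i:04d}" for i in range(n)])


def fisher_oracle(a, b, c, d, sided="greater") -> float:
    """Independent oracle: exact hypergeometric enumeration in rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = comb(n, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), total)
             for x in range(lo, hi + 1)}
    if sided == "greater":
        return float(sum(p for x, p in probs.items() if x >= a))
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestKsStatistic:
    def test_complete_separation(self):
        res = ks_rank_enrichment(_ranked(4), {"g0000", "g0001"})
        assert res.statistic == 1.0
        assert res.direction == "upward"

    def test_exact_permutation_enumeration(self):
        """All C(4,2)=6 placements; two of them reach D=1 -> p = 2/6."""
        res = ks_rank_enrichment(_ranked(4), {"g0000", "g0001"},
                                 method="permutation")
        assert res.p_value == pytest.approx(2 / 6)

    def test_interleaved_pattern_is_null(self):
        subset = {f"g{i:04d}" for i in range(0, 100, 2)}
        res = ks_rank_enrichment(_ranked(100), subset)
        assert res.statistic <= 0.05
        assert res.p_value > 0.5

    def test_brute_force_ecdf_agreement(self):
        """D matches a direct ECDF sweep on random subsets."""
        rng = np.random.default_rng(0)
        ranked = _ranked(60)
        for _ in range(20):
            k = int(rng.integers(5, 55))
            sub_idx = rng.choice(60, size=k, replace=False)
            subset = set(ranked.index[sub_idx])
            res = ks_rank_enrichment(ranked, subset)
            ranks = np.arange(1, 61)
            in_sub = np.isin(ranks - 1, sub_idx)
            grid = np.arange(0, 61)
            f1 = np.searchsorted(np.sort(ranks[in_sub]), grid, "right") / k
            f2 = np.searchsorted(np.sort(ranks[~in_sub]), grid, "right") / (60 - k)
            assert res.statistic == pytest.approx(np.abs(f1 - f2).max())

    def test_scipy_cross_check(self):
        """Two-sided statistic and p agree with an independent implementation."""
        from scipy.stats import ks_2samp
        rng = np.random.default_rng(1)
        ranked = _ranked(300)
        sub_idx = rng.choice(300, size=40, replace=False)
        subset = set(ranked.index[sub_idx])
        res = ks_rank_enrichment(ranked, subset)
        ranks = np.arange(1, 301)
        ref = ks_2samp(ranks[np.isin(ranks - 1, sub_idx)],
                       ranks[~np.isin(ranks - 1, sub_idx)])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.15)

    def test_depends_only_on_ranks(self):
        """Any strictly monotone transform of fold leaves the result fixed."""
        rng = np.random.default_rng(2)
        folds = np.sort(rng.uniform(0.1, 50, size=80))[::-1]
        t1 = pd.DataFrame({"fold": folds, "rank": range(1, 81)},
                          index=[f"g{i:04d}" for i in range(80)])
        t2 = t1.assign(fold=np.log(t1["fold"]))
        subset = set(t1.index[rng.choice(80, 15, replace=False)])
        r1 = ks_rank_enrichment(t1, subset)
        r2 = ks_rank_enrichment(t2, subset)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_degenerate_subsets_raise(self):
        ranked = _ranked(10)
        with pytest.raises(ValueError):
            ks_rank_enrichment(ranked, set())
        with pytest.raises(ValueError):
            ks_rank_enrichment(ranked, set(ranked.index))

    def test_permutation_asymptotic_agreement(self):
        """The two p-value routes agree within 2x in the moderate-p band."""
        rng = np.random.default_rng(3)
        n = 160
        ranked = _ranked(n)
        checked = 0
        for k, bias in [(60, 1.2), (70, 0.8), (55, 1.6)]:
            w = np.exp(-bias * np.arange(n) / n)
            idx = rng.choice(n, size=k, replace=False, p=w / w.sum())
            subset = set(ranked.index[idx])
            asym = ks_rank_enrichment(ranked, subset)
            perm = ks_rank_enrichment(ranked, subset, method="permutation",
                                      n_perm=6000,
                                      rng=np.random.default_rng(11))
            if 5e-3 < perm.p_value < 0.5:
                assert 0.5 < asym.p_value / perm.p_value < 2.0
                checked += 1
        assert checked >= 2

    def test_one_sided_tail_behaviour(self):
        """A subset at the top is significant upward but not downward."""
        ranked = _ranked(200)
        subset = set(ranked.index[:25])
        up = ks_rank_enrichment(ranked, subset, sided="greater")
        down = ks_rank_enrichment(ranked, subset, sided="less")
        assert up.p_value < 1e-6
        assert down.p_value > 0.5


class TestTypeIError:
    def test_uniform_null_rejection_rate(self):
        """Type-I error at alpha=0.05 under uniform subset placement."""
        rng = np.random.default_rng(42)
        n, k, reps = 500, 40, 500
        ranked = _ranked(n)
        rej = 0
        for _ in range(reps):
            subset = set(ranked.index[rng.choice(n, k, replace=False)])
            rej += ks_rank_enrichment(ranked, subset).p_value < 0.05
        assert 0.025 <= rej / reps <= 0.10


class TestFisher:
    @pytest.mark.parametrize("table,want", [
        ((2, 0, 0, 2), Fraction(1, 6)),
        ((1, 1, 1, 1), Fraction(5, 6)),
        ((0, 5, 7, 3), Fraction(1)),  # a=0: the whole support is >= a
    ])
    def test_small_tables_against_enumeration(self, table, want):
        assert cs.fisher_exact(ContingencyTable(*table),
                               "greater") == pytest.approx(float(want))

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            assert cs.fisher_exact(t, "greater") == pytest.approx(
                fisher_oracle(a, b, c, d, "greater"), rel=1e-9)
            assert cs.fisher_exact(t, "two") == pytest.approx(
                fisher_oracle(a, b, c, d, "two"), rel=1e-7)

    def test_tail_complement_identity(self):
        """P(X>=a) + P(X<=a) - P(X=a) = 1 for the hypergeometric."""
        rng = np.random.default_rng(5)
        from scipy.stats import hypergeom
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 13, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            gt = cs.fisher_exact(t, "greater")
            lt = cs.fisher_exact(t, "less")
            point = hypergeom.pmf(a, a + b + c + d, a + b, a + c)
            assert gt + lt - point == pytest.approx(1.0, abs=1e-9)

    def test_tiny_p_values_representable(self):
        # strong enrichment in a large table: extreme tails stay finite
        p = cs.fisher_exact(ContingencyTable(300, 10, 20, 1000), "greater")
        assert 0 < p < 1e-250

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 3, 4)


class TestTransitionReport:
    def test_planted_pattern(self, transition_table, fold_table):
        """Coordinated switches are significant in their predicted direction;
        one-sided switches planted without expression shift are not."""
        rep = transition_expression_report(transition_table, fold_table)
        rep = rep.set_index("category")
        assert rep.loc["K27->K4", "p"] < 0.01
        assert rep.loc["K27->K4", "direction"] == "upward"
        assert rep.loc["K4->K27", "p"] < 0.05
        assert rep.loc["K4->K27", "direction"] == "downward"
        assert rep.loc["Bi->K4", "p"] > 0.05
        assert rep.loc["none->K27", "p"] > 0.05

    def test_empty_category_flagged_untestable(self, fold_table):
        trans = pd.DataFrame({
            "k27_transition": ["loss"] * 4,
            "category": ["K27->K4"] * 4,
        }, index=list(fold_table.index[:4]))
        rep = transition_expression_report(trans, fold_table)
        rep = rep.set_index("category")
        assert bool(rep.loc["K4->K27", "untestable"])
        # subset == background is degenerate too
        assert bool(rep.loc["K27->K4", "untestable"])


def test_asymptotic_p_monotone_in_d():
    ps = [ks_asymptotic_p(d, 100, 100) for d in (0.05, 0.1, 0.2, 0.4)]
    assert all(x > y for x, y in zip(ps, ps[1:]))
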