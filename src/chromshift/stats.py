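"""Rank-enrichment (Kolmogorov-Smirnov) and contingency (Fisher) statistics.

The KS rank-enrichment test asks whether a gene subset occupies
systematically high or low positions in a fold-change-sorted list.  The
default is a two-sample test of the subset's ranks against the complement's
ranks within the background ordering, two-sided for the p-value; the
"upward"/"downward" direction label is reported separately from the mean
normalized ranks.  A one-sample mode (subset ranks against the uniform) is
exposed for comparison.

The asymptotic p-value uses the standard series
p = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2)
with lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D and
ne = n1*n2/(n1+n2); a permutation mode re-places the subset uniformly
(exhaustively when the number of placements is small, Monte Carlo
otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, exp, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class EnrichmentResult:
    label: str
    statistic: float
    p_value: float
    direction: str  # 'upward' | 'downward'
    method: str  # 'asymptotic' | 'permutation'
    n_subset: int
    n_background: int
    untestable: bool = False


def _ks_statistic_from_ranks(subset_ranks: np.ndarray, n: int,
                             sided: str = "two") -> float:
    """Two-sample KS statistic between subset ranks and complement ranks.

    All ranks are distinct integers in 1..n, so the supremum of the ECDF gap
    reduces to a max over subset rank positions, evaluated just before and
    at each subset rank.  sided='two' gives D = sup|F1 - F2|;
    sided='greater' gives D+ = sup(F1 - F2) (subset concentrated at small
    ranks, i.e. upward in a descending-fold ordering); sided='less' gives
    D- = sup(F2 - F1).
    """
    n1 = subset_ranks.size
    n2 = n - n1
    r = np.sort(subset_ranks).astype(float)
    i = np.arange(1, n1 + 1, dtype=float)
    f1_at = i / n1                      # subset ECDF at its own ranks
    f1_before = (i - 1) / n1
    f2_at = (r - i) / n2                # complement ECDF at those ranks
    d_plus = float((f1_at - f2_at).max())
    d_minus = float((f2_at - f1_before).max())
    if sided == "greater":
        return max(d_plus, 0.0)
    if sided == "less":
        return max(d_minus, 0.0)
    return max(d_plus, d_minus)


def ks_asymptotic_p(d: float, n1: int, n2: int, sided: str = "two") -> float:
    ne = n1 * n2 / (n1 + n2)
    lam = (sqrt(ne) + 0.12 + 0.11 / sqrt(ne)) * d
    if sided in ("greater", "less"):
        # Smirnov one-sided tail: leading term of the series, not doubled
        p = exp(-2.0 * lam * lam)
        return float(min(max(p, np.finfo(float).tiny), 1.0))
    total = 0.0
    for k in range(1, 101):
        term = (-1) ** (k - 1) * exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-16:
            break
    return float(min(max(2.0 * total, np.finfo(float).tiny), 1.0))


def _ks_one_sample(subset_ranks: np.ndarray, n: int) -> tuple[float, float]:
    """Subset ranks against the uniform distribution on (0, n]."""
    n1 = subset_ranks.size
    r = np.sort(subset_ranks).astype(float)
    i = np.arange(1, n1 + 1, dtype=float)
    d = float(np.maximum(np.abs(i / n1 - r / n), np.abs((i - 1) / n1 - r / n)).max())
    lam = (sqrt(n1) + 0.12 + 0.11 / sqrt(n1)) * d
    total = sum((-1) ** (k - 1) * exp(-2.0 * k * k * lam * lam)
                for k in range(1, 101))
    return d, float(min(max(2.0 * total, np.finfo(float).tiny), 1.0))


def ks_rank_enrichment(ranked: pd.DataFrame, subset: set[str],
                       method: str = "asymptotic", sided: str = "two",
                       mode: str = "two_sample",
                       n_perm: int = 10000, max_exact: int = 50000,
                       rng: np.random.Generator | None = None,
                       label: str = "") -> EnrichmentResult:
    """KS enrichment of ``subset`` within a rank-ordered background.

    ``ranked`` is a fold-change table (gene_id index with a ``rank`` column);
    the background is exactly its index.  ``sided`` is 'two' (default), or
    a directional tail: 'greater' tests enrichment toward rank 1 (upward in
    a descending-fold list), 'less' toward the bottom.  Raises on a
    degenerate test (empty subset or subset == background).
    """
    gene_ids = ranked.index
    n = len(gene_ids)
    subset = set(subset)
    if not subset <= set(gene_ids):
        raise ValueError("subset is not contained in the background")
    n1 = len(subset)
    if n1 == 0 or n1 == n:
        raise ValueError("degenerate test: empty subset or subset == background")
    ranks = ranked["rank"].to_numpy()
    in_subset = gene_ids.isin(subset)
    subset_ranks = np.asarray(ranks[in_subset])
    compl_ranks = np.asarray(ranks[~in_subset])
    direction = ("upward" if subset_ranks.mean() < compl_ranks.mean()
                 else "downward")

    if mode == "one_sample":
        d, p = _ks_one_sample(subset_ranks, n)
        return EnrichmentResult(label, d, p, direction, "asymptotic", n1, n)
    if mode != "two_sample":
        raise ValueError(f"unknown mode {mode!r}")

    d = _ks_statistic_from_ranks(subset_ranks, n, sided)
    if method == "asymptotic":
        p = ks_asymptotic_p(d, n1, n - n1, sided)
    elif method == "permutation":
        p = _permutation_p(d, n, n1, n_perm, max_exact, rng, sided)
    else:
        raise ValueError(f"unknown method {method!r}")
    return EnrichmentResult(label, d, p, direction, method, n1, n)


def _permutation_p(d_obs: float, n: int, n1: int, n_perm: int,
                   max_exact: int, rng: np.random.Generator | None,
                   sided: str = "two") -> float:
    if comb(n, n1) <= max_exact:
        hits = total = 0
        for combo in itertools.combinations(range(1, n + 1), n1):
            total += 1
            if _ks_statistic_from_ranks(np.asarray(combo), n,
                                        sided) >= d_obs - 1e-12:
                hits += 1
        return hits / total
    if rng is None:
        rng = np.random.default_rng(0)
    hits = 0
    for _ in range(n_perm):
        ranks = rng.choice(n, size=n1, replace=False) + 1
        if _ks_statistic_from_ranks(ranks, n, sided) >= d_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification counts [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0):
            raise ValueError("a margin is zero: test undefined")


def fisher_exact(table: ContingencyTable, sided: str = "greater") -> float:
    """Fisher's exact p for a 2x2 table (hypergeometric tail).

    'greater' is the enrichment tail P(X >= a) under fixed margins;
    'two' sums all tables with point probability <= the observed one.
    """
    alt = {"greater": "greater", "two": "two-sided", "less": "less"}[sided]
    arr = [[table.a, table.b], [table.c, table.d]]
    return float(sps.fisher_exact(arr, alternative=alt)[1])


# panel backgrounds and tested tails for the transition report: categories
# are tested within the set of all repressive-mark losses or all gains,
# mirroring the published figure panels ("among the 284 genes"), in the
# direction the category predicts (loss categories upward, gain categories
# downward).  A directional test is what makes a flat category come out
# non-significant even when its panel complement contains strongly shifted
# coordinated genes.
_PANEL = {"K27->K4": ("loss", "greater"), "Bi->K4": ("loss", "greater"),
          "K4->K27": ("gain", "less"), "none->K27": ("gain", "less")}


def transition_expression_report(transitions: pd.DataFrame,
                                 ranked: pd.DataFrame,
                                 method: str = "asymptotic",
                                 rng: np.random.Generator | None = None
                                 ) -> pd.DataFrame:
    """One enrichment result per coordinated category.

    Each category is tested within its panel background: the coordinated
    activation categories within all repressive-mark-loss genes, the
    coordinated repression categories within all gain genes, each in its
    predicted direction.  Genes missing from the expression ranking are
    dropped from both subset and background.  Empty or full subsets are
    flagged untestable rather than raising.
    """
    rows = []
    for category, (panel, sided) in _PANEL.items():
        bg_ids = transitions.index[transitions["k27_transition"] == panel]
        bg_ids = [g for g in bg_ids if g in ranked.index]
        sub = set(transitions.index[transitions["category"] == category])
        sub &= set(bg_ids)
        if len(sub) == 0 or len(sub) >= len(bg_ids):
            rows.append((category, panel, sided, len(sub), len(bg_ids),
                         np.nan, np.nan, "", method, True))
            continue
        panel_ranked = ranked.loc[ranked.index.isin(bg_ids)].copy()
        panel_ranked = panel_ranked.sort_values("rank", kind="mergesort")
        panel_ranked["rank"] = range(1, len(panel_ranked) + 1)
        res = ks_rank_enrichment(panel_ranked, sub, method=method,
                                 sided=sided, rng=rng, label=category)
        rows.append((category, panel, sided, res.n_subset, res.n_background,
                     res.statistic, res.p_value, res.direction, res.method,
                     False))
    return pd.DataFrame(rows, columns=["category", "panel", "sided",
                                       "n_subset", "n_background", "D", "p",
                                       "direction", "method", "untestable"])
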