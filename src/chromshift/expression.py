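"""Expression normalization, fold-change ranking, and derived gene sets.

Scores are microarray-style non-negative signal values.  Global
normalization rescales each sample so its mean score equals a target
(default 100).  Fold change compares one baseline sample against the mean
of one or more condition samples on the linear scale, with a score floor
applied to both sides so near-zero baselines cannot produce unbounded
ratios.  The descending-fold ranking (ties broken by gene id, stable) is
the substrate of all rank-enrichment tests downstream.
"""

from __future__ import annotations

import pandas as pd

from .io import ExpressionMatrix


def normalize_global(matrix: ExpressionMatrix, target: float = 100.0
                     ) -> ExpressionMatrix:
    """Scale each sample so its mean score equals ``target``."""
    means = matrix.scores.mean(axis=1)
    if (means <= 0).any():
        bad = means.index[means <= 0][0]
        raise ValueError(f"sample {bad!r} has no positive scores")
    scaled = matrix.scores.mul(target / means, axis=0)
    return ExpressionMatrix(scores=scaled)


def fold_change(matrix: ExpressionMatrix, baseline: str,
                condition: list[str], floor: float = 1.0) -> pd.DataFrame:
    """Per-gene fold change (condition mean / baseline) with rank.

    Returns a gene_id-indexed frame with columns baseline, condition_mean,
    fold, rank; rank 1 is the largest fold, ties broken lexicographically
    by gene id.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    for s in [baseline] + list(condition):
        if s not in matrix.scores.index:
            raise KeyError(f"unknown sample {s!r}")
    if not condition:
        raise ValueError("condition sample list is empty")
    base = matrix.scores.loc[baseline]
    cond = matrix.scores.loc[list(condition)].mean(axis=0)
    fold = cond.clip(lower=floor) / base.clip(lower=floor)
    out = pd.DataFrame({"baseline": base, "condition_mean": cond, "fold": fold})
    out.index.name = "gene_id"
    out = out.sort_values("fold", ascending=False, kind="mergesort")
    out = out.sort_index(kind="mergesort").sort_values(
        "fold", ascending=False, kind="mergesort")  # stable: fold desc, id asc
    out["rank"] = range(1, len(out) + 1)
    return out


def de_sets(table: pd.DataFrame, cutoff: float = 5.0
            ) -> tuple[set[str], set[str]]:
    """(up, down) gene sets at a strict fold cutoff (> cutoff / < 1/cutoff)."""
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    up = set(table.index[table["fold"] > cutoff])
    down = set(table.index[table["fold"] < 1.0 / cutoff])
    return up, down


def active_genes(matrix: ExpressionMatrix, samples: list[str],
                 score_cutoff: float = 25.0) -> set[str]:
    """Genes whose max score across the named samples exceeds the cutoff."""
    if not samples:
        raise ValueError("sample list is empty")
    for s in samples:
        if s not in matrix.scores.index:
            raise KeyError(f"unknown sample {s!r}")
    peak = matrix.scores.loc[list(samples)].max(axis=0)
    return set(peak.index[peak > score_cutoff])
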