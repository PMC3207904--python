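"""Categorical mark-status calling and between-condition transition logic.

A gene is called positive for a mark when its max windowed RPM exceeds the
high threshold, negative below the low threshold, and indeterminate in the
gap.  Pipeline defaults follow the study thresholds: H3K4me3 +/- at >4 / <3
RPM, H3K27me3 at >1.5 / <1 RPM.

A transition requires crossing the full gap: loss means above-high in the
baseline condition and below-low in the second; gain is the mirror image.
(The repressive-mark gain rule is deliberately the mirror of the printed
loss rule; the source figure legend's gain wording contradicts its own
positive-status threshold and is treated as a typo.)

Coordinated categories, in fixed precedence order:

===========  ====================================================
K27->K4      repressive-mark loss AND active-mark gain
Bi->K4       active mark positive in both conditions AND repressive loss
K4->K27      active-mark loss AND repressive-mark gain
none->K27    active mark negative in both conditions AND repressive gain
loss_only    any remaining loss of either mark
gain_only    any remaining gain of either mark
stable       both marks stable (statuses equal, not indeterminate)
other        everything else (indeterminate statuses involved)
===========  ====================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PLUS, MINUS, INDET = "plus", "minus", "indeterminate"

CATEGORIES = ["K27->K4", "Bi->K4", "K4->K27", "none->K27",
              "loss_only", "gain_only", "stable", "other"]


@dataclass(frozen=True)
class MarkThresholds:
    hi: float
    lo: float

    def __post_init__(self) -> None:
        if not (self.hi >= self.lo > 0):
            raise ValueError("require hi >= lo > 0")


K4_THRESHOLDS = MarkThresholds(hi=4.0, lo=3.0)
K27_THRESHOLDS = MarkThresholds(hi=1.5, lo=1.0)


def classify(rpm_max: float, th: MarkThresholds) -> str:
    """Categorical mark status from a gene's max windowed RPM."""
    if rpm_max < 0:
        raise ValueError("rpm_max must be >= 0")
    if rpm_max > th.hi:
        return PLUS
    if rpm_max < th.lo:
        return MINUS
    return INDET


def call_transition(rpm_a: float, rpm_b: float, th: MarkThresholds) -> str:
    """loss / gain / stable / indeterminate between two conditions."""
    sa, sb = classify(rpm_a, th), classify(rpm_b, th)
    if sa == PLUS and sb == MINUS:
        return "loss"
    if sa == MINUS and sb == PLUS:
        return "gain"
    if sa == sb and sa != INDET:
        return "stable"
    return "indeterminate"


def categorize(k4_a: str, k4_b: str, k4_tr: str,
               k27_a: str, k27_b: str, k27_tr: str) -> str:
    """Assign the first matching coordinated category (fixed precedence)."""
    if k27_tr == "loss" and k4_tr == "gain":
        return "K27->K4"
    if k4_a == PLUS and k4_b == PLUS and k27_tr == "loss":
        return "Bi->K4"
    if k4_tr == "loss" and k27_tr == "gain":
        return "K4->K27"
    if k4_a == MINUS and k4_b == MINUS and k27_tr == "gain":
        return "none->K27"
    if k27_tr == "loss" or k4_tr == "loss":
        return "loss_only"
    if k27_tr == "gain" or k4_tr == "gain":
        return "gain_only"
    if k4_tr == "stable" and k27_tr == "stable":
        return "stable"
    return "other"


def build_status_table(rpm: pd.DataFrame, th_k4: MarkThresholds = K4_THRESHOLDS,
                       th_k27: MarkThresholds = K27_THRESHOLDS) -> pd.DataFrame:
    """Long-format status table from a wide rpm table.

    ``rpm`` is indexed by gene_id with columns ``<mark>_<condition>`` for
    marks 'k4'/'k27' and conditions 'A'/'B'; returns one row per
    (gene, mark, condition) with rpm_max and status.
    """
    th = {"k4": th_k4, "k27": th_k27}
    rows = []
    for col in rpm.columns:
        mark, cond = col.rsplit("_", 1)
        for gid, val in rpm[col].items():
            rows.append((gid, mark, cond, float(val),
                         classify(float(val), th[mark])))
    return pd.DataFrame(rows, columns=["gene_id", "mark", "condition",
                                       "rpm_max", "status"])


def build_transition_table(rpm: pd.DataFrame,
                           th_k4: MarkThresholds = K4_THRESHOLDS,
                           th_k27: MarkThresholds = K27_THRESHOLDS
                           ) -> pd.DataFrame:
    """Per-gene transition calls and coordinated category.

    ``rpm``: gene_id-indexed with columns k4_A, k4_B, k27_A, k27_B.
    """
    out = pd.DataFrame(index=rpm.index)
    for mark, th in (("k4", th_k4), ("k27", th_k27)):
        a, b = rpm[f"{mark}_A"], rpm[f"{mark}_B"]
        out[f"{mark}_rpm_A"], out[f"{mark}_rpm_B"] = a, b
        out[f"{mark}_A"] = [classify(v, th) for v in a]
        out[f"{mark}_B"] = [classify(v, th) for v in b]
        out[f"{mark}_transition"] = [call_transition(x, y, th)
                                     for x, y in zip(a, b)]
        out[f"{mark}_delta"] = b - a
    out["category"] = [
        categorize(r.k4_A, r.k4_B, r.k4_transition,
                   r.k27_A, r.k27_B, r.k27_transition)
        for r in out.itertuples()
    ]
    out.index.name = "gene_id"
    return out


def category_counts(transitions: pd.DataFrame) -> pd.Series:
    return transitions["category"].value_counts().reindex(
        CATEGORIES, fill_value=0)


def delta_mark(rpm_a: float, rpm_b: float, delta: float = 0.4) -> str:
    """increase / decrease / none by an absolute RPM change of >= delta."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    if rpm_b - rpm_a >= delta:
        return "increase"
    if rpm_a - rpm_b >= delta:
        return "decrease"
    return "none"


def delta_mark_table(rpm_a: pd.Series, rpm_b: pd.Series,
                     delta: float = 0.4) -> pd.Series:
    diff = rpm_b - rpm_a
    out = pd.Series(np.where(diff >= delta, "increase",
                    np.where(-diff >= delta, "decrease", "none")),
                    index=rpm_a.index, name="delta_class")
    return out


def medip_screen(rpm_a: pd.Series, rpm_b: pd.Series, low: float = 2.0,
                 high: float = 4.0) -> list[str]:
    """Candidate promoter hypermethylation genes: RPM < low in the baseline
    condition rising to > high in the second condition (computed on
    MeDIP windowing: 500 bp windows within ±1 kb of TSS)."""
    mask = (rpm_a < low) & (rpm_b > high)
    return sorted(rpm_a.index[mask])
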