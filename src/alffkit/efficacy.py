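"""Clinical efficacy scoring on the visual analog scale (VAS) and group
comparisons of VAS and continuous sleep time.

The VAS weighted value is the fractional pain reduction from baseline,
(before - after) / before. Outcome categories partition the weighted value:
cured at >= 0.75, markedly effective in [0.50, 0.75), effective in
[0.25, 0.50), ineffective below 0.25; the total effective rate is the
fraction of subjects in the first three categories. Weighted values are
fractions internally and percentages in reports.

Between-group comparisons use the pooled-variance Student t (equal group
sizes); within-group week-versus-baseline comparisons are paired. A
summary-statistic form of the two-sample test is provided so printed
mean/SD/n triples can be compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GROUPS, ClinicalTable

__all__ = [
    "OutcomeCategory",
    "vas_weighted_value",
    "classify_outcome",
    "total_effective_rate",
    "two_sample_t_from_summary",
    "efficacy_report",
]


class OutcomeCategory(str, Enum):
    CURED = "cured"
    MARKEDLY_EFFECTIVE = "markedly_effective"
    EFFECTIVE = "effective"
    INEFFECTIVE = "ineffective"


#: categories counted toward the total effective rate
EFFECTIVE_CATEGORIES = (
    OutcomeCategory.CURED,
    OutcomeCategory.MARKEDLY_EFFECTIVE,
    OutcomeCategory.EFFECTIVE,
)


def vas_weighted_value(before: float, after: float) -> float:
    """Fractional VAS reduction (before - after) / before.

    Scale-invariant in (before, after); requires before > 0 and both scores
    on the 0-10 scale.
    """
    if not (0 <= after <= 10) or not (0 <= before <= 10):
        raise ValueError("VAS scores must lie in [0, 10]")
    if before == 0:
        raise ValueError("weighted value undefined for baseline VAS of 0")
    return (before - after) / before


def classify_outcome(wv: float) -> OutcomeCategory:
    """Outcome category of a weighted value (closed lower bounds at 0.75,
    0.50 and 0.25; strict upper bounds)."""
    if wv >= 0.75:
        return OutcomeCategory.CURED
    if wv >= 0.50:
        return OutcomeCategory.MARKEDLY_EFFECTIVE
    if wv >= 0.25:
        return OutcomeCategory.EFFECTIVE
    return OutcomeCategory.INEFFECTIVE


def total_effective_rate(categories) -> float:
    """Fraction of outcomes that are cured, markedly effective or effective
    (equivalently 1 - ineffective fraction)."""
    cats = list(categories)
    if not cats:
        raise ValueError("no outcomes to summarize")
    hits = sum(1 for c in cats if OutcomeCategory(c) in EFFECTIVE_CATEGORIES)
    return hits / len(cats)


@dataclass(frozen=True)
class SummaryTTest:
    t: float
    df: int
    p: float


def two_sample_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> SummaryTTest:
    """Pooled-variance Student t reconstructed from printed mean/SD/n.

    df = n1 + n2 - 2; two-sided p from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be > 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return SummaryTTest(t=float(t), df=df, p=float(p))


WEEKS = (1, 2, 3, 4)


def efficacy_report(table: ClinicalTable) -> dict:
    """Full efficacy summary of a clinical table.

    Returns a dict with:

    ``summary``     per-group, per-endpoint, per-week mean and SD (DataFrame)
    ``within``      within-group paired t of each week's VAS vs baseline
    ``between``     per-week between-group pooled t for VAS and sleep
    ``weighted``    per-subject week-4 weighted values and categories
    ``category_counts``  per-group outcome category counts
    ``total_effective_rate``  per-group rate

    VAS summaries are rounded to one decimal in the summary frame, matching
    the reporting precision of the scale.
    """
    df = table.frame
    for g in GROUPS:
        if (df["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 subjects")

    summary_rows = []
    for group in GROUPS:
        sub = table.group(group)
        for endpoint, cols in (
            ("vas", ["vas_baseline"] + [f"vas_week{w}" for w in WEEKS]),
            ("sleep", [f"sleep_week{w}" for w in WEEKS]),
        ):
            for col in cols:
                week = 0 if col.endswith("baseline") else int(col[-1])
                summary_rows.append(
                    {
                        "group": group,
                        "endpoint": endpoint,
                        "week": week,
                        "mean": round(float(sub[col].mean()), 1),
                        "sd": round(float(sub[col].std(ddof=1)), 1),
                        "n": len(sub),
                    }
                )
    summary = pd.DataFrame(summary_rows)

    within_rows = []
    for group in GROUPS:
        sub = table.group(group)
        base = sub["vas_baseline"].to_numpy(dtype=float)
        for w in WEEKS:
            week_vals = sub[f"vas_week{w}"].to_numpy(dtype=float)
            t, p = stats.ttest_rel(week_vals, base)
            within_rows.append({"group": group, "week": w, "t": float(t), "p": float(p)})
    within = pd.DataFrame(within_rows)

    between_rows = []
    treat = table.group("treatment")
    ctrl = table.group("control")
    for endpoint in ("vas", "sleep"):
        for w in WEEKS:
            col = f"{endpoint}_week{w}"
            a = treat[col].to_numpy(dtype=float)
            b = ctrl[col].to_numpy(dtype=float)
            res = two_sample_t_from_summary(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            between_rows.append(
                {"endpoint": endpoint, "week": w, "t": res.t, "df": res.df, "p": res.p}
            )
    between = pd.DataFrame(between_rows)

    weighted_rows = []
    for row in df.itertuples():
        wv = vas_weighted_value(float(row.vas_baseline), float(row.vas_week4))
        weighted_rows.append(
            {
                "subject_id": row.subject_id,
                "group": row.group,
                "weighted_value": wv,
                "weighted_value_pct": 100.0 * wv,
                "category": classify_outcome(wv).value,
            }
        )
    weighted = pd.DataFrame(weighted_rows)

    category_counts = {
        group: weighted[weighted["group"] == group]["category"].value_counts().to_dict()
        for group in GROUPS
    }
    rates = {
        group: total_effective_rate(
            weighted[weighted["group"] == group]["category"].tolist()
        )
        for group in GROUPS
    }
    return {
        "summary": summary,
        "within": within,
        "between": between,
        "weighted": weighted,
        "category_counts": category_counts,
        "total_effective_rate": rates,
    }
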