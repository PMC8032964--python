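"""Cohort-level atypicality summaries and extreme-deviation statistics.

Summaries mirror how such cohorts are reported: per-region mean (SD) and
median (IQR) of the atypicality index, per-CHD-subgroup medians, counts
and percentages of extreme deviations, prevalence of subjects with at
least one extreme region, and pairwise subgroup contingency tables
analysed with Fisher's exact test.  The odds ratio reported for a 2x2
table is the conditional maximum-likelihood estimate under the noncentral
hypergeometric model (the convention of R's ``fisher.test``), with the
exact conditional confidence interval and the two-sided minimum-likelihood
exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .normative import AtypicalityProfiles

EXTREME_FLAGS = ("extreme_negative", "extreme_positive")

#: Pairwise subgroup comparisons, in reporting order.
SUBGROUP_PAIRS = (
    ("abnormal_streaming", "left_sided"),
    ("abnormal_streaming", "right_sided"),
    ("left_sided", "right_sided"),
)


def extreme_threshold(per_tail_p: float = 0.005) -> float:
    """Standard-normal upper-tail quantile defining an extreme deviation.

    ``per_tail_p = 0.005`` (top and bottom 0.5% of the typical population)
    gives 2.5758..., conventionally reported rounded to 2.6.
    """
    if not 0.0 < per_tail_p < 0.5:
        raise ValueError("per_tail_p must lie in (0, 0.5)")
    return float(stats.norm.isf(per_tail_p))


def _median_iqr(x: pd.Series) -> tuple[float, float, float]:
    x = x.dropna()
    if x.empty:
        return (np.nan, np.nan, np.nan)
    return (
        float(x.median()),
        float(x.quantile(0.25)),
        float(x.quantile(0.75)),
    )


def summarize_regions(
    profiles: AtypicalityProfiles, subgroups: pd.Series | None = None
) -> pd.DataFrame:
    """One row per region: mean (SD), median (IQR), extreme counts (%).

    ``subgroups`` (indexed by subject_id) adds per-subgroup median (IQR)
    columns.  Percentages are over subjects with the region present.
    """
    if profiles.z.empty:
        raise ValueError("no profiles to summarize")
    rows = []
    for region in profiles.regions:
        z = profiles.z[region]
        fl = profiles.flags[region]
        n = int(z.notna().sum())
        med, q1, q3 = _median_iqr(z)
        n_neg = int((fl == "extreme_negative").sum())
        n_pos = int((fl == "extreme_positive").sum())
        row = {
            "region": region,
            "n": n,
            "mean": float(z.mean()),
            "sd": float(z.std(ddof=1)) if n > 1 else 0.0,
            "median": med,
            "q1": q1,
            "q3": q3,
            "n_extreme_negative": n_neg,
            "pct_extreme_negative": 100.0 * n_neg / n if n else np.nan,
            "n_extreme_positive": n_pos,
            "pct_extreme_positive": 100.0 * n_pos / n if n else np.nan,
        }
        if subgroups is not None:
            sg = subgroups.reindex(z.index)
            for name in pd.unique(sg.dropna()):
                if name == "none":
                    continue
                m, a, b = _median_iqr(z[sg == name])
                row[f"median_{name}"] = m
                row[f"q1_{name}"] = a
                row[f"q3_{name}"] = b
        rows.append(row)
    return pd.DataFrame(rows)


def any_extreme_per_subject(profiles: AtypicalityProfiles) -> dict:
    """Prevalence of subjects with >= 1 extreme region (counted once each)."""
    counts = profiles.n_extreme_per_subject()
    n_subjects = len(counts)
    n_any = int((counts > 0).sum())
    return {
        "n_subjects": n_subjects,
        "n_with_extreme": n_any,
        "pct_with_extreme": 100.0 * n_any / n_subjects if n_subjects else np.nan,
        "max_extreme_regions": int(counts.max()) if n_subjects else 0,
    }


@dataclass
class ContingencyTable2x2:
    """(>=1 extreme deviation yes/no) x (subgroup pair) counts."""

    group1: str
    group2: str
    table: np.ndarray  # [[extreme_1, not_1], [extreme_2, not_2]]

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=int)
        if self.table.shape != (2, 2) or np.any(self.table < 0):
            raise ValueError("need a 2x2 table of non-negative counts")


def subgroup_tables(
    profiles: AtypicalityProfiles, subgroups: pd.Series
) -> list[ContingencyTable2x2]:
    """Pairwise extreme-deviation contingency tables across CHD subgroups.

    Subjects with subgroup ``none`` (or missing) are excluded.  Rows are
    subgroups, columns are (>=1 extreme, none); pairs follow the reporting
    order streaming-vs-left, streaming-vs-right, left-vs-right.
    """
    counts = profiles.n_extreme_per_subject()
    sg = subgroups.reindex(counts.index)
    keep = sg.notna() & (sg != "none")
    counts, sg = counts[keep], sg[keep]
    tables = []
    for g1, g2 in SUBGROUP_PAIRS:
        if not (sg == g1).any() or not (sg == g2).any():
            raise ValueError(f"empty subgroup in pair ({g1}, {g2})")
        cells = []
        for g in (g1, g2):
            extreme = int(((sg == g) & (counts > 0)).sum())
            total = int((sg == g).sum())
            cells.append([extreme, total - extreme])
        tables.append(ContingencyTable2x2(g1, g2, np.array(cells)))
    return tables


def fisher_exact(table) -> dict:
    """Fisher's exact test on a 2x2 table.

    Returns the conditional-MLE odds ratio, its exact conditional 95% CI
    and the two-sided p-value.  With a zero margin the odds ratio is
    undefined and reported as NaN with p = 1.
    """
    t = table.table if isinstance(table, ContingencyTable2x2) else np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative integer counts")
    if t.sum() == 0:
        raise ValueError("all cells are zero")
    margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
    if min(margins) == 0:
        return {
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": 1.0,
        }
    res = _odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(0.95)
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    return {
        "odds_ratio": float(res.statistic),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "p_value": p,
    }


def subgroup_comparison(
    profiles: AtypicalityProfiles, subgroups: pd.Series
) -> pd.DataFrame:
    """Fisher exact comparison of extreme-deviation prevalence per pair."""
    rows = []
    for tab in subgroup_tables(profiles, subgroups):
        res = fisher_exact(tab)
        rows.append(
            {
                "group1": tab.group1,
                "group2": tab.group2,
                "extreme_1": tab.table[0, 0],
                "n_1": tab.table[0].sum(),
                "extreme_2": tab.table[1, 0],
                "n_2": tab.table[1].sum(),
                **res,
            }
        )
    return pd.DataFrame(rows)
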