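"""Contingency-table and rank-based engagement statistics.

Theme-by-phase association is tested with Pearson's chi-square on a
2 × 3 present/absent table (no continuity correction — the convention
under which the published contingency tables reproduce exactly).
Engagement counts (likes, shares, comments) are non-normal, so location
is summarised by medians and compared with Kruskal–Wallis (across
phases) and Mann–Whitney U (theme present vs. absent).  The
Mann–Whitney z uses the tie-corrected normal approximation without
continuity correction; z > 0 means the first ("present") group tends to
rank higher.  All rank-test p values are two-sided.  No multiple-testing
correction is applied; reports record how many tests were run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .codebook import Codebook, ThemeAssignment
from .timeline import Phase

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "RankTestResult",
    "EngagementRecord",
    "DegenerateTableError",
    "build_theme_phase_table",
    "pearson_chi_square",
    "kruskal_wallis",
    "mann_whitney",
    "median_engagement_report",
    "theme_phase_report",
    "engagement_test_report",
    "significance_stars",
]

PHASE_ORDER = (Phase.PRE_OUTBREAK, Phase.OUTBREAK, Phase.POST_OUTBREAK)
ENGAGEMENT_METRICS = ("likes", "shares", "comments")


class DegenerateTableError(ValueError):
    """Contingency table with an all-zero row or column."""


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table shape")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if counts.sum() == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    expected: np.ndarray
    low_expected: bool  # any expected cell < 5 (approximation caveat)


@dataclass(frozen=True)
class RankTestResult:
    test: str  # "kruskal_wallis" | "mann_whitney"
    statistic: float  # H for KW, U (first sample) for MW
    z: float | None
    p: float
    group_medians: Mapping[str, float]
    group_sizes: Mapping[str, int]


def build_theme_phase_table(
    assignments: Sequence[ThemeAssignment],
    phases: Sequence[Phase],
    theme: str,
    subcategory: str | None = None,
) -> ContingencyTable:
    """Present/absent × phase table for one theme (or one subcategory).

    Column sums equal the per-phase corpus sizes; a phase with no posts
    is an error naming that phase.
    """
    if len(assignments) != len(phases):
        raise ValueError("assignments and phases must align")
    counts = np.zeros((2, len(PHASE_ORDER)), dtype=np.int64)
    for a, ph in zip(assignments, phases):
        j = PHASE_ORDER.index(ph)
        if subcategory is None:
            present = theme in a.themes
        else:
            present = (theme, subcategory) in a.labels
        counts[0 if present else 1, j] += 1
    for j, ph in enumerate(PHASE_ORDER):
        if counts[:, j].sum() == 0:
            raise DegenerateTableError(f"no posts in phase {ph.value!r}")
    return ContingencyTable(
        counts=counts,
        row_labels=("present", "absent"),
        col_labels=tuple(p.value for p in PHASE_ORDER),
    )


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square without continuity correction.

    Flags (rather than rejects) tables with expected cells below 5; the
    published analyses keep Pearson's test in that regime.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        zero_rows = [table.row_labels[i] for i in np.where(counts.sum(axis=1) == 0)[0]]
        zero_cols = [table.col_labels[j] for j in np.where(counts.sum(axis=0) == 0)[0]]
        raise DegenerateTableError(
            f"all-zero rows {zero_rows} / columns {zero_cols} make chi-square undefined"
        )
    stat, p, df, expected = sps.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p=float(p),
        expected=np.asarray(expected),
        low_expected=bool((np.asarray(expected) < 5).any()),
    )


def _median(values: Sequence[float]) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> RankTestResult:
    """Kruskal–Wallis H on mid-ranks with tie correction.

    p comes from the chi-square approximation with k-1 degrees of
    freedom.  Identical groups give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"empty group {name!r}")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    return RankTestResult(
        test="kruskal_wallis",
        statistic=float(h),
        z=None,
        p=float(p),
        group_medians={k: _median(v) for k, v in groups.items()},
        group_sizes={k: len(v) for k, v in groups.items()},
    )


def mann_whitney(
    a: Sequence[float], b: Sequence[float], labels: tuple[str, str] = ("present", "absent")
) -> RankTestResult:
    """Mann–Whitney U with exact small-sample p and approximate z.

    U is the first sample's statistic (U in [0, n1*n2]); z is the
    tie-corrected normal approximation without continuity correction,
    positive when the first group tends to rank higher.  The two-sided p
    comes from the exact permutation distribution when both samples have
    at most 8 observations and there are no ties (where the normal
    approximation is coarse), and from the normal approximation
    otherwise.  Two constant identical samples give z = 0, p = 1 rather
    than an error.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        z, p = 0.0, 1.0
    else:
        z = (u1 - n1 * n2 / 2.0) / math.sqrt(var_u)
        if max(n1, n2) <= 8 and tie_term == 0:
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        else:
            p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult(
        test="mann_whitney",
        statistic=float(u1),
        z=float(z),
        p=float(min(p, 1.0)),
        group_medians={labels[0]: _median(x), labels[1]: _median(y)},
        group_sizes={labels[0]: n1, labels[1]: n2},
    )


# ---------------------------------------------------------------------------
# tabular reports
# ---------------------------------------------------------------------------


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class EngagementRecord:
    """One post's engagement with its phase and theme indicators."""

    post_id: str
    phase: Phase
    themes: frozenset[str]
    likes: int
    shares: int
    comments: int

    def metric(self, name: str) -> int:
        return {"likes": self.likes, "shares": self.shares, "comments": self.comments}[name]


def median_engagement_report(
    records: Sequence[EngagementRecord],
    codebook: Codebook | None = None,
    themes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median likes/shares/comments by theme (rows) and phase (columns).

    Mirrors the published median-engagement table: an "All" row over the
    whole corpus plus one row per theme; per-phase and pooled columns.
    Empty strata carry NaN, never zero.
    """
    if not records:
        raise ValueError("no engagement records")
    if themes is None:
        themes = codebook.theme_names if codebook is not None else sorted(
            {t for r in records for t in r.themes}
        )
    rows = []
    strata: list[tuple[str, list[EngagementRecord]]] = [("All", list(records))]
    strata += [(t, [r for r in records if t in r.themes]) for t in themes]
    for name, subset in strata:
        row: dict[str, object] = {"theme": name, "n": len(subset)}
        for metric in ENGAGEMENT_METRICS:
            vals = [r.metric(metric) for r in subset]
            row[f"{metric}_all"] = _median(vals) if vals else float("nan")
            for ph in PHASE_ORDER:
                pv = [r.metric(metric) for r in subset if r.phase == ph]
                row[f"{metric}_{ph.value}"] = _median(pv) if pv else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def theme_phase_report(
    assignments: Sequence[ThemeAssignment],
    phases: Sequence[Phase],
    codebook: Codebook,
    integer_percentages: bool = False,
) -> pd.DataFrame:
    """Theme/subcategory × phase prevalence with chi-square, in the shape
    of the published cross-tabulation.

    One row per theme (level="theme") and per subcategory
    (level="subcategory"): present counts and percentages per phase,
    overall prevalence, chi-square with df, p, significance stars and a
    low-expected-cell flag.  Percentages are one-decimal by default;
    ``integer_percentages`` reproduces the printed rounding.
    """
    n_by_phase = {ph: sum(1 for p in phases if p == ph) for ph in PHASE_ORDER}
    n_total = len(phases)
    decimals = 0 if integer_percentages else 1

    def pct(k: int, n: int) -> float:
        return round(100.0 * k / n, decimals) if n else float("nan")

    rows = []
    for theme in codebook.themes:
        targets = [(theme.name, None)] + [(theme.name, s.name) for s in theme.subcategories]
        for theme_name, sub in targets:
            table = build_theme_phase_table(assignments, phases, theme_name, sub)
            try:
                chi = pearson_chi_square(table)
                stat, df, p, low = chi.statistic, chi.df, chi.p, chi.low_expected
            except DegenerateTableError:
                stat, df, p, low = float("nan"), 2, float("nan"), True
            present = table.counts[0]
            row = {
                "theme": theme_name,
                "subcategory": sub if sub is not None else "",
                "level": "subcategory" if sub is not None else "theme",
                "n_overall": int(present.sum()),
                "pct_overall": pct(int(present.sum()), n_total),
            }
            for j, ph in enumerate(PHASE_ORDER):
                row[f"n_{ph.value}"] = int(present[j])
                row[f"pct_{ph.value}"] = pct(int(present[j]), n_by_phase[ph])
            row.update(
                {
                    "chi2": round(stat, 2) if math.isfinite(stat) else stat,
                    "df": df,
                    "p": p,
                    "stars": significance_stars(p) if math.isfinite(p) else "",
                    "low_expected": low,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


def engagement_test_report(
    records: Sequence[EngagementRecord],
    codebook: Codebook,
    alpha: float = 0.05,
    show_all: bool = False,
) -> pd.DataFrame:
    """Rank-test battery over engagement metrics.

    Kruskal–Wallis across phases per metric (scope="phases"), then
    Mann–Whitney present vs. absent per theme × metric overall
    (scope="overall") and within each phase (scope=phase name) —
    the shape of the published significant-contrast table.  Filtered to
    p <= alpha unless ``show_all``; ``n_tests_run`` is attached so the
    absence of a multiplicity correction is auditable.
    """
    rows = []
    n_tests = 0
    for metric in ENGAGEMENT_METRICS:
        groups = {
            ph.value: [r.metric(metric) for r in records if r.phase == ph]
            for ph in PHASE_ORDER
        }
        groups = {k: v for k, v in groups.items() if v}
        if len(groups) >= 2:
            res = kruskal_wallis(groups)
            n_tests += 1
            rows.append(
                {
                    "scope": "phases",
                    "variable": "phase",
                    "metric": metric,
                    "test": res.test,
                    "statistic": res.statistic,
                    "z": float("nan"),
                    "p": res.p,
                    "median_present": float("nan"),
                    "median_absent": float("nan"),
                    "stars": significance_stars(res.p),
                }
            )
    scopes: list[tuple[str, Sequence[EngagementRecord]]] = [("overall", records)]
    scopes += [(ph.value, [r for r in records if r.phase == ph]) for ph in PHASE_ORDER]
    for scope, subset in scopes:
        for theme in codebook.theme_names:
            present = [r for r in subset if theme in r.themes]
            absent = [r for r in subset if theme not in r.themes]
            if not present or not absent:
                continue
            for metric in ENGAGEMENT_METRICS:
                res = mann_whitney(
                    [r.metric(metric) for r in present],
                    [r.metric(metric) for r in absent],
                )
                n_tests += 1
                rows.append(
                    {
                        "scope": scope,
                        "variable": theme,
                        "metric": metric,
                        "test": res.test,
                        "statistic": res.statistic,
                        "z": res.z,
                        "p": res.p,
                        "median_present": res.group_medians["present"],
                        "median_absent": res.group_medians["absent"],
                        "stars": significance_stars(res.p),
                    }
                )
    out = pd.DataFrame(rows)
    if not show_all and not out.empty:
        out = out[out["p"] <= alpha].reset_index(drop=True)
    out.attrs["n_tests_run"] = n_tests
    return out
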