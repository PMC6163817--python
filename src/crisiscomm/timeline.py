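"""Epidemiological-week coordinates and crisis-phase segmentation.

Dates are mapped to MMWR epidemiological weeks (Sunday–Saturday; week 1
of a year is the week containing at least four January days, i.e. the
week whose Wednesday falls in January).  The study window is partitioned
into three contiguous crisis phases — pre-outbreak, outbreak,
post-outbreak — by calendar date, with both phase boundaries inclusive.

The default scheme is the 2016 Singapore Zika window:
pre-outbreak 1 Jan–20 Aug, outbreak 21 Aug–24 Sep, post-outbreak
25 Sep–31 Dec.  Timestamps are reduced to their calendar date
(time-of-day ignored; interpreted as local time).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "EpiWeek",
    "Phase",
    "PhaseScheme",
    "CaseSeries",
    "OutOfWindowError",
    "to_epi_week",
    "assign_phase",
    "weekly_aggregate",
    "DEFAULT_SCHEME",
]


class OutOfWindowError(ValueError):
    """A date falls outside the configured study window."""


@dataclass(frozen=True, order=True)
class EpiWeek:
    """An MMWR epidemiological week, totally ordered by (year, week)."""

    year: int
    week: int

    def __post_init__(self) -> None:
        if not 1 <= self.week <= 53:
            raise ValueError(f"epi-week out of range: {self.week}")

    def __str__(self) -> str:  # e.g. "2016-W34"
        return f"{self.year}-W{self.week:02d}"

    @property
    def start_date(self) -> date:
        wk1 = _week1_sunday(self.year)
        return wk1 + timedelta(weeks=self.week - 1)

    def next(self) -> "EpiWeek":
        return to_epi_week(self.start_date + timedelta(weeks=1))


class Phase(enum.Enum):
    PRE_OUTBREAK = "pre_outbreak"
    OUTBREAK = "outbreak"
    POST_OUTBREAK = "post_outbreak"

    def __str__(self) -> str:
        return self.value


def _as_date(d: date | datetime) -> date:
    return d.date() if isinstance(d, datetime) else d


def _sunday_on_or_before(d: date) -> date:
    # date.weekday(): Monday=0 .. Sunday=6
    return d - timedelta(days=(d.weekday() + 1) % 7)


def _week1_sunday(year: int) -> date:
    """Sunday starting MMWR week 1 of `year` (week whose Wednesday is in January)."""
    sunday = _sunday_on_or_before(date(year, 1, 4))
    wednesday = sunday + timedelta(days=3)
    if wednesday.year < year:  # cannot happen for Jan 4 anchor, kept for clarity
        sunday += timedelta(weeks=1)
    return sunday


def to_epi_week(d: date | datetime) -> EpiWeek:
    """Convert a calendar date to its MMWR epidemiological week.

    The week belongs to the year of its Wednesday (the rule that week 1
    contains at least four January days); dates before week 1 fall in the
    final week of the previous epidemiological year.
    """
    d = _as_date(d)
    sunday = _sunday_on_or_before(d)
    year = (sunday + timedelta(days=3)).year
    week = (sunday - _week1_sunday(year)).days // 7 + 1
    return EpiWeek(year=year, week=week)


@dataclass(frozen=True)
class PhaseScheme:
    """Contiguous three-phase partition of the study window by date."""

    pre_start: date = date(2016, 1, 1)
    pre_end: date = date(2016, 8, 20)
    outbreak_start: date = date(2016, 8, 21)
    outbreak_end: date = date(2016, 9, 24)
    post_start: date = date(2016, 9, 25)
    post_end: date = date(2016, 12, 31)

    def __post_init__(self) -> None:
        one = timedelta(days=1)
        if not (
            self.pre_start <= self.pre_end
            and self.pre_end + one == self.outbreak_start
            and self.outbreak_start <= self.outbreak_end
            and self.outbreak_end + one == self.post_start
            and self.post_start <= self.post_end
        ):
            raise ValueError("phases must be contiguous, ordered and non-overlapping")

    @property
    def window(self) -> tuple[date, date]:
        return (self.pre_start, self.post_end)

    def phase_range(self, phase: Phase) -> tuple[date, date]:
        return {
            Phase.PRE_OUTBREAK: (self.pre_start, self.pre_end),
            Phase.OUTBREAK: (self.outbreak_start, self.outbreak_end),
            Phase.POST_OUTBREAK: (self.post_start, self.post_end),
        }[phase]


DEFAULT_SCHEME = PhaseScheme()


def assign_phase(d: date | datetime, scheme: PhaseScheme = DEFAULT_SCHEME) -> Phase:
    """Assign a date to its crisis phase (boundaries inclusive on both ends)."""
    d = _as_date(d)
    if not scheme.pre_start <= d <= scheme.post_end:
        raise OutOfWindowError(
            f"{d.isoformat()} outside study window "
            f"[{scheme.pre_start.isoformat()}, {scheme.post_end.isoformat()}]"
        )
    if d <= scheme.pre_end:
        return Phase.PRE_OUTBREAK
    if d <= scheme.outbreak_end:
        return Phase.OUTBREAK
    return Phase.POST_OUTBREAK


@dataclass
class CaseSeries:
    """Weekly confirmed-case counts keyed by EpiWeek; zeros are explicit."""

    counts: dict[EpiWeek, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("case counts must be non-negative")
        weeks = sorted(self.counts)
        for a, b in zip(weeks, weeks[1:]):
            if a.next() != b:
                raise ValueError(f"case series not contiguous between {a} and {b}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        weeks = sorted(self.counts)
        return pd.DataFrame(
            {
                "epi_year": [w.year for w in weeks],
                "epi_week": [w.week for w in weeks],
                "cases": [self.counts[w] for w in weeks],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CaseSeries":
        counts = {
            EpiWeek(int(r.epi_year), int(r.epi_week)): int(r.cases)
            for r in df.itertuples()
        }
        return cls(counts=counts)

    @classmethod
    def read_csv(cls, path) -> "CaseSeries":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def weekly_aggregate(
    posts: Sequence,
    case_series: CaseSeries | None = None,
    span: tuple[date, date] | None = None,
) -> pd.DataFrame:
    """Per-epi-week post counts and mean engagement.

    Weeks with no posts carry count 0 and missing (NaN) means, never a
    silent gap; the sum of weekly counts equals the corpus size.  When a
    case series is supplied its counts are joined on (epi_year, epi_week).
    """
    cols = ["epi_year", "epi_week", "n_posts", "mean_likes", "mean_shares", "mean_comments"]
    if not posts and span is None:
        out = pd.DataFrame(columns=cols)
    else:
        if span is None:
            dates = [_as_date(p.timestamp) for p in posts]
            span = (min(dates), max(dates))
        first, last = to_epi_week(span[0]), to_epi_week(span[1])
        weeks: list[EpiWeek] = [first]
        while weeks[-1] < last:
            weeks.append(weeks[-1].next())
        rows = {w: {"n": 0, "likes": [], "shares": [], "comments": []} for w in weeks}
        for p in posts:
            w = to_epi_week(p.timestamp)
            if w not in rows:  # post outside requested span
                continue
            rows[w]["n"] += 1
            rows[w]["likes"].append(p.likes)
            rows[w]["shares"].append(p.shares)
            rows[w]["comments"].append(p.comment_count)
        out = pd.DataFrame(
            {
                "epi_year": [w.year for w in weeks],
                "epi_week": [w.week for w in weeks],
                "n_posts": [rows[w]["n"] for w in weeks],
                "mean_likes": [
                    float(pd.Series(rows[w]["likes"]).mean()) if rows[w]["n"] else float("nan")
                    for w in weeks
                ],
                "mean_shares": [
                    float(pd.Series(rows[w]["shares"]).mean()) if rows[w]["n"] else float("nan")
                    for w in weeks
                ],
                "mean_comments": [
                    float(pd.Series(rows[w]["comments"]).mean()) if rows[w]["n"] else float("nan")
                    for w in weeks
                ],
            }
        )
    if case_series is not None:
        out = out.merge(case_series.to_frame(), on=["epi_year", "epi_week"], how="left")
        out["cases"] = out["cases"].fillna(0).astype(int)
    return out
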