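"""Per-video variability summaries and group statistics.

The unit of analysis for the group statistics is the per-video standard
deviation of each rescaled measure — variability of the facial signal
over the tasting, not its absolute level.  Hedonic ratings are compared
across groups with the Kruskal-Wallis H test (rank-based, tie-corrected);
measure variability is compared across taste categories and hedonic
scores with separate one-way ANOVAs per measure.  No multiple-testing
correction is applied; reports state the number of tests run.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptySeriesError, ValidationError
from .io import SessionRecord, TASTES
from .measures import MEASURE_NAMES, MeasureSeries

log = logging.getLogger(__name__)

Factor = Literal["sex", "age", "order_sequence", "taste"]


@dataclass
class VideoSummary:
    """Per-measure variability of one video: the SD feature vector."""

    video_id: str
    subject_id: str
    taste: str
    hedonic_score: int
    section: str
    sds: pd.Series                # index = MEASURE_NAMES, sample SD (ddof=1)
    n_frames: int

    def __post_init__(self) -> None:
        if (self.sds < 0).any():
            raise ValidationError("standard deviations must be >= 0")


@dataclass
class GroupTestResult:
    """Outcome of one group-comparison test (H or F statistic)."""

    factor: str
    statistic_name: str           # "H" or "F"
    statistic: float
    df: tuple[int, ...]           # (k-1,) for Kruskal-Wallis, (df1, df2) for ANOVA
    p_value: float
    group_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def summarise_video(series: MeasureSeries, record: SessionRecord,
                    ddof: int = 1) -> VideoSummary:
    """Sample SD (``ddof=1`` by default) of each measure over retained frames."""
    if len(series) == 0:
        raise EmptySeriesError(f"video {series.video_id}: empty series")
    if len(series) == 1:
        log.warning("video %s: single retained frame, SDs reported as 0", series.video_id)
        sds = pd.Series(0.0, index=list(MEASURE_NAMES))
    else:
        sds = series.values.std(ddof=ddof)
    return VideoSummary(video_id=series.video_id, subject_id=record.subject_id,
                        taste=record.taste, hedonic_score=record.hedonic_score,
                        section=series.section, sds=sds, n_frames=len(series))


def summaries_frame(summaries: Iterable[VideoSummary]) -> pd.DataFrame:
    """Wide table: one row per video with metadata plus the 12 SD columns."""
    rows = []
    for s in summaries:
        row = {"video_id": s.video_id, "subject_id": s.subject_id, "taste": s.taste,
               "hedonic_score": s.hedonic_score, "section": s.section,
               "n_frames": s.n_frames}
        row.update(s.sds.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kruskal-Wallis on hedonic ratings
# ---------------------------------------------------------------------------

def kruskal_wallis(records: Sequence[SessionRecord], factor: Factor,
                   taste: str | None = None) -> GroupTestResult:
    """Kruskal-Wallis H test of hedonic score across levels of ``factor``.

    With ``taste`` given, the test is restricted to that strip's ratings
    (e.g. ratings of the sour strip compared between sexes).  Tie
    correction is applied; p-values come from the chi-square distribution
    on k-1 degrees of freedom.  Empty groups are excluded with a warning.
    """
    recs = [r for r in records if taste is None or r.taste == taste]
    if factor == "taste" and taste is not None:
        raise ValidationError("cannot stratify by taste and test factor 'taste'")
    groups: dict = {}
    for r in recs:
        groups.setdefault(getattr(r, factor), []).append(r.hedonic_score)
    sizes = {k: len(v) for k, v in groups.items()}
    nonempty = {k: v for k, v in groups.items() if len(v) > 0}
    if len(nonempty) < len(groups):
        log.warning("factor %s: excluded %d empty group(s)", factor,
                    len(groups) - len(nonempty))
    if len(nonempty) < 2:
        raise ValidationError(f"factor {factor}: fewer than 2 non-empty groups")
    samples = [np.asarray(v, dtype=float) for v in nonempty.values()]
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0   # no rank variation at all: no evidence of difference
    else:
        h, p = sps.kruskal(*samples)
    k = len(samples)
    return GroupTestResult(factor=factor if taste is None else f"{factor}|{taste}",
                           statistic_name="H", statistic=float(h), df=(k - 1,),
                           p_value=float(p), group_sizes=sizes)


# ---------------------------------------------------------------------------
# per-measure one-way ANOVA on video-level SDs
# ---------------------------------------------------------------------------

def anova_measures(summaries: Sequence[VideoSummary],
                   factor: Literal["taste", "hedonic_score"]) -> list[GroupTestResult]:
    """One-way ANOVA of each measure's per-video SD across ``factor`` levels.

    Returns one :class:`GroupTestResult` per measure, in measure order.
    Groups with fewer than 2 summaries are excluded with a warning; zero
    within-group variance with non-zero between-group variance yields an
    explicit infinite-F / zero-p result.
    """
    df = summaries_frame(summaries)
    if df.empty:
        raise ValidationError("no summaries given")
    out: list[GroupTestResult] = []
    levels = [(lvl, grp) for lvl, grp in df.groupby(factor) if len(grp) >= 2]
    dropped = df[factor].nunique() - len(levels)
    if dropped:
        log.warning("ANOVA by %s: excluded %d group(s) with < 2 videos", factor, dropped)
    if len(levels) < 2:
        raise ValidationError(f"ANOVA by {factor}: fewer than 2 usable groups")
    sizes = {lvl: len(grp) for lvl, grp in levels}
    k = len(levels)
    n = sum(sizes.values())
    for m in MEASURE_NAMES:
        samples = [grp[m].to_numpy(dtype=float) for _, grp in levels]
        within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        grand = np.concatenate(samples).mean()
        between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        if within == 0.0:
            if between == 0.0:
                f_stat, p = float("nan"), float("nan")
                log.warning("ANOVA %s by %s: all values identical", m, factor)
            else:
                f_stat, p = float("inf"), 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p = sps.f_oneway(*samples)
        out.append(GroupTestResult(factor=f"{factor}:{m}", statistic_name="F",
                                   statistic=float(f_stat), df=(k - 1, n - k),
                                   p_value=float(p), group_sizes=sizes))
    return out


def anova_table(results: Sequence[GroupTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        factor, _, measure = r.factor.partition(":")
        rows.append({"factor": factor, "measure": measure, "F": r.statistic,
                     "df_between": r.df[0], "df_within": r.df[1], "p_value": r.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grouped descriptive distributions (box-plot-ready)
# ---------------------------------------------------------------------------

def grouped_distributions(summaries: Sequence[VideoSummary],
                          by: Literal["taste", "hedonic_score"]) -> pd.DataFrame:
    """Five-number summaries of per-video SDs per group and measure.

    Quantiles use linear interpolation; whiskers follow the Tukey
    1.5*IQR rule (most extreme data point inside the fences).  The table
    is directly consumable by box-plot code.
    """
    df = summaries_frame(summaries)
    if df.empty:
        raise ValidationError("no summaries given")
    rows = []
    for lvl, grp in df.groupby(by):
        for m in MEASURE_NAMES:
            x = grp[m].to_numpy(dtype=float)
            q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = x[(x >= lo_fence) & (x <= hi_fence)]
            rows.append({by: lvl, "measure": m, "n": len(x), "min": x.min(),
                         "q1": q1, "median": med, "q3": q3, "max": x.max(),
                         "whisker_low": inside.min(), "whisker_high": inside.max()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort bookkeeping tables
# ---------------------------------------------------------------------------

@dataclass
class CohortTables:
    demographics: pd.DataFrame    # age, n, percent
    completeness: pd.DataFrame    # taste, n_hedonic_scores, n_videos (+ total row)
    median_age: float
    age_sd: float
    n_subjects: int
    n_by_sex: dict


def cohort_tables(records: Sequence[SessionRecord]) -> CohortTables:
    """Demographics (age frequencies, median, sample SD) and completeness counts.

    Ages and sexes are counted once per subject; hedonic scores and
    videos are counted per session row, with a totals row.
    """
    if not records:
        raise ValidationError("no records given")
    subjects: dict[str, SessionRecord] = {}
    for r in records:
        subjects.setdefault(r.subject_id, r)
    ages = np.array([r.age for r in subjects.values()], dtype=float)
    age_counts = pd.Series(ages.astype(int)).value_counts().sort_index()
    demo = pd.DataFrame({"age": age_counts.index, "n": age_counts.values})
    demo["percent"] = 100.0 * demo["n"] / demo["n"].sum()
    sd = float(ages.std(ddof=1)) if len(ages) > 1 else 0.0
    rows = []
    for taste in TASTES:
        trecs = [r for r in records if r.taste == taste]
        rows.append({"taste": taste, "n_hedonic_scores": len(trecs),
                     "n_videos": sum(r.video_id is not None for r in trecs)})
    rows.append({"taste": "total",
                 "n_hedonic_scores": sum(r["n_hedonic_scores"] for r in rows),
                 "n_videos": sum(r["n_videos"] for r in rows)})
    sexes = pd.Series([r.sex for r in subjects.values()]).value_counts().to_dict()
    return CohortTables(demographics=demo, completeness=pd.DataFrame(rows),
                        median_age=float(np.median(ages)), age_sd=sd,
                        n_subjects=len(subjects), n_by_sex=sexes)
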