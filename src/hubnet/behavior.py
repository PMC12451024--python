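"""Behavioral scoring: composites, reader classification, group comparisons.

Phonological awareness (PA) is measured with three accuracy tasks (phoneme
deletion and two spoonerism tasks, each scored 0-16) and summarized as the
mean of their whole-sample z-scores.  Rapid automatized naming (RAN) is
measured with three speeded naming times (digits, objects, colors, in
seconds) and summarized as the mean of the *negated* time z-scores so that
higher always means better.  Readers are classified good/poor from the
adult reading history questionnaire ratio (C-ARHQ): strictly above 0.36
indicates a history of reading difficulty ("poor reader").
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ARHQ_THRESHOLD = 0.36

PA_TASKS = ("phoneme_deletion", "spoonerism1", "spoonerism2")
RAN_TASKS = ("ran_digits", "ran_objects", "ran_colors")


@dataclass
class BehavioralRecord:
    """One subject's demographic covariates and raw task scores."""

    subject_id: str
    sex: int  # 0 = male, 1 = female
    age: float  # years
    raven_iq: float  # raw nonverbal IQ score
    arhq: float  # reading-history ratio in [0, 1]
    phoneme_deletion: float  # 0-16
    spoonerism1: float  # 0-16
    spoonerism2: float  # 0-16
    ran_digits: float  # seconds
    ran_objects: float  # seconds
    ran_colors: float  # seconds
    character_reading: float  # 0-150

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"{self.subject_id}: sex must be coded 0/1")
        if not 0 <= self.arhq <= 1:
            raise ValueError(f"{self.subject_id}: arhq must lie in [0, 1]")
        for task in PA_TASKS:
            v = getattr(self, task)
            if not 0 <= v <= 16:
                raise ValueError(f"{self.subject_id}: {task} out of range 0-16")
        for task in RAN_TASKS:
            if getattr(self, task) <= 0:
                raise ValueError(f"{self.subject_id}: {task} must be positive")
        if not 0 <= self.character_reading <= 150:
            raise ValueError(f"{self.subject_id}: character_reading out of range")


#: Column order of the on-disk behavioral table.
BEHAVIOR_COLUMNS = [f.name for f in fields(BehavioralRecord)]


@dataclass
class CompositeScores:
    """Standardized composites and reader group for one subject."""

    subject_id: str
    pa_z: float
    ran_z: float
    group: Literal["good", "poor"]


def records_to_frame(records: Sequence[BehavioralRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=BEHAVIOR_COLUMNS)


def _zscore(values: np.ndarray, task: str) -> np.ndarray:
    # Sample SD (n-1 denominator) over the whole sample.
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError(f"task {task!r} has zero variance; cannot z-score")
    return (values - values.mean()) / sd


def classify_readers(records: Sequence[BehavioralRecord]) -> list[str]:
    """Good/poor labels from the C-ARHQ ratio; poor iff arhq > 0.36 (strict)."""
    return ["poor" if r.arhq > ARHQ_THRESHOLD else "good" for r in records]


def composite_scores(records: Sequence[BehavioralRecord]) -> list[CompositeScores]:
    """PA and RAN composite z-scores over the whole sample.

    Each task is z-scored across all subjects (sample SD); the PA composite
    averages the three accuracy-task z-scores, the RAN composite averages
    the three *negated* time z-scores (faster naming scores higher).
    """
    if len(records) < 3:
        raise ValueError("composites need at least 3 subjects")
    frame = records_to_frame(records)
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"missing values in columns: {bad}")
    pa = np.mean(
        [_zscore(frame[t].to_numpy(float), t) for t in PA_TASKS], axis=0
    )
    ran = np.mean(
        [-_zscore(frame[t].to_numpy(float), t) for t in RAN_TASKS], axis=0
    )
    groups = classify_readers(records)
    return [
        CompositeScores(r.subject_id, float(pa[i]), float(ran[i]), groups[i])
        for i, r in enumerate(records)
    ]


def composite_frame(records: Sequence[BehavioralRecord]) -> pd.DataFrame:
    """Composites plus covariates as one analysis-ready table."""
    comp = composite_scores(records)
    frame = records_to_frame(records)
    frame["pa_z"] = [c.pa_z for c in comp]
    frame["ran_z"] = [c.ran_z for c in comp]
    frame["group"] = [c.group for c in comp]
    return frame


TestKind = Literal["t_pooled", "t_welch", "chi_square"]


def group_compare(
    values_by_group: Sequence[np.ndarray] | np.ndarray,
    kind: TestKind = "t_pooled",
) -> tuple[float, float, float]:
    """Two-group comparison: pooled t, Welch t, or Pearson chi-square.

    For the t-tests pass ``(group1_values, group2_values)``; for
    ``chi_square`` pass a 2x2 count table.  The chi-square uses no
    continuity correction.  Returns ``(statistic, df, p_two_tailed)``.
    """
    if kind == "chi_square":
        table = np.asarray(values_by_group, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("chi_square expects a 2x2 count table")
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            raise ValueError("chi_square table has an empty row or column")
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(df), float(p)
    g1, g2 = (np.asarray(v, dtype=float) for v in values_by_group)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects for a t-test")
    if kind == "t_pooled":
        res = stats.ttest_ind(g1, g2, equal_var=True)
        df = len(g1) + len(g2) - 2
    elif kind == "t_welch":
        res = stats.ttest_ind(g1, g2, equal_var=False)
        df = res.df
    else:
        raise ValueError(f"unknown test kind: {kind!r}")
    return float(res.statistic), float(df), float(res.pvalue)


def summary_t_from_moments(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    kind: Literal["t_pooled", "t_welch"] = "t_pooled",
) -> tuple[float, float, float]:
    """t-test from printed group moments (mean, SD, n) instead of raw data.

    Reproduces published group-comparison tables when only summary
    statistics are available.  Returns ``(statistic, df, p_two_tailed)``.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    equal_var = kind == "t_pooled"
    if kind not in ("t_pooled", "t_welch"):
        raise ValueError(f"unknown test kind: {kind!r}")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)
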