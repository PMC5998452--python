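"""Turn raw questionnaire panel records into validated stage sequences.

Subjects in a cessation-induction trial answer two items at each wave:
a 0-10 motivation-to-quit score and a yes/no 7-day smoking item. These
are binned into four stages of readiness:

    1  unmotivated   (motivation 0-3, still smoking)
    2  indecisive    (motivation 4-7, still smoking)
    3  motivated     (motivation 8-10, still smoking)
    4  former smoker (7-day point-prevalence abstinence, regardless of
                      the motivation item)

Stage 4 is treated as absorbing downstream; observed relapses out of it
are censored here. The module produces the panel container, per-group
interval transition-count matrices (the sufficient statistic for
equal-interval panels) and observed-prevalence summary tables.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageRecord",
    "PanelDataset",
    "TransitionCountMatrix",
    "StagingError",
    "MissingDataError",
    "assign_stage",
    "read_panel_csv",
    "build_panel",
    "censor_relapse",
    "transition_counts",
    "observed_prevalence",
]

N_STAGES = 4
DEFAULT_GRID = (0, 12, 26)

# default motivation bins: (low, high) inclusive, mapped to stages 1-3
MOTIVATION_BINS = ((0, 3), (4, 7), (8, 10))


class StagingError(ValueError):
    """Invalid staging input (out-of-range motivation, malformed panel)."""


class MissingDataError(StagingError):
    """A required questionnaire item is missing."""


@dataclass(frozen=True)
class StageRecord:
    """One questionnaire observation of one subject at one wave."""

    subject_id: str
    group: str
    week: int
    motivation: int | None
    smoked_past7: bool | None


def assign_stage(
    motivation: int | None,
    smoked_past7: bool,
    bins: Sequence[tuple[int, int]] = MOTIVATION_BINS,
) -> int:
    """Map the two questionnaire items to a stage in {1, 2, 3, 4}.

    A "no" on the 7-day smoking item yields stage 4 regardless of the
    motivation item (which may then be missing). Otherwise the
    motivation score is binned: 0-3 -> 1, 4-7 -> 2, 8-10 -> 3 by
    default.

    Raises
    ------
    MissingDataError
        smoked_past7 is missing, or motivation is missing while the
        subject still smokes.
    StagingError
        motivation outside [0, 10].
    """
    if smoked_past7 is None:
        raise MissingDataError("smoked_past7 item is missing")
    if not smoked_past7:
        return 4
    if motivation is None:
        raise MissingDataError(
            "motivation item is missing for a current smoker"
        )
    motivation = int(motivation)
    if not 0 <= motivation <= 10:
        raise StagingError(f"motivation {motivation} outside [0, 10]")
    for stage, (lo, hi) in enumerate(bins, start=1):
        if lo <= motivation <= hi:
            return stage
    raise StagingError(f"motivation {motivation} not covered by bins {bins}")


@dataclass
class PanelDataset:
    """Per-subject ordered (week, stage) sequences grouped by arm.

    Attributes
    ----------
    subjects : mapping subject_id -> list of (week, stage) pairs,
        weeks strictly increasing, stages in {1, 2, 3, 4}.
    groups : mapping subject_id -> arm label.
    grid : the observation week grid the panel was built on.
    exclusion_log : how many subjects each arm lost and why
        (complete-case drops, relapse drops), plus per-subject reasons.
    """

    subjects: "OrderedDict[str, list[tuple[int, int]]]"
    groups: dict[str, str]
    grid: tuple[int, ...] = DEFAULT_GRID
    exclusion_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, seq in self.subjects.items():
            weeks = [w for w, _ in seq]
            if sorted(set(weeks)) != weeks:
                raise StagingError(
                    f"subject {sid!r}: weeks not strictly increasing: {weeks}"
                )
            for _, s in seq:
                if s not in (1, 2, 3, 4):
                    raise StagingError(f"subject {sid!r}: stage {s} invalid")

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in self.subjects:
            seen.setdefault(self.groups[sid], None)
        return list(seen)

    def n_subjects(self, group: str | None = None) -> int:
        if group is None:
            return len(self.subjects)
        return sum(1 for s in self.subjects if self.groups[s] == group)

    def subset(self, group: str) -> "PanelDataset":
        keep = OrderedDict(
            (s, list(seq))
            for s, seq in self.subjects.items()
            if self.groups[s] == group
        )
        return PanelDataset(
            subjects=keep,
            groups={s: group for s in keep},
            grid=self.grid,
            exclusion_log=self.exclusion_log,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: subject_id, group, week, stage."""
        rows = [
            (sid, self.groups[sid], w, s)
            for sid, seq in self.subjects.items()
            for w, s in seq
        ]
        return pd.DataFrame(rows, columns=["subject_id", "group", "week", "stage"])


@dataclass(frozen=True)
class TransitionCountMatrix:
    """4x4 matrix of observed interval transitions for one arm."""

    counts: np.ndarray
    interval: float
    group: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (N_STAGES, N_STAGES) or (c < 0).any():
            raise StagingError("counts must be a nonnegative 4x4 matrix")
        object.__setattr__(self, "counts", c)
        if self.interval <= 0:
            raise StagingError("interval must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [str(i) for i in range(1, N_STAGES + 1)]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def snap_interval(delta: float, grid: Sequence[int]) -> float:
    """Snap an observed pair spacing to the design interval.

    Wave labels are nominal (e.g. follow-ups at weeks 12 and 26 for a
    design with two equal 13-week intervals), so a spacing within 12%
    of an integer multiple of the mean grid step is treated as that
    many design intervals. Genuinely irregular spacings are returned
    unchanged and handled by the product-form likelihood downstream.
    """
    steps = np.diff(np.sort(np.asarray(grid, float)))
    if len(steps) == 0:
        return float(delta)
    mean_step = float(steps.mean())
    k = round(delta / mean_step)
    if k >= 1 and abs(delta / mean_step - k) <= 0.12:
        return k * mean_step
    return float(delta)


def _parse_yes_no(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text in ("", "na", "nan", "none", "missing"):
        return None
    if text in ("yes", "y", "true", "1"):
        return True
    if text in ("no", "n", "false", "0"):
        return False
    raise StagingError(f"cannot parse yes/no value {value!r}")


def read_panel_csv(path) -> list[StageRecord]:
    """Read a long-format panel CSV into StageRecords.

    Required columns: subject_id, group, week, motivation, smoked_past7.
    motivation may be blank/NA; smoked_past7 is case-insensitive
    yes/no/NA.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    required = {"subject_id", "group", "week", "motivation", "smoked_past7"}
    missing = required - set(df.columns)
    if missing:
        raise StagingError(f"panel CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        motivation = row.motivation
        if pd.isna(motivation):
            motivation = None
        else:
            motivation = int(motivation)
        records.append(
            StageRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                week=int(row.week),
                motivation=motivation,
                smoked_past7=_parse_yes_no(row.smoked_past7),
            )
        )
    return records


def build_panel(
    records: Iterable[StageRecord],
    grid: Sequence[int] | None = DEFAULT_GRID,
    complete_case: bool = True,
    bins: Sequence[tuple[int, int]] = MOTIVATION_BINS,
) -> PanelDataset:
    """Assemble records into a PanelDataset, applying stage binning.

    With ``complete_case`` on (the default), subjects missing a stage at
    any grid week are dropped and tallied in the exclusion log; with it
    off, partial sequences are kept (the CTMC likelihood downstream
    handles unequal intervals). ``grid=None`` infers the wave grid from
    the distinct weeks present in the records.
    """
    records = list(records)
    if grid is None:
        grid = sorted({rec.week for rec in records})
    grid = tuple(sorted(grid))
    if len(grid) < 2:
        raise StagingError("observation grid needs at least 2 waves")

    by_subject: "OrderedDict[str, dict[int, StageRecord]]" = OrderedDict()
    groups: dict[str, str] = {}
    for rec in records:
        waves = by_subject.setdefault(rec.subject_id, {})
        if rec.week in waves:
            raise StagingError(
                f"duplicate observation for subject {rec.subject_id!r} "
                f"at week {rec.week}"
            )
        waves[rec.week] = rec
        prev = groups.setdefault(rec.subject_id, rec.group)
        if prev != rec.group:
            raise StagingError(
                f"subject {rec.subject_id!r} appears in groups "
                f"{prev!r} and {rec.group!r}"
            )

    subjects: "OrderedDict[str, list[tuple[int, int]]]" = OrderedDict()
    dropped: dict[str, str] = {}
    for sid, waves in by_subject.items():
        seq: list[tuple[int, int]] = []
        missing_weeks: list[int] = []
        for week in grid:
            rec = waves.get(week)
            if rec is None:
                missing_weeks.append(week)
                continue
            try:
                stage = assign_stage(rec.motivation, rec.smoked_past7, bins)
            except MissingDataError:
                missing_weeks.append(week)
                continue
            seq.append((week, stage))
        if complete_case and missing_weeks:
            dropped[sid] = f"missing waves {missing_weeks}"
            continue
        if len(seq) == 0:
            dropped[sid] = "no usable waves"
            continue
        subjects[sid] = seq

    if not subjects:
        raise StagingError("no subjects retained after exclusions")

    per_group_dropped: dict[str, int] = {}
    per_group_total: dict[str, int] = {}
    for sid in by_subject:
        g = groups[sid]
        per_group_total[g] = per_group_total.get(g, 0) + 1
        if sid in dropped:
            per_group_dropped[g] = per_group_dropped.get(g, 0) + 1
    log = {
        "mode": "complete_case" if complete_case else "partial",
        "dropped_subjects": dropped,
        "n_input": len(by_subject),
        "n_retained": len(subjects),
        "per_group": {
            g: {
                "input": per_group_total[g],
                "dropped": per_group_dropped.get(g, 0),
                "fraction_dropped": round(
                    per_group_dropped.get(g, 0) / per_group_total[g], 4
                ),
            }
            for g in per_group_total
        },
    }
    retained_groups = {s: groups[s] for s in subjects}
    return PanelDataset(
        subjects=subjects, groups=retained_groups, grid=grid, exclusion_log=log
    )


def censor_relapse(panel: PanelDataset, mode: str = "truncate") -> PanelDataset:
    """Enforce that stage 4 (former smoker) is absorbing.

    mode="truncate" (default): each subject's sequence is cut at the
    first stage-4 observation, removing any later waves (and therefore
    any observed 4 -> non-4 relapse transition). mode="drop": subjects
    showing a relapse transition are removed entirely.

    The number of relapse transitions removed is recorded in the
    returned panel's exclusion log under "relapse".
    """
    if mode not in ("truncate", "drop"):
        raise StagingError(f"unknown relapse mode {mode!r}")
    subjects: "OrderedDict[str, list[tuple[int, int]]]" = OrderedDict()
    groups: dict[str, str] = {}
    n_relapse = 0
    dropped: list[str] = []
    for sid, seq in panel.subjects.items():
        stages = [s for _, s in seq]
        relapses = sum(
            1
            for a, b in zip(stages, stages[1:])
            if a == 4 and b != 4
        )
        n_relapse += relapses
        if relapses and mode == "drop":
            dropped.append(sid)
            continue
        if 4 in stages:
            cut = stages.index(4) + 1
            seq = seq[:cut]
        subjects[sid] = list(seq)
        groups[sid] = panel.groups[sid]
    if not subjects:
        raise StagingError("no subjects retained after relapse censoring")
    log = dict(panel.exclusion_log)
    log["relapse"] = {
        "mode": mode,
        "transitions_removed": n_relapse,
        "subjects_dropped": dropped,
    }
    return PanelDataset(
        subjects=subjects, groups=groups, grid=panel.grid, exclusion_log=log
    )


def transition_counts(
    panel: PanelDataset,
    group: str,
    require_equal_intervals: bool = True,
) -> TransitionCountMatrix:
    """Tally consecutive-wave transitions for one arm into a 4x4 matrix.

    Entry (l, k) counts observation pairs that moved from stage l to
    stage k over one interval. With equal intervals and complete cases
    the total equals subjects x intervals; the matrix is then the
    sufficient statistic for the panel likelihood.
    """
    sub = panel.subset(group)
    if not sub.subjects:
        raise StagingError(f"no subjects in group {group!r}")
    intervals = {
        snap_interval(w2 - w1, panel.grid)
        for seq in sub.subjects.values()
        for (w1, _), (w2, _) in zip(seq, seq[1:])
    }
    if not intervals:
        raise StagingError(f"group {group!r} has no observed transitions")
    if require_equal_intervals and len(intervals) > 1:
        raise StagingError(
            f"group {group!r} has mixed interval lengths {sorted(intervals)}; "
            "pass require_equal_intervals=False to tally anyway"
        )
    counts = np.zeros((N_STAGES, N_STAGES), dtype=int)
    for seq in sub.subjects.values():
        for (_, a), (_, b) in zip(seq, seq[1:]):
            counts[a - 1, b - 1] += 1
    return TransitionCountMatrix(
        counts=counts, interval=float(min(intervals)), group=group
    )


def observed_prevalence(panel: PanelDataset) -> pd.DataFrame:
    """Stage counts and percentages per group per grid week.

    Returns a tidy frame with one row per (group, week) carrying count
    columns n1..n4 and percentage columns p1..p4 (count / group size x
    100), plus a "change" row per group holding final-week minus
    baseline-week values.
    """
    rows = []
    for group in panel.group_labels:
        sub = panel.subset(group)
        n = sub.n_subjects()
        week_counts: dict[int, np.ndarray] = {}
        for week in panel.grid:
            c = np.zeros(N_STAGES, dtype=int)
            for seq in sub.subjects.values():
                for w, s in seq:
                    if w == week:
                        c[s - 1] += 1
            week_counts[week] = c
            rows.append((group, str(week), n, *c, *(100.0 * c / n)))
        first, last = panel.grid[0], panel.grid[-1]
        dc = week_counts[last] - week_counts[first]
        rows.append(
            (group, f"{first}->{last}", n, *dc, *(100.0 * dc / n))
        )
    cols = (
        ["group", "week", "n"]
        + [f"n{i}" for i in range(1, N_STAGES + 1)]
        + [f"p{i}" for i in range(1, N_STAGES + 1)]
    )
    return pd.DataFrame(rows, columns=cols)
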