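"""Birth-order analysis from clone-induction records.

Twin-spot clones are induced in contiguous 2-hr windows spanning larval
(18-92 hr after larval hatching, ALH) and pupal-transition (22 hr before to
16 hr after pupa formation, BPF/APF) development.  Each recovered
single-cell clone dates one neuron's birth to its induction window.  From
tables of such records the module builds:

* type-level heatmaps — raw single-cell counts per (neuron type, induction
  time), capped at 10 for display;
* recovery (production) windows — maximal runs of consecutive non-zero
  induction time points; a window is *detectable* when it yields at least
  six samples over at least two time points;
* group-level heatmaps — counts pooled over a morphological group's member
  types, normalized to sum 1 within each production window, with groups
  ordered by the timing of their first window;
* an inferred birth order of neuron types from (onset, peak, offset) of
  their recovery profiles.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchedulePoint",
    "InductionSchedule",
    "CloneRecord",
    "ProductionWindow",
    "build_type_heatmap",
    "detect_recovery_windows",
    "build_group_heatmap",
    "sort_groups_by_first_window",
    "infer_birth_order",
    "read_clone_records",
    "write_clone_records",
]

logger = logging.getLogger(__name__)

CLONE_CLASSES = ("NB-clone", "single-cell", "paired-two-cell")


@dataclass(frozen=True, order=True)
class SchedulePoint:
    """One induction time point: developmental phase plus hour.

    ``hour`` is hours ALH for the larval phase and the signed offset from
    pupa formation for the pupal phase (negative = BPF, non-negative = APF).
    """

    phase: str  # "ALH" | "pupal"
    hour: int

    @property
    def label(self) -> str:
        if self.phase == "ALH":
            return f"ALH{self.hour}"
        return f"BPF{-self.hour}" if self.hour < 0 else f"APF{self.hour}"


class InductionSchedule:
    """The 2-hr clone-induction schedule.

    Larval phase 18-92 hr ALH and pupal transition -22 hr (BPF) to +16 hr
    (APF), both in 2-hr steps.  The two phases are concatenated on a single
    ordered axis, pupal points after 92 hr ALH (exact wall-clock alignment
    between the phases varies per animal and is not modelled).
    """

    def __init__(
        self,
        larval: tuple[int, int] = (18, 92),
        pupal: tuple[int, int] = (-22, 16),
        step: int = 2,
    ):
        self.step = step
        self.points: list[SchedulePoint] = [
            SchedulePoint("ALH", h) for h in range(larval[0], larval[1] + 1, step)
        ] + [SchedulePoint("pupal", h) for h in range(pupal[0], pupal[1] + 1, step)]
        self._index = {p: i for i, p in enumerate(self.points)}
        self._by_label = {p.label: p for p in self.points}

    def __len__(self) -> int:
        return len(self.points)

    def __contains__(self, point: SchedulePoint) -> bool:
        return point in self._index

    def index(self, point: SchedulePoint) -> int:
        return self._index[point]

    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    def from_label(self, label: str) -> SchedulePoint:
        return self._by_label[label]


DEFAULT_SCHEDULE = InductionSchedule()


@dataclass(frozen=True)
class CloneRecord:
    """One twin-spot clone observation."""

    lineage: str
    hemilineage: str
    neuron_type: str
    induction_time: SchedulePoint
    clone_class: str = "single-cell"
    brain_id: str = ""

    def __post_init__(self) -> None:
        if self.clone_class not in CLONE_CLASSES:
            raise ValueError(
                f"clone_class must be one of {CLONE_CLASSES}, got {self.clone_class!r}"
            )


@dataclass(frozen=True)
class ProductionWindow:
    """A maximal run of consecutive non-zero induction time points."""

    start: int  # schedule index, inclusive
    end: int  # schedule index, inclusive
    total: int  # samples in the window
    detectable: bool  # total >= min_samples and span >= min_span

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _single_cell(records: Iterable[CloneRecord]) -> list[CloneRecord]:
    """Keep clone classes that date a single neuron's birth."""
    return [r for r in records if r.clone_class in ("single-cell", "paired-two-cell")]


def _counts_by_type(
    records: Iterable[CloneRecord], schedule: InductionSchedule
) -> dict[str, np.ndarray]:
    counts: dict[str, np.ndarray] = {}
    for r in records:
        if r.induction_time not in schedule:
            raise ValueError(
                f"induction time {r.induction_time} is not a schedule point"
            )
        vec = counts.setdefault(r.neuron_type, np.zeros(len(schedule), dtype=int))
        vec[schedule.index(r.induction_time)] += 1
    return counts


def build_type_heatmap(
    records: Sequence[CloneRecord],
    type_order: Sequence[str],
    cap: int = 10,
    schedule: InductionSchedule = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Type-level heatmap: capped single-cell counts per induction point.

    Rows follow ``type_order`` (conventionally birth-order sorted); cells are
    ``min(cap, count)`` with the display cap defaulting to 10.  Records must
    come from one hemilineage and every record's type must appear in
    ``type_order``.
    """
    records = _single_cell(records)
    counts = _counts_by_type(records, schedule)
    unknown = sorted(set(counts) - set(type_order))
    if unknown:
        raise ValueError(f"record types absent from type_order: {unknown}")
    data = np.zeros((len(type_order), len(schedule)), dtype=int)
    for i, t in enumerate(type_order):
        if t in counts:
            data[i] = np.minimum(counts[t], cap)
    return pd.DataFrame(data, index=list(type_order), columns=schedule.labels())


def detect_recovery_windows(
    counts: Sequence[int],
    min_samples: int = 6,
    min_span: int = 2,
) -> list[ProductionWindow]:
    """Find candidate production windows in a per-time-point count vector.

    Candidates are maximal runs of consecutive non-zero counts (separated by
    at least one zero point).  A candidate is *detectable* when it yields at
    least ``min_samples`` samples from an uninterrupted interval spanning at
    least ``min_span`` time points.
    """
    arr = np.asarray(counts, dtype=int)
    windows: list[ProductionWindow] = []
    start: Optional[int] = None
    for i, c in enumerate(list(arr) + [0]):  # sentinel zero terminates a final run
        if c > 0 and start is None:
            start = i
        elif c == 0 and start is not None:
            total = int(arr[start:i].sum())
            span = i - start
            windows.append(
                ProductionWindow(
                    start=start,
                    end=i - 1,
                    total=total,
                    detectable=total >= min_samples and span >= min_span,
                )
            )
            start = None
    return windows


def _pooled_group_counts(
    records: Sequence[CloneRecord],
    group_assignment: Mapping[str, str],
    schedule: InductionSchedule,
) -> dict[str, np.ndarray]:
    records = _single_cell(records)
    by_type = _counts_by_type(records, schedule)
    unmapped = sorted(t for t in by_type if t not in group_assignment)
    if unmapped:
        raise ValueError(f"types not mapped to any group: {unmapped}")
    pooled: dict[str, np.ndarray] = {}
    for t, vec in by_type.items():
        g = group_assignment[t]
        pooled[g] = pooled.get(g, np.zeros(len(schedule), dtype=int)) + vec
    return pooled


def sort_groups_by_first_window(
    pooled_counts: Mapping[str, Sequence[int]],
) -> list[str]:
    """Order groups by the timing of their first production window.

    Key: ascending count-weighted mean time of the first candidate window,
    ties broken by earlier window start, then group name.  Groups without
    any samples are placed last (and logged).
    """
    keyed = []
    empty = []
    for name, counts in pooled_counts.items():
        windows = detect_recovery_windows(counts)
        if not windows:
            logger.warning("group %r has no samples; placed last", name)
            empty.append(name)
            continue
        w = windows[0]
        vec = np.asarray(counts, dtype=float)[w.start : w.end + 1]
        mean_t = float(np.average(np.arange(w.start, w.end + 1), weights=vec))
        keyed.append((mean_t, w.start, name))
    keyed.sort()
    return [name for _, _, name in keyed] + sorted(empty)


def build_group_heatmap(
    records: Sequence[CloneRecord],
    group_assignment: Mapping[str, str],
    schedule: InductionSchedule = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Group-level heatmap with per-window normalized sample distributions.

    Counts are pooled over each group's member types; within every candidate
    production window the cell weights are divided by the window total (so
    each window's row slice sums to 1, making multi-window production
    visible); rows are ordered by :func:`sort_groups_by_first_window`.
    """
    pooled = _pooled_group_counts(records, group_assignment, schedule)
    order = sort_groups_by_first_window(pooled)
    data = np.zeros((len(order), len(schedule)))
    for i, g in enumerate(order):
        vec = pooled[g].astype(float)
        for w in detect_recovery_windows(pooled[g]):
            data[i, w.start : w.end + 1] = vec[w.start : w.end + 1] / w.total
    return pd.DataFrame(data, index=order, columns=schedule.labels())


def infer_birth_order(
    records: Sequence[CloneRecord],
    schedule: InductionSchedule = DEFAULT_SCHEDULE,
) -> list[str]:
    """Sort neuron types by their recovery profiles.

    Composite key operationalizing "beginning, peak, ending of recovery":
    (1) first time point with at least two samples (first non-zero point if
    no point reaches two), (2) peak recovery time (earliest argmax), (3) last
    non-zero time point, (4) type name.  Deterministic and invariant to
    record order.
    """
    counts = _counts_by_type(_single_cell(records), schedule)

    def key(t: str):
        vec = counts[t]
        nz = np.nonzero(vec)[0]
        ge2 = np.nonzero(vec >= 2)[0]
        onset = int(ge2[0]) if len(ge2) else int(nz[0])
        peak = int(np.argmax(vec))
        offset = int(nz[-1])
        return (onset, peak, offset, t)

    return sorted(counts, key=key)


# ---------------------------------------------------------------------------
# Clone-record CSV I/O
# ---------------------------------------------------------------------------

_FIELDS = [
    "brain_id",
    "lineage",
    "hemilineage",
    "neuron_type",
    "induction_time_hr",
    "phase",
    "clone_class",
]


def write_clone_records(records: Iterable[CloneRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIELDS)
        for r in records:
            p = r.induction_time
            if p.phase == "ALH":
                phase, hr = "ALH", p.hour
            else:
                phase, hr = ("BPF", -p.hour) if p.hour < 0 else ("APF", p.hour)
            writer.writerow(
                [r.brain_id, r.lineage, r.hemilineage, r.neuron_type, hr, phase,
                 r.clone_class]
            )


def read_clone_records(path: str | Path) -> list[CloneRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            hr = int(row["induction_time_hr"])
            phase = row["phase"]
            if phase == "ALH":
                point = SchedulePoint("ALH", hr)
            elif phase == "BPF":
                point = SchedulePoint("pupal", -hr)
            elif phase == "APF":
                point = SchedulePoint("pupal", hr)
            else:
                raise ValueError(f"unknown phase {phase!r}")
            records.append(
                CloneRecord(
                    lineage=row["lineage"],
                    hemilineage=row["hemilineage"],
                    neuron_type=row["neuron_type"],
                    induction_time=point,
                    clone_class=row["clone_class"],
                    brain_id=row["brain_id"],
                )
            )
    return records
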