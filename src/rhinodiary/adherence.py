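"""Adherence to daily recording and the high/low adherence split.

Adherence is the percentage of prescribed monitoring days with a
completed diary entry. Patients at or above the threshold (default 80%)
form the high-adherence group. The cohort-level "average adherence" is
the pooled ratio (total recorded days over total prescribed days), which
differs from the mean of individual percentages when windows differ; both
are provided under distinct names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .diary import PatientSeries

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 80.0
#: Start/end deviations of at least this many days are flagged.
DEVIATION_FLAG_DAYS = 3


@dataclass(frozen=True)
class AdherenceRecord:
    """Recorded-vs-prescribed day counts and group label for one patient.

    ``delayed_start_days`` / ``early_end_days`` are None for a patient who
    never recorded (``never_started`` is then True).
    """

    patient_id: str
    recorded_days: int
    prescribed_days: int
    adherence_pct: float
    group: str  # "high" | "low"
    delayed_start_days: int | None
    early_end_days: int | None
    delayed_start_flag: bool
    early_end_flag: bool
    never_started: bool = False


def adherence_from_counts(
    patient_id: str,
    recorded_days: int,
    prescribed_days: int,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    delayed_start_days: int | None = 0,
    early_end_days: int | None = 0,
) -> AdherenceRecord:
    """Build a record straight from day counts (no item-level data needed)."""
    if prescribed_days <= 0:
        raise ValueError("prescribed_days must be positive")
    if not 0 <= recorded_days <= prescribed_days:
        raise ValueError(
            f"recorded_days {recorded_days} outside 0..{prescribed_days}"
        )
    pct = 100.0 * recorded_days / prescribed_days
    return AdherenceRecord(
        patient_id=patient_id,
        recorded_days=recorded_days,
        prescribed_days=prescribed_days,
        adherence_pct=pct,
        group="high" if pct >= threshold else "low",
        delayed_start_days=delayed_start_days,
        early_end_days=early_end_days,
        delayed_start_flag=(
            delayed_start_days is not None and delayed_start_days >= DEVIATION_FLAG_DAYS
        ),
        early_end_flag=(
            early_end_days is not None and early_end_days >= DEVIATION_FLAG_DAYS
        ),
        never_started=recorded_days == 0,
    )


def start_end_deviation(
    series: PatientSeries, *, flag_days: int = DEVIATION_FLAG_DAYS
) -> tuple[int | None, int | None, bool, bool]:
    """Days between window start/end and first/last in-window record.

    Returns ``(delayed_start_days, early_end_days, delayed_flag, early_flag)``;
    both day counts are None for a series with no in-window records.
    """
    days = series.days_in_window()
    if not days:
        return None, None, False, False
    delayed = (days[0].date - series.window.start).days
    early = (series.window.end - days[-1].date).days
    return delayed, early, delayed >= flag_days, early >= flag_days


def patient_adherence(
    series: PatientSeries, *, threshold: float = DEFAULT_THRESHOLD
) -> AdherenceRecord:
    """Adherence of one patient, counting only records inside the window."""
    in_window = series.days_in_window()
    n_outside = series.n_days - len(in_window)
    if n_outside:
        logger.warning(
            "patient %s: %d record(s) outside the prescribed window excluded",
            series.patient_id,
            n_outside,
        )
    delayed, early, delayed_flag, early_flag = start_end_deviation(series)
    record = adherence_from_counts(
        series.patient_id,
        len(in_window),
        series.window.prescribed_days,
        threshold=threshold,
        delayed_start_days=delayed,
        early_end_days=early,
    )
    # adherence_from_counts cannot know the dates; rebuild with real flags
    return AdherenceRecord(
        patient_id=record.patient_id,
        recorded_days=record.recorded_days,
        prescribed_days=record.prescribed_days,
        adherence_pct=record.adherence_pct,
        group=record.group,
        delayed_start_days=delayed,
        early_end_days=early,
        delayed_start_flag=delayed_flag,
        early_end_flag=early_flag,
        never_started=len(in_window) == 0,
    )


def cohort_adherence(
    cohort: Iterable[PatientSeries], *, threshold: float = DEFAULT_THRESHOLD
) -> list[AdherenceRecord]:
    return [patient_adherence(series, threshold=threshold) for series in cohort]


def pooled_adherence(records: Sequence[AdherenceRecord]) -> float:
    """Pooled cohort adherence: 100 x (sum recorded) / (sum prescribed)."""
    if not records:
        raise ValueError("pooled adherence of an empty cohort is undefined")
    total_recorded = sum(r.recorded_days for r in records)
    total_prescribed = sum(r.prescribed_days for r in records)
    return 100.0 * total_recorded / total_prescribed


def mean_adherence(records: Sequence[AdherenceRecord]) -> float:
    """Mean of individual adherence percentages (not the pooled ratio)."""
    if not records:
        raise ValueError("mean adherence of an empty cohort is undefined")
    return sum(r.adherence_pct for r in records) / len(records)


@dataclass(frozen=True)
class CohortClassification:
    """Partition of a cohort into high/low adherence groups."""

    threshold: float
    high_ids: tuple[str, ...]
    low_ids: tuple[str, ...]

    @property
    def n_high(self) -> int:
        return len(self.high_ids)

    @property
    def n_low(self) -> int:
        return len(self.low_ids)

    @property
    def n_total(self) -> int:
        return self.n_high + self.n_low

    @property
    def pct_high(self) -> float:
        return 100.0 * self.n_high / self.n_total

    @property
    def pct_low(self) -> float:
        return 100.0 * self.n_low / self.n_total


def classify_cohort(
    records: Sequence[AdherenceRecord], threshold: float = DEFAULT_THRESHOLD
) -> CohortClassification:
    """Partition at ``threshold`` (inclusive: exactly 80% is high)."""
    if not records:
        raise ValueError("cannot classify an empty cohort")
    high = tuple(r.patient_id for r in records if r.adherence_pct >= threshold)
    low = tuple(r.patient_id for r in records if r.adherence_pct < threshold)
    return CohortClassification(threshold=threshold, high_ids=high, low_ids=low)


def adherence_table(records: Sequence[AdherenceRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "recorded_days": r.recorded_days,
            "prescribed_days": r.prescribed_days,
            "adherence_pct": round(r.adherence_pct, 6),
            "group": r.group,
            "delayed_start_days": r.delayed_start_days,
            "early_end_days": r.early_end_days,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "recorded_days",
            "prescribed_days",
            "adherence_pct",
            "group",
            "delayed_start_days",
            "early_end_days",
        ],
    )


def write_adherence_table(
    records: Sequence[AdherenceRecord], path: str | Path, *, delimiter: str = ","
) -> None:
    adherence_table(records).to_csv(path, sep=delimiter, index=False)
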