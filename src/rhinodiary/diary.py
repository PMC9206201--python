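"""Domain types and tabular I/O for daily symptom-diary records.

A diary record is one patient-day: six symptom items graded 0-3
(none/mild/moderate/severe), three binary medication-intake flags, and a
0-10 visual analogue scale rating. Records are exchanged as delimited
text with a fixed column set (see :data:`DIARY_COLUMNS`); a missing day
is an absent row, never a sentinel.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

SYMPTOM_FIELDS: tuple[str, ...] = (
    "sneezing",
    "rhinorrhea",
    "nasal_pruritus",
    "nasal_congestion",
    "itchy_eyes",
    "watery_eyes",
)
MEDICATION_FIELDS: tuple[str, ...] = (
    "antihistamine",
    "nasal_steroid",
    "systemic_steroid",
)
DIARY_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "date",
    *SYMPTOM_FIELDS,
    *MEDICATION_FIELDS,
    "vas",
)
WINDOW_COLUMNS: tuple[str, ...] = ("patient_id", "start", "end")


class DiaryFormatError(ValueError):
    """Raised when a diary table violates the expected format."""


@dataclass(frozen=True)
class DiaryDay:
    """One completed questionnaire: a single patient-day of item-level entries."""

    patient_id: str
    date: datetime.date
    sneezing: int
    rhinorrhea: int
    nasal_pruritus: int
    nasal_congestion: int
    itchy_eyes: int
    watery_eyes: int
    antihistamine: int
    nasal_steroid: int
    systemic_steroid: int
    vas: int

    def __post_init__(self) -> None:
        for name in SYMPTOM_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or value not in (0, 1, 2, 3):
                raise ValueError(
                    f"symptom grade {name!r} must be an integer in 0..3, got {value!r}"
                )
        for name in MEDICATION_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or value not in (0, 1):
                raise ValueError(
                    f"medication flag {name!r} must be 0 or 1, got {value!r}"
                )
        if not isinstance(self.vas, int) or not 0 <= self.vas <= 10:
            raise ValueError(f"vas must be an integer in 0..10, got {self.vas!r}")

    @property
    def symptom_grades(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in SYMPTOM_FIELDS)

    @property
    def medication_flags(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in MEDICATION_FIELDS)


@dataclass(frozen=True)
class MonitoringWindow:
    """Prescribed monitoring period, endpoints inclusive."""

    start: datetime.date
    end: datetime.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} is after end {self.end}")

    @property
    def prescribed_days(self) -> int:
        """Inclusive day count of the window."""
        return (self.end - self.start).days + 1

    def __contains__(self, date: datetime.date) -> bool:
        return self.start <= date <= self.end

    def dates(self) -> list[datetime.date]:
        return [
            self.start + datetime.timedelta(days=i) for i in range(self.prescribed_days)
        ]


@dataclass(frozen=True)
class PatientSeries:
    """All recorded diary days of one patient, ordered by date."""

    patient_id: str
    window: MonitoringWindow
    days: tuple[DiaryDay, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", tuple(self.days))
        previous: datetime.date | None = None
        for day in self.days:
            if day.patient_id != self.patient_id:
                raise ValueError(
                    f"diary day for {day.patient_id!r} in series of {self.patient_id!r}"
                )
            if previous is not None and day.date <= previous:
                raise ValueError(
                    f"dates must be strictly increasing: {day.date} follows {previous}"
                )
            previous = day.date

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def dates(self) -> tuple[datetime.date, ...]:
        return tuple(day.date for day in self.days)

    def days_in_window(self) -> tuple[DiaryDay, ...]:
        """Recorded days inside the prescribed window."""
        return tuple(day for day in self.days if day.date in self.window)


def _parse_date(raw: object, *, row: int, column: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(str(raw).strip())
    except ValueError as exc:
        raise DiaryFormatError(f"row {row}: bad {column} {raw!r}: {exc}") from exc


def _parse_int(raw: object, *, row: int, column: str) -> int:
    text = str(raw).strip()
    try:
        return int(text)
    except ValueError as exc:
        raise DiaryFormatError(
            f"row {row}: field {column!r} is not an integer: {raw!r}"
        ) from exc


def read_diary_table(
    path: str | Path,
    window: MonitoringWindow | None = None,
    windows: Mapping[str, MonitoringWindow] | None = None,
    *,
    delimiter: str = ",",
    on_partial: str = "error",
) -> list[PatientSeries]:
    """Read a diary table into one :class:`PatientSeries` per patient.

    Parameters
    ----------
    path
        Delimited text file whose header is exactly :data:`DIARY_COLUMNS`.
    window
        Global monitoring window applied to every patient.
    windows
        Per-patient windows keyed by patient id; takes precedence over
        ``window``. Every patient in the file must have a window.
    on_partial
        ``"error"`` (default) rejects rows with blank fields; ``"drop"``
        discards them with a logged warning.

    Raises
    ------
    DiaryFormatError
        On malformed rows, out-of-range values, duplicate (patient, date)
        pairs, unexpected headers, or a patient without a window.
    """
    if window is None and windows is None:
        raise ValueError("either a global window or per-patient windows is required")
    if on_partial not in ("error", "drop"):
        raise ValueError(f"on_partial must be 'error' or 'drop', got {on_partial!r}")

    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if tuple(frame.columns) != DIARY_COLUMNS:
        raise DiaryFormatError(
            f"unexpected header {list(frame.columns)}; expected {list(DIARY_COLUMNS)}"
        )

    by_patient: dict[str, dict[datetime.date, DiaryDay]] = {}
    n_dropped = 0
    for position, row in enumerate(frame.itertuples(index=False), start=2):
        values = dict(zip(DIARY_COLUMNS, row))
        blank = [name for name, value in values.items() if str(value).strip() == ""]
        if blank:
            if on_partial == "drop":
                n_dropped += 1
                logger.warning("row %d: dropping partial row (blank: %s)", position, blank)
                continue
            raise DiaryFormatError(f"row {position}: blank field(s) {blank}")
        patient_id = str(values["patient_id"]).strip()
        date = _parse_date(values["date"], row=position, column="date")
        numeric = {
            name: _parse_int(values[name], row=position, column=name)
            for name in (*SYMPTOM_FIELDS, *MEDICATION_FIELDS, "vas")
        }
        try:
            day = DiaryDay(patient_id=patient_id, date=date, **numeric)
        except ValueError as exc:
            raise DiaryFormatError(f"row {position}: {exc}") from exc
        patient_days = by_patient.setdefault(patient_id, {})
        if date in patient_days:
            raise DiaryFormatError(
                f"row {position}: duplicate record for patient {patient_id!r} on {date}"
            )
        patient_days[date] = day

    if n_dropped:
        logger.warning("dropped %d partial row(s) from %s", n_dropped, path)

    cohort: list[PatientSeries] = []
    for patient_id in sorted(by_patient):
        if windows is not None and patient_id in windows:
            patient_window = windows[patient_id]
        elif window is not None:
            patient_window = window
        else:
            raise DiaryFormatError(f"no monitoring window for patient {patient_id!r}")
        days = tuple(day for _, day in sorted(by_patient[patient_id].items()))
        cohort.append(PatientSeries(patient_id=patient_id, window=patient_window, days=days))
    return cohort


def write_diary_table(
    cohort: Iterable[PatientSeries], path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a cohort as a delimited diary table (ISO-8601 dates)."""
    rows = []
    for series in cohort:
        for day in series.days:
            rows.append(
                {
                    "patient_id": day.patient_id,
                    "date": day.date.isoformat(),
                    **{name: getattr(day, name) for name in SYMPTOM_FIELDS},
                    **{name: getattr(day, name) for name in MEDICATION_FIELDS},
                    "vas": day.vas,
                }
            )
    frame = pd.DataFrame(rows, columns=list(DIARY_COLUMNS))
    frame.to_csv(path, sep=delimiter, index=False)


def read_window_table(
    path: str | Path, *, delimiter: str = ","
) -> dict[str, MonitoringWindow]:
    """Read per-patient windows from ``patient_id,start,end`` text."""
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if tuple(frame.columns) != WINDOW_COLUMNS:
        raise DiaryFormatError(
            f"unexpected header {list(frame.columns)}; expected {list(WINDOW_COLUMNS)}"
        )
    windows: dict[str, MonitoringWindow] = {}
    for position, row in enumerate(frame.itertuples(index=False), start=2):
        patient_id = str(row.patient_id).strip()
        if patient_id in windows:
            raise DiaryFormatError(f"row {position}: duplicate window for {patient_id!r}")
        windows[patient_id] = MonitoringWindow(
            start=_parse_date(row.start, row=position, column="start"),
            end=_parse_date(row.end, row=position, column="end"),
        )
    return windows


def write_window_table(
    windows: Mapping[str, MonitoringWindow], path: str | Path, *, delimiter: str = ","
) -> None:
    frame = pd.DataFrame(
        [
            {"patient_id": pid, "start": w.start.isoformat(), "end": w.end.isoformat()}
            for pid, w in sorted(windows.items())
        ],
        columns=list(WINDOW_COLUMNS),
    )
    frame.to_csv(path, sep=delimiter, index=False)
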