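"""Daily score construction: RTSS, CSMS and VAS trajectories.

RTSS is the plain sum of the six symptom grades (range 0-18). CSMS is the
daily symptom score (mean of the six grades, range 0-3) plus a daily
medication score (0-3 from a drug-class hierarchy), so its unit step is
1/6. VAS is the 0-10 self-rating passed through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .diary import DiaryDay, PatientSeries

SCORE_NAMES: tuple[str, ...] = ("RTSS", "CSMS", "VAS")

#: Unit increment of each score: the smallest possible nonzero change.
UNIT_STEPS: Mapping[str, float] = {"RTSS": 1.0, "CSMS": 1.0 / 6.0, "VAS": 1.0}

SCORE_RANGES: Mapping[str, tuple[float, float]] = {
    "RTSS": (0.0, 18.0),
    "CSMS": (0.0, 6.0),
    "VAS": (0.0, 10.0),
}

#: Stepwise daily-medication-score weights; the day's score is the maximum
#: weight among the drug classes actually taken (0 when none).
DEFAULT_MEDICATION_WEIGHTS: Mapping[str, int] = {
    "antihistamine": 1,
    "nasal_steroid": 2,
    "systemic_steroid": 3,
}


def rtss(day: DiaryDay) -> int:
    """Total symptom score: sum of the six 0-3 grades (0-18)."""
    return sum(day.symptom_grades)


def medication_component(
    day: DiaryDay, weights: Mapping[str, int] = DEFAULT_MEDICATION_WEIGHTS
) -> int:
    """Daily medication score: max weight among drug classes taken, else 0."""
    taken = [weights[name] for name in weights if getattr(day, name)]
    return max(taken, default=0)


def csms(day: DiaryDay, weights: Mapping[str, int] = DEFAULT_MEDICATION_WEIGHTS) -> float:
    """Combined symptom and medication score (0-6, multiples of 1/6)."""
    return rtss(day) / 6.0 + medication_component(day, weights)


def vas_value(day: DiaryDay) -> int:
    """The day's 0-10 visual analogue scale rating."""
    return day.vas


_SCORE_FUNCTIONS = {"RTSS": rtss, "CSMS": csms, "VAS": vas_value}


@dataclass(frozen=True)
class ScoreTrajectory:
    """Date-ordered daily values of one score for one patient."""

    patient_id: str
    score_name: str
    dates: tuple[Date, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.score_name not in SCORE_NAMES:
            raise ValueError(f"unknown score {self.score_name!r}")
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values differ in length")
        low, high = SCORE_RANGES[self.score_name]
        for value in self.values:
            if not low <= value <= high:
                raise ValueError(
                    f"{self.score_name} value {value} outside [{low}, {high}]"
                )

    @property
    def unit_step(self) -> float:
        return UNIT_STEPS[self.score_name]

    @property
    def n_observations(self) -> int:
        return len(self.values)


def build_trajectory(series: PatientSeries, score_name: str) -> ScoreTrajectory:
    """Score every recorded day of ``series``; empty series yield T=0."""
    function = _SCORE_FUNCTIONS.get(score_name)
    if function is None:
        raise ValueError(f"unknown score {score_name!r}")
    return ScoreTrajectory(
        patient_id=series.patient_id,
        score_name=score_name,
        dates=series.dates,
        values=tuple(float(function(day)) for day in series.days),
    )


def score_table(cohort: Iterable[PatientSeries]) -> pd.DataFrame:
    """Per-day score table with columns patient_id,date,rtss,csms,vas."""
    rows = [
        {
            "patient_id": day.patient_id,
            "date": day.date.isoformat(),
            "rtss": rtss(day),
            "csms": round(csms(day), 6),
            "vas": vas_value(day),
        }
        for series in cohort
        for day in series.days
    ]
    return pd.DataFrame(rows, columns=["patient_id", "date", "rtss", "csms", "vas"])


def write_score_table(
    cohort: Iterable[PatientSeries], path: str | Path, *, delimiter: str = ","
) -> None:
    score_table(cohort).to_csv(path, sep=delimiter, index=False)
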