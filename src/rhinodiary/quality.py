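"""Per-patient data-quality indices on a score trajectory.

Four candidate indices are computed from the ordered daily values
y_1..y_T of one score:

* intravariation index — percentage of consecutive-day pairs with a
  value change, divided by the individual variation range expressed in
  unit steps, rVAR = (max - min)/S;
* percentage of zero values — 100 x #{y_t = 0} / T;
* coefficient of variation — 100 x SD / mean;
* percentage of changes in trend — share of transitions between
  successive day-to-day difference signs (+/0/-).

"Consecutive" defaults to calendar-adjacent record pairs; trajectories
with gaps therefore contribute fewer pairs than T-1. Undefined values
(too few observations, zero mean) are returned as ``None`` and must be
excluded, never imputed, downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scoring import ScoreTrajectory

#: Two values closer than this are the same grid point (guards float CSMS).
VALUE_ATOL = 1e-9

PAIRING_MODES = ("calendar", "record")
TREND_MODES = ("sign_transition", "nonzero_diff")
INDEX_NAMES = ("ivi", "pct_zero", "cv", "pct_trend_change")


@dataclass(frozen=True)
class IndexConfig:
    """Analysis options for the quality indices.

    pairing
        ``"calendar"`` pairs only records on adjacent calendar days;
        ``"record"`` pairs successive records regardless of gaps.
    rvar_plus_one
        Use (max - min + S)/S instead of (max - min)/S for the variation
        range, i.e. count grid points instead of steps.
    trend_mode
        ``"sign_transition"`` counts changes between successive difference
        signs; ``"nonzero_diff"`` counts the share of nonzero differences.
    cv_ddof
        Delta degrees of freedom of the SD in the coefficient of variation.
    """

    pairing: str = "calendar"
    rvar_plus_one: bool = False
    trend_mode: str = "sign_transition"
    cv_ddof: int = 1

    def __post_init__(self) -> None:
        if self.pairing not in PAIRING_MODES:
            raise ValueError(f"pairing must be one of {PAIRING_MODES}")
        if self.trend_mode not in TREND_MODES:
            raise ValueError(f"trend_mode must be one of {TREND_MODES}")
        if self.cv_ddof not in (0, 1):
            raise ValueError("cv_ddof must be 0 or 1")


@dataclass(frozen=True)
class QualityIndexSet:
    """The four indices for one (patient, score), with their ingredients."""

    patient_id: str
    score_name: str
    n_observations: int
    n_pairs: int
    ivi: float | None
    pct_zero: float | None
    cv: float | None
    pct_trend_change: float | None
    rvar: float | None
    unit_step: float


def _day_indices(traj: ScoreTrajectory) -> list[int]:
    return [d.toordinal() for d in traj.dates]


def consecutive_pairs(
    values: Sequence[float],
    day_index: Sequence[int] | None = None,
    mode: str = "calendar",
) -> list[tuple[float, float]]:
    """Ordered (y_t, y_{t+1}) pairs of consecutive observations.

    In ``calendar`` mode a pair is kept only when the two records fall on
    adjacent calendar days (``day_index`` difference of 1); ``record``
    mode pairs successive records regardless of gaps. With fewer than two
    observations the list is empty.
    """
    if mode not in PAIRING_MODES:
        raise ValueError(f"mode must be one of {PAIRING_MODES}")
    if mode == "calendar":
        if day_index is None:
            raise ValueError("calendar pairing requires day indices")
        return [
            (values[i], values[i + 1])
            for i in range(len(values) - 1)
            if day_index[i + 1] - day_index[i] == 1
        ]
    return [(values[i], values[i + 1]) for i in range(len(values) - 1)]


def _values_differ(a: float, b: float) -> bool:
    return abs(a - b) > VALUE_ATOL


def variation_range(
    values: Sequence[float], unit_step: float, *, plus_one: bool = False
) -> float:
    """Individual variation range rVAR in unit steps: (max - min)/S."""
    if not values:
        raise ValueError("variation range of an empty series is undefined")
    span = max(values) - min(values)
    if plus_one:
        span += unit_step
    return span / unit_step


def pct_variations(pairs: Sequence[tuple[float, float]]) -> float | None:
    """Percentage of pairs whose two values differ; None without pairs."""
    if not pairs:
        return None
    changed = sum(1 for a, b in pairs if _values_differ(a, b))
    return 100.0 * changed / len(pairs)


def intravariation_index(
    values: Sequence[float],
    unit_step: float,
    day_index: Sequence[int] | None = None,
    config: IndexConfig = IndexConfig(),
) -> float | None:
    """pctVar / rVAR; 0 for a constant series; None when T < 2 or no pairs."""
    if len(values) < 2:
        return None
    pairs = consecutive_pairs(values, day_index, config.pairing)
    pct_var = pct_variations(pairs)
    if pct_var is None:
        return None
    rvar = variation_range(values, unit_step, plus_one=config.rvar_plus_one)
    if rvar == 0.0:
        return 0.0
    return pct_var / rvar


def pct_zero_values(values: Sequence[float]) -> float | None:
    """100 x number of zero values / number of observations; None if T=0."""
    if not values:
        return None
    zeros = sum(1 for v in values if abs(v) <= VALUE_ATOL)
    return 100.0 * zeros / len(values)


def coefficient_of_variation(
    values: Sequence[float], *, ddof: int = 1
) -> float | None:
    """100 x SD / mean; None when T < 2 or the mean is zero."""
    if len(values) < 2:
        return None
    mean = sum(values) / len(values)
    if mean <= VALUE_ATOL:
        return None
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - ddof))
    return 100.0 * sd / mean


def _sign(diff: float) -> int:
    if diff > VALUE_ATOL:
        return 1
    if diff < -VALUE_ATOL:
        return -1
    return 0


def pct_changes_in_trend(
    values: Sequence[float],
    day_index: Sequence[int] | None = None,
    config: IndexConfig = IndexConfig(),
) -> float | None:
    """Percentage of trend changes among consecutive-day differences.

    Each consecutive pair gives a sign s_t in {+, 0, -} (worsening,
    stability, improvement); the default mode reports 100 x
    #{s_t != s_{t-1}} over the sign comparisons it can make and needs at
    least two pairs. Two signs are compared only when their pairs are
    themselves adjacent (they share the middle observation), so on
    gap-free data the denominator is n_pairs - 1; comparing signs across
    recording gaps would penalise sparse recorders mechanically.
    ``nonzero_diff`` mode reports the percentage of nonzero differences
    instead.
    """
    if config.trend_mode == "nonzero_diff":
        return pct_variations(consecutive_pairs(values, day_index, config.pairing))
    if config.pairing == "calendar":
        if day_index is None:
            raise ValueError("calendar pairing requires day indices")
        indexed = [
            (i, _sign(values[i + 1] - values[i]))
            for i in range(len(values) - 1)
            if day_index[i + 1] - day_index[i] == 1
        ]
        comparisons = [
            (first_sign, second_sign)
            for (i, first_sign), (j, second_sign) in zip(indexed, indexed[1:])
            if j == i + 1
        ]
    else:
        signs = [_sign(b - a) for a, b in zip(values, values[1:])]
        comparisons = list(zip(signs, signs[1:]))
    if len(comparisons) < 1 or len(values) < 3:
        return None
    changes = sum(1 for previous, current in comparisons if current != previous)
    return 100.0 * changes / len(comparisons)


def compute_all(
    traj: ScoreTrajectory, config: IndexConfig = IndexConfig()
) -> QualityIndexSet:
    """Bundle the four indices for one trajectory; missing stays missing."""
    values = traj.values
    day_index = _day_indices(traj)
    pairs = consecutive_pairs(values, day_index, config.pairing) if len(values) > 1 else []
    rvar = (
        variation_range(values, traj.unit_step, plus_one=config.rvar_plus_one)
        if values
        else None
    )
    return QualityIndexSet(
        patient_id=traj.patient_id,
        score_name=traj.score_name,
        n_observations=traj.n_observations,
        n_pairs=len(pairs),
        ivi=intravariation_index(values, traj.unit_step, day_index, config),
        pct_zero=pct_zero_values(values),
        cv=coefficient_of_variation(values, ddof=config.cv_ddof),
        pct_trend_change=pct_changes_in_trend(values, day_index, config),
        rvar=rvar,
        unit_step=traj.unit_step,
    )


def index_table(index_sets: Iterable[QualityIndexSet]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": s.patient_id,
            "score_name": s.score_name,
            "T": s.n_observations,
            "n_pairs": s.n_pairs,
            "ivi": s.ivi,
            "pct_zero": s.pct_zero,
            "cv": s.cv,
            "pct_trend_change": s.pct_trend_change,
            "rVAR": s.rvar,
        }
        for s in index_sets
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "score_name",
            "T",
            "n_pairs",
            "ivi",
            "pct_zero",
            "cv",
            "pct_trend_change",
            "rVAR",
        ],
    )


def write_index_table(
    index_sets: Iterable[QualityIndexSet], path: str | Path, *, delimiter: str = ","
) -> None:
    index_table(index_sets).to_csv(path, sep=delimiter, index=False)
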