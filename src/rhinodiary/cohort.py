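"""Cohort-level statistics: score interrelations, index summaries, and the
comparison of quality indices between high- and low-adherence groups."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adherence import DEFAULT_THRESHOLD, classify_cohort, cohort_adherence
from .diary import PatientSeries
from .quality import INDEX_NAMES, IndexConfig, QualityIndexSet, compute_all
from .scoring import SCORE_NAMES, build_trajectory

logger = logging.getLogger(__name__)

#: Score pairs whose per-patient means are rank-correlated.
CORRELATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("RTSS", "VAS"),
    ("CSMS", "VAS"),
    ("CSMS", "RTSS"),
)

#: Largest combined sample size for which the Mann-Whitney p is exact.
EXACT_MW_LIMIT = 20


@dataclass(frozen=True)
class CohortIndexSummary:
    """Mean and t-based 95% CI of one index over patients with defined values."""

    score_name: str
    index_name: str
    mean: float
    ci95_low: float | None
    ci95_high: float | None
    n_used: int
    n_excluded: int


@dataclass(frozen=True)
class GroupComparisonRow:
    """Low- vs high-adherence comparison of one index on one score."""

    score_name: str
    index_name: str
    n_low: int
    n_high: int
    median_low: float
    iqr_low: tuple[float, float]
    median_high: float
    iqr_high: tuple[float, float]
    u_statistic: float
    p_value: float


@dataclass(frozen=True)
class ScoreCorrelationRow:
    score_pair: tuple[str, str]
    spearman_rho: float
    p_value: float
    n: int


def population_trajectory(
    cohort: Sequence[PatientSeries], score_name: str
) -> pd.DataFrame:
    """Per-date mean of a score over the patients who recorded that date.

    Returns a frame with columns ``date``, ``mean``, ``n``; dates nobody
    recorded are omitted.
    """
    if not cohort:
        raise ValueError("population trajectory of an empty cohort is undefined")
    rows: list[tuple[object, float]] = []
    for series in cohort:
        traj = build_trajectory(series, score_name)
        rows.extend(zip(traj.dates, traj.values))
    frame = pd.DataFrame(rows, columns=["date", "value"])
    grouped = (
        frame.groupby("date")["value"].agg(mean="mean", n="size").reset_index()
    )
    grouped["n"] = grouped["n"].astype(int)
    return grouped.sort_values("date").reset_index(drop=True)


def patient_mean_scores(cohort: Sequence[PatientSeries]) -> pd.DataFrame:
    """Per-patient mean of each score over recorded days (NaN when T=0)."""
    rows = []
    for series in cohort:
        row: dict[str, object] = {"patient_id": series.patient_id}
        for name in SCORE_NAMES:
            traj = build_trajectory(series, name)
            row[name] = float(np.mean(traj.values)) if traj.values else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", *SCORE_NAMES])


def score_correlations(
    cohort: Sequence[PatientSeries],
) -> list[ScoreCorrelationRow]:
    """Spearman rank correlations of per-patient mean scores."""
    means = patient_mean_scores(cohort).dropna()
    if len(means) < 3:
        raise ValueError("score correlations need at least 3 patients with data")
    rows = []
    for first, second in CORRELATION_PAIRS:
        result = stats.spearmanr(means[first], means[second])
        rows.append(
            ScoreCorrelationRow(
                score_pair=(first, second),
                spearman_rho=float(result.statistic),
                p_value=float(result.pvalue),
                n=len(means),
            )
        )
    return rows


def compute_cohort_indices(
    cohort: Sequence[PatientSeries], config: IndexConfig = IndexConfig()
) -> list[QualityIndexSet]:
    """All quality indices for every (patient, score) combination."""
    return [
        compute_all(build_trajectory(series, name), config)
        for series in cohort
        for name in SCORE_NAMES
    ]


def summarize_indices(
    index_sets: Sequence[QualityIndexSet],
) -> list[CohortIndexSummary]:
    """Mean (95% CI) of each index per score over defined per-patient values.

    The CI is mean +/- t_{0.975,n-1} x SE; it is undefined (None) when
    fewer than two values are available. Patients whose index is missing
    are excluded and counted in ``n_excluded``.
    """
    summaries = []
    for score_name in SCORE_NAMES:
        of_score = [s for s in index_sets if s.score_name == score_name]
        for index_name in INDEX_NAMES:
            values = [
                getattr(s, index_name)
                for s in of_score
                if getattr(s, index_name) is not None
            ]
            n_excluded = len(of_score) - len(values)
            if not values:
                continue
            mean = float(np.mean(values))
            if len(values) >= 2:
                se = float(np.std(values, ddof=1)) / np.sqrt(len(values))
                half = stats.t.ppf(0.975, len(values) - 1) * se
                ci = (mean - half, mean + half)
            else:
                ci = (None, None)
            if n_excluded:
                logger.info(
                    "%s/%s: %d patient(s) without a defined value excluded",
                    score_name,
                    index_name,
                    n_excluded,
                )
            summaries.append(
                CohortIndexSummary(
                    score_name=score_name,
                    index_name=index_name,
                    mean=mean,
                    ci95_low=ci[0],
                    ci95_high=ci[1],
                    n_used=len(values),
                    n_excluded=n_excluded,
                )
            )
    return summaries


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for ``x``) and p-value.

    Exact p for combined n <= 20 without ties; normal approximation with
    tie correction and continuity correction otherwise.
    """
    if not len(x) or not len(y):
        raise ValueError("both samples must be non-empty")
    combined = list(x) + list(y)
    has_ties = len(set(combined)) != len(combined)
    method = "exact" if (len(combined) <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def _median_iqr(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    array = np.asarray(values, dtype=float)
    # linear-interpolation quantiles; the printed medians depend on this
    q25, q50, q75 = np.percentile(array, [25, 50, 75], method="linear")
    return float(q50), (float(q25), float(q75))


def compare_by_adherence(
    cohort: Sequence[PatientSeries],
    threshold: float = DEFAULT_THRESHOLD,
    config: IndexConfig = IndexConfig(),
    index_sets: Sequence[QualityIndexSet] | None = None,
) -> list[GroupComparisonRow]:
    """Low vs high adherence comparison of every (score, index) pair.

    Per row: group medians with 25th-75th percentile IQRs and a two-sided
    Mann-Whitney U test on the per-patient index values. Raw p-values are
    reported (no multiplicity adjustment). Patients with an undefined
    index are excluded from that row.
    """
    records = cohort_adherence(cohort, threshold=threshold)
    classification = classify_cohort(records, threshold)
    if classification.n_high == 0:
        raise ValueError("high-adherence group is empty")
    if classification.n_low == 0:
        raise ValueError("low-adherence group is empty")
    high_ids = set(classification.high_ids)
    if index_sets is None:
        index_sets = compute_cohort_indices(cohort, config)

    rows = []
    for score_name in SCORE_NAMES:
        of_score = [s for s in index_sets if s.score_name == score_name]
        for index_name in INDEX_NAMES:
            low_values = [
                getattr(s, index_name)
                for s in of_score
                if s.patient_id not in high_ids and getattr(s, index_name) is not None
            ]
            high_values = [
                getattr(s, index_name)
                for s in of_score
                if s.patient_id in high_ids and getattr(s, index_name) is not None
            ]
            if not low_values or not high_values:
                which = "low" if not low_values else "high"
                raise ValueError(
                    f"{score_name}/{index_name}: no defined values in the {which}-adherence group"
                )
            u_stat, p_value = mann_whitney(low_values, high_values)
            median_low, iqr_low = _median_iqr(low_values)
            median_high, iqr_high = _median_iqr(high_values)
            rows.append(
                GroupComparisonRow(
                    score_name=score_name,
                    index_name=index_name,
                    n_low=len(low_values),
                    n_high=len(high_values),
                    median_low=median_low,
                    iqr_low=iqr_low,
                    median_high=median_high,
                    iqr_high=iqr_high,
                    u_statistic=u_stat,
                    p_value=p_value,
                )
            )
    return rows


def summary_table(summaries: Sequence[CohortIndexSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "score_name": s.score_name,
                "index_name": s.index_name,
                "mean": s.mean,
                "ci95_low": s.ci95_low,
                "ci95_high": s.ci95_high,
                "n_used": s.n_used,
                "n_excluded": s.n_excluded,
            }
            for s in summaries
        ]
    )


def comparison_table(rows: Sequence[GroupComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "score_name": r.score_name,
                "index_name": r.index_name,
                "n_low": r.n_low,
                "n_high": r.n_high,
                "median_low": r.median_low,
                "q25_low": r.iqr_low[0],
                "q75_low": r.iqr_low[1],
                "median_high": r.median_high,
                "q25_high": r.iqr_high[0],
                "q75_high": r.iqr_high[1],
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
            }
            for r in rows
        ]
    )


def correlation_table(rows: Sequence[ScoreCorrelationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "score_a": r.score_pair[0],
                "score_b": r.score_pair[1],
                "spearman_rho": r.spearman_rho,
                "p_value": r.p_value,
                "n": r.n,
            }
            for r in rows
        ]
    )
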