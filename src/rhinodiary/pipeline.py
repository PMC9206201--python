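"""End-to-end pipeline: read -> score -> adherence -> indices -> cohort stats.

Every stage's row counts and exclusions are echoed into a JSON run log so
no record is silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import metadata
from pathlib import Path

import pandas as pd

from . import adherence as adherence_mod
from . import cohort as cohort_mod
from .config import AnalysisConfig
from .diary import MonitoringWindow, PatientSeries, read_diary_table, read_window_table
from .quality import index_table
from .scoring import SCORE_NAMES, score_table

logger = logging.getLogger(__name__)

OUTPUT_TABLES = (
    "scores.csv",
    "adherence.csv",
    "indices.csv",
    "table2.csv",
    "table3.csv",
    "correlations.csv",
    "population_trajectory.csv",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    cohort: list[PatientSeries]
    scores: pd.DataFrame
    adherence: pd.DataFrame
    indices: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    correlations: pd.DataFrame
    population_trajectory: pd.DataFrame
    run_log: dict


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return decorator


def run_pipeline(
    diary_path: str | Path,
    out_dir: str | Path,
    *,
    config: AnalysisConfig = AnalysisConfig(),
    window: MonitoringWindow | None = None,
    windows_path: str | Path | None = None,
) -> ReportBundle:
    """Run the full analysis and write all output tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    diary_path = Path(diary_path)
    if not diary_path.exists():
        raise PipelineError("read", FileNotFoundError(f"diary table not found: {diary_path}"))

    windows = None
    if windows_path is not None:
        windows_path = Path(windows_path)
        if not windows_path.exists():
            raise PipelineError(
                "read", FileNotFoundError(f"window table not found: {windows_path}")
            )
        windows = _stage("read")(read_window_table)(windows_path)

    cohort = _stage("read")(read_diary_table)(diary_path, window=window, windows=windows)

    scores = _stage("score")(score_table)(cohort)

    records = _stage("adherence")(adherence_mod.cohort_adherence)(
        cohort, threshold=config.adherence_threshold
    )
    adherence_frame = adherence_mod.adherence_table(records)
    classification = adherence_mod.classify_cohort(records, config.adherence_threshold)

    index_sets = _stage("indices")(cohort_mod.compute_cohort_indices)(
        cohort, config.index_config
    )
    indices_frame = index_table(index_sets)

    summaries = _stage("summaries")(cohort_mod.summarize_indices)(index_sets)
    table2 = cohort_mod.summary_table(summaries)

    comparison = _stage("compare")(cohort_mod.compare_by_adherence)(
        cohort, config.adherence_threshold, config.index_config, index_sets
    )
    table3 = cohort_mod.comparison_table(comparison)

    correlations = cohort_mod.correlation_table(
        _stage("correlations")(cohort_mod.score_correlations)(cohort)
    )

    trajectory_frames = []
    for name in SCORE_NAMES:
        frame = _stage("population_trajectory")(cohort_mod.population_trajectory)(
            cohort, name
        )
        frame.insert(0, "score_name", name)
        trajectory_frames.append(frame)
    population = pd.concat(trajectory_frames, ignore_index=True)

    n_records = sum(series.n_days for series in cohort)
    n_undefined = {
        name: sum(1 for s in index_sets if getattr(s, name) is None)
        for name in ("ivi", "pct_zero", "cv", "pct_trend_change")
    }
    try:
        version = metadata.version("rhinodiary")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    run_log = {
        "config": config.to_dict(),
        "software_version": version,
        "inputs": {
            "diary": str(diary_path),
            "windows": str(windows_path) if windows_path else None,
        },
        "counts": {
            "n_patients": len(cohort),
            "n_diary_records": n_records,
            "n_score_rows": int(len(scores)),
            "n_high_adherence": classification.n_high,
            "n_low_adherence": classification.n_low,
            "pooled_adherence_pct": adherence_mod.pooled_adherence(records),
            "mean_adherence_pct": adherence_mod.mean_adherence(records),
            "undefined_index_values": n_undefined,
        },
    }

    scores.to_csv(out / "scores.csv", index=False)
    adherence_frame.to_csv(out / "adherence.csv", index=False)
    indices_frame.to_csv(out / "indices.csv", index=False)
    table2.to_csv(out / "table2.csv", index=False)
    table3.to_csv(out / "table3.csv", index=False)
    correlations.to_csv(out / "correlations.csv", index=False)
    population.to_csv(out / "population_trajectory.csv", index=False)
    with open(out / "run_log.json", "w") as handle:
        json.dump(run_log, handle, indent=2)
    logger.info("pipeline outputs written to %s", out)

    return ReportBundle(
        cohort=cohort,
        scores=scores,
        adherence=adherence_frame,
        indices=indices_frame,
        table2=table2,
        table3=table3,
        correlations=correlations,
        population_trajectory=population,
        run_log=run_log,
    )
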