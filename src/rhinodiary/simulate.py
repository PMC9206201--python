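"""Synthetic diary-cohort generator with ground-truth behaviour labels.

The generator emulates a pollen-season monitoring study: a noisy unimodal
daily exposure curve, per-patient sensitivity, ordinal symptom grades cut
from a latent burden, medication uptake increasing with burden (and
persisting once started), per-patient recording probability with optional
delayed start / early stop, and a "carry-forward" (insufficient-effort)
responding style.

A carry-forward responder replicates the previous recorded questionnaire
in lazy streaks (a sticky copy process), and when they do update they
mostly nudge their previous entries in a persistent direction instead of
re-assessing how they actually feel, occasionally re-anchoring to the
true state. Their day-to-day *rate* of value changes therefore stays
close to that of engaged responders — what differs is the run structure:
long no-change runs and one-directional ramps, which is exactly what the
trend-change quality index is sensitive to, while the intravariation
index, the share of zero values and the coefficient of variation remain
largely unaffected.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diary import (
    DiaryDay,
    MEDICATION_FIELDS,
    MonitoringWindow,
    PatientSeries,
    SYMPTOM_FIELDS,
)

#: Per-item additive threshold offsets: some symptoms appear earlier than
#: others as the latent burden grows.
ITEM_OFFSETS = (0.0, 0.02, 0.06, 0.08, 0.25, 0.27)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the simulated cohort."""

    n_patients: int = 101
    window_start: datetime.date = datetime.date(2016, 5, 4)
    n_days: int = 56
    seed: int = 0

    # exposure curve
    pollen_peak_day: float = 25.0
    pollen_width: float = 11.0
    pollen_max: float = 199.0
    pollen_noise_sd: float = 0.04  # lognormal sigma of day-to-day noise

    # latent burden and symptom thresholds
    sensitivity_mu: float = 0.0    # log-scale mean of patient sensitivity
    sensitivity_sigma: float = 0.45
    burden_scale: float = 1.35
    burden_ar_phi: float = -0.5    # AR(1) persistence of daily burden noise
    burden_ar_sd: float = 0.05   # innovation SD of burden noise
    grade_thresholds: tuple[float, float, float] = (0.35, 1.05, 1.75)

    # VAS construction
    vas_gain: float = 3.1
    vas_noise_sd: float = 0.15
    #: careless responders place the VAS slider sloppily when they update
    careless_vas_noise_sd: float = 0.8
    #: per-item probability of a +/-1 mis-grading when a careless
    #: responder nudges their previous entries
    careless_grade_jitter_prob: float = 0.2

    # medication-uptake logistics (intercept, burden slope, persistence)
    antihistamine_logit: tuple[float, float, float] = (-4.8, 1.8, 6.5)
    nasal_steroid_logit: tuple[float, float, float] = (-6.2, 1.7, 6.5)
    systemic_steroid_logit: tuple[float, float, float] = (-9.2, 2.0, 6.5)

    # adherence-to-recording mixture
    frac_high_adherence: float = 0.65
    rec_prob_high: tuple[float, float] = (0.86, 1.0)
    rec_prob_low: tuple[float, float] = (0.55, 0.78)
    delayed_start_prob: float = 0.05
    early_end_prob: float = 0.07
    #: first-order persistence of the daily recording indicator: diary
    #: keeping comes in bursts while the long-run recording rate stays at
    #: the patient's recording probability
    recording_stickiness: float = 0.6
    deviation_days: tuple[int, int] = (3, 7)

    # responding-style mixture
    carry_forward_fraction: float = 0.35   # used when behaviour is unlinked
    q_carry_forward: float = 0.7           # mean repetition probability, careless
    #: half-width of the uniform spread of individual repetition
    #: probabilities around ``q_carry_forward``
    q_carry_forward_spread: float = 0.05
    q_engaged: float = 0.12                # repetition probability, engaged
    #: first-order persistence of the copy decision for carry-forward
    #: responders: copying comes in lazy streaks, not as independent coin
    #: flips, while the long-run copy rate stays at the repetition
    #: probability. Streaks cluster the no-change days into runs, which
    #: depresses trend transitions without changing the overall rate of
    #: day-to-day value changes.
    carry_forward_stickiness: float = 0.65
    #: longest possible run of copied questionnaires; even the laziest
    #: responder eventually updates their entries
    carry_forward_max_run: int = 10
    #: when a carry-forward responder does update, they usually just nudge
    #: their previous entries in a persistent direction (anchoring) rather
    #: than re-assessing; log-scale step size of that nudge
    careless_ramp_sd: float = 0.75
    #: probability that an update is a genuine re-assessment of the true
    #: state instead of a nudge of the previous entry
    careless_reanchor_prob: float = 0.1
    #: probability that a new nudge direction points towards worsening;
    #: above 0.5 compensates for copy streaks missing the season peak
    careless_ramp_up_prob: float = 0.55
    #: carry-forward responders understate their worst days: ramps are
    #: capped at this fraction of the patient's own peak-season burden
    careless_ceiling_factor: float = 1.1
    link_behavior_to_adherence: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.pollen_max < 0:
            raise ValueError("pollen_max must be non-negative")
        for name in (
            "frac_high_adherence",
            "delayed_start_prob",
            "early_end_prob",
            "carry_forward_fraction",
            "q_carry_forward",
            "q_engaged",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability, got {value}")

    @property
    def window(self) -> MonitoringWindow:
        return MonitoringWindow(
            start=self.window_start,
            end=self.window_start + datetime.timedelta(days=self.n_days - 1),
        )

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["window_start"] = self.window_start.isoformat()
        return raw


@dataclass(frozen=True)
class GroundTruthEntry:
    """Simulation bookkeeping for one patient."""

    patient_id: str
    behavior: str                  # "accurate" | "carry_forward"
    repetition_prob: float
    recording_prob: float
    sensitivity: float
    high_adherence_intent: bool
    delayed_start: int
    early_end: int


def generate_pollen_series(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Daily pollen concentrations: a noisy unimodal curve, max <= pollen_max."""
    days = np.arange(config.n_days, dtype=float)
    curve = config.pollen_max * np.exp(
        -0.5 * ((days - config.pollen_peak_day) / config.pollen_width) ** 2
    )
    noise = rng.lognormal(mean=0.0, sigma=config.pollen_noise_sd, size=config.n_days)
    return np.clip(curve * noise, 0.0, config.pollen_max)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _grade(burden: float, thresholds: Sequence[float], offset: float) -> int:
    return int(sum(burden > t + offset for t in thresholds))


#: latent values are clipped to this band when carelessly nudged, keeping
#: ramps within the range where grades and VAS still respond
_LATENT_BAND = (0.30, 2.6)


def _render_report(
    latent: float,
    meds: tuple[int, int, int],
    config: SyntheticConfig,
    rng: np.random.Generator,
    careless: bool = False,
) -> tuple[list[int], int, tuple[int, int, int]]:
    grades = [
        _grade(latent, config.grade_thresholds, offset) for offset in ITEM_OFFSETS
    ]
    noise_sd = config.careless_vas_noise_sd if careless else config.vas_noise_sd
    vas = int(np.clip(round(config.vas_gain * latent + rng.normal(0.0, noise_sd)), 0, 10))
    return grades, vas, meds


def generate_patient(
    config: SyntheticConfig,
    pollen: np.ndarray,
    rng: np.random.Generator,
    patient_id: str = "P001",
) -> tuple[PatientSeries, GroundTruthEntry]:
    """Simulate one patient's diary over the monitoring window."""
    if len(pollen) < config.n_days:
        raise ValueError("pollen series does not cover the monitoring window")

    intent_high = rng.random() < config.frac_high_adherence
    if config.link_behavior_to_adherence:
        careless = not intent_high
    else:
        careless = rng.random() < config.carry_forward_fraction
    if careless:
        lo = max(0.0, config.q_carry_forward - config.q_carry_forward_spread)
        hi = min(1.0, config.q_carry_forward + config.q_carry_forward_spread)
        q = float(rng.uniform(lo, hi))
    else:
        q = config.q_engaged
    p_rec = rng.uniform(*(config.rec_prob_high if intent_high else config.rec_prob_low))

    delay = (
        int(rng.integers(config.deviation_days[0], config.deviation_days[1] + 1))
        if rng.random() < config.delayed_start_prob
        else 0
    )
    early = (
        int(rng.integers(config.deviation_days[0], config.deviation_days[1] + 1))
        if rng.random() < config.early_end_prob
        else 0
    )

    sensitivity = float(rng.lognormal(config.sensitivity_mu, config.sensitivity_sigma))
    exposure = sensitivity * config.burden_scale * pollen[: config.n_days] / max(config.pollen_max, 1e-12)

    # AR(1) noise makes the burden drift smoothly between days
    noise = np.empty(config.n_days)
    noise[0] = rng.normal(0.0, config.burden_ar_sd / math.sqrt(1 - config.burden_ar_phi**2))
    for d in range(1, config.n_days):
        noise[d] = config.burden_ar_phi * noise[d - 1] + rng.normal(0.0, config.burden_ar_sd)
    burden = np.maximum(exposure + noise, 0.0)

    # medication with persistence
    meds = np.zeros((config.n_days, 3), dtype=int)
    params = (
        config.antihistamine_logit,
        config.nasal_steroid_logit,
        config.systemic_steroid_logit,
    )
    for d in range(config.n_days):
        for k, (a0, a1, a2) in enumerate(params):
            prev = meds[d - 1, k] if d else 0
            if rng.random() < _sigmoid(a0 + a1 * burden[d] + a2 * prev):
                meds[d, k] = 1

    r = config.recording_stickiness
    recorded = np.zeros(config.n_days, dtype=bool)
    prev = rng.random() < p_rec
    for d in range(config.n_days):
        p_today = p_rec + r * (1 - p_rec) if prev else p_rec * (1 - r)
        recorded[d] = prev = rng.random() < p_today
    if delay:
        recorded[:delay] = False
    if early:
        recorded[config.n_days - early:] = False

    window = config.window
    days: list[DiaryDay] = []
    last_report: tuple[list[int], int, tuple[int, int, int]] | None = None
    # sticky Markov copy process: P(copy | copied)   = q + s(1-q)
    #                             P(copy | refreshed) = q(1-s)
    # keeps the stationary copy rate at q for any stickiness s
    stickiness = config.carry_forward_stickiness if careless else 0.0
    was_copy = bool(rng.random() < q)  # stationary initial state
    copy_run = 0
    latent: float | None = None   # careless responder's anchored self-estimate
    direction = 1.0
    # ramps stay below the patient's own plausible peak severity
    latent_ceiling = max(
        1.5 * _LATENT_BAND[0],
        min(
            _LATENT_BAND[1],
            config.careless_ceiling_factor * sensitivity * config.burden_scale,
        ),
    )
    for d in np.flatnonzero(recorded):
        p_copy = q + stickiness * (1 - q) if was_copy else q * (1 - stickiness)
        if copy_run >= config.carry_forward_max_run:
            p_copy = 0.0
        was_copy = last_report is not None and rng.random() < p_copy
        copy_run = copy_run + 1 if was_copy else 0
        if was_copy:
            report = last_report
        elif careless:
            nudged: float | None = None
            nudge_jitter = False
            truly_fine = burden[d] < _LATENT_BAND[0]  # nothing to misjudge
            if (
                latent is not None
                and not truly_fine
                and rng.random() >= config.careless_reanchor_prob
            ):
                # anchored update: nudge the previous entries one way
                step = math.exp(direction * abs(rng.normal(0.0, config.careless_ramp_sd)))
                nudged = latent * step
            if nudged is None or not _LATENT_BAND[0] <= nudged <= latent_ceiling:
                # genuine re-assessment: back to the true state (also when
                # a ramp runs off the plausible range)
                latent = float(burden[d])
                direction = 1.0 if rng.random() < config.careless_ramp_up_prob else -1.0
            else:
                latent = float(nudged)
                nudge_jitter = True
            # medication boxes follow the app's personalised plan, so even
            # lazy responders tick them from their actual intake
            report = _render_report(latent, tuple(meds[d]), config, rng, careless=True)
            if nudge_jitter and config.careless_grade_jitter_prob > 0:
                grades0, vas0, meds0 = report
                grades0 = [
                    int(np.clip(g + rng.choice((-1, 1)), 0, 3))
                    if rng.random() < config.careless_grade_jitter_prob
                    else g
                    for g in grades0
                ]
                report = (grades0, vas0, meds0)
        else:
            report = _render_report(float(burden[d]), tuple(meds[d]), config, rng)
        last_report = report
        grades, vas, med_flags = report
        days.append(
            DiaryDay(
                patient_id=patient_id,
                date=window.start + datetime.timedelta(days=int(d)),
                **dict(zip(SYMPTOM_FIELDS, (int(g) for g in grades))),
                **dict(zip(MEDICATION_FIELDS, (int(m) for m in med_flags))),
                vas=vas,
            )
        )

    series = PatientSeries(patient_id=patient_id, window=window, days=tuple(days))
    truth = GroundTruthEntry(
        patient_id=patient_id,
        behavior="carry_forward" if careless else "accurate",
        repetition_prob=q,
        recording_prob=float(p_rec),
        sensitivity=sensitivity,
        high_adherence_intent=intent_high,
        delayed_start=delay,
        early_end=early,
    )
    return series, truth


def generate_cohort(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[list[PatientSeries], list[GroundTruthEntry], dict]:
    """Simulate a full cohort; reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    pollen = generate_pollen_series(config, rng)
    width = max(3, len(str(config.n_patients)))
    cohort: list[PatientSeries] = []
    truths: list[GroundTruthEntry] = []
    for i in range(config.n_patients):
        series, truth = generate_patient(config, pollen, rng, f"P{i + 1:0{width}d}")
        cohort.append(series)
        truths.append(truth)
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "pollen_max_observed": float(pollen.max()) if len(pollen) else 0.0,
    }
    return cohort, truths, manifest


def ground_truth_table(truths: Sequence[GroundTruthEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": t.patient_id,
                "behavior": t.behavior,
                "repetition_prob": t.repetition_prob,
                "recording_prob": t.recording_prob,
                "sensitivity": t.sensitivity,
                "high_adherence_intent": t.high_adherence_intent,
                "delayed_start": t.delayed_start,
                "early_end": t.early_end,
            }
            for t in truths
        ]
    )
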