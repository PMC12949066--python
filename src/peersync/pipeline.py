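"""End-to-end orchestration: beat series -> synchrony table -> models.

Used by the CLI and by the recovery tests; every stage is also callable on
its own so a run can be resumed from any intermediate table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hrv, measures, models, simulate, wavelet
from .preprocess import (RRSeries, UniformHeartRate, preprocess_series,
                         resample_heart_rate)

logger = logging.getLogger(__name__)

SYNC_PHASES = ("story", "discussion")

#: fixed-effect layout of the dyadic synchrony models (reference levels:
#: story phase, mixed-gender dyads, non-friend dyads)
SYNC_CATEGORICAL = {
    "phase": "story",
    "gender_combo": "mixed",
    "friendship_status": "none",
}
SYNC_CONTINUOUS = (
    "closeness_sum", "liking_sum", "affect_coherence",
    "arousal_sum", "valence_sum", "empathic_accuracy_sum",
)


@dataclass
class StudyResult:
    preprocess_reports: pd.DataFrame
    hrv_table: pd.DataFrame
    synchrony: pd.DataFrame
    dyad_table: pd.DataFrame
    model_data: pd.DataFrame
    fits: dict[str, models.MixedModelFit] = field(default_factory=dict)
    truth: simulate.SyntheticTruth | None = None
    excluded_subjects: list[str] = field(default_factory=list)


def preprocess_all(
    series_by_subject: dict[str, RRSeries],
    threshold: float = 0.30,
    max_gap_s: float = 2.0,
) -> tuple[dict[str, RRSeries], pd.DataFrame, list[str]]:
    """Run outlier correction + gap filling for every subject; subjects with
    >= 10% of beats changed are excluded from further stages."""
    cleaned: dict[str, RRSeries] = {}
    rows = []
    excluded = []
    for sid, series in series_by_subject.items():
        out, report = preprocess_series(series, threshold=threshold,
                                        max_gap_s=max_gap_s)
        rows.append(report.as_row())
        if report.excluded:
            excluded.append(sid)
            logger.info("subject %s excluded (%.1f%% changed)", sid,
                        100 * report.fraction_modified)
        else:
            cleaned[sid] = out
    return cleaned, pd.DataFrame(rows), excluded


def heart_rate_trajectories(
    cleaned: dict[str, RRSeries],
    phases: tuple[str, ...] = SYNC_PHASES,
    rate_hz: float = 1.0,
) -> dict[tuple[str, str], UniformHeartRate]:
    out = {}
    for sid, series in cleaned.items():
        for phase in phases:
            if phase not in series.phase_marks:
                continue
            try:
                out[(sid, phase)] = resample_heart_rate(series, phase,
                                                        rate_hz=rate_hz)
            except ValueError as exc:
                logger.warning("skipping %s/%s: %s", sid, phase, exc)
    return out


def hrv_table(
    cleaned: dict[str, RRSeries],
    phases: tuple[str, ...] = ("baseline", "story", "discussion"),
) -> pd.DataFrame:
    frames = []
    for sid, series in cleaned.items():
        for phase in phases:
            if phase not in series.phase_marks:
                continue
            windows = hrv.hf_hrv_windows(series, phase)
            frames.append(hrv.windows_to_frame(windows))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def synchrony_for_dyads(
    hr_map: dict[tuple[str, str], UniformHeartRate],
    dyads: list[tuple[str, str, str]],
    spec: wavelet.WaveletSpec = wavelet.WaveletSpec(),
    interval_s: float = 20.0,
    coi_mask: bool = True,
) -> list[wavelet.SynchronySeries]:
    """Cross-wavelet band maxima for every dyad and phase.

    The per-subject transform is computed once per phase and shared across
    all dyads the subject belongs to.
    """
    cwt_cache: dict[tuple[str, str], wavelet.CWTResult] = {}

    def _cwt(key):
        if key not in cwt_cache:
            cwt_cache[key] = wavelet.cwt(hr_map[key], spec)
        return cwt_cache[key]

    out = []
    for a, b, group_id in dyads:
        for phase in SYNC_PHASES:
            ka, kb = (a, phase), (b, phase)
            if ka not in hr_map or kb not in hr_map:
                continue
            spec_ab = wavelet.cross_power(_cwt(ka), _cwt(kb))
            hf = wavelet.band_interval_max(
                spec_ab, wavelet.HF_SYNC_BAND, interval_s, coi_mask)
            lf = wavelet.band_interval_max(
                spec_ab, wavelet.LF_SYNC_BAND, interval_s, coi_mask)
            out.append(wavelet.SynchronySeries(
                dyad_id=f"{a}__{b}", group_id=group_id, phase_label=phase,
                hf_raw=hf, lf_raw=lf))
    return out


def default_synchrony_spec(outcome: str) -> models.ModelSpec:
    return models.ModelSpec(
        outcome=outcome,
        group_col="group_id",
        unit_col="dyad_id",
        continuous=SYNC_CONTINUOUS,
        categorical=dict(SYNC_CATEGORICAL),
        time_col="interval_index",
    )


def dyad_model_data(sync_frame: pd.DataFrame,
                    dyad_table: pd.DataFrame) -> pd.DataFrame:
    return sync_frame.merge(
        dyad_table.drop(columns=["group_id"]), on="dyad_id", how="inner")


def run_synthetic_study(
    config: simulate.CohortConfig,
    fit_models: bool = True,
    with_hrv: bool = False,
    random_slope_time: bool = False,
    ar1: bool = False,
) -> StudyResult:
    """Generate a cohort and push it through the full analysis chain."""
    roster = simulate.generate_roster(config)
    quest = simulate.generate_questionnaires(roster, config)
    series, truth = simulate.generate_coupled_rr(roster, quest, config)

    cleaned, reports, excluded = preprocess_all(series)
    hr_map = heart_rate_trajectories(cleaned)
    dyads = [(a, b, g) for a, b, g in roster.dyads()
             if a in cleaned and b in cleaned]

    sync_series = synchrony_for_dyads(hr_map, dyads)
    sync_series = wavelet.truncate_and_zscore(sync_series)
    sync_frame = wavelet.synchrony_frame(sync_series)

    dyads_df = measures.dyad_table(
        roster.subjects, roster.nominations, quest.ios, quest.liking,
        quest.self_affect, quest.estimates)
    data = dyad_model_data(sync_frame, dyads_df)

    fits: dict[str, models.MixedModelFit] = {}
    if fit_models and not data.empty:
        for outcome in ("hf_z", "lf_z"):
            spec = default_synchrony_spec(outcome)
            spec = models.ModelSpec(
                **{**spec.__dict__, "random_slope_time": random_slope_time,
                   "ar1": ar1})
            fits[outcome] = models.fit_model(spec, data)

    return StudyResult(
        preprocess_reports=reports,
        hrv_table=hrv_table(cleaned) if with_hrv else pd.DataFrame(),
        synchrony=sync_frame,
        dyad_table=dyads_df,
        model_data=data,
        fits=fits,
        truth=truth,
        excluded_subjects=excluded,
    )


def null_terms() -> dict[str, float]:
    """Terms planted with no effect on synchrony in the default generator."""
    return {
        "closeness_sum": 0.0,
        "liking_sum": 0.0,
        "empathic_accuracy_sum": 0.0,
        "affect_coherence": 0.0,
    }
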