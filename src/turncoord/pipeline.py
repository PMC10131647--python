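"""End-to-end trial and cohort analysis.

Ties the modules together: markers -> occlusion policy -> segment yaw and
angular velocity -> per-segment turn detection -> turn matching -> gait
events -> per-turn measures -> per-trial averages -> long-format cohort
table ready for the DTC and statistics layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import gait_events as ge
from . import kinematics as kin
from . import metrics as met
from .io_mocap import SEGMENT_MARKERS, TrialRecord, interpolate_gaps
from .turns import TurnConfig, TurnEvent, detect_turns

__all__ = ["PipelineConfig", "TrialAnalysis", "analyze_trial", "cohort_table"]


@dataclass
class PipelineConfig:
    """Knobs of the full per-trial analysis."""

    turn: TurnConfig = field(default_factory=TurnConfig)
    gait: ge.GaitEventConfig = field(default_factory=ge.GaitEventConfig)
    filter_cutoff_hz: float = 6.0
    max_gap_samples: int = 10
    max_onset_gap_s: float = 1.5
    guard_band_s: float = 0.25


@dataclass
class TrialAnalysis:
    """Everything the per-trial pipeline computed, for audit and plotting."""

    metrics: met.TrialMetrics
    turn_measures: list[met.TurnMeasures]
    events_by_segment: dict[str, list[TurnEvent]]
    matched: list[dict[str, TurnEvent]]
    gait_events: list[ge.GaitEvent]
    yaws: dict[str, kin.SegmentYawSignal]
    gait_speed_mps: float


def analyze_trial(trial: TrialRecord, cfg: PipelineConfig | None = None) -> TrialAnalysis:
    """Run the full turning analysis on one trial.

    Raises
    ------
    ValueError
        if no turn could be matched across all three segments (invalid
        trial, e.g. straight walking only).
    """
    cfg = cfg or PipelineConfig()
    trial.require()

    yaws, omegas, events = {}, {}, {}
    for segment in SEGMENT_MARKERS:
        markers = [
            interpolate_gaps(m, cfg.max_gap_samples)
            for m in trial.segment_markers(segment)
        ]
        yaw = kin.segment_yaw(markers, segment)
        omega = kin.angular_velocity(yaw, cfg.filter_cutoff_hz)
        yaws[segment], omegas[segment] = yaw, omega
        events[segment] = detect_turns(yaw, omega, cfg.turn)

    matched = met.match_turns(events, cfg.max_onset_gap_s)

    contacts = []
    for foot, suffix in (("left", "L"), ("right", "R")):
        heel = interpolate_gaps(trial.markers[f"heel_{suffix}"], cfg.max_gap_samples)
        toe = interpolate_gaps(trial.markers[f"toe_{suffix}"], cfg.max_gap_samples)
        contacts.extend(ge.detect_contacts(heel, toe, cfg.gait, foot))
    contacts.sort(key=lambda e: e.time_s)

    windows = [(e.start_s, e.end_s) for evs in events.values() for e in evs]
    pelvis_markers = [
        interpolate_gaps(m, cfg.max_gap_samples)
        for m in trial.segment_markers("pelvis")
    ]
    speed = kin.gait_speed(pelvis_markers, windows, cfg.guard_band_s)

    measures = [met.compute_turn_measures(t, yaws, contacts) for t in matched]
    metrics = met.aggregate_trial(
        measures, speed, trial.subject_id, trial.group, trial.condition
    )
    return TrialAnalysis(
        metrics=metrics,
        turn_measures=measures,
        events_by_segment=events,
        matched=matched,
        gait_events=contacts,
        yaws=yaws,
        gait_speed_mps=speed,
    )


def cohort_table(trials, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Analyze a sequence of trials into one long-format cohort table."""
    frames = [met.metrics_to_rows(analyze_trial(t, cfg).metrics) for t in trials]
    return pd.concat(frames, ignore_index=True)
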