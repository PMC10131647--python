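"""Per-turn and per-trial turning measures.

Three families of measures are computed for every matched turn:

* general — turn duration and number of steps while turning, both taken
  over the pelvis segment's turn window (the pelvis being the most
  whole-body-representative of the three axial segments);
* segmental — peak angular velocity of head, sternum and pelvis, each
  within its own turn window, and the detected turn magnitude per segment;
* intersegmental — for the three segment pairs (sternum-head, pelvis-head,
  pelvis-sternum): the relative turning onset latency, referenced to the
  more cranial segment so that a *negative* value means the cranial segment
  started turning first (the healthy top-down pattern), and the maximum
  intersegmental angle, the largest absolute yaw difference within the
  pair's turn windows after re-referencing both signals to their pre-turn
  plateau so static posture offsets cancel. Small maximum angles together
  with near-zero latencies are the signature of en bloc turning.

Per-trial values are arithmetic means over all turns where the three
segments could be matched into a triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gait_events import GaitEvent, steps_in_window
from .kinematics import SegmentYawSignal
from .turns import TurnEvent

__all__ = [
    "PAIRS",
    "TurnMeasures",
    "TrialMetrics",
    "match_turns",
    "onset_latency",
    "max_intersegmental_angle",
    "compute_turn_measures",
    "aggregate_trial",
    "metrics_to_rows",
]

log = logging.getLogger(__name__)

#: (cranial, caudal) segment pairs: the cranial segment is the reference,
#: matching the reporting convention "sternum relative to the head" etc.
PAIRS = (("head", "sternum"), ("head", "pelvis"), ("sternum", "pelvis"))
_SEGMENTS = ("head", "sternum", "pelvis")


def _pair_key(cranial: str, caudal: str) -> str:
    # measure keys read "<caudal> relative to <cranial>": sternum_head etc.
    return f"{caudal}_{cranial}"


@dataclass
class TurnMeasures:
    """All measures of one matched turn (head+sternum+pelvis triple)."""

    duration_s: float
    n_steps: int
    peak_omega_degps: dict[str, float]
    onset_latency_s: dict[str, float]
    max_intersegmental_angle_deg: dict[str, float]
    magnitude_deg: dict[str, float]

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.n_steps < 0:
            raise ValueError("step count cannot be negative")
        if any(v < 0 for v in self.max_intersegmental_angle_deg.values()):
            raise ValueError("maximum intersegmental angle cannot be negative")


@dataclass
class TrialMetrics:
    """Per-trial (condition-level) averages over matched turns."""

    subject_id: str
    group: str
    condition: str
    gait_speed_mps: float
    n_turns_used: int
    means: dict[str, float] = field(default_factory=dict)


def match_turns(
    events_by_segment: dict[str, list[TurnEvent]],
    max_onset_gap_s: float = 1.5,
) -> list[dict[str, TurnEvent]]:
    """Greedily match per-segment turn events into head/sternum/pelvis triples.

    Head events anchor the matching; for each, the nearest-in-onset event of
    every other segment within ``max_onset_gap_s`` and with the same turn
    direction is claimed. Head events that cannot claim all segments — and
    segment events left unclaimed — are dropped with a log entry, so a turn
    one segment missed (e.g. through occlusion) is excluded everywhere.
    """
    pools = {s: list(events_by_segment.get(s, [])) for s in _SEGMENTS}
    triples = []
    for head_ev in sorted(pools["head"], key=lambda e: e.start_s):
        triple = {"head": head_ev}
        for seg in ("sternum", "pelvis"):
            cands = [
                e
                for e in pools[seg]
                if abs(e.start_s - head_ev.start_s) <= max_onset_gap_s
                and e.direction == head_ev.direction
            ]
            if cands:
                best = min(cands, key=lambda e: abs(e.start_s - head_ev.start_s))
                triple[seg] = best
        if len(triple) == 3:
            for seg in ("sternum", "pelvis"):
                pools[seg].remove(triple[seg])
            triples.append(triple)
        else:
            missing = [s for s in _SEGMENTS if s not in triple]
            log.info(
                "turn at %.2f s dropped: no matching event for %s",
                head_ev.start_s,
                ", ".join(missing),
            )
    return triples


def onset_latency(cranial: TurnEvent, caudal: TurnEvent) -> float:
    """Relative turning onset latency, cranial segment as reference.

    ``start(cranial) - start(caudal)``: negative exactly when the more
    cranial segment started turning first.
    """
    return cranial.start_s - caudal.start_s


def max_intersegmental_angle(
    yaw_cranial: SegmentYawSignal,
    yaw_caudal: SegmentYawSignal,
    window: tuple[float, float],
    *,
    ref_window_s: float = 0.5,
    ref_gap_s: float = 0.1,
) -> float:
    """Maximum absolute yaw difference of a segment pair within a turn window.

    Both signals are re-referenced to their mean over a pre-turn plateau
    window (``ref_window_s`` long, ending ``ref_gap_s`` before the window
    start) so that static posture offsets between segments cancel; the
    result is the maximum of ``|yaw_cr(t) - yaw_ca(t)|`` over the window.
    """
    start_s, end_s = window
    if end_s <= start_s:
        raise ValueError("empty intersegmental-angle window")
    fs = yaw_cranial.fs
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs)) + 1
    r1 = int(round((start_s - ref_gap_s) * fs))
    r0 = int(round((start_s - ref_gap_s - ref_window_s) * fs))
    r0 = max(r0, 0)
    if r1 <= r0:
        raise ValueError("no pre-turn reference interval before the window")
    diff = (yaw_cranial.yaw_deg[i0:i1] - np.nanmean(yaw_cranial.yaw_deg[r0:r1])) - (
        yaw_caudal.yaw_deg[i0:i1] - np.nanmean(yaw_caudal.yaw_deg[r0:r1])
    )
    if len(diff) == 0 or np.all(np.isnan(diff)):
        raise ValueError("intersegmental-angle window contains no valid samples")
    return float(np.nanmax(np.abs(diff)))


def compute_turn_measures(
    triple: dict[str, TurnEvent],
    yaws: dict[str, SegmentYawSignal],
    gait_events: list[GaitEvent],
) -> TurnMeasures:
    """All measures for one matched turn triple."""
    pelvis = triple["pelvis"]
    latencies, max_angles = {}, {}
    for cranial, caudal in PAIRS:
        key = _pair_key(cranial, caudal)
        latencies[key] = onset_latency(triple[cranial], triple[caudal])
        w = (
            min(triple[cranial].start_s, triple[caudal].start_s),
            max(triple[cranial].end_s, triple[caudal].end_s),
        )
        max_angles[key] = max_intersegmental_angle(yaws[cranial], yaws[caudal], w)
    return TurnMeasures(
        duration_s=pelvis.duration_s,
        n_steps=steps_in_window(gait_events, (pelvis.start_s, pelvis.end_s)),
        peak_omega_degps={s: triple[s].peak_omega_degps for s in _SEGMENTS},
        onset_latency_s=latencies,
        max_intersegmental_angle_deg=max_angles,
        magnitude_deg={s: triple[s].magnitude_deg for s in _SEGMENTS},
    )


#: long-format measure names produced per trial
MEASURE_NAMES = (
    "duration_s",
    "n_steps",
    *(f"peak_omega_{s}" for s in _SEGMENTS),
    *(f"latency_{_pair_key(c, d)}" for c, d in PAIRS),
    *(f"max_angle_{_pair_key(c, d)}" for c, d in PAIRS),
    *(f"magnitude_{s}" for s in _SEGMENTS),
)


def _measures_as_flat(m: TurnMeasures) -> dict[str, float]:
    flat = {"duration_s": m.duration_s, "n_steps": float(m.n_steps)}
    for s in _SEGMENTS:
        flat[f"peak_omega_{s}"] = m.peak_omega_degps[s]
        flat[f"magnitude_{s}"] = m.magnitude_deg[s]
    for c, d in PAIRS:
        key = _pair_key(c, d)
        flat[f"latency_{key}"] = m.onset_latency_s[key]
        flat[f"max_angle_{key}"] = m.max_intersegmental_angle_deg[key]
    return flat


def aggregate_trial(
    turn_measures: list[TurnMeasures],
    gait_speed_mps: float,
    subject_id: str,
    group: str,
    condition: str,
) -> TrialMetrics:
    """Average all measures over a trial's matched turns.

    Latencies are averaged *signed* (not absolute): the sign carries the
    top-down vs bottom-up information.

    Raises
    ------
    ValueError
        if no matched turn is available (invalid trial).
    """
    if not turn_measures:
        raise ValueError(f"{subject_id}/{condition}: no matched turns; invalid trial")
    flat = [_measures_as_flat(m) for m in turn_measures]
    means = {k: float(np.mean([f[k] for f in flat])) for k in MEASURE_NAMES}
    return TrialMetrics(
        subject_id=subject_id,
        group=group,
        condition=condition,
        gait_speed_mps=gait_speed_mps,
        n_turns_used=len(turn_measures),
        means=means,
    )


def metrics_to_rows(metrics: TrialMetrics) -> pd.DataFrame:
    """Long-format rows (one per measure) for the cohort table."""
    return pd.DataFrame(
        {
            "subject_id": metrics.subject_id,
            "group": metrics.group,
            "condition": metrics.condition,
            "gait_speed": metrics.gait_speed_mps,
            "measure": list(metrics.means),
            "value": list(metrics.means.values()),
        }
    )
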