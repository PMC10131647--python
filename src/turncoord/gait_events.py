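"""Gait events from heel/toe marker vertical velocities.

Initial contact (foot touchdown) is detected at prominent local minima of
the toe marker's vertical velocity; final contact (lift-off) at prominent
local maxima of the heel marker's vertical velocity. Peaks below a
prominence threshold or closer together than a minimum step interval are
suppressed, and a repair pass enforces per-foot alternation of the two
event kinds by dropping the less prominent of two same-kind neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io_mocap import MarkerTrajectory
from .kinematics import lowpass

__all__ = ["GaitEvent", "GaitEventConfig", "detect_contacts", "steps_in_window"]

log = logging.getLogger(__name__)

INITIAL_CONTACT = "initial_contact"
FINAL_CONTACT = "final_contact"


@dataclass
class GaitEvent:
    foot: str  # "left" | "right"
    kind: str  # INITIAL_CONTACT | FINAL_CONTACT
    time_s: float
    prominence: float = float("nan")


@dataclass
class GaitEventConfig:
    """Peak-picking parameters for contact detection.

    ``filter_cutoff_hz`` smooths the vertical position before
    differentiation; the swing-phase velocity bump is a ~2 Hz feature, so a
    6 Hz cutoff keeps its extremum sharp while suppressing the marker
    jitter that differentiation would otherwise amplify.
    ``prominence_mps`` and ``min_step_interval_s`` suppress jitter peaks and
    physiologically impossible double-counts.
    """

    filter_cutoff_hz: float = 6.0
    prominence_mps: float = 0.2
    min_step_interval_s: float = 0.3


def _vertical_velocity(traj: MarkerTrajectory, cutoff_hz: float) -> np.ndarray:
    # 2nd order: a gentle roll-off biases the swing bump's extremum less
    # than a sharp filter whose longer impulse response reaches the
    # stance-phase truncation of the bump
    z = lowpass(traj.positions[:, 2], traj.fs, cutoff_hz, order=2)
    return np.gradient(z) * traj.fs


def detect_contacts(
    heel: MarkerTrajectory,
    toe: MarkerTrajectory,
    cfg: GaitEventConfig | None = None,
    foot: str = "left",
) -> list[GaitEvent]:
    """Detect initial and final contacts for one foot.

    Returns events sorted by time, alternating in kind after repair. Very
    short trajectories (under one gait cycle worth of samples) yield an
    empty list.
    """
    cfg = cfg or GaitEventConfig()
    fs = heel.fs
    if heel.n_frames < int(fs * 2 * cfg.min_step_interval_s):
        log.info("%s foot: trajectory shorter than one gait cycle; no events", foot)
        return []
    v_toe = _vertical_velocity(toe, cfg.filter_cutoff_hz)
    v_heel = _vertical_velocity(heel, cfg.filter_cutoff_hz)
    dist = max(int(cfg.min_step_interval_s * fs), 1)

    events: list[GaitEvent] = []
    with np.errstate(invalid="ignore"):
        ic_idx, ic_props = find_peaks(
            np.nan_to_num(-v_toe), prominence=cfg.prominence_mps, distance=dist
        )
        fc_idx, fc_props = find_peaks(
            np.nan_to_num(v_heel), prominence=cfg.prominence_mps, distance=dist
        )
    for i, p in zip(ic_idx, ic_props["prominences"]):
        events.append(GaitEvent(foot, INITIAL_CONTACT, i / fs, float(p)))
    for i, p in zip(fc_idx, fc_props["prominences"]):
        events.append(GaitEvent(foot, FINAL_CONTACT, i / fs, float(p)))
    events.sort(key=lambda e: e.time_s)
    return _repair_alternation(events, foot)


def _repair_alternation(events: list[GaitEvent], foot: str) -> list[GaitEvent]:
    """Drop the less prominent of two consecutive same-kind events."""
    out: list[GaitEvent] = []
    for ev in events:
        if out and out[-1].kind == ev.kind:
            keep = ev if ev.prominence > out[-1].prominence else out[-1]
            drop = out[-1] if keep is ev else ev
            log.warning(
                "%s foot: consecutive %s events at %.3f/%.3f s; dropping the less "
                "prominent one",
                foot,
                ev.kind,
                out[-1].time_s,
                ev.time_s,
            )
            out[-1] = keep
            del drop
        else:
            out.append(ev)
    return out


def steps_in_window(events: list[GaitEvent], window: tuple[float, float]) -> int:
    """Number of initial contacts (both feet pooled) in the half-open window.

    Events exactly at ``end_s`` are excluded: the half-open ``[start, end)``
    convention avoids double counting across adjacent phases.
    """
    start_s, end_s = window
    if end_s < start_s:
        raise ValueError("window end before start")
    return sum(
        1
        for e in events
        if e.kind == INITIAL_CONTACT and start_s <= e.time_s < end_s
    )
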