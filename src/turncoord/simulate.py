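"""Synthetic turning-while-walking trials with exact ground truth.

The generator emulates the walkway paradigm the analysis pipeline targets:
a participant walks up and down a 5-m walkway at self-selected speed,
performing 180-degree turns to change direction, for roughly 30 s per trial.
Segment yaw (head, sternum, pelvis) is a staircase of plateaus joined by
smooth sigmoid transitions; each more caudal segment starts its transition a
configurable latency after the head (the healthy top-down sequence). Rigid
three-marker triads are rotated by their segment's yaw and translated along
the walkway; heel/toe markers follow a parametric step cycle whose contact
times are known analytically. Gaussian noise of configurable SD is added to
every marker coordinate.

Transition shape
----------------
Transitions use the quintic smoothstep ``s(u) = 6u^5 - 15u^4 + 10u^3`` on a
compact support, rather than a logistic: it is smooth (C2), monotone, has an
analytic derivative, and — unlike any logistic — is *exactly* at the plateau
value outside the transition, so plateau-level ground truth is exact rather
than polluted by sigmoid tails at realistic inter-turn spacing.
``turn_duration_s`` is the time from 5% to 95% of the magnitude, which covers
a fixed fraction (~0.6215) of the full support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io_mocap import MarkerTrajectory, TrialRecord, CONDITIONS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationError",
    "simulate_trial",
    "simulate_cohort",
    "sample_cohort_configs",
    "smoothstep",
    "smoothstep_rate",
    "SPAN_FRACTION_5_95",
]

SEGMENTS = ("head", "sternum", "pelvis")

# u solving 6u^5 - 15u^4 + 10u^3 = 0.05 (root found once by bisection)
_U05 = 0.189255377437771
#: fraction of the full transition support covered by the 5-95% span
SPAN_FRACTION_5_95 = 1.0 - 2.0 * _U05
#: peak of d/du smoothstep(u), attained at u = 1/2
_PEAK_SLOPE = 1.875


def smoothstep(u):
    """Quintic smoothstep, clamped: 0 for u<=0, 1 for u>=1."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (u * (6.0 * u - 15.0) + 10.0)


def smoothstep_rate(u):
    """Analytic derivative of :func:`smoothstep` with respect to u."""
    u = np.asarray(u, dtype=float)
    inside = (u > 0.0) & (u < 1.0)
    uu = np.clip(u, 0.0, 1.0)
    return np.where(inside, 30.0 * uu**2 * (1.0 - uu) ** 2, 0.0)


class SimulationError(ValueError):
    """Raised for configurations that cannot produce a valid trial."""


# marker triad geometry per segment: (label suffix is 1..3)
# offsets are in the segment frame, meters; z is height above the floor.
_TRIAD_OFFSETS = {
    "head": np.array(
        [[0.00, 0.10, 1.72], [-0.087, -0.05, 1.68], [0.087, -0.05, 1.68]]
    ),
    "sternum": np.array(
        [[0.08, 0.00, 1.40], [-0.04, 0.069, 1.32], [-0.04, -0.069, 1.32]]
    ),
    "pelvis": np.array(
        [[0.104, 0.06, 1.00], [-0.104, 0.06, 1.00], [0.00, -0.12, 0.98]]
    ),
}

_SWING_FRACTION = 0.4  # of the per-foot gait cycle
_TOE_LIFT_M = 0.05
_HEEL_LIFT_M = 0.07


@dataclass
class SimulationConfig:
    """Parameters of one synthetic trial.

    Attributes
    ----------
    n_turns : int
        Number of 180-degree direction changes in the trial.
    turn_magnitude_deg : float
        Nominal yaw change per turn.
    turn_duration_s : float
        5-95% span of each segment's sigmoid transition, seconds.
    onset_latency_s : mapping segment -> float
        Transition onset delay relative to the head (head must be 0).
        Defaults follow the healthy top-down sequence: sternum 80 ms and
        pelvis 180 ms after the head.
    peak_angular_velocity_degps : mapping segment -> float, optional
        Per-segment peak yaw rate override. When given for a segment, that
        segment's transition duration is rescaled so its analytic peak rate
        equals the requested value (duration and peak rate are redundant for
        a fixed-shape transition of fixed magnitude; duration is primary).
    step_frequency_hz : float
        Cadence in steps per second, both feet pooled.
    walking_speed_mps : float
        Straight-walking speed along the walkway.
    walkway_length_m, trial_duration_s : float
        Paradigm geometry; the realized duration is whatever the configured
        walk/turn pattern needs, with ``trial_duration_s`` as documentation
        of the nominal protocol length.
    marker_noise_sd_m : float
        SD of i.i.d. Gaussian noise added to every marker coordinate.
        Default 2 mm, a typical optical-capture jitter scale.
    fs : float
        Sampling rate, Hz.
    seed : int
        RNG seed; a fixed seed makes the output bit-reproducible.
    allow_bottom_up : bool
        Permit negative latencies (caudal segment leading) when True.
    """

    n_turns: int = 4
    turn_magnitude_deg: float = 180.0
    turn_duration_s: float = 2.0
    onset_latency_s: Mapping[str, float] = field(
        default_factory=lambda: {"head": 0.0, "sternum": 0.08, "pelvis": 0.18}
    )
    peak_angular_velocity_degps: Mapping[str, float] | None = None
    step_frequency_hz: float = 1.8
    walking_speed_mps: float = 1.2
    walkway_length_m: float = 5.0
    trial_duration_s: float = 30.0
    marker_noise_sd_m: float = 0.002
    fs: float = 200.0
    seed: int = 0
    allow_bottom_up: bool = False

    def validate(self) -> None:
        if self.fs <= 0 or self.turn_duration_s <= 0 or self.n_turns < 1:
            raise SimulationError("fs, turn_duration_s and n_turns must be positive")
        if self.turn_magnitude_deg <= 0:
            raise SimulationError("turn_magnitude_deg must be positive")
        lat = dict(self.onset_latency_s)
        if lat.get("head", 0.0) != 0.0:
            raise SimulationError("onset_latency_s['head'] must be 0 (head is the reference)")
        for seg in SEGMENTS:
            lat.setdefault(seg, 0.0)
            if lat[seg] < 0 and not self.allow_bottom_up:
                raise SimulationError(
                    f"negative latency for {seg}; set allow_bottom_up=True to permit"
                )
        # Turn blocks are allotted turn duration + max latency in the
        # timeline, so transitions cannot overlap; what must remain is a
        # usable straight-walking plateau between successive turns.
        walk_s = self.walkway_length_m / self.walking_speed_mps
        if walk_s < 1.0:
            raise SimulationError(
                f"turns too closely spaced: straight-walking bout {walk_s:.2f} s "
                "(walkway length / speed) is under 1 s; no heading plateau would "
                "separate successive turns"
            )

    @property
    def latencies(self) -> dict[str, float]:
        lat = dict(self.onset_latency_s)
        for seg in SEGMENTS:
            lat.setdefault(seg, 0.0)
        return lat

    def segment_support_s(self, segment: str) -> float:
        """Full transition support duration for one segment, seconds."""
        base = self.turn_duration_s / SPAN_FRACTION_5_95
        if self.peak_angular_velocity_degps:
            peak = self.peak_angular_velocity_degps.get(segment)
            if peak is not None:
                if peak <= 0:
                    raise SimulationError("peak angular velocity must be positive")
                return _PEAK_SLOPE * self.turn_magnitude_deg / peak
        return base

    def segment_peak_omega(self, segment: str) -> float:
        """Analytic peak yaw rate of one segment's transition, deg/s."""
        return _PEAK_SLOPE * self.turn_magnitude_deg / self.segment_support_s(segment)

    @property
    def min_turn_spacing_s(self) -> float:
        sup = max(self.segment_support_s(s) for s in SEGMENTS)
        return sup + max(self.latencies.values())


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests.

    Turn boundaries are the 5% and 95% crossing times of each segment's
    transition, so ``turn_starts[seg] - turn_starts['head']`` equals the
    configured onset latency exactly.
    """

    turn_starts: dict[str, np.ndarray]
    turn_ends: dict[str, np.ndarray]
    directions: np.ndarray
    magnitude_deg: float
    initial_contacts: dict[str, np.ndarray]
    final_contacts: dict[str, np.ndarray]
    gait_speed_mps: float
    onset_latency_s: dict[str, float]
    peak_omega_degps: dict[str, float]

    def __post_init__(self):
        for seg, starts in self.turn_starts.items():
            if np.any(self.turn_ends[seg] <= starts):
                raise ValueError(f"{seg}: turn end must follow start")
        for foot in ("left", "right"):
            for ev in (self.initial_contacts, self.final_contacts):
                if np.any(np.diff(ev[foot]) <= 0):
                    raise ValueError(f"{foot}: contacts must be strictly increasing")

    @property
    def n_turns(self) -> int:
        return len(self.directions)

    def steps_in_window(self, start_s: float, end_s: float) -> int:
        """Ground-truth step count: initial contacts of both feet in [start, end)."""
        ics = np.concatenate([self.initial_contacts["left"], self.initial_contacts["right"]])
        return int(np.sum((ics >= start_s) & (ics < end_s)))


def _segment_yaw_truth(cfg: SimulationConfig, t: np.ndarray, segment: str, block_starts):
    """Noise-free yaw time series and per-turn 5%/95% crossings for one segment."""
    lat = cfg.latencies[segment]
    sup = cfg.segment_support_s(segment)
    yaw = np.zeros_like(t)
    starts, ends = [], []
    level = 0.0
    for i, b in enumerate(block_starts):
        direction = 1.0 if i % 2 == 0 else -1.0
        a = b + lat
        u = (t - a) / sup
        yaw = yaw + direction * cfg.turn_magnitude_deg * smoothstep(u)
        starts.append(a + _U05 * sup)
        ends.append(a + (1.0 - _U05) * sup)
        level += direction * cfg.turn_magnitude_deg
    return yaw, np.array(starts), np.array(ends)


def _foot_events(cfg: SimulationConfig, duration: float, phase: float):
    """Analytic contact times for one foot over [0, duration].

    The foot's vertical profile is a smooth lift bump per swing phase; the
    ground-truth initial contact is the time of the analytic minimum of the
    toe's vertical velocity (3/4 through swing) and the final contact the
    analytic maximum of the heel's vertical velocity (1/4 through swing).
    """
    period = 2.0 / cfg.step_frequency_hz
    swing = _SWING_FRACTION * period
    n_cycles = int(np.ceil(duration / period)) + 1
    k = np.arange(n_cycles)
    swing_starts = (k + phase) * period
    fc = swing_starts + 0.25 * swing
    ic = swing_starts + 0.75 * swing
    keep = lambda ev: ev[(ev >= 0) & (ev <= duration)]
    return keep(ic), keep(fc), swing_starts, period, swing


def _foot_z(t: np.ndarray, swing_starts, swing: float, lift: float) -> np.ndarray:
    z = np.zeros_like(t)
    for s0 in swing_starts:
        u = (t - s0) / swing
        m = (u > 0) & (u < 1)
        z[m] += lift * np.sin(np.pi * u[m]) ** 2
    return z


def simulate_trial(
    cfg: SimulationConfig,
    *,
    subject_id: str = "sim",
    group: str = "young",
    condition: str = "ST",
) -> tuple[TrialRecord, GroundTruth]:
    """Generate one synthetic trial and its exact ground truth.

    The trial alternates straight walking bouts (walkway length / speed
    seconds each) with turn blocks long enough for the slowest segment to
    finish its transition; turn direction alternates on successive turns as
    in up-and-down walking. The same configuration and seed always produce
    bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    walk_s = cfg.walkway_length_m / cfg.walking_speed_mps
    block = cfg.min_turn_spacing_s
    # head turn block i starts after i+1 walking bouts and i turn blocks
    block_starts = np.array([(i + 1) * walk_s + i * block for i in range(cfg.n_turns)])
    duration = (cfg.n_turns + 1) * walk_s + cfg.n_turns * block
    n = int(round(duration * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs

    # Horizontal path at constant speed throughout: straight bouts along the
    # walkway joined by semicircular arcs during the turn blocks (locomotion
    # continues through the turn, as in the real paradigm). The motion
    # heading ramps 0 <-> 180 degrees with the same smoothstep shape over
    # each full turn block, so straight bouts have exactly constant speed.
    heading = np.zeros(n)
    for i, b in enumerate(block_starts):
        direction = 1.0 if i % 2 == 0 else -1.0
        heading += direction * np.pi * smoothstep((t - b) / block)
    dt = 1.0 / cfg.fs
    vx = cfg.walking_speed_mps * np.cos(heading)
    vy = cfg.walking_speed_mps * np.sin(heading)
    x = np.concatenate(([0.0], np.cumsum(vx[:-1] * dt)))
    y = np.concatenate(([0.0], np.cumsum(vy[:-1] * dt)))

    markers: dict[str, MarkerTrajectory] = {}
    turn_starts, turn_ends, peak_omega = {}, {}, {}
    for seg in SEGMENTS:
        yaw, starts, ends = _segment_yaw_truth(cfg, t, seg, block_starts)
        turn_starts[seg], turn_ends[seg] = starts, ends
        peak_omega[seg] = cfg.segment_peak_omega(seg)
        rad = np.deg2rad(yaw)
        c, s = np.cos(rad), np.sin(rad)
        for j, offset in enumerate(_TRIAD_OFFSETS[seg], start=1):
            px = x + c * offset[0] - s * offset[1]
            py = y + s * offset[0] + c * offset[1]
            pz = np.full(n, offset[2])
            markers[f"{seg}_{j}"] = MarkerTrajectory(
                f"{seg}_{j}", np.column_stack([px, py, pz]), cfg.fs
            )

    ic, fc = {}, {}
    for foot, phase, ysign in (("left", 0.0, 1.0), ("right", 0.5, -1.0)):
        ic[foot], fc[foot], swing_starts, period, swing = _foot_events(
            cfg, duration, phase
        )
        suffix = "L" if foot == "left" else "R"
        hc, hs = np.cos(heading), np.sin(heading)
        for part, lift, dx in (("heel", _HEEL_LIFT_M, -0.12), ("toe", _TOE_LIFT_M, 0.12)):
            z = _foot_z(t, swing_starts, swing, lift)
            offy = ysign * 0.12
            posxyz = np.column_stack(
                [x + hc * dx - hs * offy, y + hs * dx + hc * offy, z]
            )
            lab = f"{part}_{suffix}"
            markers[lab] = MarkerTrajectory(lab, posxyz, cfg.fs)

    if cfg.marker_noise_sd_m > 0:
        for m in markers.values():
            m.positions += rng.normal(0.0, cfg.marker_noise_sd_m, m.positions.shape)

    directions = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(cfg.n_turns)])
    truth = GroundTruth(
        turn_starts=turn_starts,
        turn_ends=turn_ends,
        directions=directions,
        magnitude_deg=cfg.turn_magnitude_deg,
        initial_contacts=ic,
        final_contacts=fc,
        gait_speed_mps=cfg.walking_speed_mps,
        onset_latency_s=cfg.latencies,
        peak_omega_degps=peak_omega,
    )
    trial = TrialRecord(subject_id, group, condition, markers)
    return trial, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: config fields a condition effect or subject random effect may scale
_SCALABLE = (
    "turn_duration_s",
    "walking_speed_mps",
    "step_frequency_hz",
    "marker_noise_sd_m",
    "turn_magnitude_deg",
    "onset_latency_s",
)


def _apply_multipliers(cfg: SimulationConfig, mult: Mapping[str, float]) -> SimulationConfig:
    changes = {}
    for name, m in mult.items():
        if name not in _SCALABLE:
            raise SimulationError(f"cannot scale config field {name!r}")
        if name == "onset_latency_s":
            changes[name] = {k: v * m for k, v in cfg.latencies.items()}
        else:
            changes[name] = getattr(cfg, name) * m
    return replace(cfg, **changes)


def sample_cohort_configs(
    design: Mapping[str, SimulationConfig],
    n_subjects: Mapping[str, int],
    effects: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    *,
    subject_sd: Mapping[str, float] | None = None,
):
    """Draw per-trial configurations for a simulated cohort.

    Every subject performs all three conditions (ST, SDT, CDT). Subject
    heterogeneity enters as lognormal multipliers (median 1) on transition
    duration, walking speed and onset latencies, layered over the group's
    mean configuration; ``effects`` maps condition -> {field: multiplier}
    applied on top (ST is conventionally the identity).

    Returns a list of ``(subject_id, group, condition, SimulationConfig)``
    in deterministic order; trial seeds are spawned from ``seed``.
    """
    effects = effects or {}
    sd = {"turn_duration_s": 0.10, "walking_speed_mps": 0.10, "onset_latency_s": 0.15}
    if subject_sd:
        sd.update(subject_sd)
    missing = [g for g in n_subjects if g not in design]
    if missing:
        raise SimulationError(f"design lacks groups: {missing}")
    root = np.random.SeedSequence(seed)
    out = []
    for group in n_subjects:
        base = design[group]
        for i in range(n_subjects[group]):
            sid = f"{group}_{i + 1:03d}"
            rng = np.random.default_rng(root.spawn(1)[0])
            subj_mult = {k: float(rng.lognormal(0.0, s)) for k, s in sd.items()}
            subj_cfg = _apply_multipliers(base, subj_mult)
            for condition in CONDITIONS:
                # trial-to-trial (within-subject) variability at half the
                # between-subject spread
                trial_mult = {k: float(rng.lognormal(0.0, s / 2)) for k, s in sd.items()}
                cfg = _apply_multipliers(subj_cfg, trial_mult)
                cfg = _apply_multipliers(cfg, effects.get(condition, {}))
                cfg = replace(cfg, seed=int(rng.integers(2**31)))
                out.append((sid, group, condition, cfg))
    return out


def simulate_cohort(
    design: Mapping[str, SimulationConfig],
    n_subjects: Mapping[str, int],
    effects: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    **kwargs,
):
    """Simulate a full cohort: every subject x {ST, SDT, CDT}.

    Returns a list of ``(TrialRecord, GroundTruth)`` whose metadata carries
    subject, group and condition. Fully reproducible under a fixed seed.
    """
    out = []
    for sid, group, condition, cfg in sample_cohort_configs(
        design, n_subjects, effects, seed, **kwargs
    ):
        out.append(simulate_trial(cfg, subject_id=sid, group=group, condition=condition))
    return out
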