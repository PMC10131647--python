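"""Segment orientation, angular velocity and gait speed from marker triads.

Segment yaw is estimated per frame as the least-squares rigid rotation
(orthogonal Procrustes / Kabsch) that maps the segment's marker configuration
at the first valid frame onto the current frame, followed by Euler z-y-x
decomposition with the z angle (yaw, rotation about the vertical) extracted
first. Only yaw is consumed downstream; the sequence choice is documented
for reproducibility. The yaw series is unwrapped over time, so a continuous
rotation through 170 -> 190 degrees reads 190, not -170.

Angular velocity is obtained by zero-phase low-pass filtering of the yaw
series (4th-order Butterworth, default 6 Hz cutoff: turning dynamics live
below ~2 Hz, marker jitter well above) followed by central differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .io_mocap import MarkerTrajectory

__all__ = [
    "SegmentYawSignal",
    "AngularVelocitySignal",
    "DegenerateTriadError",
    "segment_yaw",
    "angular_velocity",
    "lowpass",
    "gait_speed",
]


class DegenerateTriadError(ValueError):
    """Raised when a segment's markers are collinear or otherwise rank-deficient."""


@dataclass
class SegmentYawSignal:
    """Unwrapped rotation of one segment about the vertical axis.

    ``yaw_deg`` is NaN wherever fewer than three non-collinear markers are
    valid (occlusion policy applied upstream).
    """

    segment: str
    yaw_deg: np.ndarray
    fs: float

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.yaw_deg)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.yaw_deg)) / self.fs


@dataclass
class AngularVelocitySignal:
    """Yaw rate of one segment, degrees/second."""

    segment: str
    omega_degps: np.ndarray
    fs: float


def _kabsch_yaw(ref: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Batched least-squares rotations ref -> frames; returns yaw in radians.

    ref : (m, 3) centered reference configuration
    frames : (T, m, 3) centered per-frame configurations (may contain NaN)
    """
    H = np.einsum("mi,tmj->tij", ref, frames)  # (T, 3, 3) cross-covariance
    bad = np.isnan(H).any(axis=(1, 2))
    H = np.where(bad[:, None, None], np.eye(3), H)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("tij,tjk->tik", U, Vt).swapaxes(1, 2))
    D = np.repeat(np.eye(3)[None], len(H), axis=0)
    D[:, 2, 2] = np.sign(det)
    # R maps ref onto frame: R = V D U^T
    R = np.einsum("tji,tjk,tlk->til", Vt, D, U)
    yaw = np.arctan2(R[:, 1, 0], R[:, 0, 0])
    yaw[bad] = np.nan
    return yaw


def segment_yaw(markers: Sequence[MarkerTrajectory], segment: str = "") -> SegmentYawSignal:
    """Estimate a segment's unwrapped yaw from its marker cloud (>= 3 markers).

    The reference configuration is the first frame where all markers are
    valid. Frames with any missing marker yield NaN yaw. Unwrapping is
    performed over contiguous valid runs, each run re-anchored so yaw is
    continuous within runs.

    Raises
    ------
    DegenerateTriadError
        if fewer than 3 markers are given or the reference configuration is
        collinear (rotation about the vertical would be unobservable).
    """
    if len(markers) < 3:
        raise DegenerateTriadError("need at least 3 markers per segment")
    fs = markers[0].fs
    pos = np.stack([m.positions for m in markers], axis=1)  # (T, m, 3)
    valid = ~np.isnan(pos).any(axis=(1, 2))
    if not valid.any():
        raise DegenerateTriadError("no frame with all markers valid")
    ref_idx = int(np.argmax(valid))
    ref = pos[ref_idx]
    ref_c = ref - ref.mean(axis=0)
    # collinearity: second singular value of the centered cloud ~ 0
    svals = np.linalg.svd(ref_c, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise DegenerateTriadError("reference marker configuration is collinear")

    centered = pos - np.nanmean(pos, axis=1, keepdims=True)
    yaw = _kabsch_yaw(ref_c, centered)
    yaw[~valid] = np.nan

    out = np.full(len(yaw), np.nan)
    good = ~np.isnan(yaw)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], good.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        out[a:b] = np.unwrap(yaw[a:b])
    return SegmentYawSignal(segment or markers[0].label, np.rad2deg(out), fs)


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; NaN runs are preserved untouched."""
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    b, a = butter(order, cutoff_hz / (fs / 2))
    out = np.full_like(np.asarray(x, dtype=float), np.nan)
    good = ~np.isnan(x)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], good.view(np.int8), [0]))))
    padlen = 3 * max(len(a), len(b))
    for s, e in zip(idx[::2], idx[1::2]):
        if e - s > padlen:
            out[s:e] = filtfilt(b, a, x[s:e])
        else:
            out[s:e] = x[s:e]
    return out


def angular_velocity(
    yaw: SegmentYawSignal, filter_cutoff_hz: float = 6.0
) -> AngularVelocitySignal:
    """Differentiate yaw: zero-phase low-pass then central differences."""
    smoothed = lowpass(yaw.yaw_deg, yaw.fs, filter_cutoff_hz)
    omega = np.gradient(smoothed) * yaw.fs
    return AngularVelocitySignal(yaw.segment, omega, yaw.fs)


def gait_speed(
    pelvis_markers: Sequence[MarkerTrajectory],
    turn_windows: Sequence[tuple[float, float]],
    guard_band_s: float = 0.25,
) -> float:
    """Mean horizontal speed of the pelvis centroid over straight-walking intervals.

    Samples inside any detected turn window, extended by ``guard_band_s`` on
    both sides, are excluded. Each remaining contiguous interval contributes
    its horizontal displacement (straight-line chord) divided by its
    duration; intervals are combined weighted by duration. Using endpoint
    displacement rather than summed frame-to-frame steps keeps marker noise
    from inflating the estimate.

    Raises
    ------
    ValueError
        if no straight-walking interval remains.
    """
    fs = pelvis_markers[0].fs
    centroid = np.nanmean(np.stack([m.positions for m in pelvis_markers]), axis=0)
    t = np.arange(len(centroid)) / fs
    straight = np.ones(len(t), dtype=bool)
    for start, end in turn_windows:
        straight &= ~((t >= start - guard_band_s) & (t <= end + guard_band_s))
    straight &= ~np.isnan(centroid).any(axis=1)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], straight.view(np.int8), [0]))))
    dist = dur = 0.0
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a < 2:
            continue
        dist += float(np.linalg.norm(centroid[b - 1, :2] - centroid[a, :2]))
        dur += (b - 1 - a) / fs
    if dur == 0.0:
        raise ValueError("no straight-walking interval outside turns")
    return dist / dur
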