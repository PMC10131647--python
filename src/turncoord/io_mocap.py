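"""Marker-trajectory data model and trial/table I/O.

The pipeline's on-disk formats are

* C3D — the standard optical motion-capture container (see :mod:`turncoord._c3d`
  for the subset supported);
* a wide CSV dialect — one row per frame, a ``time`` column in seconds plus
  ``{label}_{x|y|z}`` columns in meters, chosen so fixtures stay hand-editable;
* a long metrics CSV — one row per subject x condition x measure.

Conventions
-----------
The lab frame is right-handed with **z vertical** (gravity axis) and x along
the walkway; yaw is rotation about z. Input files recorded with other axis
conventions are remapped through the ``axes`` entry of the schema config.

Occluded samples are represented as NaN coordinates and stay NaN ("flagged,
never silently zero") unless the gap is short enough for the interpolation
policy: gaps of at most ``max_gap_samples`` (default 10, i.e. 50 ms at
200 Hz) are linearly interpolated; longer gaps remain invalid and downstream
code discards any turn that overlaps them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarkerTrajectory",
    "TrialRecord",
    "MissingMarkerError",
    "NonUniformSamplingError",
    "REQUIRED_LABELS",
    "SEGMENT_MARKERS",
    "read_c3d",
    "write_c3d",
    "read_csv_trial",
    "write_csv_trial",
    "read_metrics",
    "write_metrics",
    "interpolate_gaps",
    "load_schema",
]

GROUPS = ("young", "older", "pd", "stroke", "ms", "lbp")
CONDITIONS = ("ST", "SDT", "CDT")

#: Marker labels each axial segment's yaw estimate is built from (rigid triads).
SEGMENT_MARKERS: dict[str, tuple[str, ...]] = {
    "head": ("head_1", "head_2", "head_3"),
    "sternum": ("sternum_1", "sternum_2", "sternum_3"),
    "pelvis": ("pelvis_1", "pelvis_2", "pelvis_3"),
}

#: Minimal marker set the full pipeline needs: three-marker triads for head,
#: sternum and pelvis plus heel/toe markers on both feet.
REQUIRED_LABELS: tuple[str, ...] = (
    *SEGMENT_MARKERS["head"],
    *SEGMENT_MARKERS["sternum"],
    *SEGMENT_MARKERS["pelvis"],
    "heel_L",
    "toe_L",
    "heel_R",
    "toe_R",
)


class MissingMarkerError(KeyError):
    """Raised when a trial lacks required marker labels; lists the absent ones."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"missing required markers: {', '.join(self.missing)}")


class NonUniformSamplingError(ValueError):
    """Raised when a CSV time column is not uniformly sampled within tolerance."""


@dataclass
class MarkerTrajectory:
    """One labeled marker's 3D position time series.

    Parameters
    ----------
    label : str
        Marker name.
    positions : (T, 3) ndarray
        Coordinates in meters, lab frame (z vertical). NaN rows mark
        occluded samples.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    label: str
    positions: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"{self.label}: positions must be (T, 3)")
        if self.positions.shape[0] < 2:
            raise ValueError(f"{self.label}: need at least 2 samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask, True where all three coordinates are present."""
        return ~np.isnan(self.positions).any(axis=1)

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fs


@dataclass
class TrialRecord:
    """One recorded trial: a marker set plus subject/condition metadata."""

    subject_id: str
    group: str
    condition: str
    markers: dict[str, MarkerTrajectory]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        lengths = {m.n_frames for m in self.markers.values()}
        rates = {m.fs for m in self.markers.values()}
        if len(lengths) > 1 or len(rates) > 1:
            raise ValueError("all markers in a trial must share fs and length")

    @property
    def fs(self) -> float:
        return next(iter(self.markers.values())).fs

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).n_frames

    def require(self, labels=REQUIRED_LABELS) -> None:
        missing = [lab for lab in labels if lab not in self.markers]
        if missing:
            raise MissingMarkerError(missing)

    def segment_markers(self, segment: str) -> list[MarkerTrajectory]:
        return [self.markers[lab] for lab in SEGMENT_MARKERS[segment]]


def interpolate_gaps(traj: MarkerTrajectory, max_gap_samples: int = 10) -> MarkerTrajectory:
    """Fill short occlusion gaps by linear interpolation.

    Interior NaN runs of length <= ``max_gap_samples`` are linearly
    interpolated per coordinate; longer runs and edge runs are left as NaN so
    downstream consumers can invalidate overlapping turns.
    """
    pos = traj.positions.copy()
    bad = ~traj.valid
    if not bad.any():
        return traj
    t = np.arange(len(bad))
    # locate maximal NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    good = ~bad
    for a, b in zip(starts, ends):
        if b - a > max_gap_samples or a == 0 or b == len(bad):
            continue
        for c in range(3):
            pos[a:b, c] = np.interp(t[a:b], t[good], traj.positions[good, c])
    return MarkerTrajectory(traj.label, pos, traj.fs, traj.t0)


# ---------------------------------------------------------------------------
# schema / config
# ---------------------------------------------------------------------------

def load_schema(path) -> dict:
    """Load a YAML schema config (marker-label mapping, axis mapping, fs)."""
    with open(path) as fh:
        return yaml.safe_load(fh)


_AXES = {"x": 0, "y": 1, "z": 2}


def _axis_permutation(axes: Mapping[str, str] | None):
    """Map file axes onto the lab convention (z vertical, x walkway).

    ``axes`` maps lab axis -> file axis with optional sign, e.g.
    ``{"x": "y", "y": "-x", "z": "z"}``. None means identity.
    """
    if not axes:
        return None
    perm, signs = [], []
    for lab_ax in ("x", "y", "z"):
        src = axes[lab_ax]
        sign = -1.0 if src.startswith("-") else 1.0
        perm.append(_AXES[src.lstrip("+-")])
        signs.append(sign)
    return np.asarray(perm), np.asarray(signs)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_csv_trial(
    path,
    schema: Mapping | None = None,
    *,
    subject_id: str | None = None,
    group: str | None = None,
    condition: str | None = None,
) -> TrialRecord:
    """Read a trial from the wide CSV dialect.

    The default dialect is one row per frame with a ``time`` column (seconds)
    and ``{label}_{x|y|z}`` position columns in meters. ``schema`` may supply:

    ``time_col``
        name of the time column (default ``"time"``);
    ``fs``
        declared sampling rate, validated against the median time step
        within 0.1%;
    ``columns``
        mapping of CSV column name -> ``"label:axis"`` for files whose
        headers do not follow the default dialect;
    ``axes``
        lab-axis -> file-axis remap (see module docstring);
    ``units_scale``
        multiplier applied to positions (e.g. 0.001 for mm files);
    ``subject_id``, ``group``, ``condition``, ``meta``
        trial metadata (overridden by keyword arguments).

    Raises
    ------
    NonUniformSamplingError
        if any time step deviates from the median by more than 1%.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path)
    time_col = schema.get("time_col", "time")
    if time_col not in df.columns:
        raise ValueError(f"CSV lacks time column {time_col!r}")
    t = df[time_col].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError("need at least 2 frames")
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise NonUniformSamplingError("time column is not increasing")
    if np.any(np.abs(dt - dt_med) > 0.01 * dt_med):
        worst = float(np.max(np.abs(dt - dt_med)))
        raise NonUniformSamplingError(
            f"non-uniform sampling: time step deviates up to {worst * 1e3:.2f} ms "
            f"from the median {dt_med * 1e3:.2f} ms"
        )
    fs = 1.0 / dt_med
    declared = schema.get("fs")
    if declared is not None and abs(fs - declared) > 1e-3 * declared:
        raise ValueError(
            f"inferred fs {fs:.3f} Hz disagrees with declared {declared} Hz (>0.1%)"
        )

    colmap = schema.get("columns")
    per_label: dict[str, dict[str, np.ndarray]] = {}
    if colmap:
        for col, target in colmap.items():
            label, axis = target.rsplit(":", 1)
            per_label.setdefault(label, {})[axis] = df[col].to_numpy(dtype=float)
    else:
        for col in df.columns:
            if col == time_col or "_" not in col:
                continue
            label, axis = col.rsplit("_", 1)
            if axis in _AXES:
                per_label.setdefault(label, {})[axis] = df[col].to_numpy(dtype=float)

    scale = float(schema.get("units_scale", 1.0))
    remap = _axis_permutation(schema.get("axes"))
    markers = {}
    for label, cols in per_label.items():
        if set(cols) != {"x", "y", "z"}:
            raise ValueError(f"marker {label!r} lacks one of x/y/z columns")
        pos = np.column_stack([cols["x"], cols["y"], cols["z"]]) * scale
        if remap is not None:
            perm, signs = remap
            pos = pos[:, perm] * signs
        markers[label] = MarkerTrajectory(label, pos, fs, t0=float(t[0]))

    return TrialRecord(
        subject_id=subject_id or schema.get("subject_id", "unknown"),
        group=group or schema.get("group", "young"),
        condition=condition or schema.get("condition", "ST"),
        markers=markers,
        meta=dict(schema.get("meta", {})),
    )


def write_csv_trial(trial: TrialRecord, path) -> None:
    """Write a trial in the wide CSV dialect (meters, lab frame)."""
    labels = sorted(trial.markers)
    first = trial.markers[labels[0]]
    data = {"time": first.time}
    for lab in labels:
        pos = trial.markers[lab].positions
        for ax, j in _AXES.items():
            data[f"{lab}_{ax}"] = pos[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# C3D
# ---------------------------------------------------------------------------

def read_c3d(path, *, require=None) -> TrialRecord:
    """Read a trial from a C3D file.

    Point units are normalized to meters; invalid points (negative residual)
    become NaN. Metadata not stored in the C3D (subject, group, condition)
    defaults to placeholders and can be set via ``require``-style keywords on
    the returned record.

    Parameters
    ----------
    path : path-like
    require : sequence of str, optional
        Marker labels that must be present; raises
        :class:`MissingMarkerError` naming the absent ones. Pass
        :data:`REQUIRED_LABELS` to enforce the full pipeline set.
    """
    from . import _c3d

    points, labels, fs, units = _c3d.read(path)
    scale = {"m": 1.0, "mm": 0.001, "cm": 0.01}.get(units.strip().lower(), 1.0)
    markers = {
        lab: MarkerTrajectory(lab, points[:, i, :] * scale, fs)
        for i, lab in enumerate(labels)
    }
    trial = TrialRecord("unknown", "young", "ST", markers)
    if require is not None:
        missing = [lab for lab in require if lab not in markers]
        if missing:
            raise MissingMarkerError(missing)
    return trial


def write_c3d(trial: TrialRecord, path) -> None:
    """Write a trial to a C3D file (meters, float point data)."""
    from . import _c3d

    labels = sorted(trial.markers)
    points = np.stack([trial.markers[lab].positions for lab in labels], axis=1)
    _c3d.write(path, points, labels, trial.fs, units="m")


# ---------------------------------------------------------------------------
# metrics tables
# ---------------------------------------------------------------------------

_METRIC_COLUMNS = ["subject_id", "group", "condition", "gait_speed", "measure", "value"]


def write_metrics(table: pd.DataFrame, path) -> None:
    """Write a long-format cohort metrics table.

    One row per subject x condition x measure, columns
    ``subject_id, group, condition, gait_speed, measure, value``.
    Write -> read round-trips exactly.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty metrics table")
    missing = [c for c in _METRIC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns: {missing}")
    table[_METRIC_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_metrics(path) -> pd.DataFrame:
    """Read a long-format cohort metrics table written by :func:`write_metrics`."""
    df = pd.read_csv(
        Path(path),
        dtype={"subject_id": str, "group": str, "condition": str, "measure": str},
    )
    missing = [c for c in _METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns: {missing}")
    return df
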