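"""Dual-task cost (DTC) of turning measures.

DTC expresses, in percent, how much a mobility measure changes from the
single-task condition (ST: walking and turning only) to a dual-task
condition (SDT/CDT: the same mobility task while operating a smartphone).
The default convention is

    DTC = 100 * (ST - DT) / ST

so that a dual-task-related *decrease* of a higher-is-better measure such
as peak angular velocity yields a *positive* cost. The ``relative_change``
convention exposes the raw signed change ``100 * (DT - ST) / ST``, which
reads more naturally for measures that increase under load (turn duration,
number of steps). The two differ only by sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_dtc", "dtc_table", "DEFAULT_DTC_MEASURES"]

#: measures DTC is conventionally computed for
DEFAULT_DTC_MEASURES = (
    "duration_s",
    "n_steps",
    "peak_omega_head",
    "peak_omega_sternum",
    "peak_omega_pelvis",
)

_CONVENTIONS = ("cost", "relative_change")


def compute_dtc(st_value: float, dt_value: float, convention: str = "cost") -> float:
    """Dual-task cost in percent.

    Parameters
    ----------
    st_value, dt_value : float
        The measure under single task and dual task, same units.
    convention : {"cost", "relative_change"}
        ``cost`` returns ``100 * (st - dt) / st`` (positive when the
        measure drops under dual task); ``relative_change`` returns
        ``100 * (dt - st) / st``.

    Raises
    ------
    ZeroDivisionError
        if ``st_value`` is zero (DTC undefined).
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}")
    if st_value == 0:
        raise ZeroDivisionError("DTC undefined for a zero single-task value")
    change = 100.0 * (st_value - dt_value) / st_value
    return change if convention == "cost" else -change


def dtc_table(
    cohort: pd.DataFrame,
    measures=DEFAULT_DTC_MEASURES,
    convention: str = "cost",
) -> pd.DataFrame:
    """Per-subject DTC records from a long-format cohort metrics table.

    For every subject and measure, pairs the ST value with each dual-task
    condition present (SDT, CDT). Subjects lacking an ST value for a measure
    are skipped. Gait speed is carried over as the mean of the ST and DT
    condition speeds, for use as a covariate downstream.

    Returns a DataFrame with columns ``subject_id, group, measure,
    dt_condition, st_value, dt_value, gait_speed, dtc_pct``.
    """
    rows = []
    for (sid, measure), sub in cohort.groupby(["subject_id", "measure"], sort=False):
        if measure not in measures:
            continue
        by_cond = sub.set_index("condition")
        if "ST" not in by_cond.index:
            continue
        st = by_cond.loc["ST"]
        for dt_cond in ("SDT", "CDT"):
            if dt_cond not in by_cond.index:
                continue
            dt = by_cond.loc[dt_cond]
            rows.append(
                {
                    "subject_id": sid,
                    "group": st["group"],
                    "measure": measure,
                    "dt_condition": dt_cond,
                    "st_value": float(st["value"]),
                    "dt_value": float(dt["value"]),
                    "gait_speed": float(np.mean([st["gait_speed"], dt["gait_speed"]])),
                    "dtc_pct": compute_dtc(
                        float(st["value"]), float(dt["value"]), convention
                    ),
                }
            )
    return pd.DataFrame(rows)
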