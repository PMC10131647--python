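"""Group x condition statistics on cohort metric tables.

The analysis layer runs split-plot ("mixed") ANOVAs with the between-subject
factor *group* and the within-subject (repeated) factor *condition* on each
turning measure, with an optional gait-speed covariate adjustment,
Greenhouse-Geisser correction of the repeated factor when Mauchly's test
indicates non-sphericity, and Bonferroni-corrected pairwise post hoc t
tests for significant main effects.

Covariate handling
------------------
Gait speed varies by condition, so by default the covariate enters per
subject x condition cell: a common slope is estimated from within-cell
variation (so group/condition differences do not leak into the slope) and
each value is replaced by its covariate-adjusted counterpart before the
ANOVA. ``covariate_mode="subject_mean"`` instead adjusts for each subject's
mean speed only, and ``covariate=None`` disables adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = ["AnovaResult", "mixed_anova", "bonferroni_posthoc"]

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class AnovaResult:
    """Tidy mixed-ANOVA output for one measure.

    ``effects`` has one row per effect (group, condition, interaction) with
    columns ``effect, F, df_num, df_den, p_unc, eps, p_gg, sphericity_p,
    gg_applied, p`` where ``p`` is the working p value (GG-corrected when
    Mauchly's test rejects sphericity at .05, uncorrected otherwise).
    """

    measure: str
    effects: pd.DataFrame
    n_subjects: int
    excluded_subjects: tuple[str, ...] = ()
    covariate: str | None = None

    def p(self, effect: str) -> float:
        return float(self.effects.set_index("effect").loc[effect, "p"])


def _adjust_for_covariate(df: pd.DataFrame, covariate: str, mode: str) -> pd.Series:
    """Covariate-adjusted values (common within-cell slope, centered covariate)."""
    if mode == "subject_mean":
        cov = df.groupby("subject_id")[covariate].transform("mean")
    elif mode == "per_cell":
        cov = df[covariate].astype(float)
    else:
        raise ValueError("covariate_mode must be 'per_cell' or 'subject_mean'")
    cov_c = cov - cov.mean()
    # slope from variation within group x condition cells only
    cell = df["group"].astype(str) + "/" + df["condition"].astype(str)
    xw = cov_c - cov_c.groupby(cell).transform("mean")
    yw = df["value"] - df["value"].groupby(cell).transform("mean")
    denom = float((xw**2).sum())
    slope = float((xw * yw).sum() / denom) if denom > 0 else 0.0
    return df["value"] - slope * cov_c


def mixed_anova(
    table: pd.DataFrame,
    measure: str,
    covariate: str | None = "gait_speed",
    *,
    covariate_mode: str = "per_cell",
    alpha: float = ALPHA,
) -> AnovaResult:
    """Split-plot ANOVA (between: group, within: condition) for one measure.

    Subjects with missing condition cells are excluded listwise with a
    warning. Requires at least 2 groups, 2 conditions and 2 subjects per
    group after exclusion. Degenerate data (zero effect and error sums of
    squares, e.g. identical values everywhere) yields F = 0, p = 1.
    """
    df = table.loc[table["measure"] == measure].copy()
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    n_cond = df["condition"].nunique()
    counts = df.groupby("subject_id")["condition"].nunique()
    excluded = tuple(counts.index[counts < n_cond])
    if excluded:
        log.warning(
            "%s: excluding %d subject(s) with missing condition cells: %s",
            measure,
            len(excluded),
            ", ".join(excluded),
        )
        df = df[~df["subject_id"].isin(excluded)]
    if df["group"].nunique() < 2 or n_cond < 2:
        raise ValueError("need >=2 groups and >=2 conditions")
    if (df.groupby("group")["subject_id"].nunique() < 2).any():
        raise ValueError("need >=2 subjects per group")

    if covariate is not None:
        df["value"] = _adjust_for_covariate(df, covariate, covariate_mode)

    if np.var(df["value"].to_numpy()) <= 1e-24:
        # degenerate: identical values everywhere -> no effect, no error
        a, k = df["group"].nunique(), n_cond
        n = int(df["subject_id"].nunique())
        rows = [
            {"effect": e, "F": 0.0, "df_num": d1, "df_den": d2, "p_unc": 1.0,
             "eps": np.nan, "p_gg": np.nan, "sphericity_p": np.nan,
             "gg_applied": False, "p": 1.0}
            for e, d1, d2 in (
                ("group", a - 1, n - a),
                ("condition", k - 1, (n - a) * (k - 1)),
                ("interaction", (a - 1) * (k - 1), (n - a) * (k - 1)),
            )
        ]
        return AnovaResult(measure, pd.DataFrame(rows), n, excluded, covariate)

    aov = pg.mixed_anova(
        df,
        dv="value",
        within="condition",
        between="group",
        subject="subject_id",
        correction=True,
    )
    aov = aov.set_index("Source")
    sph_p = float(aov.loc["condition"].get("p_spher", np.nan))
    eps = float(aov.loc["condition"].get("eps", np.nan))
    gg_applied = bool(np.isfinite(sph_p) and sph_p < alpha)

    rows = []
    for src, name in (("group", "group"), ("condition", "condition"), ("Interaction", "interaction")):
        r = aov.loc[src]
        F, p_unc = float(r["F"]), float(r["p_unc"])
        if not np.isfinite(F) and float(r["SS"]) <= 1e-12:
            F, p_unc = 0.0, 1.0
        p_gg = float(r["p_GG_corr"]) if "p_GG_corr" in r and np.isfinite(r.get("p_GG_corr", np.nan)) else np.nan
        use_gg = gg_applied and name in ("condition", "interaction") and np.isfinite(p_gg)
        rows.append(
            {
                "effect": name,
                "F": F,
                "df_num": float(r["DF1"]),
                "df_den": float(r["DF2"]),
                "p_unc": p_unc,
                "eps": eps if name in ("condition", "interaction") else np.nan,
                "p_gg": p_gg if name in ("condition", "interaction") else np.nan,
                "sphericity_p": sph_p if name in ("condition", "interaction") else np.nan,
                "gg_applied": use_gg,
                "p": p_gg if use_gg else p_unc,
            }
        )
    return AnovaResult(
        measure=measure,
        effects=pd.DataFrame(rows),
        n_subjects=int(df["subject_id"].nunique()),
        excluded_subjects=excluded,
        covariate=covariate,
    )


def bonferroni_posthoc(
    table: pd.DataFrame,
    measure: str,
    factor: str,
    anova: AnovaResult | None = None,
    *,
    force: bool = False,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """All pairwise t tests for one factor, Bonferroni-adjusted.

    Between-subject factor (``group``): independent t tests on per-subject
    means across conditions. Within-subject factor (``condition``): paired t
    tests across subjects. Adjusted p is ``min(1, m * p)`` with ``m`` the
    number of level pairs. When ``anova`` is given and its main effect for
    ``factor`` is not significant at ``alpha``, an empty table is returned
    unless ``force`` is set — post hocs follow significant main effects.
    """
    if factor not in ("group", "condition"):
        raise ValueError("factor must be 'group' or 'condition'")
    cols = ["level_a", "level_b", "mean_a", "mean_b", "mean_diff", "t", "df", "p_unc", "p_bonf"]
    if anova is not None and not force and anova.p(factor) >= alpha:
        log.info("%s: %s main effect not significant; skipping post hocs", measure, factor)
        return pd.DataFrame(columns=cols)

    df = table.loc[table["measure"] == measure]
    if factor == "group":
        per_subject = (
            df.groupby(["subject_id", "group"])["value"].mean().reset_index()
        )
        samples = {g: s["value"].to_numpy() for g, s in per_subject.groupby("group")}
    else:
        wide = df.pivot_table(index="subject_id", columns="condition", values="value")
        samples = {c: wide[c] for c in wide.columns}

    levels = sorted(samples)
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = samples[a], samples[b]
        if factor == "condition":
            both = (~xa.isna()) & (~xb.isna())
            xa, xb = xa[both].to_numpy(), xb[both].to_numpy()
            if len(xa) < 2:
                log.warning("pair %s-%s: fewer than 2 paired observations; skipped", a, b)
                continue
            t, p = sps.ttest_rel(xa, xb)
            dof = len(xa) - 1
        else:
            if len(xa) < 2 or len(xb) < 2:
                log.warning("pair %s-%s: a level has <2 observations; skipped", a, b)
                continue
            t, p = sps.ttest_ind(xa, xb)
            dof = len(xa) + len(xb) - 2
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_a": float(np.mean(xa)),
                "mean_b": float(np.mean(xb)),
                "mean_diff": float(np.mean(xa) - np.mean(xb)),
                "t": float(t),
                "df": dof,
                "p_unc": float(p),
                "p_bonf": float(min(1.0, m * p)),
            }
        )
    return pd.DataFrame(rows, columns=cols)
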