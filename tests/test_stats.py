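"""Mixed (split-plot) ANOVA layer: sums-of-squares oracle, GG, post hocs."""

import numpy as np
import pandas as pd
import pytest

from turncoord.stats import _adjust_for_covariate, bonferroni_posthoc, mixed_anova


def make_table(y, groups, measure="m", speeds=None):
    """Long table from y[g][s][c] (group x subject x condition)."""
    rows = []
    conds = ("ST", "SDT", "CDT")[: y.shape[2]]
    sid = 0
    for g in range(y.shape[0]):
        for s in range(y.shape[1]):
            sid += 1
            for c in range(y.shape[2]):
                rows.append(
                    {
                        "subject_id": f"s{sid:03d}",
                        "group": groups[g],
                        "condition": conds[c],
                        "gait_speed": 1.0 if speeds is None else speeds[g, s, c],
                        "measure": measure,
                        "value": float(y[g, s, c]),
                    }
                )
    return pd.DataFrame(rows)


def splitplot_oracle(y):
    """Textbook balanced split-plot sums of squares, coded independently.

    y : (a, n, k) array — groups x subjects-per-group x repeated levels.
    Returns F statistics for the group, condition and interaction effects.
    """
    a, n, k = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_gs = y.mean(axis=2)
    m_c = y.mean(axis=(0, 1))
    m_gc = y.mean(axis=1)
    ss_group = n * k * np.sum((m_g - grand) ** 2)
    ss_subj = k * np.sum((m_gs - m_g[:, None]) ** 2)
    ss_cond = a * n * np.sum((m_c - grand) ** 2)
    ss_int = n * np.sum((m_gc - m_g[:, None] - m_c[None, :] + grand) ** 2)
    resid = y - m_gc[:, None, :] - m_gs[:, :, None] + m_g[:, None, None]
    ss_err = np.sum(resid**2)
    ms_group = ss_group / (a - 1)
    ms_subj = ss_subj / (a * (n - 1))
    ms_cond = ss_cond / (k - 1)
    ms_int = ss_int / ((a - 1) * (k - 1))
    ms_err = ss_err / (a * (n - 1) * (k - 1))
    return ms_group / ms_subj, ms_cond / ms_err, ms_int / ms_err


class TestMixedAnova:
    def test_agrees_with_textbook_sums_of_squares(self):
        """F values match an independent computation on integer data to 1e-8."""
        rng = np.random.default_rng(0)
        y = rng.integers(0, 20, size=(3, 6, 3)).astype(float)
        res = mixed_anova(make_table(y, ("young", "pd", "stroke")), "m", covariate=None)
        f_group, f_cond, f_int = splitplot_oracle(y)
        eff = res.effects.set_index("effect")["F"]
        assert eff["group"] == pytest.approx(f_group, rel=1e-8)
        assert eff["condition"] == pytest.approx(f_cond, rel=1e-8)
        assert eff["interaction"] == pytest.approx(f_int, rel=1e-8)

    def test_identical_cells_give_zero_f(self):
        y = np.full((2, 4, 3), 7.5)
        res = mixed_anova(make_table(y, ("young", "pd")), "m", covariate=None)
        assert (res.effects["F"] == 0.0).all()
        assert (res.effects["p"] == 1.0).all()

    def test_subject_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(2, 8, 3))
        t1 = make_table(y, ("young", "pd"))
        # permute subjects within each group
        perm = y[:, rng.permutation(8), :]
        t2 = make_table(perm, ("young", "pd"))
        f1 = mixed_anova(t1, "m", covariate=None).effects["F"].to_numpy()
        f2 = mixed_anova(t2, "m", covariate=None).effects["F"].to_numpy()
        np.testing.assert_allclose(f1, f2, rtol=1e-10)

    def test_gg_correction_raises_p_under_nonsphericity(self):
        rng = np.random.default_rng(2)
        n = 12
        base = rng.normal(size=(2, n))
        y = np.empty((2, n, 3))
        y[:, :, 0] = base
        y[:, :, 1] = base + rng.normal(0, 0.05, (2, n))  # highly correlated pair
        y[:, :, 2] = rng.normal(size=(2, n)) * 3 + 1.5  # different variance + shift
        res = mixed_anova(make_table(y, ("young", "pd")), "m", covariate=None)
        row = res.effects.set_index("effect").loc["condition"]
        k = 3
        assert 1.0 / (k - 1) < row["eps"] <= 1.0
        assert row["F"] > 1.0  # correction inflates p in the F > 1 regime
        assert row["p_gg"] >= row["p_unc"]

    def test_missing_cell_excludes_subject_listwise(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(2, 5, 3))
        table = make_table(y, ("young", "pd"))
        table = table.drop(table[(table.subject_id == "s001") & (table.condition == "CDT")].index)
        res = mixed_anova(table, "m", covariate=None)
        assert res.excluded_subjects == ("s001",)
        assert res.n_subjects == 9

    def test_requires_two_groups(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(1, 6, 3))
        with pytest.raises(ValueError, match="groups"):
            mixed_anova(make_table(y, ("young",)), "m", covariate=None)

    def test_covariate_adjustment_removes_common_slope(self):
        rng = np.random.default_rng(5)
        speeds = rng.uniform(0.8, 1.4, size=(2, 10, 3))
        y = 2.0 + 3.0 * speeds + rng.normal(0, 0.01, speeds.shape)
        table = make_table(y, ("young", "pd"), speeds=speeds)
        adj = _adjust_for_covariate(table, "gait_speed", "per_cell")
        cov = table["gait_speed"] - table["gait_speed"].mean()
        assert abs(np.corrcoef(adj, cov)[0, 1]) < 0.05


class TestBonferroniPosthoc:
    @staticmethod
    def _table(n_groups=2, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        groups = ("young", "older", "pd", "stroke", "ms", "lbp")[:n_groups]
        y = rng.normal(size=(n_groups, 8, 3))
        y[0] += shift
        return make_table(y, groups)

    def test_two_levels_adjustment_is_identity(self):
        ph = bonferroni_posthoc(self._table(), "m", "group", force=True)
        assert len(ph) == 1
        assert ph["p_bonf"].iloc[0] == pytest.approx(ph["p_unc"].iloc[0])

    def test_six_groups_give_fifteen_pairs(self):
        ph = bonferroni_posthoc(self._table(6), "m", "group", force=True)
        assert len(ph) == 15

    def test_adjusted_p_capped_at_one(self):
        ph = bonferroni_posthoc(self._table(6), "m", "group", force=True)
        assert (ph["p_bonf"] <= 1.0).all()
        assert (ph["p_bonf"] >= ph["p_unc"]).all()

    def test_skipped_when_main_effect_not_significant(self):
        table = self._table()
        res = mixed_anova(table, "m", covariate=None)
        assert res.p("group") > 0.05  # null data
        ph = bonferroni_posthoc(table, "m", "group", res)
        assert ph.empty
        assert not bonferroni_posthoc(table, "m", "group", res, force=True).empty

    def test_condition_factor_uses_paired_tests(self):
        table = self._table()
        wide = table.pivot_table(index="subject_id", columns="condition", values="value")
        from scipy.stats import ttest_rel

        t_expected, _ = ttest_rel(wide["CDT"], wide["SDT"])
        ph = bonferroni_posthoc(table, "m", "condition", force=True).set_index(
            ["level_a", "level_b"]
        )
        assert ph.loc[("CDT", "SDT"), "t"] == pytest.approx(t_expected)
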