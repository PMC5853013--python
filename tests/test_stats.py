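"""Statistics layer: cross-implementation Shapiro-Wilk oracle, hand
sums-of-squares ANOVA oracles, Bonferroni arithmetic, t-test edge cases and
the bundled clinical-rating fixtures."""

import math

import numpy as np
import pandas as pd
import pytest

from pdmotor import stats as cst

LOCATIONS = ("index", "thumb", "metacarpus", "wrist", "arm")


def long_table(values_pd=None, values_hs=None, index="total_power",
               task="finger_tapping", locations=LOCATIONS):
    """Cohort table from arrays shaped (subjects, states, locations) for PD
    and (subjects, locations) for healthy."""
    rows = []
    if values_pd is not None:
        for s in range(values_pd.shape[0]):
            for i, state in enumerate(("OFF", "ON")):
                for j, loc in enumerate(locations):
                    rows.append((f"P{s}", "PD", state, task, loc, index,
                                 values_pd[s, i, j]))
    if values_hs is not None:
        for s in range(values_hs.shape[0]):
            for j, loc in enumerate(locations):
                rows.append((f"H{s}", "HS", "HS", task, loc, index,
                             values_hs[s, j]))
    return pd.DataFrame(rows, columns=cst.COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# Shapiro screening
# ---------------------------------------------------------------------------

class TestShapiroScreen:
    # Reference W/p computed independently with R's shapiro.test on the
    # identical fixed-seed vectors (default_rng(42): normal then lognormal).
    R_NORMAL_W = 0.9212486549
    R_LOGNORMAL_W = 0.8347887541
    R_LOGNORMAL_P = 0.0239432620

    @staticmethod
    def _single_cell_table(values):
        rows = [("S%d" % i, "PD", "OFF", "finger_tapping", "index",
                 "total_power", v) for i, v in enumerate(values)]
        return pd.DataFrame(rows, columns=cst.COHORT_COLUMNS)

    def test_matches_r_reference_to_1e6(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=12)
        rep = cst.shapiro_screen(self._single_cell_table(x),
                                 "total_power", "finger_tapping")
        assert rep.iloc[0]["W"] == pytest.approx(self.R_NORMAL_W, abs=1e-6)

    def test_heavy_tailed_sample_flagged_non_normal(self):
        rng = np.random.default_rng(42)
        rng.normal(size=12)  # advance the stream past the normal draw
        y = rng.lognormal(mean=0.0, sigma=1.2, size=12)
        rep = cst.shapiro_screen(self._single_cell_table(y),
                                 "total_power", "finger_tapping")
        assert rep.iloc[0]["W"] == pytest.approx(self.R_LOGNORMAL_W, abs=1e-6)
        assert rep.iloc[0]["p"] == pytest.approx(self.R_LOGNORMAL_P, abs=1e-6)
        assert rep.iloc[0]["p"] < 0.05

    def test_constant_and_tiny_cells_marked_untestable(self):
        rep = cst.shapiro_screen(self._single_cell_table([3.0, 3.0, 3.0, 3.0]),
                                 "total_power", "finger_tapping")
        assert not rep.iloc[0]["testable"]
        rep = cst.shapiro_screen(self._single_cell_table([1.0, 2.0]),
                                 "total_power", "finger_tapping")
        assert not rep.iloc[0]["testable"]


# ---------------------------------------------------------------------------
# ANOVA against hand sums-of-squares oracles
# ---------------------------------------------------------------------------

def rm2way_oracle(Y):
    """Hand decomposition of a fully within-subject two-factor design.

    Y has shape (subjects, A, B); each effect is tested against its own
    effect-by-subject interaction.
    Returns {effect: (F, df1, df2)}.
    """
    S, A, B = Y.shape
    grand = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mS = Y.mean(axis=(1, 2))
    mAB = Y.mean(axis=0)
    mAS = Y.mean(axis=2)  # (S, A)
    mBS = Y.mean(axis=1)  # (S, B)

    ss_a = S * B * np.sum((mA - grand) ** 2)
    ss_b = S * A * np.sum((mB - grand) ** 2)
    ss_ab = S * np.sum((mAB - mA[:, None] - mB[None, :] + grand) ** 2)
    ss_as = B * np.sum((mAS - mA[None, :] - mS[:, None] + grand) ** 2)
    ss_bs = A * np.sum((mBS - mB[None, :] - mS[:, None] + grand) ** 2)
    resid = (Y - mAB[None] - mAS[:, :, None] - mBS[:, None, :]
             + mA[None, :, None] + mB[None, None, :] + mS[:, None, None]
             - grand)
    ss_abs = np.sum(resid ** 2)

    out = {}
    out["state"] = ((ss_a / (A - 1)) / (ss_as / ((A - 1) * (S - 1))),
                    A - 1, (A - 1) * (S - 1))
    out["location"] = ((ss_b / (B - 1)) / (ss_bs / ((B - 1) * (S - 1))),
                       B - 1, (B - 1) * (S - 1))
    df_int = (A - 1) * (B - 1)
    df_err = (A - 1) * (B - 1) * (S - 1)
    out["state x location"] = ((ss_ab / df_int) / (ss_abs / df_err),
                               df_int, df_err)
    return out


def mixed_oracle(groups):
    """Hand decomposition of a balanced mixed design.

    ``groups`` is a list of arrays shaped (subjects, B): one between-subject
    group each, all with the same number of within levels B.
    """
    B = groups[0].shape[1]
    all_y = np.concatenate(groups, axis=0)
    N = all_y.shape[0]
    G = len(groups)
    grand = all_y.mean()

    m_group = [g.mean() for g in groups]
    ss_between = B * sum(g.shape[0] * (mg - grand) ** 2
                         for g, mg in zip(groups, m_group))
    m_subj = all_y.mean(axis=1)
    subj_group_mean = np.concatenate(
        [np.full(g.shape[0], mg) for g, mg in zip(groups, m_group)])
    ss_subj_within = B * np.sum((m_subj - subj_group_mean) ** 2)

    mB = all_y.mean(axis=0)
    # within-factor SS weighted by group sizes (cell-mean based, balanced)
    ss_b = 0.0
    ss_gb = 0.0
    for g, mg in zip(groups, m_group):
        cell = g.mean(axis=0)
        ss_gb += g.shape[0] * np.sum((cell - mg - mB + grand) ** 2)
    ss_b = N * np.sum((mB - grand) ** 2)
    ss_total = np.sum((all_y - grand) ** 2)
    ss_err = ss_total - ss_between - ss_subj_within - ss_b - ss_gb

    out = {}
    out["group"] = ((ss_between / (G - 1)) / (ss_subj_within / (N - G)),
                    G - 1, N - G)
    df_err = (N - G) * (B - 1)
    out["location"] = ((ss_b / (B - 1)) / (ss_err / df_err), B - 1, df_err)
    out["group x location"] = ((ss_gb / ((G - 1) * (B - 1)))
                               / (ss_err / df_err), (G - 1) * (B - 1), df_err)
    return out


class TestRmAnova:
    def test_matches_hand_sums_of_squares_on_small_fixture(self):
        # 4 subjects x 2 states x 2 locations, values constructed by hand
        Y = np.array([
            [[3.0, 5.0], [4.0, 7.0]],
            [[2.0, 4.0], [5.0, 6.0]],
            [[6.0, 8.0], [7.0, 12.0]],
            [[1.0, 3.0], [2.0, 2.0]],
        ])
        df = long_table(values_pd=Y, locations=("index", "wrist"))
        res = cst.rm_anova_state_by_location(df, "total_power",
                                             "finger_tapping")
        oracle = rm2way_oracle(Y)
        for effect, (f, df1, df2) in oracle.items():
            got = res.effect(effect)
            assert got["F"] == pytest.approx(f, abs=1e-8)
            assert (got["df1"], got["df2"]) == (df1, df2)

    def test_matches_oracle_on_random_five_location_design(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(12, 2, 5))
        df = long_table(values_pd=Y)
        res = cst.rm_anova_state_by_location(df, "total_power",
                                             "finger_tapping")
        oracle = rm2way_oracle(Y)
        for effect, (f, _, _) in oracle.items():
            assert res.effect(effect)["F"] == pytest.approx(f, abs=1e-8)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(8, 2, 5))
        a = cst.rm_anova_state_by_location(long_table(values_pd=Y),
                                           "total_power", "finger_tapping")
        b = cst.rm_anova_state_by_location(long_table(values_pd=Y + 137.0),
                                           "total_power", "finger_tapping")
        pd.testing.assert_frame_equal(a.effects, b.effects, atol=1e-9,
                                      check_exact=False)

    def test_incomplete_subjects_dropped_then_too_few_rejected(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(3, 2, 5))
        df = long_table(values_pd=Y)
        df = df[~((df["subject_id"] == "P0") & (df["location"] == "arm")
                  & (df["state"] == "ON"))]
        with pytest.raises(ValueError, match=">= 3"):
            cst.rm_anova_state_by_location(df, "total_power", "finger_tapping")


class TestMixedAnova:
    def test_matches_hand_oracle_on_balanced_2x2(self):
        off = np.array([[3.0, 5.0], [4.0, 7.0], [6.0, 9.0], [2.0, 2.0]])
        hs = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [2.0, 3.0]])
        df = long_table(values_pd=np.stack([off, off], axis=1),
                        values_hs=hs, locations=("index", "wrist"))
        df = df[df["state"].isin(("OFF", "HS"))]
        res = cst.mixed_anova_group_by_location(df, "total_power",
                                                "finger_tapping", ("OFF", "HS"))
        oracle = mixed_oracle([hs, off])  # alphabetical group order irrelevant
        for effect, (f, df1, df2) in oracle.items():
            got = res.effect(effect)
            assert got["F"] == pytest.approx(f, abs=1e-8)
            assert (got["df1"], got["df2"]) == (df1, df2)

    def test_identical_groups_give_zero_between_f(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(6, 5))
        pd_vals = np.stack([base, base], axis=1)
        df = long_table(values_pd=pd_vals, values_hs=base.copy())
        res = cst.mixed_anova_group_by_location(df, "total_power",
                                                "finger_tapping", ("OFF", "HS"))
        assert res.effect("group")["F"] == pytest.approx(0.0, abs=1e-10)
        assert res.effect("group")["p"] == pytest.approx(1.0, abs=1e-9)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(11)
        df = long_table(values_pd=rng.normal(size=(5, 2, 5)),
                        values_hs=rng.normal(size=(2, 5)))
        with pytest.raises(ValueError, match="need >= 3"):
            cst.mixed_anova_group_by_location(df, "total_power",
                                              "finger_tapping", ("OFF", "HS"))


# ---------------------------------------------------------------------------
# Bonferroni, post hoc, t-tests, correlation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("alpha,n,expected", [
    (0.05, 5, 0.01),   # five sensor locations
    (0.05, 1, 0.05),
    (0.05, 2, 0.025),  # two wrists in the rigidity montage
])
def test_bonferroni_threshold(alpha, n, expected):
    assert cst.bonferroni_threshold(alpha, n) == pytest.approx(expected)


def test_bonferroni_rejects_zero_comparisons():
    with pytest.raises(ValueError):
        cst.bonferroni_threshold(0.05, 0)


class TestPostHoc:
    def test_only_location_with_true_effect_is_flagged(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(12, 2, 5))
        Y[:, 0, 0] += 4.0  # strong OFF-only shift at the index finger
        df = long_table(values_pd=Y)
        ph = cst.posthoc_by_location(df, "total_power", "finger_tapping",
                                     ("OFF", "ON"))
        assert (ph["threshold"] == 0.01).all()
        flagged = set(ph[ph["significant"]]["location"])
        assert flagged == {"index"}

    def test_vs_healthy_uses_independent_tests(self):
        rng = np.random.default_rng(13)
        df = long_table(values_pd=rng.normal(size=(12, 2, 5)),
                        values_hs=rng.normal(size=(13, 5)))
        ph = cst.posthoc_by_location(df, "total_power", "finger_tapping",
                                     ("OFF", "HS"))
        assert len(ph) == 5
        assert (ph["df"] == 23).all()  # 12 + 13 - 2 pooled dof


class TestTTests:
    def test_paired_identical_samples(self):
        res = cst.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_paired_constant_difference_flagged_degenerate(self):
        res = cst.paired_t([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        assert res.degenerate
        assert math.isinf(res.t)

    def test_independent_matches_pooled_variance_oracle(self):
        x = np.array([5.1, 4.9, 5.0, 5.2])
        y = np.array([6.0, 6.2, 5.9, 6.1])
        res = cst.independent_t(x, y)
        # pooled-variance formula by hand
        sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) \
            / (x.size + y.size - 2)
        t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / x.size + 1 / y.size))
        assert res.t == pytest.approx(t_hand, abs=1e-8)
        from scipy import stats as sst
        p_hand = 2 * sst.t.sf(abs(t_hand), x.size + y.size - 2)
        assert res.p == pytest.approx(p_hand, abs=1e-8)

    def test_welch_option_changes_dof(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [10.0, 30.0, 20.0]
        res = cst.independent_t(x, y, equal_var=False)
        assert res.df != len(x) + len(y) - 2

    def test_scale_and_shift_invariance_of_t(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=10), rng.normal(size=10)
        base = cst.paired_t(x, y)
        scaled = cst.paired_t(5.0 * x + 3.0, 5.0 * y + 3.0)
        assert scaled.t == pytest.approx(base.t, abs=1e-10)
        assert scaled.p == pytest.approx(base.p, abs=1e-10)


class TestRSquared:
    def test_perfectly_linear_pairs(self):
        x = np.arange(10.0)
        assert cst.r_squared(x, 3.0 * x - 7.0) == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        assert math.isnan(cst.r_squared(np.ones(5), np.arange(5.0)))

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(scale=math.sqrt(1 - 0.49), size=12)
        r2 = cst.r_squared(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        hand = cov ** 2 / (x.var() * y.var())
        assert r2 == pytest.approx(hand, abs=1e-10)


# ---------------------------------------------------------------------------
# Clinical-rating fixtures
# ---------------------------------------------------------------------------

class TestUpdrsFixtures:
    def test_item_scores_are_integers_zero_to_four(self):
        for which in ("bradykinesia", "rigidity"):
            df = cst.load_updrs_table(which)
            assert len(df) == 14
            items = df.drop(columns="subject_id")
            assert ((items >= 0) & (items <= 4)).all().all()
            assert (items == items.astype(int)).all().all()

    def test_spot_values_match_printed_ratings(self):
        tap_off = cst.updrs_item_scores("finger_tapping", "OFF")
        assert tap_off["S1"] == 3 and tap_off["S7"] == 1
        pro_off = cst.updrs_item_scores("pronosupination", "OFF")
        assert pro_off["S6"] == 4
        rig_on_left = cst.updrs_item_scores("rigidity", "ON", side="left")
        assert rig_on_left["S8"] == 2 and rig_on_left["S9"] == 0

    def test_patient_table_metadata(self):
        df = cst.load_updrs_table("patients")
        assert len(df) == 14
        assert df.set_index("subject_id").loc["S6", "updrs3_total_off"] == 65

    def test_correlation_against_fixture_scores(self):
        # index values proportional to the OFF tapping score recover r^2 ~ 1
        scores = cst.updrs_item_scores("finger_tapping", "OFF")
        rows = [(s, "PD", "OFF", "finger_tapping", "index", "total_time",
                 10.0 + 2.0 * v) for s, v in scores.items()]
        df = pd.DataFrame(rows, columns=cst.COHORT_COLUMNS)
        r2 = cst.r_squared_vs_updrs(df, "total_time", "finger_tapping",
                                    "OFF", "index")
        assert r2 == pytest.approx(1.0)


def test_cohort_table_duplicate_keys_rejected():
    rows = [("P1", "PD", "OFF", "finger_tapping", "index", "total_power", 1.0)] * 2
    df = pd.DataFrame(rows, columns=cst.COHORT_COLUMNS)
    with pytest.raises(ValueError, match="duplicate"):
        cst.validate_cohort_table(df)
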