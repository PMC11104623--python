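"""Permutation t-test, mixed ANOVA, Holm correction, learning trend."""
import numpy as np
import pandas as pd
import pytest

from gazehmi import (holm_correct, learning_trend_test, perm_mixed_anova,
                     perm_ttest)
from gazehmi.exceptions import DegenerateTestError, UnbalancedDesignError
from gazehmi.stats import _mixed_anova_F


class TestPermTtest:
    def test_identical_pairs_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = perm_ttest(a, a, paired=True, n_perm=499, seed=0)
        assert r.p_value == 1.0
        assert r.statistic == 0.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=15), rng.normal(size=15)
        r1 = perm_ttest(a, b, n_perm=499, seed=7)
        r2 = perm_ttest(a, b, n_perm=499, seed=7)
        assert r1.p_value == r2.p_value

    def test_p_in_unit_interval_never_zero(self):
        rng = np.random.default_rng(6)
        a = rng.normal(3.0, 1.0, 25)  # very strong effect
        r = perm_ttest(a, 0.0, n_perm=999, seed=1)
        assert 0.0 < r.p_value <= 1.0
        assert r.p_value == pytest.approx(1.0 / 1000.0)

    def test_two_sample_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            perm_ttest(np.ones(5), np.full(5, 2.0), paired=False,
                       n_perm=99, seed=0)

    def test_power_on_shifted_groups(self):
        rng = np.random.default_rng(8)
        hits = 0
        for i in range(100):
            a = rng.normal(0.0, 1.0, 20)
            b = rng.normal(1.5, 1.0, 20)
            r = perm_ttest(a, b, paired=False, n_perm=199, seed=i)
            hits += r.p_value <= 0.05
        assert hits / 100 > 0.9

    def test_one_sided_alternatives(self):
        rng = np.random.default_rng(9)
        a = rng.normal(1.0, 1.0, 30)
        up = perm_ttest(a, 0.0, alternative="greater", n_perm=499, seed=3)
        down = perm_ttest(a, 0.0, alternative="less", n_perm=499, seed=3)
        assert up.p_value < 0.05 < down.p_value


def _long_frame(y, groups, levels_b, levels_c):
    rows = []
    for s in range(y.shape[0]):
        for j, bj in enumerate(levels_b):
            for k, ck in enumerate(levels_c):
                rows.append({"participant": s, "order": f"g{groups[s]}",
                             "condition": bj, "phase": ck,
                             "value": y[s, j, k]})
    return pd.DataFrame(rows)


def _ols_oracle(y, groups):
    """Independent route: recover every mixed-model SS from ordinary
    saturated OLS decompositions on the balanced data (statsmodels)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    N, b, c = y.shape
    a = len(np.unique(groups))
    n_per = N // a
    df = _long_frame(y, groups, [f"b{j}" for j in range(b)],
                     [f"c{k}" for k in range(c)])
    df["A"] = df["order"]
    df["S"] = df["participant"].astype(str)
    full = ols("value ~ C(S)*C(condition)*C(phase)", data=df).fit()
    t_full = sm.stats.anova_lm(full, typ=1)
    fixed = ols("value ~ C(A)*C(condition)*C(phase)", data=df).fit()
    t_fix = sm.stats.anova_lm(fixed, typ=1)

    def ss(table, term):
        return float(table.loc[term, "sum_sq"])

    out = {}
    ss_A = ss(t_fix, "C(A)")
    ss_S = ss(t_full, "C(S)") - ss_A
    out["between"] = (ss_A / (a - 1)) / (ss_S / (a * (n_per - 1)))
    ss_B = ss(t_fix, "C(condition)")
    ss_AB = ss(t_fix, "C(A):C(condition)")
    ss_BS = ss(t_full, "C(S):C(condition)") - ss_AB
    df_BS = a * (n_per - 1) * (b - 1)
    out["within1"] = (ss_B / (b - 1)) / (ss_BS / df_BS)
    out["between:within1"] = (ss_AB / ((a - 1) * (b - 1))) / (ss_BS / df_BS)
    if c > 1:
        ss_C = ss(t_fix, "C(phase)")
        ss_AC = ss(t_fix, "C(A):C(phase)")
        ss_CS = ss(t_full, "C(S):C(phase)") - ss_AC
        df_CS = a * (n_per - 1) * (c - 1)
        out["within2"] = (ss_C / (c - 1)) / (ss_CS / df_CS)
        out["between:within2"] = (ss_AC / ((a - 1) * (c - 1))) / (ss_CS / df_CS)
        ss_BC = ss(t_fix, "C(condition):C(phase)")
        ss_ABC = ss(t_fix, "C(A):C(condition):C(phase)")
        ss_BCS = ss(t_full, "C(S):C(condition):C(phase)") - ss_ABC
        df_BCS = a * (n_per - 1) * (b - 1) * (c - 1)
        out["within1:within2"] = (ss_BC / ((b - 1) * (c - 1))) / (ss_BCS / df_BCS)
        out["between:within1:within2"] = (
            ss_ABC / ((a - 1) * (b - 1) * (c - 1))) / (ss_BCS / df_BCS)
    return out


class TestMixedAnova:
    def test_all_cells_equal(self):
        y = np.full((6, 2, 2), 3.0)
        groups = np.array([0, 0, 0, 1, 1, 1])
        table = _long_frame(y, groups, ["m", "a"], ["early", "late"])
        res = perm_mixed_anova(table, within=("condition", "phase"),
                               n_perm=99, seed=0)
        for eff in res.effects.values():
            assert eff["F"] == 0.0
            assert eff["p_perm"] == 1.0

    def test_f_matches_saturated_ols_decomposition_two_within(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(8, 2, 3))
        groups = np.repeat([0, 1], 4)
        mine = _mixed_anova_F(y, groups, 2)
        oracle = _ols_oracle(y, groups)
        for eff, F in oracle.items():
            assert mine[eff][0] == pytest.approx(F, rel=1e-8), eff

    def test_f_matches_pingouin_one_within(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        y = rng.normal(size=(10, 3, 1))
        groups = np.repeat([0, 1], 5)
        mine = _mixed_anova_F(y, groups, 2)
        df = _long_frame(y, groups, ["x", "y", "z"], ["only"])
        res = pg.mixed_anova(data=df, dv="value", within="condition",
                             subject="participant", between="order")
        res = res.set_index("Source")
        assert mine["between"][0] == pytest.approx(
            float(res.loc["order", "F"]), rel=1e-6)
        assert mine["within1"][0] == pytest.approx(
            float(res.loc["condition", "F"]), rel=1e-6)
        assert mine["between:within1"][0] == pytest.approx(
            float(res.loc["Interaction", "F"]), rel=1e-6)

    def test_small_hand_fixture(self):
        """2 groups x 3 participants x 2 conditions with integer values;
        the textbook decomposition is reproduced exactly."""
        y = np.array([[[1.0], [3.0]],
                      [[2.0], [5.0]],
                      [[0.0], [4.0]],
                      [[3.0], [3.0]],
                      [[4.0], [5.0]],
                      [[5.0], [4.0]]])
        groups = np.array([0, 0, 0, 1, 1, 1])
        eff = _mixed_anova_F(y, groups, 2)
        oracle = _ols_oracle(y, groups)
        for name, F in oracle.items():
            assert eff[name][0] == pytest.approx(F, rel=1e-8)
        # hand check of the within effect: condition means 2.5 vs 4.0,
        # SS_B = 12*(0.75^2) = 6.75; error SS from subject-by-condition
        assert eff["within1"][1] == 1 and eff["within1"][2] == 4

    def test_unbalanced_design_raises(self):
        y = np.zeros((5, 2, 2))
        groups = np.array([0, 0, 0, 1, 1])
        table = _long_frame(y, groups, ["m", "a"], ["e", "l"])
        with pytest.raises(UnbalancedDesignError):
            perm_mixed_anova(table, within=("condition", "phase"),
                             n_perm=9, seed=0)
        table2 = _long_frame(np.zeros((4, 2, 2)), np.repeat([0, 1], 2),
                             ["m", "a"], ["e", "l"])
        with pytest.raises(UnbalancedDesignError):
            perm_mixed_anova(table2.drop(index=0),
                             within=("condition", "phase"), n_perm=9, seed=0)

    def test_detects_injected_within_effect(self):
        rng = np.random.default_rng(12)
        hits = 0
        for i in range(30):
            y = rng.normal(size=(12, 2, 2))
            y[:, :, 1] += 1.0  # phase shift
            groups = np.repeat([0, 1], 6)
            table = _long_frame(y, groups, ["m", "a"], ["e", "l"])
            res = perm_mixed_anova(table, within=("condition", "phase"),
                                   n_perm=199, seed=i)
            hits += res.effects["phase"]["p_perm"] < 0.05
        assert hits >= 27

    def test_permutation_p_reproducible(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=(8, 2, 2))
        groups = np.repeat([0, 1], 4)
        table = _long_frame(y, groups, ["m", "a"], ["e", "l"])
        r1 = perm_mixed_anova(table, within=("condition", "phase"),
                              n_perm=99, seed=21)
        r2 = perm_mixed_anova(table, within=("condition", "phase"),
                              n_perm=99, seed=21)
        assert r1.effects == r2.effects


class TestHolm:
    def test_hand_computed_example(self):
        adj, reject = holm_correct([0.01, 0.04, 0.03], alpha=0.05)
        assert adj == pytest.approx([0.03, 0.06, 0.06])
        assert list(reject) == [True, False, False]

    def test_single_p_unchanged(self):
        adj, _ = holm_correct([0.2])
        assert adj[0] == pytest.approx(0.2)

    def test_all_ones(self):
        adj, reject = holm_correct([1.0, 1.0, 1.0])
        assert np.all(adj == 1.0)
        assert not reject.any()

    def test_between_raw_and_bonferroni(self, rng):
        for _ in range(20):
            p = rng.random(6)
            adj, _ = holm_correct(p)
            bonf = np.minimum(p * p.size, 1.0)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= bonf + 1e-12)


def _outcome_frame(participants, n_trials, prob_fn, rng):
    rows = []
    for pid in range(participants):
        t = np.arange(1, n_trials + 1)
        tc = t - n_trials // 2
        p = prob_fn(tc)
        y = rng.random(n_trials) < p
        rows.append(pd.DataFrame({"participant": pid, "trial_centered": tc,
                                  "outcome": y.astype(int)}))
    return pd.concat(rows, ignore_index=True)


class TestLearningTrend:
    def test_improving_cohort_detected(self, rng):
        from scipy.special import expit
        df = _outcome_frame(8, 100, lambda tc: expit(0.05 * tc), rng)
        res = learning_trend_test(df, n_perm=499, seed=2)
        assert res.p_value < 0.01
        assert (res.slopes["slope"] > 0).all()

    def test_flat_cohort_not_detected(self, rng):
        df = _outcome_frame(8, 100, lambda tc: np.full_like(tc, 0.5,
                                                            dtype=float), rng)
        res = learning_trend_test(df, n_perm=499, seed=3)
        assert res.p_value > 0.05

    def test_separated_participant_uses_fallback(self):
        tc = np.arange(-50, 50)
        df = pd.DataFrame({
            "participant": np.repeat([0, 1], tc.size),
            "trial_centered": np.tile(tc, 2),
            "outcome": np.concatenate([(tc >= 0).astype(int),   # separation
                                       np.ones(tc.size, int)]),  # all-1
        })
        res = learning_trend_test(df, n_perm=199, seed=4)
        assert res.slopes["fallback"].any()
        sep = res.slopes.set_index("participant")
        assert sep.loc[0, "slope"] > 0.0
        assert np.isfinite(sep.loc[1, "slope"])

    def test_reproducible(self, rng):
        from scipy.special import expit
        df = _outcome_frame(5, 60, lambda tc: expit(0.02 * tc), rng)
        r1 = learning_trend_test(df, n_perm=199, seed=9)
        r2 = learning_trend_test(df, n_perm=199, seed=9)
        assert r1.p_value == r2.p_value
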