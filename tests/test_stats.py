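import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ddmeta.stats import (
    cronbach_alpha,
    lisas,
    lisas_table,
    mixed_anova,
    power_simulation,
)


class TestLisas:
    def test_zero_error_reduces_to_mean_rt(self):
        assert lisas(0.6, 0.0, 0.15, 0.4) == pytest.approx(0.6)

    def test_formula_value(self):
        assert lisas(0.6, 0.2, 0.15, 0.4) == pytest.approx(0.675)

    def test_never_erring_subject_flagged(self):
        assert lisas(0.55, 0.0, 0.1, 0.0) == pytest.approx(0.55)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        m=st.floats(0.2, 2.0),
        pe=st.floats(0.0, 0.5),
        s_rt=st.floats(0.01, 0.5),
        s_pe=st.floats(0.05, 0.5),
        c=st.floats(0.1, 10),
    )
    def test_time_scale_covariance(self, m, pe, s_rt, s_pe, c):
        assert lisas(c * m, pe, c * s_rt, s_pe) == pytest.approx(c * lisas(m, pe, s_rt, s_pe))

    def test_slower_less_accurate_condition_scores_worse(self, rng):
        rows = []
        for cond, (mu, pc) in {"good": (0.5, 0.95), "bad": (0.8, 0.7)}.items():
            for i in range(300):
                rows.append(
                    dict(
                        subject="s01",
                        cond=cond,
                        rt=max(rng.normal(mu, 0.1), 0.1),
                        correct=bool(rng.random() < pc),
                    )
                )
        tab = lisas_table(pd.DataFrame(rows), ["cond"]).set_index("cond")
        assert tab.loc["bad", "lisas"] > tab.loc["good", "lisas"]


class TestMixedAnova:
    def _frame(self, rng, n_per=12, shift=0.0, within_levels=("w1", "w2")):
        rows = []
        for s in range(2 * n_per):
            g = "action" if s < n_per else "state"
            base = rng.normal(shift if g == "action" else 0.0, 1.0)
            for w in within_levels:
                rows.append(dict(subject=f"s{s:02d}", group=g, cond=w, y=base + rng.normal(0, 0.3)))
        return pd.DataFrame(rows)

    def test_constant_dv_gives_zero_f(self, rng):
        df = self._frame(rng)
        df["y"] = 1.0
        tab = mixed_anova(df, "y", within=["cond"], between="group")
        assert (tab["F"] == 0).all()

    def test_two_level_within_has_epsilon_one(self, rng):
        tab = mixed_anova(self._frame(rng), "y", within=["cond"], between="group")
        assert tab.query("effect == 'cond'")["gg_eps"].iloc[0] == 1.0

    def test_between_only_reduces_to_t_squared(self, rng):
        df = self._frame(rng, shift=0.8, within_levels=("only",))
        tab = mixed_anova(df, "y", within=["cond"], between="group")
        means = df.groupby(["subject", "group"])["y"].mean().reset_index()
        t = sps.ttest_ind(
            means.query("group=='action'")["y"], means.query("group=='state'")["y"]
        )
        f_row = tab.query("effect == 'group'").iloc[0]
        assert f_row["F"] == pytest.approx(t.statistic**2, abs=1e-10)
        assert f_row["p"] == pytest.approx(t.pvalue, abs=1e-12)

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = []
        for s in range(20):
            g = "A" if s < 10 else "B"
            base = rng.normal(0.2 if g == "A" else 0.0, 0.5)
            for j, w in enumerate(["c1", "c2", "c3"]):
                rows.append(dict(subject=f"s{s}", grp=g, cond=w, y=base + 0.1 * j + rng.normal(0, 0.2)))
        df = pd.DataFrame(rows)
        mine = mixed_anova(df, "y", within=["cond"], between="grp")
        ref = pg.mixed_anova(data=df, dv="y", within="cond", subject="subject", between="grp", effsize="ng2")
        for my_eff, ref_eff in (("grp", "grp"), ("cond", "cond"), ("cond * grp", "Interaction")):
            m = mine[mine["effect"] == my_eff].iloc[0]
            r = ref[ref["Source"] == ref_eff].iloc[0]
            assert m["F"] == pytest.approx(r["F"], rel=1e-9)
            assert m["eta_g_sq"] == pytest.approx(r["ng2"], rel=1e-6, abs=1e-9)

    def test_detects_planted_group_shift(self, rng):
        hits = 0
        n_reps = 40
        for k in range(n_reps):
            r = np.random.default_rng(k)
            df = self._frame(r, n_per=30, shift=1.0)
            tab = mixed_anova(df, "y", within=["cond"], between="group")
            hits += tab.query("effect == 'group'")["p"].iloc[0] < 0.05
        assert hits >= 0.85 * n_reps  # analytic power for d=1 at n=30/30 is ~0.97

    def test_ges_bounded_and_ss_positive(self, rng):
        tab = mixed_anova(self._frame(rng, shift=0.5), "y", within=["cond"], between="group")
        assert ((tab["eta_g_sq"] >= 0) & (tab["eta_g_sq"] <= 1)).all()
        assert (tab["ss"] >= 0).all()

    def test_incomplete_subject_dropped_with_warning(self, rng):
        df = self._frame(rng)
        df = df.drop(df[(df["subject"] == "s00") & (df["cond"] == "w2")].index)
        with pytest.warns(UserWarning, match="incomplete"):
            mixed_anova(df, "y", within=["cond"], between="group")


class TestCronbachAlpha:
    def test_duplicated_item_gives_alpha_one(self, rng):
        x = rng.standard_normal(500)
        assert cronbach_alpha(np.c_[x, x]) == pytest.approx(1.0)

    def test_spearman_brown_equivalence_at_r049(self, rng):
        n = 400_000
        f = rng.standard_normal(n)
        lam = np.sqrt(0.49)
        items = np.c_[
            lam * f + np.sqrt(1 - 0.49) * rng.standard_normal(n),
            lam * f + np.sqrt(1 - 0.49) * rng.standard_normal(n),
        ]
        assert cronbach_alpha(items) == pytest.approx(2 * 0.49 / 1.49, abs=0.01)

    def test_independent_items_near_zero(self, rng):
        assert abs(cronbach_alpha(rng.standard_normal((100_000, 6)))) < 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 3)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.random.randn(5, 1))


class TestPowerSimulation:
    @staticmethod
    def _normal_pool(n, rng):
        return rng.normal(12, 5, n)

    def test_null_correlation_rejects_at_alpha(self):
        pc = power_simulation(self._normal_pool, [0.0], n_sims=3000, seed=3)
        assert pc.power[0] == pytest.approx(0.05, abs=3 * pc.mc_se[0] + 0.005)
        assert pc.power_minus_alpha[0] == pytest.approx(pc.power[0] - 0.05)

    def test_power_monotone_in_correlation(self):
        pc = power_simulation(self._normal_pool, [0.1, 0.3, 0.5], n_sims=1500, seed=4)
        mc = 2 * np.max(pc.mc_se)
        assert pc.power[1] > pc.power[0] - mc
        assert pc.power[2] > pc.power[1] - mc

    def test_pool_smaller_than_groups_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(lambda n, rng: rng.normal(0, 1, 40), [0.3], n_sims=10, n_per_group=30)
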