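import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pstpupil.stats import (DesignError, anova_total_ss, cousineau_morey,
                            difference_score, mixed_rm_anova, paired_t,
                            two_sample_t)

from oracles import anova_oracle


def make_long(rng, a=2, n=3, wsizes=(2, 3), names=("time", "task")):
    rows = []
    for g in range(a):
        for s in range(n):
            for idx in np.ndindex(*wsizes):
                row = {"subject": f"g{g}s{s}", "group": f"g{g}",
                       "value": float(rng.normal())}
                for w, k in zip(names, idx):
                    row[w] = f"{w}{k}"
                rows.append(row)
    return pd.DataFrame(rows)


class TestCousineauMorey:
    def test_pure_subject_offsets_vanish(self):
        out = cousineau_morey(np.array([[10.0, 12.0], [20.0, 22.0]]))
        assert np.allclose(out["within_subject_sem"], 0.0)
        assert out["mean"].tolist() == [15.0, 17.0]

    def test_single_condition_rejected(self):
        with pytest.raises(DesignError):
            cousineau_morey(np.array([[1.0], [2.0]]))

    def test_matches_hand_computation(self):
        m = np.array([[1.0, 4.0, 5.0], [2.0, 6.0, 4.0], [0.0, 5.0, 9.0]])
        norm = m - m.mean(axis=1, keepdims=True) + m.mean()
        expect = norm.std(axis=0, ddof=1) / np.sqrt(3) * np.sqrt(3 / 2)
        out = cousineau_morey(m)
        assert np.allclose(out["within_subject_sem"], expect, atol=1e-12)

    @given(offsets=st.lists(st.floats(-100, 100), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50)
    def test_invariant_to_per_subject_constants(self, offsets):
        m = np.array([[1.0, 4.0, 5.0], [2.0, 6.0, 4.0], [0.0, 5.0, 9.0]])
        shifted = m + np.asarray(offsets)[:, None]
        a = cousineau_morey(m)["within_subject_sem"].to_numpy()
        b = cousineau_morey(shifted)["within_subject_sem"].to_numpy()
        assert np.allclose(a, b, atol=1e-9)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(DesignError):
            cousineau_morey(m)


class TestMixedAnova:
    def test_all_identical_values_give_f0_p1(self):
        df = make_long(np.random.default_rng(0))
        df["value"] = 7.0
        out = mixed_rm_anova(df)
        tested = out[out["F"].notna()]
        assert (tested["F"] == 0).all()
        assert (tested["p"] == 1).all()

    def test_oracle_equivalence_toy(self):
        rng = np.random.default_rng(1)
        df = make_long(rng, a=2, n=2, wsizes=(2,), names=("time",))
        mine = mixed_rm_anova(df, within=["time"])
        oracle = anova_oracle(df, within=("time",))
        merged = mine.merge(oracle, on="effect", suffixes=("", "_o"))
        assert len(merged) == len(oracle)
        assert np.allclose(merged["F"], merged["F_o"], atol=1e-9)
        assert (merged["df_num"] == merged["df_num_o"]).all()
        assert (merged["df_den"] == merged["df_den_o"]).all()

    def test_matches_pingouin_one_within_factor(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        df = make_long(rng, a=2, n=6, wsizes=(3,), names=("task",))
        mine = mixed_rm_anova(df, within=["task"])
        ref = pg.mixed_anova(df, dv="value", within="task", subject="subject",
                             between="group")
        for src, eff in (("group", "group"), ("task", "task"),
                         ("Interaction", "group * task")):
            row = mine[mine["effect"] == eff].iloc[0]
            rrow = ref[ref["Source"] == src].iloc[0]
            assert row["F"] == pytest.approx(rrow["F"], rel=1e-9)
            assert row["p"] == pytest.approx(rrow["p_unc"], rel=1e-9)

    def test_ss_conservation(self):
        rng = np.random.default_rng(2)
        df = make_long(rng, a=2, n=4, wsizes=(2, 3))
        out = mixed_rm_anova(df)
        assert out["ss"].sum() == pytest.approx(anova_total_ss(df), rel=1e-9)

    def test_study_design_df_pattern(self):
        """n = 10 + 10 with 2 x 3 within cells reproduces the study's df."""
        rng = np.random.default_rng(3)
        df = make_long(rng, a=2, n=10, wsizes=(2, 3))
        out = mixed_rm_anova(df).set_index("effect")
        assert tuple(out.loc["task", ["df_num", "df_den"]]) == (2, 36)
        assert tuple(out.loc["time * task", ["df_num", "df_den"]]) == (2, 36)
        assert tuple(out.loc["group * time", ["df_num", "df_den"]]) == (1, 18)
        assert tuple(out.loc["group", ["df_num", "df_den"]]) == (1, 18)

    def test_f_equals_squared_paired_t_single_group(self):
        rng = np.random.default_rng(4)
        df = make_long(rng, a=1, n=8, wsizes=(2,), names=("time",))
        out = mixed_rm_anova(df, within=["time"]).set_index("effect")
        wide = df.pivot_table(index="subject", columns="time", values="value")
        t = paired_t(wide["time0"], wide["time1"])
        assert out.loc["time", "F"] == pytest.approx(t.t ** 2, rel=1e-9)
        assert out.loc["time", "p"] == pytest.approx(t.p, rel=1e-9)

    def test_unbalanced_and_incomplete_rejected(self):
        rng = np.random.default_rng(6)
        df = make_long(rng, a=2, n=3, wsizes=(2,), names=("time",))
        with pytest.raises(DesignError, match="incomplete"):
            mixed_rm_anova(df.iloc[:-1], within=["time"])
        extra = df[df["group"] == "g0"].head(2).assign(subject="g0s9")
        with pytest.raises(DesignError, match="unequal group sizes"):
            mixed_rm_anova(pd.concat([df, extra]), within=["time"])
        dup = pd.concat([df, df.head(1)])
        with pytest.raises(DesignError, match="duplicate"):
            mixed_rm_anova(dup, within=["time"])

    def test_gg_correction_reduces_p_dimensionality(self):
        rng = np.random.default_rng(8)
        df = make_long(rng, a=2, n=6, wsizes=(3,), names=("task",))
        plain = mixed_rm_anova(df, within=["task"]).set_index("effect")
        gg = mixed_rm_anova(df, within=["task"], gg_correction=True).set_index("effect")
        assert gg.loc["task", "F"] == plain.loc["task", "F"]
        assert gg.loc["task", "p"] >= plain.loc["task", "p"] - 1e-12


class TestTTests:
    def test_paired_identical_is_zero(self):
        res = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_paired_df_and_hand_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(size=5)
        res = paired_t(x, y)
        d = x - y
        expect = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert res.df == 4
        assert res.t == pytest.approx(expect, rel=1e-12)
        ref = sps.ttest_rel(x, y)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_paired_n20_gives_df19(self):
        rng = np.random.default_rng(1)
        assert paired_t(rng.normal(size=20), rng.normal(size=20)).df == 19

    def test_two_sample_pooled_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=10)
        res = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.df == 18
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_sample_identical_groups(self):
        assert two_sample_t([1.0, 2, 3], [1.0, 2, 3]).t == 0.0

    def test_zero_variance_nonzero_mean_is_infinite_t(self):
        with pytest.warns(UserWarning):
            res = paired_t([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert np.isinf(res.t) and res.p == 0.0


class TestDifferenceScore:
    def test_equals_task4_value_under_normalization(self):
        df = pd.DataFrame({
            "subject": ["s1"] * 3 + ["s2"] * 3,
            "time": ["pre"] * 6,
            "task": [2, 3, 4] * 2,
            "value": [0.0, 0.11, 2.74, 0.0, -0.3, -0.06],
        })
        out = difference_score(df)
        assert out["difference"].tolist() == [2.74, -0.06]

    def test_missing_cell_rejected(self):
        df = pd.DataFrame({"subject": ["s1", "s1"], "time": ["pre"] * 2,
                           "task": [2, 3], "value": [0.0, 1.0]})
        with pytest.raises(DesignError):
            difference_score(df)


class TestNullCalibration:
    def test_task_effect_rejects_near_nominal_rate(self):
        """Under a pure-noise null the Task main-effect F test should
        reject at about the nominal 5% level (quick version; the full
        1000-replicate check lives in the acceptance suite)."""
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            df = make_long(rng, a=2, n=10, wsizes=(3,), names=("task",))
            out = mixed_rm_anova(df, within=["task"]).set_index("effect")
            hits += out.loc["task", "p"] < 0.05
        assert abs(hits / n_rep - 0.05) < 0.04
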