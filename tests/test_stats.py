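"""Paired tests, within-subject ANOVA, post hocs and corrected correlations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from threatnet.stats import (
    correlate_bonferroni,
    paired_ttest,
    posthoc_contrasts,
    rm_anova_2way,
    shapiro_normality,
)


def anova_table(rng, n_subj=8, conditions=("CS+", "CS-"),
                times=("baseline", "T1", "T2", "T3"), effect=0.0):
    rows = []
    for s in range(n_subj):
        for c in conditions:
            for t in times:
                rows.append(
                    {"subject": f"s{s}", "condition": c, "time": t,
                     "value": rng.normal() + (effect if c == conditions[0] else 0)}
                )
    return pd.DataFrame(rows)


class TestPairedT:
    def test_identical_samples_give_t0_p1(self):
        res = paired_ttest(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_offset_is_machine_level_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_ttest(a + 2.0, a)
        assert res.t == np.inf and res.p == 0.0
        assert res.significant and res.degenerate
        rev = paired_ttest(a, a + 2.0)
        assert rev.t == -np.inf

    def test_matches_closed_form(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        res = paired_ttest(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        assert res.t == pytest.approx(t, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 pairs"):
            paired_ttest([1.0, 2.0], [0.0, 1.0])


class TestRmAnova:
    def test_location_invariance(self, rng):
        df = anova_table(rng)
        r1 = rm_anova_2way(df)
        r2 = rm_anova_2way(df.assign(value=df["value"] + 100.0))
        assert np.allclose(r1.table["F"], r2.table["F"], atol=1e-8)

    def test_toy_table_matches_frozen_oracle(self):
        # 4 subjects x 2 conditions x 2 times; expected F values computed
        # with an independent repeated-measures ANOVA implementation
        vals = {
            (0, "a", "t1"): 3, (0, "a", "t2"): 5, (0, "b", "t1"): 2, (0, "b", "t2"): 3,
            (1, "a", "t1"): 4, (1, "a", "t2"): 6, (1, "b", "t1"): 3, (1, "b", "t2"): 5,
            (2, "a", "t1"): 5, (2, "a", "t2"): 8, (2, "b", "t1"): 4, (2, "b", "t2"): 6,
            (3, "a", "t1"): 6, (3, "a", "t2"): 9, (3, "b", "t1"): 4, (3, "b", "t2"): 6,
        }
        df = pd.DataFrame(
            [{"subject": s, "condition": c, "time": t, "value": float(v)}
             for (s, c, t), v in vals.items()]
        )
        res = rm_anova_2way(df)
        expect = {"condition": 26.68421052631579, "time": 78.81818181818183,
                  "condition * time": 9.0}
        for _, row in res.table.iterrows():
            assert row["F"] == pytest.approx(expect[row["factor"]], abs=1e-10)

    def test_agrees_with_pingouin_on_random_data(self, rng):
        df = anova_table(rng, effect=0.4)
        res = rm_anova_2way(df)
        ref = pg.rm_anova(data=df, dv="value", within=["condition", "time"],
                          subject="subject")
        assert np.allclose(res.table["F"].to_numpy(), ref["F"].to_numpy(),
                           atol=1e-10)

    def test_unbalanced_design_lists_missing_cells(self, rng):
        df = anova_table(rng)
        df = df[~((df.subject == "s0") & (df.time == "T2"))]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_2way(df)

    def test_sphericity_reported_for_time_factor(self, rng):
        res = rm_anova_2way(anova_table(rng))
        assert 0 <= res.sphericity_p <= 1
        assert 0 < res.gg_epsilon <= 1
        assert (res.table["p_corrected"] <= 1).all()


class TestPosthocs:
    @staticmethod
    def flex_table(rng, effect_at=None):
        rows = []
        for s in range(10):
            for w in ["baseline"] + [f"T{k}" for k in range(1, 7)]:
                v = rng.normal() + (1.0 if w == effect_at else 0.0)
                rows.append({"subject": f"s{s}", "window": w, "value": v})
        return pd.DataFrame(rows)

    def test_consecutive_scheme_has_six_contrasts(self, rng):
        out = posthoc_contrasts(self.flex_table(rng), scheme="consecutive")
        assert len(out) == 6
        assert out["contrast"].iloc[0] == "baseline vs T1"

    def test_baseline_scheme_has_six_contrasts(self, rng):
        out = posthoc_contrasts(self.flex_table(rng), scheme="vs_baseline")
        assert len(out) == 6
        assert all(c.startswith("baseline vs") for c in out["contrast"])

    def test_contrasts_equal_paired_t_on_slices(self, rng):
        df = self.flex_table(rng, effect_at="T3")
        out = posthoc_contrasts(df, scheme="vs_baseline")
        wide = df.pivot_table(index="subject", columns="window", values="value")
        res = paired_ttest(wide["T3"].to_numpy(), wide["baseline"].to_numpy())
        row = out[out["contrast"] == "baseline vs T3"].iloc[0]
        assert row["t"] == pytest.approx(res.t, abs=1e-12)
        assert row["p_bonf"] == pytest.approx(min(res.p * 6, 1.0), abs=1e-12)

    def test_unknown_scheme_rejected(self, rng):
        with pytest.raises(ValueError, match="scheme"):
            posthoc_contrasts(self.flex_table(rng), scheme="everything")


class TestCorrelations:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        out = correlate_bonferroni([("up", x, 2 * x), ("down", x, -x)])
        assert out.loc[out.pair == "up", "r"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out.pair == "down", "r"].iloc[0] == pytest.approx(-1.0)

    def test_bonferroni_multiplies_by_family_size(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30) * 2.0
        out = correlate_bonferroni([("xy", x, y)], family_size=10)
        row = out.iloc[0]
        assert row["p_adj"] == pytest.approx(min(row["p_raw"] * 10, 1.0))
        assert row["p_adj"] >= row["p_raw"]

    def test_zero_variance_degenerate_not_exception(self):
        x = np.ones(8)
        y = np.arange(8.0)
        out = correlate_bonferroni([("flat", x, y)])
        assert out.iloc[0]["degenerate"] and np.isnan(out.iloc[0]["r"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="4 paired"):
            correlate_bonferroni([("tiny", np.ones(3), np.ones(3))])

    def test_shapiro_reported(self, rng):
        w, p = shapiro_normality(rng.normal(size=40))
        assert 0 < w <= 1 and 0 <= p <= 1
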