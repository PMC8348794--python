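"""Cell aggregation, the within-subject ANOVA, and post hoc pairing."""

import numpy as np
import pandas as pd
import pytest

from cogload.montage import DEFAULT_MONTAGE as MONTAGE
from cogload.stats import (
    CellMeans,
    aggregate_cells,
    posthoc_pairs,
    rm_anova,
    rm_anova_array,
)

from conftest import cohort_features, condition_features
from cogload.simulate import LoadEffectProfile


def _cells_from_array(data: np.ndarray, factors: dict) -> CellMeans:
    names = list(factors)
    rows = []
    for s in range(data.shape[0]):
        for idx in np.ndindex(*data.shape[1:]):
            row = {"subject": f"S{s:02d}", "value": data[(s, *idx)]}
            for k, name in enumerate(names):
                row[name] = factors[name][idx[k]]
            rows.append(row)
    return CellMeans(table=pd.DataFrame(rows))


class TestAggregateCells:
    def test_single_epoch_single_channel_lobe(self):
        df = condition_features(LoadEffectProfile.null(), ["L0"], 1, seed=1)
        cells = aggregate_cells(df)
        one = cells.table.query("lobe == 'temporal' and band == 'theta'")["value"].item()
        expect = df[["theta_T7", "theta_T8"]].mean(axis=1).item()
        assert one == pytest.approx(expect)

    def test_frontal_lobe_is_mean_of_eight_channels(self):
        df = condition_features(LoadEffectProfile.null(), ["L0", "L1"], 5, seed=2)
        cells = aggregate_cells(df)
        got = cells.table.query("lobe == 'frontal' and band == 'alpha' and condition == 'L1'")[
            "value"
        ].item()
        cols = [f"alpha_{ch}" for ch in MONTAGE.lobes["frontal"]]
        assert len(cols) == 8
        expect = df.loc[df["condition"] == "L1", cols].to_numpy().mean()
        assert got == pytest.approx(expect)

    def test_epoch_order_invariance(self):
        df = condition_features(LoadEffectProfile.null(), ["L0", "L1"], 8, seed=3)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            aggregate_cells(df).table, aggregate_cells(shuffled).table
        )

    def test_missing_cells_reported(self):
        df = condition_features(LoadEffectProfile.null(), ["L0", "L1"], 3, seed=4)
        df2 = condition_features(
            LoadEffectProfile.null(), ["L0"], 3, seed=5, subject="S02"
        )
        cells = aggregate_cells(pd.concat([df, df2], ignore_index=True))
        assert ("S02", 1, "L1") in cells.missing


class TestRmAnova:
    def test_agrees_with_statsmodels(self):
        """Independent oracle: statsmodels AnovaRM on the same balanced data."""
        AnovaRM = pytest.importorskip("statsmodels.stats.anova").AnovaRM
        rng = np.random.default_rng(12)
        data = rng.normal(size=(7, 4, 2, 2))
        ours = rm_anova_array(data, ("cond", "band", "lobe"))
        rows = []
        for s in range(7):
            for a in range(4):
                for b in range(2):
                    for c in range(2):
                        rows.append(
                            {"subject": s, "cond": a, "band": b, "lobe": c,
                             "y": data[s, a, b, c]}
                        )
        oracle = AnovaRM(
            pd.DataFrame(rows), "y", "subject", within=["cond", "band", "lobe"]
        ).fit().anova_table
        for _, row in ours.table.iterrows():
            assert row["F"] == pytest.approx(oracle.loc[row["effect"], "F Value"], rel=1e-8)
            assert row["df1"] == oracle.loc[row["effect"], "Num DF"]
            assert row["df2"] == oracle.loc[row["effect"], "Den DF"]

    def test_sums_of_squares_partition_total(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(6, 4, 4, 4, 2))
        res = rm_anova_array(data)
        assert sum(res.ss.values()) == pytest.approx(res.ss_total, rel=1e-10)

    def test_f_equals_t_squared_in_two_condition_reduction(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(14)
        data = rng.normal(size=(10, 2))
        res = rm_anova_array(data, ("condition",))
        t, p = ttest_rel(data[:, 0], data[:, 1])
        row = res.effect("condition")
        assert row["F"] == pytest.approx(t**2, rel=1e-10)
        assert row["p"] == pytest.approx(p, rel=1e-10)

    def test_pure_condition_shift_detected_without_interactions(self):
        rng = np.random.default_rng(15)
        base = rng.normal(size=(10, 1, 2, 2)) * 0.3  # subject noise
        data = np.tile(base, (1, 4, 1, 1)) + rng.normal(size=(10, 4, 2, 2)) * 0.1
        data += np.array([0.0, 0.5, 1.0, 1.5])[None, :, None, None]  # additive shift
        res = rm_anova_array(data, ("condition", "band", "lobe"))
        assert res.effect("condition")["p"] < 1e-6
        assert res.effect("condition:band")["p"] > 0.01
        assert res.effect("condition:band:lobe")["p"] > 0.01

    def test_identical_days_give_zero_day_effect(self):
        rng = np.random.default_rng(16)
        one_day = rng.normal(size=(6, 3, 1))
        data = np.concatenate([one_day, one_day], axis=2)
        res = rm_anova_array(data, ("condition", "day"))
        assert res.effect("day")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_partial_eta_squared_definition(self):
        rng = np.random.default_rng(17)
        res = rm_anova_array(rng.normal(size=(5, 3, 2)), ("a", "b"))
        row = res.effect("a")
        assert row["partial_eta_sq"] == pytest.approx(
            row["SS"] / (row["SS"] + row["SS_error"])
        )

    def test_unbalanced_design_rejected_with_cells(self):
        cells = _cells_from_array(
            np.random.default_rng(18).normal(size=(4, 2, 2)),
            {"condition": ["L0", "L1"], "band": ["theta", "alpha"]},
        )
        table = cells.table[~((cells.table.subject == "S00") & (cells.table.condition == "L1"))]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(CellMeans(table=table), ("condition", "band"))

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError, match="3 subjects"):
            rm_anova_array(np.zeros((2, 4, 4, 4, 2)))

    def test_degrees_of_freedom_match_design(self):
        """Full design: 24 subjects, 4x4x4x2 levels reproduces the canonical
        df pattern (27, 594) for the three-way condition:band:lobe term."""
        rng = np.random.default_rng(19)
        res = rm_anova_array(rng.normal(size=(23, 4, 4, 4, 2)))
        row = res.effect("condition:band:lobe")
        assert (row["df1"], row["df2"]) == (27, 594)
        assert (res.effect("band")["df1"], res.effect("band")["df2"]) == (3, 66)
        assert (res.effect("day")["df1"], res.effect("day")["df2"]) == (1, 22)


class TestPosthoc:
    def test_identical_conditions_give_t0_p1(self):
        vals = np.random.default_rng(20).normal(size=(5, 1, 1))
        data = np.tile(vals, (1, 4, 2))  # same value in every condition
        cells = _cells_from_array(
            data.reshape(5, 4, 2),
            {"condition": ["L0", "L1", "L2", "L3"], "band": ["theta", "alpha"]},
        )
        cells.table["lobe"] = "frontal"
        cells.table["day"] = 1
        out = posthoc_pairs(cells)
        assert (out["t"] == 0).all()
        assert (out["p"] == 1).all()

    def test_six_pairs_per_lobe_band(self):
        df = cohort_features(4, ["L0", "L1", "L2", "L3"], 4, seed=21, n_days=1)
        out = posthoc_pairs(aggregate_cells(df))
        counts = out.groupby(["lobe", "band"]).size()
        assert (counts == 6).all()

    def test_planted_shift_flagged_at_n24(self):
        """A +1 SD frontal-theta shift in L3 is detected at p<0.01 with 24 subjects."""
        rng = np.random.default_rng(22)
        n = 24
        rows = []
        for s in range(n):
            for cond in ("L0", "L3"):
                base = rng.normal()
                shift = 1.0 if cond == "L3" else 0.0
                rows.append(
                    {"subject": f"S{s:02d}", "day": 1, "condition": cond,
                     "lobe": "frontal", "band": "theta",
                     "value": base * 0.3 + shift + rng.normal() * 1.0}
                )
        out = posthoc_pairs(CellMeans(table=pd.DataFrame(rows)))
        row = out.query("pair == 'L0-L3'").iloc[0]
        assert row["significant"]
        assert row["df"] == n - 1
        assert row["t"] < 0  # L0 below L3

    def test_needs_three_subjects(self):
        cells = _cells_from_array(
            np.zeros((2, 2, 1)), {"condition": ["L0", "L1"], "band": ["theta"]}
        )
        with pytest.raises(ValueError, match="3 subjects"):
            posthoc_pairs(cells)


def test_synthetic_effect_directions_reproduced():
    """On cohort data built with the default effect profile, post hoc flags
    show frontal theta rising and occipital alpha falling with load."""
    df = cohort_features(8, ["L0", "L1", "L2", "L3"], 30, seed=23,
                         subject_sd=0.02, day_gain_sd=0.02)
    cells = aggregate_cells(df)
    out = posthoc_pairs(cells)
    ft = out.query("lobe == 'frontal' and band == 'theta' and pair == 'L0-L3'").iloc[0]
    assert ft["significant"] and ft["t"] < 0  # theta higher at L3
    oa = out.query("lobe == 'occipital' and band == 'alpha' and pair == 'L0-L3'").iloc[0]
    assert oa["significant"] and oa["t"] > 0  # alpha lower at L3
    res = rm_anova(cells)
    assert res.effect("condition:band:lobe")["p"] < 0.01
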