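import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lidarpheno as lp
from lidarpheno.drought import (classify_tolerance, compute_indices, dri,
                                dsi, group_dynamics, pad_profile,
                                stage_significance, yrr)
from lidarpheno.errors import LidarPhenoError

GROUPS17 = {f"V{i + 1:02d}": ("L1" if i < 9 else "L2" if i < 14 else "L3")
            for i in range(17)}
REDUCTIONS = {"L1": 0.85, "L2": 0.48, "L3": 0.27}


class TestIndices:
    def test_yrr(self):
        assert yrr(100.0, 100.0) == 0.0
        assert yrr(0.0, 100.0) == 1.0
        assert yrr(30.0, 200.0) == pytest.approx(0.85)
        with pytest.raises(LidarPhenoError):
            yrr(10.0, 0.0)

    def test_dsi(self):
        assert dsi(50.0, 100.0, 50.0, 100.0) == pytest.approx(1.0)
        assert dsi(100.0, 100.0, 50.0, 100.0) == 0.0
        assert dsi(60.0, 100.0, 50.0, 100.0) == pytest.approx(0.8)
        with pytest.raises(LidarPhenoError):
            dsi(60.0, 100.0, 100.0, 100.0)

    def test_dri(self):
        assert dri(80.0, 80.0, 80.0, 80.0) == pytest.approx(1.0)
        assert dri(0.0, 100.0, 50.0, 100.0) == 0.0
        assert dri(50.0, 100.0, 50.0, 100.0) == pytest.approx(1.0)
        with pytest.raises(LidarPhenoError):
            dri(50.0, 100.0, 0.0, 100.0)

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, c):
        y_a, y_m, y_pa, y_pm = 30.0, 150.0, 60.0, 140.0
        assert yrr(c * y_a, c * y_m) == pytest.approx(yrr(y_a, y_m))
        assert dsi(c * y_a, c * y_m, c * y_pa, c * y_pm) == pytest.approx(
            dsi(y_a, y_m, y_pa, y_pm))
        assert dri(c * y_a, c * y_m, c * y_pa, c * y_pm) == pytest.approx(
            dri(y_a, y_m, y_pa, y_pm))

    def test_compute_indices_requires_control(self):
        table = pd.DataFrame({"variety_id": ["V1"], "treatment": ["drought"],
                              "grain_yield": [10.0]})
        with pytest.raises(LidarPhenoError):
            compute_indices(table)


class TestClassify:
    def test_recovers_generating_partition(self):
        from sklearn.metrics import adjusted_rand_score
        table = lp.generate_yields(17, GROUPS17, REDUCTIONS, cv=0.05,
                                   seed=4)
        out = classify_tolerance(compute_indices(table))
        truth = [GROUPS17[v] for v in out["variety_id"]]
        assert adjusted_rand_score(truth, out["group"]) == 1.0
        sizes = out.groupby("group").size().to_dict()
        assert sizes == {"L1": 9, "L2": 5, "L3": 3}

    def test_labels_ordered_by_yrr(self):
        table = lp.generate_yields(17, GROUPS17, REDUCTIONS, cv=0.05,
                                   seed=4)
        out = classify_tolerance(compute_indices(table))
        means = out.groupby("group")["yrr"].mean()
        assert means["L1"] > means["L2"] > means["L3"]

    def test_permutation_stability(self):
        table = lp.generate_yields(17, GROUPS17, REDUCTIONS, cv=0.05,
                                   seed=8)
        idx = compute_indices(table)
        a = classify_tolerance(idx).set_index("variety_id")["group"]
        shuffled = idx.sample(frac=1.0, random_state=3)
        b = classify_tolerance(shuffled).set_index("variety_id")["group"]
        assert (a.sort_index() == b.sort_index()).all()

    def test_degenerate_identical_indices_warns(self):
        idx = pd.DataFrame({"variety_id": [f"V{i}" for i in range(5)],
                            "yrr": 0.5, "dsi": 1.0, "dri": 1.0})
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = classify_tolerance(idx)
        assert len(out) == 5

    def test_two_true_groups_split_but_ordered(self):
        # 6-point toy: two tight groups; k=3 splits one, order holds
        idx = pd.DataFrame({
            "variety_id": [f"V{i}" for i in range(6)],
            "yrr": [0.9, 0.88, 0.86, 0.2, 0.21, 0.22],
            "dsi": [1.5, 1.48, 1.46, 0.3, 0.31, 0.32],
            "dri": [0.1, 0.12, 0.14, 2.0, 2.1, 2.2]})
        out = classify_tolerance(idx)
        means = out.groupby("group")["yrr"].mean()
        assert means["L1"] >= means["L2"] >= means["L3"]

    def test_fewer_than_k_errors(self):
        idx = pd.DataFrame({"variety_id": ["V1", "V2"],
                            "yrr": [0.5, 0.6], "dsi": [1, 1.2],
                            "dri": [1, 0.8]})
        with pytest.raises(LidarPhenoError):
            classify_tolerance(idx)

    def test_non_finite_excluded_with_warning(self):
        table = lp.generate_yields(17, GROUPS17, REDUCTIONS, cv=0.05,
                                   seed=4)
        idx = compute_indices(table)
        idx.loc[0, "dri"] = np.nan
        with pytest.warns(RuntimeWarning, match="non-finite"):
            out = classify_tolerance(idx)
        assert len(out) == 16


def _pheno_frame():
    rows = []
    rng = np.random.default_rng(0)
    means = {"D20": 0.55, "D35": 1.00, "D45": 1.42, "D60": 1.80,
             "D70": 1.76, "D95": 1.66}
    for stage, m in means.items():
        for i in range(20):
            rows.append({"variety_id": f"V{i % 4:02d}", "group": "L1",
                         "stage": stage,
                         "height_m": m + rng.normal(0, 0.001)})
    return pd.DataFrame(rows)


class TestDynamics:
    def test_change_rate_d60_d95_scale(self):
        df = pd.DataFrame({
            "group": "L1", "stage": ["D60"] * 3 + ["D95"] * 3,
            "height_m": [1.80, 1.80, 1.80, 1.66, 1.66, 1.66]})
        dyn = group_dynamics(df, df, "height_m", stages=("D60", "D95"))
        rate = dyn.loc[dyn["stage"] == "D95", "change_rate"].iloc[0]
        assert rate == pytest.approx((1.66 - 1.80) / 1.80)
        assert rate == pytest.approx(-0.0778, abs=5e-4)

    def test_constant_series_zero_rates(self):
        df = pd.DataFrame({"group": "L1",
                           "stage": np.repeat(list(lp.STAGES), 3),
                           "pai": 1.5})
        dyn = group_dynamics(df, df, "pai")
        rates = dyn["change_rate"].dropna()
        assert np.allclose(rates, 0.0)

    def test_rates_reconstruct_series(self):
        df = _pheno_frame()
        dyn = group_dynamics(df, df, "height_m")
        sub = dyn[dyn["group"] == "L1"].reset_index(drop=True)
        rebuilt = [sub["mean"][0]]
        for r in sub["change_rate"][1:]:
            rebuilt.append(rebuilt[-1] * (1 + r))
        assert np.allclose(rebuilt, sub["mean"])

    def test_missing_stage_undefines_next_rate(self):
        df = pd.DataFrame({"group": "L1",
                           "stage": ["D20"] * 3 + ["D45"] * 3,
                           "pla": [0.1, 0.11, 0.12, 0.2, 0.21, 0.19]})
        dyn = group_dynamics(df, df, "pla", stages=("D20", "D35", "D45"))
        sub = dyn.set_index("stage")
        assert np.isnan(sub.loc["D35", "mean"])
        assert np.isnan(sub.loc["D45", "change_rate"])


class TestSignificance:
    def _frame(self, a, b):
        return pd.DataFrame({
            "stage": ["A"] * len(a) + ["B"] * len(b),
            "v": np.concatenate([a, b]), "group": "L1"})

    def test_identical_samples_p_one(self):
        x = np.full(5, 1.3)
        p, flag = stage_significance(self._frame(x, x), "L1", "v", "A", "B")
        assert p == 1.0 and flag == "ns"

    def test_extreme_separation(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(10 * 1.0, 1, 10) + 10
        p, flag = stage_significance(self._frame(a, b), "L1", "v", "A", "B")
        assert p < 0.01 and flag == "**"

    def test_too_few_observations(self):
        with pytest.raises(LidarPhenoError):
            stage_significance(self._frame([1.0], [2.0]), "L1", "v",
                               "A", "B")


class TestPadProfile:
    def _frame(self):
        rows = []
        for i in range(4):
            rows.append({"group": "L1", "stage": "D60",
                         **{f"pad_l{k}": 0.5 + 0.1 * k for k in
                            range(1, 6)}})
        return pd.DataFrame(rows)

    def test_identical_plants(self):
        prof = pad_profile(self._frame(), "L1", "D60")
        assert np.allclose(prof, [0.6, 0.7, 0.8, 0.9, 1.0])

    def test_single_plant_group(self):
        df = self._frame().iloc[:1]
        prof = pad_profile(df, "L1", "D60")
        assert np.allclose(prof, [0.6, 0.7, 0.8, 0.9, 1.0])

    def test_empty_group_missing(self):
        prof = pad_profile(self._frame(), "L3", "D60")
        assert np.isnan(prof).all()

    def test_smaller_upper_leaves_lower_upper_pad(self):
        """Generator truth: shrinking the two upper layers' leaf area by
        20% lowers the upper-layer mean PAD relative to the baseline."""
        base_areas = (0.02, 0.05, 0.07, 0.06, 0.04)
        tol_areas = (0.02, 0.05, 0.07, 0.048, 0.032)
        rows = []
        for g, areas in (("L1", base_areas), ("L3", tol_areas)):
            for i in range(3):
                spec = lp.PlantSpec(height=1.8,
                                    leaf_count_per_layer=(1, 2, 2, 2, 2),
                                    one_sided_area_per_layer=areas)
                _, rec = lp.generate_plant(spec, 0.006, seed=10 + i)
                rows.append({"group": g, "stage": "D60",
                             **{f"pad_l{k + 1}": rec.true_pad_per_layer[k]
                                for k in range(5)}})
        df = pd.DataFrame(rows)
        low = pad_profile(df, "L1", "D60")
        high = pad_profile(df, "L3", "D60")
        assert high[3] < low[3] and high[4] < low[4]
        assert np.allclose(high[:3], low[:3], rtol=1e-9)
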