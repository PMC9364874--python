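import math

import numpy as np
import pandas as pd
import pytest

from segquant import cohort_reporting as cr
from segquant import synthetic_phantoms as sp
from segquant.volumes_io import LabelVolume, ProbabilityVolume


def _cube(shape=(24, 24, 24), corner=(6, 6, 6), size=8):
    g = np.zeros(shape, np.uint8)
    g[corner[0]:corner[0] + size, corner[1]:corner[1] + size, corner[2]:corner[2] + size] = 1
    return LabelVolume(g, (1.0, 1.0, 1.0), "cube")


class TestEvaluateCase:
    def test_perfect_prediction(self):
        gt = _cube()
        row = cr.evaluate_case(gt, gt)
        assert row["dice"] == 1.0
        assert row["hd95"] == 0.0
        assert row["ravd"] == 0.0
        assert row["patient_detected"]
        assert row["n_detected_gt"] == row["n_gt_objects"] == 1

    def test_empty_prediction_flagged(self):
        gt = _cube()
        empty = LabelVolume(np.zeros(gt.shape, np.uint8), gt.spacing)
        row = cr.evaluate_case(gt, empty)
        assert row["dice"] == 0.0
        assert math.isnan(row["hd95"]) and math.isnan(row["assd"])
        assert not row["patient_detected"]

    def test_fixture_a_composition(self, fixture_a):
        gt, pred = fixture_a
        row = cr.evaluate_case(gt, pred, config=cr.EvalConfig(min_size_voxels=0))
        assert row["dice"] == pytest.approx(4 / 7)
        assert row["vs"] == pytest.approx(6 / 7)
        assert row["gt_volume_ml"] == pytest.approx(0.004)

    def test_probability_map_requires_threshold(self):
        gt = _cube()
        prob = ProbabilityVolume(gt.grid.astype(float), gt.spacing)
        with pytest.raises(ValueError, match="threshold"):
            cr.evaluate_case(gt, prob)


class TestSweep:
    def test_volumes_non_increasing_and_binary_gt_all_perfect(self):
        gt = _cube()
        prob = sp.make_probability_map(gt, prob_ramp_mm=4.0)
        records = cr.sweep_thresholds(gt, prob, config=cr.EvalConfig(compute_instances=False))
        assert len(records) == 10
        vols = [r["pred_volume_ml"] for r in records]
        assert all(a >= b - 1e-12 for a, b in zip(vols, vols[1:]))
        assert records[-1]["dice"] == 1.0  # threshold 1.0 recovers the mask

    def test_constant_zero_map(self):
        gt = _cube()
        prob = ProbabilityVolume(np.zeros(gt.shape), gt.spacing)
        records = cr.sweep_thresholds(gt, prob, config=cr.EvalConfig(compute_instances=False))
        assert all(r["pred_volume_ml"] == 0 for r in records)


class TestOperatingThreshold:
    def test_peak_selection(self):
        df = pd.DataFrame(
            {"threshold": [0.1, 0.5, 0.9] * 2, "dice": [0.5, 0.9, 0.6, 0.4, 0.8, 0.7]}
        )
        assert cr.select_operating_threshold(df) == 0.5

    def test_tie_goes_to_lower(self):
        df = pd.DataFrame({"threshold": [0.1, 0.5, 0.9], "dice": [0.7, 0.7, 0.7]})
        assert cr.select_operating_threshold(df) == 0.1


class TestPooling:
    def test_weighted_mean_example(self):
        folds = pd.DataFrame(
            [
                {"fold_id": 0, "metric": "dice", "n": 10, "mean": 80.0, "sd": 5.0},
                {"fold_id": 1, "metric": "dice", "n": 10, "mean": 90.0, "sd": 5.0},
            ]
        )
        pooled = cr.pool_folds(folds)
        assert pooled.loc[0, "mean"] == pytest.approx(85.0)

    def test_single_fold_identity(self):
        folds = pd.DataFrame([{"fold_id": 0, "metric": "dice", "n": 7, "mean": 0.8, "sd": 0.1}])
        pooled = cr.pool_folds(folds)
        assert pooled.loc[0, "mean"] == pytest.approx(0.8)
        assert pooled.loc[0, "sd"] == pytest.approx(0.1)

    def test_identical_folds_reproduce_concatenated_sd(self):
        folds = pd.DataFrame(
            [{"fold_id": k, "metric": "dice", "n": 10, "mean": 0.8, "sd": 0.05} for k in range(5)]
        )
        pooled = cr.pool_folds(folds)
        # equal means: pooled sd is the concatenated-sample sd,
        # sqrt(sum (n_i-1) s^2 / (sum n_i - 1))
        assert pooled.loc[0, "mean"] == pytest.approx(0.8)
        assert pooled.loc[0, "sd"] == pytest.approx(0.05 * np.sqrt(45 / 49), abs=1e-12)

    def test_pooled_matches_direct_concatenation(self):
        rng = np.random.default_rng(23)
        values = rng.normal(0.8, 0.1, size=40)
        df = pd.DataFrame({"fold_id": np.repeat(np.arange(4), 10), "dice": values})
        folds = cr.fold_summaries(df, metrics=["dice"])
        pooled = cr.pool_folds(folds)
        assert pooled.loc[0, "mean"] == pytest.approx(values.mean(), abs=1e-9)
        assert pooled.loc[0, "sd"] == pytest.approx(values.std(ddof=1), abs=1e-9)

    def test_pooled_mean_within_fold_means(self):
        rng = np.random.default_rng(29)
        df = pd.DataFrame(
            {"fold_id": rng.integers(0, 3, 50), "dice": rng.uniform(0, 1, 50)}
        )
        folds = cr.fold_summaries(df, metrics=["dice"])
        pooled = cr.pool_folds(folds)
        assert folds["mean"].min() - 1e-12 <= pooled.loc[0, "mean"] <= folds["mean"].max() + 1e-12

    def test_undefined_values_excluded(self):
        df = pd.DataFrame({"fold_id": [0, 0, 0], "hd95": [1.0, np.nan, 3.0]})
        folds = cr.fold_summaries(df, metrics=["hd95"])
        assert folds.loc[0, "n"] == 2
        assert folds.loc[0, "mean"] == pytest.approx(2.0)


class TestCorrelation:
    def test_volume_correlation_scale_invariance(self):
        df = pd.DataFrame({"gt_volume_ml": [1.0, 2, 3, 4], "pred_volume_ml": [0.8, 1.6, 2.4, 3.2]})
        assert cr.volume_correlation(df) == pytest.approx(1.0)

    def test_anti_ordered_volumes_negative(self):
        df = pd.DataFrame({"gt_volume_ml": [1.0, 2, 3, 4], "pred_volume_ml": [4.0, 3, 2, 1]})
        assert cr.volume_correlation(df) < 0

    def test_matrix_diagonal_and_symmetry(self):
        rng = np.random.default_rng(37)
        df = pd.DataFrame({"dice": rng.uniform(0, 1, 30)})
        df["cks"] = df["dice"] * 0.95 + rng.normal(0, 0.01, 30)
        m = cr.correlation_matrix(df, metrics=["dice", "cks"])
        assert m.loc["dice", "dice"] == 1.0
        assert m.loc["dice", "cks"] == m.loc["cks", "dice"]

    def test_noise_metric_uncorrelated(self):
        rng = np.random.default_rng(41)
        df = pd.DataFrame({"dice": np.linspace(0, 1, 300), "noise": rng.uniform(0, 1, 300)})
        m = cr.correlation_matrix(df, metrics=["dice", "noise"], decimals=None)
        assert abs(m.loc["dice", "noise"]) < 0.2

    def test_pairwise_deletion(self):
        df = pd.DataFrame(
            {"dice": [0.1, 0.5, 0.9, 0.7], "hd95": [9.0, 5.0, np.nan, 2.0]}
        )
        m = cr.correlation_matrix(df, metrics=["dice", "hd95"], decimals=None)
        expect = np.corrcoef([0.1, 0.5, 0.7], [9.0, 5.0, 2.0])[0, 1]
        assert m.loc["dice", "hd95"] == pytest.approx(expect)


class TestVolumeBins:
    def _cohort(self, n=100, seed=43):
        rng = np.random.default_rng(seed)
        vol = np.sort(rng.uniform(0.1, 100, n))
        # small tumors get low Dice by construction
        dice = np.clip(vol / 100 + rng.normal(0, 0.05, n), 0, 1)
        return pd.DataFrame({"case_id": [f"c{i}" for i in range(n)],
                             "gt_volume_ml": vol, "dice": dice})

    def test_equal_counts(self):
        bins = cr.bin_by_volume(self._cohort(100))
        assert list(bins["n_cases"]) == [10] * 10

    def test_counts_differ_by_at_most_one_and_partition(self):
        bins = cr.bin_by_volume(self._cohort(103))
        assert bins["n_cases"].max() - bins["n_cases"].min() <= 1
        assert bins["n_cases"].sum() == 103

    def test_small_tumors_score_lower(self):
        bins = cr.bin_by_volume(self._cohort())
        assert bins.loc[0, "dice_median"] < bins.loc[9, "dice_median"]

    def test_ties_stable(self):
        df = pd.DataFrame({"case_id": [f"c{i:03d}" for i in range(20)],
                           "gt_volume_ml": 5.0, "dice": 0.5})
        bins = cr.bin_by_volume(df, n_bins=10)
        assert list(bins["n_cases"]) == [2] * 10

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            cr.bin_by_volume(self._cohort(5), n_bins=10)


class TestDiceTP:
    def test_direct_arithmetic(self):
        df = pd.DataFrame({"dice": [0.8, 0.7, 0.0]})
        mean, tp = cr.dice_tp_aggregate(df)
        assert mean == pytest.approx(0.5)
        assert tp == pytest.approx(0.75)

    def test_all_detected_equal(self):
        df = pd.DataFrame({"dice": [0.8, 0.9]})
        mean, tp = cr.dice_tp_aggregate(df)
        assert mean == tp

    def test_none_detected_undefined(self):
        df = pd.DataFrame({"dice": [0.0, 0.0]})
        _, tp = cr.dice_tp_aggregate(df)
        assert math.isnan(tp)

    def test_dice_tp_never_below_mean(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            df = pd.DataFrame({"dice": rng.uniform(0, 1, 30) * (rng.random(30) > 0.3)})
            mean, tp = cr.dice_tp_aggregate(df)
            if not math.isnan(tp):
                assert tp >= mean - 1e-12


class TestCohortPipeline:
    def test_manifest_round_trip_and_outputs(self, tmp_path):
        spec = sp.PhantomSpec(shape=(32, 32, 32), focus_volume_range_ml=(0.5, 2.0),
                              erode_iters=1, seed=5)
        manifest = sp.make_cohort(spec, n_cases=4, n_folds=2, out_dir=tmp_path / "cohort")
        config = cr.EvalConfig(thresholds=(0.5, 1.0), compute_distances=False)
        df = cr.evaluate_cohort(tmp_path / "cohort" / "manifest.csv", config=config)
        assert len(df) == 8  # 4 cases x 2 thresholds
        assert set(df["fold_id"]) == {0, 1}
        paths = cr.write_cohort_outputs(df, tmp_path / "out", config=config)
        for key in ("cases", "folds", "pooled", "correlation", "log"):
            assert paths[key].exists()
        pooled = pd.read_csv(paths["pooled"])
        assert "mean_sd" in pooled.columns

    def test_manifest_missing_columns(self, tmp_path):
        bad = tmp_path / "bad.csv"
        pd.DataFrame({"case_id": ["a"]}).to_csv(bad, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            cr.evaluate_cohort(bad)
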