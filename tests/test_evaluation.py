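"""Monte Carlo CV harness, paired tests, metric-table comparison."""

import numpy as np
import pytest
from scipy import stats

import echolv as e
from echolv.exceptions import InsufficientDataError, PairingError


class TestMcPartition:
    def test_sizes_at_136_animals(self):
        ids = [f"m{i}" for i in range(136)]
        train, val, test = e.mc_partition(ids, seed=0)
        assert (len(train), len(val), len(test)) == (102, 17, 17)

    def test_sizes_at_16_animals(self):
        train, val, test = e.mc_partition([f"m{i}" for i in range(16)], seed=0)
        assert (len(train), len(val), len(test)) == (12, 2, 2)

    def test_disjoint_and_covering(self):
        ids = [f"m{i}" for i in range(21)]
        train, val, test = e.mc_partition(ids, seed=3)
        assert set(train) | set(val) | set(test) == set(ids)
        assert not (set(train) & set(val) or set(train) & set(test)
                    or set(val) & set(test))

    def test_deterministic_under_seed(self):
        ids = [f"m{i}" for i in range(24)]
        assert e.mc_partition(ids, seed=5) == e.mc_partition(ids, seed=5)
        assert e.mc_partition(ids, seed=5) != e.mc_partition(ids, seed=6)

    def test_too_few_animals_rejected(self):
        with pytest.raises(InsufficientDataError):
            e.mc_partition(["a"] * 7, seed=0)


class TestPairedTTest:
    def test_symmetric_differences_give_t_zero(self):
        res = e.paired_error_ttest(np.array([1.0, 2.0, 3.0]),
                                   np.array([2.0, 2.0, 2.0]))
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_closed_form_t_statistic(self):
        # differences {1,2,3}: t = 2 / (1/sqrt(3)) = 3.464
        res = e.paired_error_ttest(np.array([2.0, 4.0, 6.0]),
                                   np.array([1.0, 2.0, 3.0]))
        assert res["t"] == pytest.approx(2.0 * np.sqrt(3), abs=1e-3)
        assert res["t"] == pytest.approx(3.464, abs=1e-3)

    def test_p_matches_t_distribution_cdf_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        res = e.paired_error_ttest(a, b)
        oracle = 2.0 * stats.t.sf(abs(res["t"]), df=29)
        assert res["p"] == pytest.approx(oracle, abs=1e-10)
        # full cross-check against scipy's own paired test
        t_sp, p_sp = stats.ttest_rel(a, b)
        assert res["t"] == pytest.approx(t_sp, abs=1e-10)
        assert res["p"] == pytest.approx(p_sp, abs=1e-10)

    def test_degenerate_zero_variance(self):
        shifted = e.paired_error_ttest(np.array([2.0, 2.0, 2.0]),
                                       np.array([1.0, 1.0, 1.0]))
        assert shifted["p"] == 0.0 and shifted["degenerate"]
        equal = e.paired_error_ttest(np.ones(3), np.ones(3))
        assert equal["p"] == 1.0 and equal["degenerate"]

    def test_direction_check(self):
        rng = np.random.default_rng(1)
        small = rng.normal(0.0, 0.1, 50) ** 2
        large = small + 1.0
        assert e.significantly_better(small, large)
        assert not e.significantly_better(large, small)


class TestCrossValidation:
    @pytest.fixture(scope="class")
    def family_cohort(self):
        return e.generate_model_family_cohort(n_animals=12, frames_per_cycle=16,
                                              image_shape=(12, 12), k_true=3,
                                              seed=0)

    def test_noiseless_model_family_recovers_r2_above_099(self, family_cohort):
        cv = e.run_cross_validation(family_cohort, variants=(1, 2, 3), n_iter=5,
                                    k_grid=(2, 4), seed=0)
        for v in (2, 3):
            r2 = np.concatenate([it.r2[v] for it in cv.iterations])
            assert np.median(r2) > 0.99

    def test_pure_noise_images_give_r2_near_zero(self):
        rng = np.random.default_rng(5)
        cohort = e.generate_model_family_cohort(n_animals=12, frames_per_cycle=16,
                                                image_shape=(12, 12), seed=1)
        # replace every image with pure noise: no boundary information remains
        noise_cohort = []
        for stack, truth in cohort:
            imgs = rng.normal(0.4, 0.1, size=stack.images.shape).astype(np.float32)
            s = e.SliceStack(images=imgs, cycle_phase=stack.cycle_phase,
                             animal_id=stack.animal_id, apex_z=stack.apex_z,
                             base_z=stack.base_z,
                             cycle_duration_s=stack.cycle_duration_s)
            noise_cohort.append((s, truth))
        cv = e.run_cross_validation(noise_cohort, variants=(2,), n_iter=10,
                                    k_grid=(2, 4), seed=0)
        r2 = np.concatenate([it.r2[2] for it in cv.iterations])
        assert abs(np.median(r2)) < 0.2

    def test_single_value_k_grid_bypasses_selection(self, family_cohort):
        cv = e.run_cross_validation(family_cohort, variants=(2,), n_iter=2,
                                    k_grid=(3,), seed=0)
        assert all(it.selected_k[2] == 3 for it in cv.iterations)

    def test_split_disjointness_every_iteration(self, family_cohort):
        cv = e.run_cross_validation(family_cohort, variants=(2,), n_iter=4,
                                    k_grid=(3,), seed=0)
        ids = {s.animal_id for s, _ in family_cohort}
        for it in cv.iterations:
            union = set(it.train_ids) | set(it.val_ids) | set(it.test_ids)
            assert union == ids
            assert len(it.train_ids) + len(it.val_ids) + len(it.test_ids) == len(ids)

    def test_result_serializes_to_json(self, family_cohort, tmp_path):
        import json

        cv = e.run_cross_validation(family_cohort, variants=(2,), n_iter=2,
                                    k_grid=(3,), seed=0)
        path = tmp_path / "cv.json"
        cv.to_json(path)
        payload = json.loads(path.read_text())
        assert len(payload["iterations"]) == 2
        assert len(payload["iterations"][0]["mse"]["2"]) == 48


class TestCompareMetricTables:
    def make_tables(self, n=50, shift_metric=None, seed=0):
        rng = np.random.default_rng(seed)
        import pandas as pd

        metrics = [f"metric_{i}" for i in range(10)]
        truth, pred = [], []
        for _ in range(n):
            base = rng.normal(0.0, 1.0, size=10)
            t = pd.DataFrame({
                "metric": metrics, "frame_type": "circ", "location": "mid_lv",
                "boundary": "endo", "value": base, "units": "x",
            })
            p = t.copy()
            noise = rng.normal(0.0, 0.01, size=10)
            p["value"] = base + noise
            if shift_metric is not None:
                p.loc[p.metric == shift_metric, "value"] += 0.1  # 10 SD of noise
            truth.append(t)
            pred.append(p)
        return truth, pred

    def test_identical_tables_flag_nothing(self):
        truth, _ = self.make_tables()
        cmp = e.compare_metric_tables(truth, [t.copy() for t in truth])
        assert cmp["flagged"].sum() == 0

    def test_single_shifted_metric_is_the_only_flag(self):
        truth, pred = self.make_tables(shift_metric="metric_3")
        cmp = e.compare_metric_tables(truth, pred)
        flagged = cmp[cmp.flagged]
        assert list(flagged.metric) == ["metric_3"]

    def test_bonferroni_bounds(self):
        truth, pred = self.make_tables(shift_metric="metric_3")
        cmp = e.compare_metric_tables(truth, pred)
        assert (cmp.p_adjusted >= cmp.p - 1e-15).all()
        assert (cmp.p_adjusted <= 1.0).all()

    def test_mismatched_tables_rejected(self):
        truth, pred = self.make_tables(n=5)
        pred[2] = pred[2].iloc[::-1].reset_index(drop=True)
        with pytest.raises(PairingError):
            e.compare_metric_tables(truth, pred)
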