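import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroquant.io_core import REGIONS, ParametricMap
from neuroquant.phantom import CohortDesign, GroundTruth, simulate_cohort, simulate_pet
from neuroquant.maps import compute_suv
from neuroquant.roi import (
    DEFAULT_REGION_SETS,
    extract_regions,
    hemisphere_correlation,
    hemispheric_relative_difference,
    whole_brain_series,
)


def _map_like(atlas, values, quantity="SUV"):
    return ParametricMap(
        values=values, quantity=quantity, mask=atlas.brain_mask,
        voxel_size=atlas.voxel_size,
    )


class TestExtractRegions:
    def test_constant_map(self, atlas):
        m = _map_like(atlas, np.ones(atlas.labels.shape))
        table = extract_regions(m, atlas, exclude=set())
        assert (table["mean_value"] == 1.0).all()
        assert len(table) == 16
        assert (table["voxel_count"] >= 50).all()

    def test_ground_truth_recovered_exactly(self, atlas, truth_clean):
        frame = simulate_pet(atlas, truth_clean)
        suv = compute_suv(frame, mask=atlas.brain_mask)
        table = extract_regions(suv, atlas, exclude=set())
        for _, row in table.iterrows():
            expected = truth_clean.get(truth_clean.suv, row.region, row.hemisphere)
            assert row.mean_value == pytest.approx(expected, rel=1e-10)

    def test_cerebellum_excluded(self, atlas):
        m = _map_like(atlas, np.ones(atlas.labels.shape))
        table = extract_regions(m, atlas, exclude={"cerebellum"})
        assert "cerebellum" not in set(table["region"])

    def test_modality_default_region_sets(self, atlas):
        m = _map_like(atlas, np.ones(atlas.labels.shape), quantity="K1")
        table = extract_regions(m, atlas)
        assert set(table["region"]) == set(DEFAULT_REGION_SETS["K1"])

    def test_grid_mismatch_rejected(self, atlas):
        m = ParametricMap(
            values=np.ones((8, 8, 4)), quantity="SUV", mask=np.ones((8, 8, 4), bool),
            voxel_size=atlas.voxel_size,
        )
        with pytest.raises(ValueError, match="grid"):
            extract_regions(m, atlas)

    def test_extra_row_keys_propagate(self, atlas):
        m = _map_like(atlas, np.ones(atlas.labels.shape))
        table = extract_regions(m, atlas, subject="s01", timepoint="pre")
        assert (table["subject"] == "s01").all()


class TestHemisphericDifference:
    def _table(self, left, right):
        rows = []
        for r, lv in left.items():
            rows.append(dict(subject="s", timepoint="pre", modality="SUV",
                             region=r, hemisphere="left", mean_value=lv, voxel_count=10))
        for r, rv in right.items():
            rows.append(dict(subject="s", timepoint="pre", modality="SUV",
                             region=r, hemisphere="right", mean_value=rv, voxel_count=10))
        return pd.DataFrame(rows)

    def test_symmetric_phantom_zero_difference(self, atlas, truth_clean):
        frame = simulate_pet(atlas, truth_clean)
        suv = compute_suv(frame, mask=atlas.brain_mask)
        table = extract_regions(suv, atlas, exclude=set(), subject="s", timepoint="pre")
        d = hemispheric_relative_difference(table)
        assert abs(d["rel_diff"].iloc[0]) < 1e-12

    def test_arithmetic_one_percent(self):
        t = self._table({"cortex": 1.0}, {"cortex": 0.99})
        d = hemispheric_relative_difference(t)
        assert d["rel_diff"].iloc[0] == pytest.approx(0.01, rel=1e-12)
        assert d["abs_rel_diff_pct"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_unweighted_mean_over_regions(self):
        # whole hemisphere = unweighted mean of regional means, so unequal
        # voxel counts must not change the result
        t = self._table({"cortex": 2.0, "thalamus": 0.0}, {"cortex": 1.0, "thalamus": 0.0})
        t.loc[t.region == "cortex", "voxel_count"] = 1000
        d = hemispheric_relative_difference(t)
        assert d["rel_diff"].iloc[0] == pytest.approx((1.0 - 0.5) / 1.0)

    def test_scale_invariance(self):
        t1 = self._table({"cortex": 1.0}, {"cortex": 0.9})
        t2 = t1.copy()
        t2["mean_value"] *= 1e3
        d1 = hemispheric_relative_difference(t1)["rel_diff"].iloc[0]
        d2 = hemispheric_relative_difference(t2)["rel_diff"].iloc[0]
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_zero_left_mean_rejected(self):
        t = self._table({"cortex": 0.0}, {"cortex": 1.0})
        with pytest.raises(ZeroDivisionError):
            hemispheric_relative_difference(t)

    def test_noisy_symmetric_phantom_unbiased(self):
        """With a common bilateral signal plus independent regional noise the
        expected relative difference is 0 (checked over replicates)."""
        rng = np.random.default_rng(9)
        diffs = []
        for _ in range(500):
            rows = []
            for r in ("cortex", "thalamus"):
                for h, v in (("left", 1.0), ("right", 1.0)):
                    rows.append(dict(subject="s", timepoint="pre", modality="SUV",
                                     region=r, hemisphere=h,
                                     mean_value=v + rng.normal(0, 0.02), voxel_count=5))
            diffs.append(
                hemispheric_relative_difference(pd.DataFrame(rows))["rel_diff"].iloc[0]
            )
        diffs = np.asarray(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std() / np.sqrt(diffs.size)


class TestHemisphereCorrelation:
    def _cohort_table(self, seed=0, regional_sd=0.05):
        design = CohortDesign(rng_seed=seed, regional_sd=regional_sd)
        table, _ = simulate_cohort(design)
        return table

    def test_identical_series_diagonal_one(self):
        table = self._cohort_table(regional_sd=0.0)
        # left and right carry the identical subject-by-time signal
        r, n = hemisphere_correlation(table, modality="SUV", dose=5.0)
        np.testing.assert_allclose(np.diag(r.to_numpy(dtype=float)), 1.0, rtol=1e-12)
        assert (n.to_numpy() >= 3).all()

    def test_negated_series_minus_one(self):
        table = self._cohort_table(regional_sd=0.0)
        table.loc[table.hemisphere == "right", "mean_value"] *= -1.0
        r, _ = hemisphere_correlation(table, modality="SUV", dose=5.0)
        np.testing.assert_allclose(np.diag(r.to_numpy(dtype=float)), -1.0, rtol=1e-12)

    def test_matches_independent_pearson(self):
        """Every cell equals scipy.stats.pearsonr computed directly from the
        pooled per-scan series."""
        table = self._cohort_table(seed=3, regional_sd=0.05)
        r, n = hemisphere_correlation(table, modality="SUV", dose=20.0)
        sub = table[(table.dose_Gy == 20.0)]
        for ri in ("cortex", "hippocampus"):
            for rj in ("thalamus", "cortex"):
                left = sub[(sub.region == ri) & (sub.hemisphere == "left")]
                right = sub[(sub.region == rj) & (sub.hemisphere == "right")]
                merged = left.merge(right, on=["subject", "timepoint"])
                expected = stats.pearsonr(merged.mean_value_x, merged.mean_value_y)[0]
                assert r.loc[ri, rj] == pytest.approx(expected, abs=1e-12)
                assert n.loc[ri, rj] == len(merged)

    def test_cells_bounded(self):
        table = self._cohort_table(seed=4)
        r, _ = hemisphere_correlation(table, modality="SUV")
        vals = r.to_numpy(dtype=float)
        assert np.nanmin(vals) >= -1.0 - 1e-12 and np.nanmax(vals) <= 1.0 + 1e-12

    def test_affine_invariance_of_one_hemisphere(self):
        table = self._cohort_table(seed=5)
        r1, _ = hemisphere_correlation(table, modality="SUV", dose=5.0)
        t2 = table.copy()
        right = t2.hemisphere == "right"
        t2.loc[right, "mean_value"] = 3.0 * t2.loc[right, "mean_value"] + 7.0
        r2, _ = hemisphere_correlation(t2, modality="SUV", dose=5.0)
        np.testing.assert_allclose(
            r1.to_numpy(dtype=float), r2.to_numpy(dtype=float), rtol=1e-9
        )

    def test_symmetric_region_drop_leaves_other_cells(self):
        table = self._cohort_table(seed=6)
        r_full, _ = hemisphere_correlation(table, modality="SUV", dose=5.0)
        dropped = table[table.region != "amygdala"]
        r_drop, _ = hemisphere_correlation(dropped, modality="SUV", dose=5.0)
        keep = [x for x in r_drop.index if x != "amygdala"]
        np.testing.assert_allclose(
            r_full.loc[keep, keep].to_numpy(dtype=float),
            r_drop.loc[keep, keep].to_numpy(dtype=float),
            rtol=1e-12,
        )

    def test_insufficient_pairs_nan(self):
        table = self._cohort_table(seed=7)
        tiny = table[table.timepoint == "pre"].groupby("subject").head(100)
        tiny = tiny[tiny.subject.isin(["s01", "s02"])]  # 2 observations only
        r, n = hemisphere_correlation(tiny, modality="SUV")
        assert np.isnan(r.to_numpy(dtype=float)).all()


class TestWholeBrain:
    def test_mean_over_hemisphere_means(self):
        table, _ = simulate_cohort(CohortDesign(rng_seed=1, regional_sd=0.0))
        wb = whole_brain_series(table, "SUV")
        # regional noise is zero, so the whole-brain value equals y itself
        one = table[(table.subject == "s01") & (table.timepoint == "pre")]
        got = wb[(wb.subject == "s01") & (wb.timepoint == "pre")]["whole_brain"].iloc[0]
        assert got == pytest.approx(one["mean_value"].iloc[0], rel=1e-12)
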