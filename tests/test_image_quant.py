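"""ROI algebra, rolling-ball subtraction and the recruitment measures,
checked against brute-force oracles where the operation is geometric."""

import numpy as np
import pandas as pd
import pytest

from synscreen.errors import MaskShapeError, UndefinedRatioError
from synscreen.quant import (
    Mask,
    coclustering_ratio,
    coculture_contact_measures,
    combine_masks,
    dilate_mask,
    invert_mask,
    match_surface_expression,
    morphology_measures,
    normalize_to_control,
    rolling_ball_subtract,
    threshold_mask,
)
from synscreen.scenes import CocultureSceneSpec, make_coculture_scene

# ---------------------------------------------------------------------------
# brute-force oracles


def brute_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Lattice-point oracle: pixel in output iff any true pixel lies within
    Euclidean distance `radius`."""
    out = np.zeros_like(mask)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return out
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            out[i, j] = np.any((ys - i) ** 2 + (xs - j) ** 2 <= radius**2)
    return out


def brute_ball_opening(img: np.ndarray, r: int) -> np.ndarray:
    """Per-pixel erosion-then-dilation with a spherical-cap structuring
    element, padded by edge replication."""
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    fp = dy**2 + dx**2 <= r**2
    hs = np.zeros_like(fp, dtype=float)
    hs[fp] = np.sqrt(float(r) ** 2 - (dy**2 + dx**2)[fp])
    offs = [(a, b) for a in range(-r, r + 1) for b in range(-r, r + 1) if fp[a + r, b + r]]

    def erode(f):
        pad = np.pad(f, r, mode="edge")
        out = np.empty_like(f)
        for i in range(f.shape[0]):
            for j in range(f.shape[1]):
                out[i, j] = min(pad[i + r + a, j + r + b] - hs[a + r, b + r] for a, b in offs)
        return out

    def dilate(f):
        pad = np.pad(f, r, mode="edge")
        out = np.empty_like(f)
        for i in range(f.shape[0]):
            for j in range(f.shape[1]):
                out[i, j] = max(pad[i + r - a, j + r - b] + hs[a + r, b + r] for a, b in offs)
        return out

    return dilate(erode(img))


# ---------------------------------------------------------------------------
# thresholding and mask algebra


class TestThresholdMask:
    def test_all_zero_image_gives_empty_mask(self):
        assert threshold_mask(np.zeros((8, 8)), 1.0).area == 0

    def test_threshold_zero_gives_full_mask(self):
        assert threshold_mask(np.zeros((8, 8)), 0.0).area == 64

    def test_disk_area_recovered(self):
        yy, xx = np.mgrid[:32, :32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= 36
        img = np.where(disk, 100.0, 0.0)
        assert threshold_mask(img, 50.0).area == disk.sum()

    def test_threshold_is_lower_inclusive(self):
        img = np.array([[49.0, 50.0, 51.0]])
        assert threshold_mask(img, 50.0).pixels.tolist() == [[False, True, True]]


class TestMaskAlgebra:
    def test_double_inversion_is_identity(self, rng):
        m = Mask(rng.random((16, 16)) < 0.3)
        assert invert_mask(invert_mask(m)) == m

    def test_mask_and_its_complement_are_disjoint(self, rng):
        m = Mask(rng.random((16, 16)) < 0.3)
        assert (m & invert_mask(m)).area == 0
        assert (m | invert_mask(m)).area == 16 * 16

    def test_combine_ops(self):
        a = Mask(np.array([[True, True], [False, False]]))
        b = Mask(np.array([[True, False], [True, False]]))
        assert combine_masks(a, b, "and").pixels.tolist() == [[True, False], [False, False]]
        assert combine_masks(a, b, "or").pixels.tolist() == [[True, True], [True, False]]
        assert combine_masks(a, b, "minus").pixels.tolist() == [[False, True], [False, False]]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(MaskShapeError):
            Mask(np.zeros((2, 2), bool)) & Mask(np.zeros((3, 3), bool))


class TestDilation:
    def test_empty_mask_stays_empty(self):
        assert dilate_mask(Mask(np.zeros((16, 16), bool)), 5).area == 0

    def test_radius_zero_is_identity(self, rng):
        m = Mask(rng.random((16, 16)) < 0.3)
        assert dilate_mask(m, 0) == m

    def test_single_pixel_dilation_counts_lattice_points_in_disk(self):
        m = np.zeros((21, 21), bool)
        m[10, 10] = True
        expected = sum(
            1 for a in range(-5, 6) for b in range(-5, 6) if a * a + b * b <= 25
        )
        assert dilate_mask(Mask(m), 5).area == expected == 81

    def test_dilation_contains_input(self, rng):
        m = Mask(rng.random((24, 24)) < 0.1)
        for radius in (1, 3, 5):
            assert (m & dilate_mask(m, radius)) == m

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_distance_oracle_exactly_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((32, 32)) < 0.05
        got = dilate_mask(Mask(m), 5).pixels
        assert np.array_equal(got, brute_dilate(m, 5))


class TestRollingBall:
    def test_constant_image_is_fully_removed(self):
        out = rolling_ball_subtract(np.full((64, 64), 37.5), 14)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_narrow_peak_survives_subtraction(self):
        img = np.full((64, 64), 20.0)
        img[30:33, 30:33] += 100.0  # 3-px-wide peak, ball radius 14
        out = rolling_ball_subtract(img, 14)
        assert out[31, 31] == pytest.approx(100.0, rel=0.05)

    def test_output_never_exceeds_input(self, rng):
        img = rng.uniform(0, 100, (48, 48))
        out = rolling_ball_subtract(img, 10)
        assert np.all(out <= img + 1e-12)
        assert np.all(out >= 0)

    def test_matches_brute_force_opening_oracle(self, rng):
        img = rng.uniform(0, 100, (32, 32))
        background = img - rolling_ball_subtract(img, 14)
        oracle = np.minimum(brute_ball_opening(img, 14), img)
        assert np.abs(background - oracle).max() < 1e-9

    def test_background_estimate_is_idempotent(self, rng):
        img = rng.uniform(0, 100, (48, 48))
        bg1 = img - rolling_ball_subtract(img, 10)
        bg2 = bg1 - rolling_ball_subtract(bg1, 10)
        assert np.abs(bg1 - bg2).max() < 1e-9

    def test_translation_equivariance_away_from_borders(self, rng):
        img = rng.uniform(0, 100, (64, 64))
        out = rolling_ball_subtract(img, 6)
        out_shifted = rolling_ball_subtract(np.roll(img, 5, axis=1), 6)
        # compare interior pixels unaffected by the border handling
        assert np.allclose(out[:, 12:40], np.roll(out_shifted, -5, axis=1)[:, 12:40])

    def test_oversized_ball_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(np.zeros((16, 16)), 14)


class TestCoclusteringRatio:
    def _masks(self):
        cell = np.zeros((32, 32), bool)
        cell[4:28, 4:28] = True
        puncta = np.zeros((32, 32), bool)
        puncta[10:14, 10:14] = True
        return Mask(puncta), Mask(cell)

    def test_uniform_reporter_gives_ratio_one(self):
        puncta, cell = self._masks()
        res = coclustering_ratio(np.full((32, 32), 7.0), puncta, cell)
        assert res.value == pytest.approx(1.0)

    def test_twofold_enrichment_gives_ratio_two(self):
        puncta, cell = self._masks()
        v5 = np.ones((32, 32))
        v5[puncta.pixels] = 2.0
        res = coclustering_ratio(v5, puncta, cell)
        assert res.value == pytest.approx(2.0)
        assert res.roi_in_area == 16

    def test_ratio_invariant_under_positive_scaling(self, rng):
        puncta, cell = self._masks()
        v5 = rng.uniform(1, 10, (32, 32))
        r1 = coclustering_ratio(v5, puncta, cell).value
        r2 = coclustering_ratio(13.7 * v5, puncta, cell).value
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_empty_roi_is_an_error(self):
        _, cell = self._masks()
        empty = Mask(np.zeros((32, 32), bool))
        with pytest.raises(UndefinedRatioError):
            coclustering_ratio(np.ones((32, 32)), empty, cell)


THRESH = {"inducer": 50.0, "tau": 45.0, "map2": 55.0, "synapsin": 90.0}


class TestCocultureMeasures:
    def test_zero_synapsin_gives_zero_measure(self):
        s = make_coculture_scene(
            CocultureSceneSpec(
                image_shape=(192, 192),
                synapsin_density_on_contact=0.0,
                synapsin_density_off_contact=0.0,
                diffuse_synapsin=0.0,
                seed=0,
            )
        )
        m = coculture_contact_measures(s.channels, THRESH)
        assert m.synapsin_per_contact_area == 0.0

    def test_contact_roi_matches_ground_truth_mask_algebra(self):
        s = make_coculture_scene(CocultureSceneSpec(image_shape=(192, 192), seed=1))
        m = coculture_contact_measures(s.channels, THRESH)
        assert m.contact_area == int(s.ground_truth["contact_mask"].sum())
        assert m.contact_area <= m.cos_area

    def test_enlarging_map2_shrinks_contact_area(self):
        s = make_coculture_scene(CocultureSceneSpec(image_shape=(192, 192), seed=1))
        small = coculture_contact_measures(s.channels, THRESH, map2_dilate_px=2)
        large = coculture_contact_measures(s.channels, THRESH, map2_dilate_px=10)
        assert large.contact_area < small.contact_area

    def test_empty_contact_reports_absent_not_zero(self):
        channels = {
            "inducer": np.where(np.arange(64)[None, :] < 32, 100.0, 0.0) * np.ones((64, 1)),
            "tau": np.zeros((64, 64)),
            "map2": np.zeros((64, 64)),
            "synapsin": np.zeros((64, 64)),
        }
        m = coculture_contact_measures(channels, THRESH)
        assert m.contact_area == 0
        assert m.synapsin_per_contact_area is None


class TestMatchSurfaceExpression:
    def _cells(self, levels, groups=None):
        return pd.DataFrame(
            {
                "cell_id": range(len(levels)),
                "group": groups or ["WT"] * len(levels),
                "v5_level": levels,
            }
        )

    def test_identical_levels_exclude_nothing(self):
        out = match_surface_expression(self._cells([5.0] * 10), "WT")
        assert out["kept"].all()

    def test_tenfold_outlier_is_excluded(self):
        levels = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 1.02, 0.98, 10.0]
        out = match_surface_expression(self._cells(levels), "WT")
        assert not out.loc[out["v5_level"] == 10.0, "kept"].iloc[0]
        assert "above" in out.loc[out["v5_level"] == 10.0, "reason"].iloc[0]

    def test_full_band_keeps_everything(self):
        levels = [0.1, 1.0, 50.0]
        out = match_surface_expression(self._cells(levels), "WT", band=(0.0, 100.0))
        assert out["kept"].all()

    def test_band_is_computed_on_the_reference_group_only(self):
        cells = self._cells([1.0] * 8 + [100.0], groups=["WT"] * 8 + ["mut"])
        out = match_surface_expression(cells, "WT")
        assert not out.loc[out["group"] == "mut", "kept"].iloc[0]


class TestNormalizeToControl:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["culture", "condition", "value"])

    def test_control_group_mean_is_one_by_construction(self):
        df = self._frame([("c1", "ctrl", 2.0), ("c1", "ctrl", 4.0), ("c1", "x", 6.0)])
        out = normalize_to_control(df, "ctrl")
        assert out.loc[out["condition"] == "ctrl", "normalized"].mean() == pytest.approx(1.0)

    def test_values_divided_by_control_mean(self):
        df = self._frame([("c1", "ctrl", 2.0), ("c1", "x", 2.0), ("c1", "x", 4.0)])
        out = normalize_to_control(df, "ctrl")
        assert out.loc[out["condition"] == "x", "normalized"].tolist() == [1.0, 2.0]

    def test_cultures_normalize_independently(self):
        df = self._frame(
            [("c1", "ctrl", 2.0), ("c1", "x", 4.0), ("c2", "ctrl", 10.0), ("c2", "x", 20.0)]
        )
        out = normalize_to_control(df, "ctrl")
        assert out.loc[out["condition"] == "x", "normalized"].tolist() == [2.0, 2.0]

    def test_missing_control_flags_culture_instead_of_dropping(self):
        df = self._frame([("c1", "ctrl", 2.0), ("c2", "x", 4.0)])
        out = normalize_to_control(df, "ctrl")
        assert out.loc[out["culture"] == "c2", "control_missing"].all()
        assert len(out) == 2


class TestMorphology:
    def test_scaling_intensities_and_thresholds_leaves_areas_unchanged(self, rng):
        channels = {
            "tau": rng.uniform(0, 100, (64, 64)),
            "map2": rng.uniform(0, 100, (64, 64)),
            "dapi": np.where(brute_dilate(np.eye(64, dtype=bool), 4), 150.0, 0.0),
        }
        thr = {"tau": 50.0, "map2": 40.0, "dapi": 75.0}
        m1 = morphology_measures(channels, thr)
        m2 = morphology_measures(
            {k: 2 * v for k, v in channels.items()}, {k: 2 * v for k, v in thr.items()}
        )
        assert (m1.tau_area, m1.map2_area) == (m2.tau_area, m2.map2_area)

    def test_zero_nuclei_leaves_per_nucleus_measures_undefined(self):
        channels = {
            "tau": np.full((32, 32), 100.0),
            "map2": np.full((32, 32), 100.0),
            "dapi": np.zeros((32, 32)),
        }
        m = morphology_measures(channels, {"tau": 50.0, "map2": 50.0, "dapi": 75.0})
        assert m.n_nuclei == 0
        assert m.tau_area_per_nucleus is None

    def test_small_specks_below_min_area_are_not_counted_as_nuclei(self):
        dapi = np.zeros((64, 64))
        dapi[10:12, 10:12] = 150.0  # 4-px speck
        dapi[30:40, 30:40] = 150.0  # genuine nucleus
        channels = {"tau": np.zeros((64, 64)), "map2": np.zeros((64, 64)), "dapi": dapi}
        m = morphology_measures(channels, {"tau": 50.0, "map2": 50.0, "dapi": 75.0})
        assert m.n_nuclei == 1
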