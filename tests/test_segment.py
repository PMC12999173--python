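"""Maxima detection, seeded segmentation, measurement and tiling contracts."""

import numpy as np
import pandas as pd
import pytest
from _oracles import flood_maxima

from azprofile.core import VolumetricImage
from azprofile.segment import (
    DetectionParams,
    find_maxima_3d,
    measure_clusters,
    segment_spots,
    segment_stack,
    tile_and_stitch,
    upsample_xy,
)
from azprofile.synthetic import Layout, SyntheticSpec, render_stack

SPACING = (0.37, 0.079, 0.079)
ISO = (0.1, 0.1, 0.1)


def gaussian_image(centers_um, intensities, sigma_xy=0.15, sigma_z=0.3,
                   shape=(20, 64, 64), spacing=SPACING, background=0.0):
    spec = SyntheticSpec(shape=shape, spacing=spacing, noise_model="none",
                         background=background, layout=Layout(names=("roi",)))
    n = len(centers_um)
    marks = pd.DataFrame({"intensity": list(intensities),
                          "sigma_xy_um": [sigma_xy] * n,
                          "sigma_z_um": [sigma_z] * n,
                          "compartment": ["roi"] * n})
    img, _ = render_stack(np.asarray(centers_um, float), marks, spec, quantize=False)
    return VolumetricImage(img.data, spacing)


class TestUpsample:
    def test_factor_one_is_identity(self, rng):
        img = VolumetricImage(rng.uniform(0, 100, (5, 12, 12)), SPACING)
        out = upsample_xy(img, 1)
        np.testing.assert_array_equal(out.data, img.data)
        assert out.spacing == img.spacing

    def test_factor_two_doubles_xy_and_halves_lateral_spacing(self, rng):
        img = VolumetricImage(rng.uniform(0, 100, (10, 64, 64)), SPACING)
        out = upsample_xy(img, 2)
        assert out.shape == (10, 128, 128)
        assert out.spacing == (0.37, 0.079 / 2, 0.079 / 2)

    def test_constant_image_stays_constant(self):
        img = VolumetricImage(np.full((4, 8, 8), 42.0), SPACING)
        out = upsample_xy(img, 2)
        np.testing.assert_allclose(out.data, 42.0)


class TestFindMaxima:
    def test_uniform_image_has_no_seeds(self):
        img = np.full((8, 8, 8), 10.0)
        assert len(find_maxima_3d(img, 0.0, 1.0)) == 0

    def test_two_separated_peaks_detected_at_their_voxels(self):
        img = gaussian_image([(1.2, 1.2, 1.85), (3.8, 3.8, 5.55)],
                             [30000, 30000])
        seeds = find_maxima_3d(img, 50.0, 200.0)
        assert len(seeds) == 2
        vals = img.data[tuple(seeds.T)]
        assert np.all(vals >= 0.99 * img.data.max())

    def test_shoulder_below_noise_tolerance_suppressed(self):
        # ridge with main peak and a shoulder within the tolerance: one seed
        img = np.zeros((5, 9, 9))
        img[2, 4, 2] = 1100.0          # main peak
        img[2, 4, 3:6] = 950.0         # ridge
        img[2, 4, 6] = 1050.0          # shoulder, prominence 100 < 200
        seeds = find_maxima_3d(img, 0.0, 200.0)
        assert [tuple(s) for s in seeds] == [(2, 4, 2)]
        seeds2 = find_maxima_3d(img, 0.0, 90.0)  # tolerance below prominence
        assert len(seeds2) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_literal_flood_oracle_on_random_stacks(self, seed):
        rng = np.random.default_rng(seed)
        img = np.round(rng.uniform(0, 60, size=(6, 12, 12))
                       + 400 * rng.binomial(1, 0.01, size=(6, 12, 12)))
        thr = float(rng.choice([0.0, 20.0, 45.0]))
        nt = float(rng.choice([5.0, 15.0, 40.0]))
        got = [tuple(s) for s in find_maxima_3d(img, thr, nt)]
        assert got == flood_maxima(img, thr, nt)

    @pytest.mark.parametrize("seed", range(4))
    def test_seed_count_monotone_in_threshold_and_tolerance(self, seed):
        rng = np.random.default_rng(100 + seed)
        img = np.round(rng.uniform(0, 100, size=(6, 14, 14)))
        levels = [0.0, 10.0, 30.0, 60.0]
        for nt in levels:
            counts = [len(find_maxima_3d(img, thr, nt)) for thr in levels]
            assert counts == sorted(counts, reverse=True)
        for thr in levels:
            counts = [len(find_maxima_3d(img, thr, nt)) for nt in levels]
            assert counts == sorted(counts, reverse=True)

    def test_empty_image_returns_empty(self):
        assert len(find_maxima_3d(np.zeros((4, 4, 4)), 10.0, 1.0)) == 0


class TestSegmentSpots:
    def test_isotropic_spot_region_reaches_two_sigma(self):
        # sd_value = 2 puts the local threshold at the e^{-2} isocontour,
        # i.e. a ball of radius 2 sigma for an isotropic Gaussian
        sigma = 0.4
        img = gaussian_image([(3.2, 3.2, 3.2)], [1e6], sigma_xy=sigma,
                             sigma_z=sigma, shape=(64, 64, 64), spacing=ISO)
        params = DetectionParams(threshold=0.0, noise_tolerance=100.0,
                                 max_spot_radius_um=2.0)
        seeds = find_maxima_3d(img, 0.0, 100.0)
        labels = segment_spots(img, seeds, params)
        vol_um3 = np.count_nonzero(labels.labels) * np.prod(ISO)
        r_eq = (3 * vol_um3 / (4 * np.pi)) ** (1 / 3)
        assert r_eq == pytest.approx(2 * sigma, rel=0.15)

    def test_adjacent_identical_spots_split_at_midplane(self):
        img = gaussian_image([(2.4, 3.2, 3.2), (4.0, 3.2, 3.2)], [1e6, 1e6],
                             sigma_xy=0.4, sigma_z=0.4, shape=(64, 64, 64),
                             spacing=ISO)
        params = DetectionParams(threshold=0.0, noise_tolerance=500.0,
                                 max_spot_radius_um=2.0)
        seeds = find_maxima_3d(img, 0.0, 500.0)
        assert len(seeds) == 2
        labels = segment_spots(img, seeds, params)
        v1 = np.count_nonzero(labels.labels == 1)
        v2 = np.count_nonzero(labels.labels == 2)
        # voxel counts equal up to one boundary layer
        assert abs(v1 - v2) <= 64 * 64
        # no voxel on the wrong side of the midplane (x index 32)
        x_of = np.nonzero(labels.labels == 1)[2]
        assert x_of.min() >= 0 and np.all(np.nonzero(labels.labels == 2)[2] >= 32 - 1)

    def test_single_voxel_impulse_segments_to_itself(self):
        img = np.full((7, 9, 9), 5.0)
        img[3, 4, 4] = 500.0
        vi = VolumetricImage(img, ISO)
        seeds = find_maxima_3d(vi, 0.0, 10.0)
        labels = segment_spots(vi, seeds, DetectionParams(threshold=0.0,
                                                          noise_tolerance=10.0,
                                                          max_spot_radius_um=0.5))
        assert np.count_nonzero(labels.labels) == 1
        assert labels.labels[3, 4, 4] == 1

    def test_regions_are_disjoint_and_contain_their_seeds(self):
        img = gaussian_image([(1.0, 1.0, 1.85), (2.5, 2.8, 3.7), (4.0, 1.5, 5.55)],
                             [20000, 35000, 25000])
        seeds = find_maxima_3d(img, 10.0, 100.0)
        labels = segment_spots(img, seeds, DetectionParams(threshold=10.0,
                                                           noise_tolerance=100.0))
        for i, (z, y, x) in enumerate(seeds, start=1):
            assert labels.labels[z, y, x] == i


class TestMeasure:
    def test_cube_volume_and_intensity_arithmetic(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[1:4, 1:4, 1:4] = 1
        raw = np.full((6, 6, 6), 100.0)
        from azprofile.core import LabelVolume
        table = measure_clusters(LabelVolume(labels, ISO), VolumetricImage(raw, ISO))
        assert table.df.loc[0, "volume_vox"] == 27
        assert table.df.loc[0, "intensity"] == 2700.0

    def test_empty_labels_give_empty_table(self):
        from azprofile.core import LabelVolume
        table = measure_clusters(LabelVolume(np.zeros((4, 4, 4), np.int32), ISO),
                                 VolumetricImage(np.ones((4, 4, 4)), ISO))
        assert len(table) == 0

    def test_recovered_intensities_match_ground_truth_marks(self):
        # well-separated noise-free spots: integrated intensity within 5%
        centers = [(1.0, 1.0, 1.85), (4.0, 1.0, 5.55), (1.0, 4.0, 5.55),
                   (4.0, 4.0, 1.85)]
        truth_intensity = np.array([20000.0, 30000.0, 25000.0, 40000.0])
        img = gaussian_image(centers, truth_intensity, shape=(20, 64, 64))
        params = DetectionParams(threshold=5.0, noise_tolerance=100.0,
                                 sd_value=3.0, max_spot_radius_um=0.8)
        table = segment_stack(img, img, params)
        assert len(table) == 4
        got = table.df.sort_values("x_um")["intensity"].to_numpy()
        want = truth_intensity[np.argsort([c[0] for c in centers])]
        np.testing.assert_allclose(got, want, rtol=0.05)


def synthetic_pair(seed, shape=(16, 96, 96)):
    """(detect, measure) images for a small synthetic sample."""
    spec = SyntheticSpec(shape=shape, spacing=SPACING, density=0.15,
                         min_separation=0.4, intensity_logmean=9.0,
                         noise_model="poisson", background=2.0,
                         layout=Layout(names=("roi",)), seed=seed)
    from azprofile.synthetic import simulate
    img, truth, _ = simulate(spec)
    vi = VolumetricImage(img.data.astype(float), img.spacing)
    return vi, vi


class TestTiling:
    PARAMS = DetectionParams(threshold=80.0, noise_tolerance=80.0,
                             tile_margin=16, max_spot_radius_um=0.6)

    @staticmethod
    def _records(table):
        cols = ["seed_z", "seed_y", "seed_x", "volume_vox"]
        df = table.df.sort_values(["seed_z", "seed_y", "seed_x"]).reset_index(drop=True)
        return df[cols + ["x_um", "y_um", "z_um", "intensity"]]

    def test_single_tile_equals_untiled(self):
        det, mea = synthetic_pair(0)
        p = DetectionParams(threshold=80.0, noise_tolerance=80.0, tile_grid=(1, 1),
                            tile_margin=16, max_spot_radius_um=0.6)
        a = self._records(segment_stack(det, mea, p))
        b = self._records(tile_and_stitch(det, mea, p))
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_five_by_five_grid_equals_untiled(self, seed):
        det, mea = synthetic_pair(seed)
        a = self._records(segment_stack(det, mea, self.PARAMS))
        b = self._records(tile_and_stitch(det, mea, self.PARAMS))
        pd.testing.assert_frame_equal(a, b)

    def test_cluster_on_tile_boundary_appears_once(self):
        # spot centred exactly on the x midline of a 2x1 grid
        img = gaussian_image([(32 * 0.079, 2.0, 2.96)], [50000],
                             shape=(16, 64, 64))
        p = DetectionParams(threshold=20.0, noise_tolerance=50.0, tile_grid=(2, 1),
                            tile_margin=16, max_spot_radius_um=0.6)
        table = tile_and_stitch(img, img, p)
        assert len(table) == 1

    def test_margin_below_window_warns(self):
        det, mea = synthetic_pair(3, shape=(8, 48, 48))
        p = DetectionParams(threshold=80.0, noise_tolerance=80.0, tile_grid=(2, 2),
                            tile_margin=1, max_spot_radius_um=0.6)
        with pytest.warns(UserWarning, match="tile_margin"):
            tile_and_stitch(det, mea, p)
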