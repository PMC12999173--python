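"""Generator contracts: domains, point processes, marks, rendering."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, pearsonr, spearmanr

from azprofile.spatial import nearest_neighbor_indices
from azprofile.synthetic import (
    DensityInfeasibleError,
    Layout,
    SyntheticSpec,
    apply_condition_effect,
    assign_marks,
    domain_for,
    generate_domain,
    render_stack,
    sample_cluster_centers,
    simulate,
)

SPACING = (0.2, 0.1, 0.1)


def flat_spec(**kw) -> SyntheticSpec:
    base = dict(shape=(30, 60, 60), spacing=SPACING, process="hardcore",
                density=0.5, min_separation=0.2, noise_model="none",
                background=0.0, layout=Layout(names=("roi",)), seed=0)
    base.update(kw)
    return SyntheticSpec(**base)


class TestDomain:
    def test_single_compartment_box_is_fully_labelled(self):
        dom = generate_domain((10, 10, 10), SPACING, Layout(names=("roi",)))
        assert np.all(dom.labels == 1)
        assert dom.names == {1: "roi"}

    def test_five_equal_slabs_each_own_a_fifth_of_the_axis(self):
        dom = generate_domain((100, 100, 100), SPACING,
                              Layout(names=tuple("abcde"), axis="x"))
        for lab in range(1, 6):
            planes = np.unique(np.nonzero(dom.labels == lab)[2])
            assert len(planes) == 20
        # every voxel assigned exactly one compartment
        assert np.all(dom.labels > 0)

    def test_tube_volume_matches_cylinder_formula(self):
        # radius 5 um tube along x in a 20 um box, spacing 0.1 um:
        # foreground fraction = pi r^2 / side^2
        dom = generate_domain((200, 200, 200), (0.1, 0.1, 0.1),
                              Layout(names=("t",), kind="tube", radius_um=5.0))
        expected = np.pi * 25.0 / 400.0
        assert dom.foreground_fraction() == pytest.approx(expected, rel=0.05)

    def test_zero_volume_compartment_rejected(self):
        with pytest.raises(ValueError, match="zero volume"):
            generate_domain((10, 10, 3), SPACING,
                            Layout(names=tuple("abcde"), axis="x"))


class TestCenters:
    def test_zero_density_gives_empty_list(self):
        spec = flat_spec(density=0.0)
        assert len(sample_cluster_centers(spec)) == 0

    def test_hardcore_count_is_poisson_around_density_times_volume(self):
        spec = flat_spec(density=0.5, min_separation=0.15)
        dom = domain_for(spec)
        lam = spec.density * dom.foreground_volume_um3()
        counts = [len(sample_cluster_centers(dataclasses.replace(spec, seed=s), dom))
                  for s in range(20)]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam)

    @pytest.mark.parametrize("seed", range(5))
    def test_hardcore_separation_never_violated(self, seed):
        spec = flat_spec(density=1.0, min_separation=0.4, seed=seed)
        pts = sample_cluster_centers(spec)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.4

    def test_infeasible_density_reports_after_retry_budget(self):
        spec = flat_spec(density=50.0, min_separation=1.0)
        with pytest.raises(DensityInfeasibleError):
            sample_cluster_centers(spec)

    def test_centers_stay_inside_foreground(self):
        spec = flat_spec(layout=Layout(names=("t",), kind="tube", radius_um=1.5),
                         density=1.0, min_separation=0.1)
        dom = domain_for(spec)
        pts = sample_cluster_centers(spec, dom)
        assert len(pts) > 0
        assert np.all(dom.label_at_points(pts) > 0)

    def test_thomas_process_produces_clustered_offspring(self):
        spec = flat_spec(process="thomas", parent_rate=0.05, offspring_mean=20,
                         offspring_scatter=0.4, min_separation=0.0)
        pts = sample_cluster_centers(spec)
        assert len(pts) > 50
        # clustered pattern: mean NND well below the Poisson expectation
        from _oracles import brute_nnd
        dom = domain_for(spec)
        lam = len(pts) / dom.foreground_volume_um3()
        poisson_nnd = 0.5540 * lam ** (-1 / 3)
        assert brute_nnd(pts).mean() < 0.7 * poisson_nnd


class TestMarks:
    def _points_spec(self, **kw):
        base = dict(shape=(40, 120, 120), spacing=SPACING, density=0.6,
                    min_separation=0.15, corr_length=1.0,
                    intensity_logmean=6.0, intensity_logsd=0.5,
                    noise_model="none", background=0.0,
                    layout=Layout(names=("roi",)))
        base.update(kw)
        return SyntheticSpec(**base)

    def test_uncorrelated_marks_have_no_neighbour_correlation(self):
        rs = []
        for seed in range(5):
            spec = self._points_spec(spatial_corr_weight=0.0, seed=seed)
            pts = sample_cluster_centers(spec)
            marks = assign_marks(pts, spec)
            nn = nearest_neighbor_indices(pts)
            logi = np.log(marks["intensity"].to_numpy())
            rs.append(pearsonr(logi, logi[nn]).statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_spatially_correlated_marks_correlate_between_neighbours(self):
        spec = self._points_spec(spatial_corr_weight=0.8, corr_length=2.0, seed=3)
        pts = sample_cluster_centers(spec)
        marks = assign_marks(pts, spec)
        nn = nearest_neighbor_indices(pts)
        logi = np.log(marks["intensity"].to_numpy())
        assert pearsonr(logi, logi[nn]).statistic > 0.5

    def test_log_intensity_marginal_is_normal(self):
        # KS against Normal(logmean, logsd^2), n ~ 5000, alpha = 0.01
        spec = self._points_spec(shape=(60, 160, 160), density=1.8,
                                 spatial_corr_weight=0.6, seed=11)
        pts = sample_cluster_centers(spec)
        assert len(pts) >= 5000
        marks = assign_marks(pts[:5000], spec)
        logi = np.log(marks["intensity"].to_numpy())
        stat = kstest(logi, "norm", args=(6.0, 0.5))
        assert stat.pvalue > 0.01

    def test_full_size_intensity_coupling_forces_monotone_sizes(self):
        spec = self._points_spec(size_intensity_coupling=1.0, seed=2)
        pts = sample_cluster_centers(spec)
        marks = assign_marks(pts, spec)
        rho = spearmanr(marks["sigma_xy_um"], marks["intensity"]).statistic
        assert rho == pytest.approx(1.0)


class TestRender:
    def test_single_cluster_voxel_sum_equals_integrated_intensity(self):
        spec = flat_spec()
        marks = pd.DataFrame({"intensity": [5000.0], "sigma_xy_um": [0.15],
                              "sigma_z_um": [0.3], "compartment": ["roi"]})
        img, truth = render_stack(np.array([[3.0, 3.0, 3.0]]), marks, spec,
                                  quantize=False)
        assert img.data.sum() == pytest.approx(5000.0, rel=0.005)
        assert len(truth) == 1

    def test_zero_clusters_gives_background_only_stack(self):
        spec = flat_spec(background=7.0)
        img, truth = render_stack(np.empty((0, 3)), pd.DataFrame(
            columns=["intensity", "sigma_xy_um", "sigma_z_um", "compartment"]), spec)
        assert len(truth) == 0
        assert img.data.max() == 7  # noise floor only

    def test_two_separated_clusters_preserve_intensity_ratio(self):
        spec = flat_spec()
        marks = pd.DataFrame({"intensity": [1000.0, 3000.0],
                              "sigma_xy_um": [0.15, 0.15],
                              "sigma_z_um": [0.3, 0.3],
                              "compartment": ["roi", "roi"]})
        centers = np.array([[1.5, 1.5, 1.5], [4.5, 4.5, 4.5]])
        img, _ = render_stack(centers, marks, spec, quantize=False)
        a = img.data[:, :30, :30].sum()
        b = img.data.sum() - a
        assert b / a == pytest.approx(3.0, rel=0.02)

    def test_flux_conserved_over_many_clusters(self):
        spec = flat_spec(density=0.3, seed=5)
        pts = sample_cluster_centers(spec)
        marks = assign_marks(pts, spec)
        img, truth = render_stack(pts, marks, spec, quantize=False)
        assert img.data.sum() == pytest.approx(truth["intensity"].sum(), rel=0.01)

    def test_psf_spacing_mismatch_rejected(self):
        from azprofile.psf import gaussian_psf
        spec = flat_spec()
        psf = gaussian_psf((0.5, 0.2, 0.2), 0.1, 0.3, shape=(5, 9, 9))
        marks = pd.DataFrame({"intensity": [100.0], "sigma_xy_um": [0.15],
                              "sigma_z_um": [0.3], "compartment": ["roi"]})
        with pytest.raises(ValueError, match="spacing"):
            render_stack(np.array([[3.0, 3.0, 3.0]]), marks, spec, psf=psf)

    def test_identical_spec_and_seed_reproduce_stack_bitwise(self):
        spec = flat_spec(density=0.3, noise_model="poisson", background=2.0, seed=9)
        img1, truth1, _ = simulate(spec)
        img2, truth2, _ = simulate(spec)
        assert np.array_equal(img1.data, img2.data)
        pd.testing.assert_frame_equal(truth1, truth2)


class TestConditionEffect:
    def _spec(self):
        return flat_spec(layout=Layout(names=("g1", "g2", "g3")),
                         density_coupling=0.9, spatial_corr_weight=0.8)

    def test_zero_decoupling_leaves_spec_unchanged(self):
        spec = self._spec()
        out = apply_condition_effect(spec, ["g2"], 0.0)
        assert out.coupling_for("g2") == spec.coupling_for("g2")

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValueError, match="unknown compartment"):
            apply_condition_effect(self._spec(), ["nope"], 0.5)

    def test_decoupling_scales_named_compartment_only(self):
        spec = self._spec()
        out = apply_condition_effect(spec, ["g2"], 1.0)
        assert out.coupling_for("g2") == 0.0
        assert out.coupling_for("g1") == spec.coupling_for("g1")
        half = apply_condition_effect(spec, ["g2"], 0.5)
        assert 0.0 < half.coupling_for("g2") < spec.coupling_for("g2")


class TestValidation:
    @pytest.mark.parametrize("kw", [
        {"density": -1.0},
        {"min_separation": -0.1},
        {"spatial_corr_weight": 1.5},
        {"size_intensity_coupling": -2.0},
        {"spot_sigma_xy": 0.0},
        {"noise_model": "salt"},
        {"process": "matern"},
    ])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            flat_spec(**kw)
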