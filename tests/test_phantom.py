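import warnings

import numpy as np
import pytest

from lungafc import ImageVolume, build_phantom, default_spec_2d
from lungafc.grids import Grid
from lungafc.phantom import (
    Ellipsoid,
    PhantomSpec,
    digital_twin_from_labels,
    lung_analysis_mask,
    lung_density_stats,
    make_voi,
)


class TestMixtureModelConsistency:
    def test_mu_map_satisfies_two_component_model_exactly(self, bundle):
        lung = bundle.lung_mask.data > 0.5
        spec = bundle.spec
        expected = bundle.vt_map.data * spec.mu_t + (1 - bundle.vt_map.data) * spec.mu_a
        assert np.max(np.abs(bundle.mu_map.data[lung] - expected[lung])) == 0.0

    def test_ground_truth_af_corrected_lung_is_uniform(self, bundle):
        lung = bundle.lung_mask.data > 0.5
        afc = bundle.emission.data[lung] / bundle.vt_map.data[lung]
        assert afc.std() < 1e-9
        assert np.allclose(afc.mean(), bundle.spec.suv_afc)

    def test_uniform_half_tissue_gives_half_mu(self):
        spec = PhantomSpec(vt_healthy=0.5, vt_fibrotic=0.5, vt_rel_sd_healthy=0.0,
                           vt_rel_sd_fibrotic=0.0, vt_edge_mm=0.0, vessels=(), seed=0)
        b = build_phantom(spec)
        lung = b.lung_mask.data > 0.5
        assert np.allclose(b.mu_map.data[lung], 0.048)

    def test_emission_zero_outside_body(self, bundle):
        body = bundle.mu_map.data > 0
        assert np.all(bundle.emission.data[~body] == 0)


class TestGeneratorStatistics:
    def test_lung_density_matches_study_conditions(self, bundle):
        mean, sd = lung_density_stats(bundle)
        assert abs(mean - 0.24) / 0.24 < 0.10
        assert abs(sd - 0.18) / 0.18 < 0.10

    def test_same_seed_is_bit_identical(self):
        a = build_phantom(default_spec_2d(7))
        b = build_phantom(default_spec_2d(7))
        assert np.array_equal(a.vt_map.data, b.vt_map.data)
        assert np.array_equal(a.emission.data, b.emission.data)

    def test_different_seed_changes_field(self):
        a = build_phantom(default_spec_2d(7))
        b = build_phantom(default_spec_2d(8))
        assert not np.array_equal(a.vt_map.data, b.vt_map.data)

    def test_six_vois_inside_lung(self, bundle):
        assert len(bundle.vois) == 6
        occupancy = bundle.vois.union_mask()
        assert occupancy.any()
        classes = {v.tissue_class for v in bundle.vois}
        assert classes == {"healthy", "fibrotic"}


class TestMakeVoi:
    def test_sphere_voxel_count_matches_brute_force(self):
        grid = Grid((24, 24, 20), (2.71, 2.71, 3.27))
        center, diameter = (1.0, -2.0, 0.5), 20.0
        mask = make_voi(center, diameter, grid)
        axes = [grid.axis_centers(a) for a in range(3)]
        count = 0
        for i, x in enumerate(axes[0]):
            for j, y in enumerate(axes[1]):
                for k, z in enumerate(axes[2]):
                    cx = grid.center[0] + center[0]
                    cy = grid.center[1] + center[1]
                    cz = grid.center[2] + center[2]
                    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
                    count += d2 <= (diameter / 2) ** 2
        assert mask.sum() == count

    def test_diameter_of_one_pitch_is_single_voxel(self):
        grid = Grid((11, 11), (2.0, 2.0))
        mask = make_voi((0.0, 0.0), 2.0, grid)
        assert mask.sum() == 1

    def test_sphere_outside_grid_rejected(self):
        grid = Grid((10, 10), (2.0, 2.0))
        with pytest.raises(ValueError, match="outside the grid"):
            make_voi((8.0, 0.0), 10.0, grid)

    def test_voi_leaving_lung_warns_or_errors(self):
        grid = Grid((20, 20), (2.0, 2.0))
        lung = np.zeros((20, 20), bool)
        lung[8:12, 8:12] = True
        with pytest.warns(UserWarning, match="outside the lung"):
            make_voi((0.0, 0.0), 16.0, grid, lung_mask=lung)
        with pytest.raises(ValueError, match="outside the lung"):
            make_voi((0.0, 0.0), 16.0, grid, lung_mask=lung, on_partial_outside="error")


class TestLungAnalysisMask:
    def test_ball_erosion_shrinks_radius_by_two_voxels(self):
        grid = Grid((40, 40), (2.0, 2.0))
        hr = Grid((80, 80), (1.0, 1.0))
        ball = make_voi((0.0, 0.0), 44.0, hr)
        mask = lung_analysis_mask(ImageVolume(ball.astype(float), hr.spacing), grid)
        eroded_expected = make_voi((0.0, 0.0), 44.0 - 2 * 2 * 2.0, grid)
        # within one-voxel digitisation of the ideal eroded ball
        assert abs(int(mask.sum()) - int(eroded_expected.sum())) <= 0.15 * eroded_expected.sum()

    def test_thin_slab_erodes_to_nothing(self):
        hr = Grid((60, 60), (1.0, 1.0))
        slab = np.zeros((60, 60), bool)
        slab[:, 29:32] = True  # 3 voxels thick on the target grid scale
        with pytest.raises(ValueError, match="erosion emptied"):
            lung_analysis_mask(ImageVolume(slab.astype(float), hr.spacing),
                               Grid((60, 60), (1.0, 1.0)))

    def test_all_ones_mask_downsamples_to_all_ones(self):
        hr = Grid((40, 40), (1.0, 1.0))
        mask = lung_analysis_mask(ImageVolume(np.ones((40, 40)), hr.spacing),
                                  Grid((10, 10), (4.0, 4.0)), erode_voxels=0)
        assert mask.all()

    def test_empty_mask_rejected(self):
        hr = Grid((10, 10), (1.0, 1.0))
        with pytest.raises(ValueError, match="empty"):
            lung_analysis_mask(ImageVolume(np.zeros((10, 10)), hr.spacing),
                               Grid((5, 5), (2.0, 2.0)))


class TestDigitalTwin:
    def _labels(self):
        lab = np.zeros((8, 8))
        lab[2:6, 2:6] = 1
        lab[3:5, 3:5] = 2
        return ImageVolume(lab, (1.0, 1.0))

    def test_two_labels_give_two_values(self):
        em, mu = digital_twin_from_labels(self._labels(), {0: 0, 1: 5.0, 2: 0.0},
                                          {0: 0, 1: 0.02, 2: 0.11})
        assert set(np.unique(em.data)) == {0.0, 5.0}
        assert set(np.unique(mu.data)) == {0.0, 0.02, 0.11}

    def test_unknown_label_reported(self):
        with pytest.raises(KeyError, match="2"):
            digital_twin_from_labels(self._labels(), {0: 0, 1: 1.0}, {0: 0, 1: 0.1})

    def test_all_zero_activities_give_zero_emission(self):
        em, _ = digital_twin_from_labels(self._labels(), {0: 0, 1: 0, 2: 0},
                                         {0: 0, 1: 0.1, 2: 0.1})
        assert not em.data.any()

    def test_insert_fill_modes_pre_and_post(self):
        from lungafc.phantom import InsertSphere
        spec = PhantomSpec(
            inserts=(InsertSphere((-57.0, 0.0), 24.0, wall_mm=2.0, fill="pre"),
                     InsertSphere((57.0, 0.0), 24.0, wall_mm=2.0, fill="post")),
            seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = build_phantom(spec)
        hr = b.emission.grid
        pre = make_voi((-57.0, 0.0), 18.0, hr)
        post = make_voi((57.0, 0.0), 18.0, hr)
        wall = make_voi((-57.0, 0.0), 24.0, hr) & ~make_voi((-57.0, 0.0), 20.0, hr)
        lung = b.lung_mask.data > 0.5
        mean_em = b.emission.data[lung].mean()
        mean_vt = b.vt_map.data[lung].mean()
        assert np.allclose(b.emission.data[pre], b.emission.data[pre][0])
        assert b.emission.data[post].mean() > b.emission.data[pre].mean()
        assert np.allclose(b.emission.data[post].mean(), mean_em / mean_vt, rtol=0.1)
        assert np.all(b.emission.data[wall] == 0)
        assert np.allclose(b.mu_map.data[wall], spec.mu_perspex)

    def test_overlapping_inserts_rejected(self):
        from lungafc.phantom import InsertSphere
        spec = PhantomSpec(inserts=(InsertSphere((-57.0, 0.0), 20.0),
                                    InsertSphere((-52.0, 0.0), 20.0)))
        with pytest.raises(ValueError, match="overlap"):
            spec.validate()


class TestGeometryValidation:
    def test_primitive_outside_grid_rejected(self):
        spec = PhantomSpec(body=Ellipsoid((0.0, 0.0), (200.0, 85.0)))
        with pytest.raises(ValueError, match="does not fit"):
            spec.validate()

    def test_3d_variant_builds(self):
        from lungafc.phantom import default_spec_3d
        spec = default_spec_3d(seed=1, n_slices=10)
        spec.hr_factor = 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = build_phantom(spec)
        assert b.emission.ndim == 3
        lung = b.lung_mask.data > 0.5
        afc = b.emission.data[lung] / b.vt_map.data[lung]
        assert afc.std() < 1e-9
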