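import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lungafc import ImageVolume, KernelSpec
from lungafc.kernels import (
    KernelSearchGrid,
    SmoothedLibrary,
    convergence_profile,
    estimate_h_afc,
    estimate_h_pvc,
    global_kernel,
    nwmse,
    rmse,
    subsample_uncertainty,
)


class TestObjectives:
    def test_rmse_zero_for_identical_images(self, rng):
        a = rng.random((6, 6))
        assert rmse(a, a.copy(), np.ones((6, 6), bool), 1.0) == 0.0

    def test_rmse_constant_offset(self):
        a = np.zeros((4, 4))
        b = np.full((4, 4), 0.0996)
        assert np.isclose(rmse(a, b, np.ones((4, 4), bool), 0.996), 10.0)

    def test_rmse_matches_direct_formula(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        mask = rng.random((8, 8)) > 0.4
        expected = 100 * np.sqrt(np.mean((a[mask] - b[mask]) ** 2)) / 0.7
        assert abs(rmse(a, b, mask, 0.7) - expected) < 1e-12

    def test_rmse_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rmse(np.ones((2, 2)), np.ones((2, 2)), np.zeros((2, 2), bool), 1.0)

    def test_nwmse_hand_computed_case(self):
        obs = np.array([4.0, 1.0])
        true = np.array([2.0, 2.0])
        assert np.isclose(nwmse(obs, true, np.ones(2, bool), 1.0), 1.0)

    def test_nwmse_zero_for_identical(self):
        x = np.array([3.0, 5.0, 1.0])
        assert nwmse(x, x.copy(), np.ones(3, bool), 2.0) == 0.0

    @given(c=st.floats(0.1, 10.0))
    def test_nwmse_homogeneous_of_degree_one(self, c):
        obs = np.array([4.0, 1.0, 2.5])
        true = np.array([2.0, 2.0, 2.0])
        m = np.ones(3, bool)
        assert np.isclose(nwmse(obs * c, true * c, m, 1.0),
                          c * nwmse(obs, true, m, 1.0))

    def test_nwmse_rejects_widespread_nonpositive_obs(self):
        obs = np.array([-1.0, 1.0])
        with pytest.raises(ValueError, match="nonpositive"):
            nwmse(obs, np.ones(2), np.ones(2, bool), 1.0)


class TestSearchGrid:
    def test_default_grid_is_5_to_15_by_tenths(self):
        vals = KernelSearchGrid().values()
        assert vals[0] == 5.0 and vals[-1] == 15.0 and len(vals) == 101
        assert np.allclose(np.diff(vals), 0.1)

    def test_decoupled_3d_grid_is_product(self):
        grid = KernelSearchGrid(5, 6, 0.5, axes="decoupled")
        ks = grid.kernels(3)
        assert len(ks) == 9
        assert {(k.fwhm_xy, k.fwhm_z) for k in ks} == {
            (a, b) for a in (5.0, 5.5, 6.0) for b in (5.0, 5.5, 6.0)}

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            KernelSearchGrid(5, 4)


class TestKernelRecovery:
    def test_manufactured_recon_recovered_exactly(self, bundle):
        lib = SmoothedLibrary(bundle.emission, bundle.pet_grid)
        voi = bundle.vois["VOI4_IPF"]
        recon = lib.get(KernelSpec(8.0))
        res = estimate_h_pvc(bundle.emission, recon, voi.mask, library=lib)
        assert res.best.fwhm_xy == 8.0
        assert res.best_value < 1e-9

    def test_twenty_random_kernels_recovered_within_one_step(self, bundle):
        lib = SmoothedLibrary(bundle.emission, bundle.pet_grid)
        grid = KernelSearchGrid()
        gen = np.random.default_rng(7)
        voi = bundle.vois["VOI5_IPF"]
        for k_true in np.round(gen.uniform(5, 15, 20), 1):
            recon = lib.get(KernelSpec(float(k_true)))
            res = estimate_h_pvc(bundle.emission, recon, voi.mask, grid, library=lib)
            assert abs(res.best.fwhm_xy - k_true) <= 0.1 + 1e-9, k_true

    def test_coarse_fine_matches_exhaustive(self, bundle):
        lib = SmoothedLibrary(bundle.emission, bundle.pet_grid)
        voi = bundle.vois["VOI6_IPF"]
        recon = lib.get(KernelSpec(9.7))
        exhaustive = estimate_h_pvc(bundle.emission, recon, voi.mask,
                                    KernelSearchGrid(search="exhaustive"), library=lib)
        coarse = estimate_h_pvc(bundle.emission, recon, voi.mask,
                                KernelSearchGrid(search="coarse-fine"), library=lib)
        assert coarse.best == exhaustive.best

    def test_afc_fixed_point_recovered(self, bundle):
        from lungafc.kernels import make_vt_library
        from lungafc.pipeline import _gt_afc_reference
        lib_vt = make_vt_library(bundle.mu_map, bundle.pet_grid)
        gt_afc = _gt_afc_reference(bundle)
        voi = bundle.vois["VOI4_IPF"]
        # manufacture a reconstruction for which AFC with the 9 mm kernel
        # reproduces the reference exactly
        vt9 = lib_vt.get(KernelSpec(9.0))
        recon = gt_afc.with_data(gt_afc.data * vt9.data)
        res = estimate_h_afc(bundle.mu_map, gt_afc, recon, voi.mask,
                             vt_library=lib_vt, reference=0.996)
        assert res.best.fwhm_xy == 9.0
        assert res.best_value < 1e-9

    def test_constant_voi_flags_flat_minimum(self):
        vol_hr = ImageVolume(np.ones((64, 64)), (1.0, 1.0))
        from lungafc.grids import Grid
        pet = Grid((16, 16), (4.0, 4.0))
        recon = ImageVolume(np.ones((16, 16)), (4.0, 4.0))
        mask = np.zeros((16, 16), bool)
        mask[6:10, 6:10] = True
        with pytest.warns(UserWarning, match="flat"):
            res = estimate_h_pvc(vol_hr, recon, mask, KernelSearchGrid(5, 8, 0.5))
        assert res.flat_fraction > 0.5

    def test_tie_break_prefers_smallest_width(self):
        from lungafc.kernels import _argmin_tiebreak
        kernels = [KernelSpec(9.0), KernelSpec(6.0), KernelSpec(7.0)]
        obj = np.array([1.0, 1.0, 2.0])
        assert _argmin_tiebreak(kernels, obj) == 1


class TestGlobalKernel:
    def test_identical_vois_reduce_to_single_voi_result(self, bundle):
        lib = SmoothedLibrary(bundle.emission, bundle.pet_grid)
        voi = bundle.vois["VOI4_IPF"]
        recon = lib.get(KernelSpec(8.5))
        single = estimate_h_pvc(bundle.emission, recon, voi.mask, library=lib)
        pooled = global_kernel([voi.mask, voi.mask.copy()], KernelSearchGrid(), "pvc",
                               gt_emission_hr=bundle.emission, recon_pet=recon,
                               library=lib)
        assert pooled.best == single.best

    def test_pooled_objective_at_argmin_not_worse_than_member_argmins(self, bundle, study_report):
        recon = study_report.base_result.checkpoints[200]
        lib = SmoothedLibrary(bundle.emission, bundle.pet_grid)
        masks = [v.mask for v in bundle.vois]
        pooled = np.zeros_like(masks[0])
        for m in masks:
            pooled |= m
        res_g = global_kernel(masks, KernelSearchGrid(), "pvc",
                              gt_emission_hr=bundle.emission, recon_pet=recon,
                              library=lib)
        for v in bundle.vois:
            res_v = estimate_h_pvc(bundle.emission, recon, v.mask, library=lib)
            pooled_at_v = rmse(lib.get(res_v.best), recon, pooled,
                               max(float(recon.data[pooled].mean()), 1e-12))
            pooled_at_g = rmse(lib.get(res_g.best), recon, pooled,
                               max(float(recon.data[pooled].mean()), 1e-12))
            assert pooled_at_g <= pooled_at_v + 1e-9

    def test_needs_at_least_two_vois(self, bundle):
        with pytest.raises(ValueError, match="two"):
            global_kernel([bundle.vois["VOI4_IPF"].mask], KernelSearchGrid(), "pvc")


class TestConvergenceProfile:
    def test_identical_checkpoints_stable_from_first(self):
        prof = convergence_profile({10: KernelSpec(8.0), 20: KernelSpec(8.0),
                                    30: KernelSpec(8.0)})
        assert prof.stable_from == 10
        assert prof.deltas == [0.0, 0.0]

    def test_synthetic_series_stabilises_at_third_entry(self):
        series = {i: KernelSpec(f) for i, f in zip((10, 30, 100, 300, 1000),
                                                   (12.0, 10.0, 9.2, 9.0, 8.9))}
        prof = convergence_profile(series, threshold=0.5)
        assert prof.stable_from == 100

    def test_never_stable_when_last_step_jumps(self):
        series = {1: KernelSpec(8.0), 2: KernelSpec(8.1), 3: KernelSpec(9.5)}
        assert convergence_profile(series).stable_from is None


class TestSubsampleUncertainty:
    def test_exactly_recoverable_input_has_zero_sd(self, bundle):
        lib = SmoothedLibrary(bundle.emission, bundle.pet_grid)
        recon = lib.get(KernelSpec(9.0))
        voi = bundle.vois["VOI4_IPF"]
        est = lambda m: estimate_h_pvc(bundle.emission, recon, m, library=lib)  # noqa: E731
        u = subsample_uncertainty(est, voi.mask, n_realisations=20, seed=5)
        assert u.sd_xy == 0.0

    def test_same_seed_reproducible(self, bundle):
        lib = SmoothedLibrary(bundle.emission, bundle.pet_grid)
        noise = np.random.default_rng(3).normal(0, 0.002, bundle.pet_grid.shape)
        recon = lib.get(KernelSpec(9.0))
        noisy = recon.with_data(recon.data + noise)
        voi = bundle.vois["VOI4_IPF"]
        est = lambda m: estimate_h_pvc(bundle.emission, noisy, m, library=lib)  # noqa: E731
        u1 = subsample_uncertainty(est, voi.mask, n_realisations=15, seed=11)
        u2 = subsample_uncertainty(est, voi.mask, n_realisations=15, seed=11)
        assert u1.sd_xy == u2.sd_xy

    def test_small_voi_rejected(self, bundle):
        voi = np.zeros(bundle.pet_grid.shape, bool)
        voi[0, :10] = True
        with pytest.raises(ValueError, match="20"):
            subsample_uncertainty(lambda m: KernelSpec(8.0), voi)
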