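"""Point-source insertion-and-subtraction resolution estimation (h_pts).

A single ground-truth voxel perturbation is added at the VOI centre on
top of the full emission background (reconstructing a point without
background would let the non-negativity constraint sharpen it
artificially).  Both datasets are reconstructed identically; their
difference approximates the local PSF of the reconstruction.  The
perturbation amplitude is calibrated so the reconstructed contrast stays
below a cap (0.1), keeping the perturbation in the linear regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .afc import FWHM_TO_SIGMA
from .grids import ImageVolume
from .kernels import KernelSearchGrid, KernelSearchResult, SmoothedLibrary, fit_h_pts
from .phantom import PhantomBundle, VOI
from .recon import ReconResult, ReconSettings, mlem
from .simulator import (
    ScannerModel,
    Sinogram,
    attenuation_factors,
    forward_project,
    insert_point_source,
    intrinsic_blur,
    perturbation_contrast,
)

__all__ = ["PointSourceRun", "run_point_source", "estimate_h_pts"]


@dataclass
class PointSourceRun:
    """Calibrated perturbation study for one VOI."""

    point_hr: ImageVolume                 # GT single-voxel point image (final amplitude)
    library: SmoothedLibrary              # smoothed+down-sampled point over the kernel grid
    differences: dict[int, ImageVolume]   # checkpoint -> post-filtered difference image
    amplitude: float
    contrast: float
    voi: VOI


def _point_voxel_index(grid, center_mm) -> tuple[int, ...]:
    idx = []
    for a, c in enumerate(center_mm):
        pos = grid.center[a] + c
        i = int(np.floor((pos - grid.origin[a]) / grid.spacing[a]))
        idx.append(int(np.clip(i, 0, grid.shape[a] - 1)))
    return tuple(idx)


def _initial_amplitude(bundle: PhantomBundle, scanner: ScannerModel,
                       settings: ReconSettings, voi_mean: float,
                       target_contrast: float) -> float:
    """Predict the point value giving roughly the target contrast.

    Uses the expected total blur (intrinsic (+) post-filter in quadrature)
    to estimate the reconstructed point's mean over the 3x3(x3) PET
    neighbourhood relative to the VOI background.
    """
    pf = settings.post_filter_fwhm
    pf_xy = float(pf if np.isscalar(pf) else pf[0])
    f_tot = float(np.hypot(scanner.intrinsic_fwhm, pf_xy))
    sigma = f_tot * FWHM_TO_SIGMA
    hr = bundle.emission
    pet_spacing = scanner.pet_spacing[: hr.ndim]
    frac = float(np.prod([erf(1.5 * s / (sigma * np.sqrt(2.0))) for s in pet_spacing]))
    neigh_vol = float(np.prod([3.0 * s for s in pet_spacing]))
    factor = frac * hr.voxel_volume / neigh_vol
    return target_contrast * voi_mean / max(factor, 1e-300)


def run_point_source(bundle: PhantomBundle, scanner: ScannerModel,
                     settings: ReconSettings, voi: VOI,
                     base_result: ReconResult, base_sino: Sinogram,
                     grid: KernelSearchGrid = KernelSearchGrid(),
                     contrast_cap: float = 0.1, target_contrast: float = 0.05,
                     max_tries: int = 5) -> PointSourceRun:
    """Insert, calibrate and reconstruct a point source at the VOI centre."""
    hr_grid = bundle.emission.grid
    idx = _point_voxel_index(hr_grid, voi.center)
    if bundle.lung_mask.data[idx] == 0:
        raise ValueError(f"point-source voxel for {voi.name} is outside the lung")

    contrast_it = max(base_result.checkpoints)
    voi_mean = float(base_result.checkpoints[contrast_it].data[voi.mask].mean())
    amplitude = _initial_amplitude(bundle, scanner, settings, voi_mean, target_contrast)

    # the perturbation's sinogram is linear in amplitude and attenuation is
    # unchanged, so only the point needs forward-projecting per try
    mu_blur = intrinsic_blur(bundle.mu_map, scanner)
    attn = attenuation_factors(mu_blur, scanner)
    unit_point = insert_point_source(
        bundle.emission.with_data(np.zeros(hr_grid.shape)), idx, 1.0)
    unit_sino = forward_project(intrinsic_blur(unit_point, scanner), scanner,
                                check_fov=False)

    pet_shape = base_result.grid.shape
    for attempt in range(max_tries):
        sino_with = Sinogram(
            base_sino.values + amplitude * attn.values * unit_sino.values, scanner)
        pert = mlem(sino_with, scanner, pet_shape, mu_map=bundle.mu_map,
                    settings=settings)
        diffs = {
            it: base_result.checkpoints[it].with_data(
                pert.checkpoints[it].data - base_result.checkpoints[it].data)
            for it in base_result.checkpoints
        }
        diff_c = diffs[contrast_it]
        contrast = perturbation_contrast(
            diff_c, base_result.checkpoints[contrast_it], voi.center, voi.mask)
        if contrast < contrast_cap:
            break
        amplitude *= target_contrast / contrast
        if amplitude < 1e-30:
            raise RuntimeError("contrast calibration underflow")
    else:
        raise RuntimeError(
            f"could not bring reconstructed contrast below {contrast_cap} "
            f"in {max_tries} attempts (last contrast {contrast:.3f})")

    point_hr = insert_point_source(
        bundle.emission.with_data(np.zeros(hr_grid.shape)), idx, amplitude)
    library = SmoothedLibrary(point_hr, base_result.grid)
    return PointSourceRun(point_hr, library, diffs, amplitude, contrast, voi)


def estimate_h_pts(bundle: PhantomBundle, scanner: ScannerModel,
                   settings: ReconSettings, voi: VOI,
                   base_result: ReconResult, base_sino: Sinogram,
                   grid: KernelSearchGrid = KernelSearchGrid(),
                   contrast_cap: float = 0.1,
                   iteration: int | None = None) -> KernelSearchResult:
    """End-to-end h_pts for one VOI at one checkpoint (the last by default)."""
    run = run_point_source(bundle, scanner, settings, voi, base_result, base_sino,
                           grid=grid, contrast_cap=contrast_cap)
    it = iteration if iteration is not None else max(run.differences)
    return fit_h_pts(run.differences[it], run.library, voi.mask, grid,
                     voi_name=voi.name)
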