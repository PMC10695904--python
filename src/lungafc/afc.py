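"""Air fraction correction (AFC) for lung PET/CT.

The lung is modelled as a two-component mixture of tissue (parenchyma +
blood) and air.  The linear attenuation coefficient (LAC) of a lung voxel
is a volume-weighted average of the tissue and air LACs,

    mu_l = V_t * mu_t + (1 - V_t) * mu_a,

so the tissue fraction V_t can be inverted voxel-wise from a mu-map and
used to convert activity per ml of lung into activity per ml of tissue
(the AFC: divide the reconstructed PET image by V_t).  Because the mu-map
derives from CT at much finer resolution than the reconstructed PET, it
must first be smoothed with a Gaussian kernel matched to the reconstructed
PET resolution and down-sampled to the PET grid; choosing that kernel is
the job of :mod:`lungafc.kernels`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid, ImageVolume, resample_to_grid

__all__ = [
    "FWHM_TO_SIGMA",
    "KernelSpec",
    "TissueFractionModel",
    "gaussian_smooth",
    "smooth_downsample",
    "tissue_fraction",
    "apply_afc",
    "hu_to_lac",
]

log = logging.getLogger(__name__)

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class KernelSpec:
    """Anisotropic Gaussian kernel: transaxial (xy) and axial (z) FWHM in mm.

    ``fwhm_z=None`` denotes a 2D (single-slice) kernel.  The scalar summary
    reported throughout is the mean transaxial-axial width
    ``FWHM(xyz) = (2*fwhm_xy + fwhm_z) / 3`` (arithmetic mean over the three
    image axes), reducing to ``fwhm_xy`` in 2D.
    """

    fwhm_xy: float
    fwhm_z: float | None = None

    def __post_init__(self):
        if self.fwhm_xy < 0 or (self.fwhm_z is not None and self.fwhm_z < 0):
            raise ValueError("kernel FWHM must be >= 0")

    @property
    def mean_fwhm_xyz(self) -> float:
        if self.fwhm_z is None:
            return float(self.fwhm_xy)
        return float((2.0 * self.fwhm_xy + self.fwhm_z) / 3.0)

    def fwhm_per_axis(self, ndim: int) -> tuple[float, ...]:
        if ndim == 2:
            return (self.fwhm_xy, self.fwhm_xy)
        if ndim == 3:
            fz = self.fwhm_xy if self.fwhm_z is None else self.fwhm_z
            return (self.fwhm_xy, self.fwhm_xy, fz)
        raise ValueError("only 2D and 3D volumes are supported")

    def __str__(self) -> str:
        if self.fwhm_z is None:
            return f"{self.fwhm_xy:.1f} mm (2D)"
        return f"{self.fwhm_xy:.1f} x {self.fwhm_xy:.1f} x {self.fwhm_z:.1f} mm"


@dataclass(frozen=True)
class TissueFractionModel:
    """Two-component LAC mixture model at 511 keV.

    mu_t defaults to water-equivalent tissue (0.096 cm^-1); mu_a (air) is
    0 to good approximation.  ``floor`` bounds V_t away from zero so the
    voxel-wise division cannot blow up at lung boundaries.
    """

    mu_t: float = 0.096  # cm^-1
    mu_a: float = 0.0    # cm^-1
    floor: float = 0.01

    def __post_init__(self):
        if not (self.mu_t > self.mu_a >= 0):
            raise ValueError("require mu_t > mu_a >= 0")
        if not (0 < self.floor < 1):
            raise ValueError("require 0 < floor < 1")


def gaussian_smooth(volume: ImageVolume, kernel: KernelSpec) -> ImageVolume:
    """Separable Gaussian convolution with per-axis FWHM in mm."""
    fwhm = kernel.fwhm_per_axis(volume.ndim)
    sigma_vox = [f * FWHM_TO_SIGMA / s for f, s in zip(fwhm, volume.spacing)]
    if all(s == 0 for s in sigma_vox):
        return volume.with_data(volume.data.copy())
    # truncate=8 keeps kernel-composition identities (semigroup) accurate
    out = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="nearest",
                                  truncate=8.0)
    return volume.with_data(out)


def smooth_downsample(volume_hr: ImageVolume, kernel: KernelSpec, pet_grid: Grid) -> ImageVolume:
    """Gaussian-smooth at high resolution, then down-sample to the PET grid.

    Smoothing happens first, on the fine grid, exactly as in the AFC
    workflow; the subsequent resampling is exact overlap averaging.
    """
    for s_hr, s_pet in zip(volume_hr.spacing, pet_grid.spacing):
        if s_hr > s_pet + 1e-9:
            raise ValueError("high-resolution spacing exceeds PET spacing")
    fwhm = kernel.fwhm_per_axis(volume_hr.ndim)
    for f, s in zip(fwhm, volume_hr.spacing):
        if 0 < f < s:
            warnings.warn(
                f"kernel FWHM {f:.2f} mm below voxel pitch {s:.2f} mm: under-resolved",
                stacklevel=2,
            )
    smoothed = gaussian_smooth(volume_hr, kernel)
    out = resample_to_grid(smoothed, pet_grid)
    out.meta["kernel"] = kernel
    return out


def tissue_fraction(mu_map: ImageVolume, model: TissueFractionModel = TissueFractionModel(),
                    clamp_log: dict | None = None) -> ImageVolume:
    """Invert the LAC mixture model: V_t = (mu_l - mu_a) / (mu_t - mu_a).

    Values are clamped to [floor, 1]; clamp counts are logged (and stored
    in ``clamp_log`` when provided).
    """
    mu = mu_map.data
    if np.any(mu < -1e-12):
        raise ValueError("mu-map contains negative values")
    vt = (mu - model.mu_a) / (model.mu_t - model.mu_a)
    n_low = int(np.count_nonzero(vt < model.floor))
    n_high = int(np.count_nonzero(vt > 1.0))
    if n_low or n_high:
        log.debug("tissue_fraction clamps: %d below floor, %d above 1", n_low, n_high)
    if clamp_log is not None:
        clamp_log["below_floor"] = n_low
        clamp_log["above_one"] = n_high
    vt = np.clip(vt, model.floor, 1.0)
    out = mu_map.with_data(vt, kind="tissue_fraction")
    out.meta["tf_model"] = model
    return out


def apply_afc(recon_pet: ImageVolume, vt_pet: ImageVolume,
              lung_mask: np.ndarray) -> ImageVolume:
    """Voxel-wise AFC: divide the reconstruction by V_t inside the mask."""
    if not recon_pet.same_grid_as(vt_pet):
        raise ValueError("reconstruction and V_t grids do not match")
    mask = np.asarray(lung_mask, dtype=bool)
    if mask.shape != recon_pet.data.shape:
        raise ValueError("mask shape does not match image grid")
    out = recon_pet.data.copy()
    out[mask] = out[mask] / vt_pet.data[mask]
    result = recon_pet.with_data(out, kind="suv_afc")
    result.meta["afc_kernel"] = vt_pet.meta.get("kernel")
    return result


def hu_to_lac(hu: ImageVolume, lac_water: float = 0.096) -> ImageVolume:
    """Simple linear HU -> 511 keV LAC conversion: LAC = lac_water * (1 + HU/1000).

    Valid in the lung/soft-tissue range where HU scales linearly with LAC;
    vendor bilinear curves (bone) are out of scope.
    """
    lac = np.clip(lac_water * (1.0 + hu.data / 1000.0), 0.0, None)
    return hu.with_data(lac, kind="lac_cm")
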