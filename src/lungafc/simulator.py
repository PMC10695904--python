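"""Noiseless (optionally Poisson-noisy) non-TOF PET data simulation.

The forward model follows the simulation workflow of the study: the
ground-truth emission and mu-map are first convolved with an isotropic
Gaussian matching the scanner's intrinsic resolution (4.7 mm FWHM by
default), then forward-projected; attenuation factors exp(-integral mu dl)
multiply the emission sinogram.  The projector is ray-driven with
bilinear (per-slice) interpolation sampled at half-voxel steps and is
materialised as a sparse matrix, so its adjoint is the exact transpose —
the property MLEM correctness rests on.  Axial planes are treated as
independent 2D slices (single-slice-rebinned geometry); axial coupling
enters through the 3D intrinsic blur in image space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
from scipy import ndimage, sparse

from .afc import FWHM_TO_SIGMA
from .grids import Grid, ImageVolume

__all__ = [
    "ScannerModel",
    "Sinogram",
    "Projector",
    "get_projector",
    "forward_project",
    "attenuation_factors",
    "acquire",
    "insert_point_source",
    "perturbation_contrast",
]


@dataclass(frozen=True)
class ScannerModel:
    """Non-TOF scanner geometry and intrinsic resolution.

    Angles sample 180 degrees; radial bins are centred on the FOV centre.
    ``pet_spacing`` is the reconstruction voxel size in mm.
    """

    intrinsic_fwhm: float = 4.7  # mm
    n_angles: int = 120
    n_radial: int = 96
    radial_spacing: float = 3.0  # mm
    pet_spacing: tuple[float, ...] = (2.71, 2.71)

    def __post_init__(self):
        if self.n_angles < self.n_radial / 2:
            warnings.warn(
                "angular sampling below radial_bins/2: streak artefacts likely",
                stacklevel=3,
            )

    @property
    def radial_extent(self) -> float:
        """Maximum |radial offset| covered, mm (bin centres +/- half a bin)."""
        return (self.n_radial / 2.0) * self.radial_spacing

    def pet_grid(self, pet_shape: tuple[int, ...]) -> Grid:
        return Grid(pet_shape, self.pet_spacing[: len(pet_shape)])


@dataclass
class Sinogram:
    """Projection-domain data: (angles, radial) or (angles, radial, planes)."""

    values: np.ndarray
    scanner: ScannerModel
    domain: str = "emission"  # emission | attenuation

    def copy(self) -> "Sinogram":
        return Sinogram(self.values.copy(), self.scanner, self.domain)


class Projector:
    """Sparse line-integral operator for one (scanner, image grid) pair.

    ``forward`` returns line integrals in (image units x mm); ``back`` is
    the exact matrix transpose.
    """

    def __init__(self, scanner: ScannerModel, grid: Grid):
        self.scanner = scanner
        self.grid = grid
        self.in_plane_shape = grid.shape[:2]
        self.n_planes = grid.shape[2] if grid.ndim == 3 else 1
        self.matrix = _build_system_matrix(scanner, grid)

    def _flatten(self, data: np.ndarray) -> np.ndarray:
        nx, ny = self.in_plane_shape
        return data.reshape(nx * ny, -1)

    def forward(self, data: np.ndarray) -> np.ndarray:
        out = self.matrix @ self._flatten(np.asarray(data, dtype=np.float64))
        shape = (self.scanner.n_angles, self.scanner.n_radial)
        if self.n_planes > 1:
            return out.reshape(*shape, self.n_planes)
        return out.reshape(shape)

    def back(self, sino: np.ndarray) -> np.ndarray:
        flat = np.asarray(sino, dtype=np.float64).reshape(
            self.scanner.n_angles * self.scanner.n_radial, -1
        )
        out = self.matrix.T @ flat
        return out.reshape(self.grid.shape)


def _build_system_matrix(scanner: ScannerModel, grid: Grid) -> sparse.csr_matrix:
    nx, ny = grid.shape[:2]
    sx, sy = grid.spacing[:2]
    ox, oy = grid.origin[:2]
    cx = ox + nx * sx / 2.0
    cy = oy + ny * sy / 2.0

    step = 0.5 * min(scanner.pet_spacing[:2])
    half_diag = 0.5 * float(np.hypot(nx * sx, ny * sy))
    n_t = int(np.ceil(2.0 * half_diag / step))
    t = (np.arange(n_t) + 0.5) * step - half_diag

    angles = np.arange(scanner.n_angles) * np.pi / scanner.n_angles
    s = (np.arange(scanner.n_radial) - (scanner.n_radial - 1) / 2.0) * scanner.radial_spacing

    rows_all, cols_all, vals_all = [], [], []
    for a_idx, th in enumerate(angles):
        u = np.array([np.cos(th), np.sin(th)])
        v = np.array([-np.sin(th), np.cos(th)])
        px = cx + s[:, None] * u[0] + t[None, :] * v[0]
        py = cy + s[:, None] * u[1] + t[None, :] * v[1]
        gx = (px - ox) / sx - 0.5
        gy = (py - oy) / sy - 0.5
        i0 = np.floor(gx).astype(np.int64)
        j0 = np.floor(gy).astype(np.int64)
        fx = gx - i0
        fy = gy - j0
        valid = (i0 >= 0) & (i0 < nx - 1) & (j0 >= 0) & (j0 < ny - 1)
        ray = np.broadcast_to(
            (a_idx * scanner.n_radial + np.arange(scanner.n_radial))[:, None], gx.shape
        )
        for di, dj, w in (
            (0, 0, (1 - fx) * (1 - fy)),
            (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy),
            (1, 1, fx * fy),
        ):
            m = valid & (w > 0)
            rows_all.append(ray[m])
            cols_all.append((i0[m] + di) * ny + (j0[m] + dj))
            vals_all.append(w[m] * step)
    mat = sparse.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(scanner.n_angles * scanner.n_radial, nx * ny),
    )
    return mat.tocsr()


_PROJECTOR_CACHE: dict[tuple, Projector] = {}


def get_projector(scanner: ScannerModel, grid: Grid) -> Projector:
    key = (scanner.n_angles, scanner.n_radial, round(scanner.radial_spacing, 9),
           tuple(scanner.pet_spacing), grid.shape, grid.spacing, grid.origin)
    if key not in _PROJECTOR_CACHE:
        if len(_PROJECTOR_CACHE) > 8:
            _PROJECTOR_CACHE.clear()
        _PROJECTOR_CACHE[key] = Projector(scanner, grid)
    return _PROJECTOR_CACHE[key]


def _check_fov(image: ImageVolume, scanner: ScannerModel) -> None:
    support = np.abs(image.data) > 0
    if not support.any():
        return
    grid = image.grid
    coords = grid.coordinate_mesh()
    cx, cy = grid.center[:2]
    r2 = (coords[0] - cx) ** 2 + (coords[1] - cy) ** 2
    r_max = np.sqrt(np.max(np.broadcast_to(r2, image.data.shape)[support]))
    if r_max > scanner.radial_extent + 1e-9:
        raise ValueError(
            f"image support radius {r_max:.1f} mm exceeds radial FOV "
            f"{scanner.radial_extent:.1f} mm: projections would be truncated"
        )


def forward_project(image: ImageVolume, scanner: ScannerModel,
                    check_fov: bool = True) -> Sinogram:
    """Line integrals of the image (mm-weighted), all angles and offsets."""
    if check_fov:
        _check_fov(image, scanner)
    proj = get_projector(scanner, image.grid)
    return Sinogram(proj.forward(image.data), scanner, domain="emission")


def attenuation_factors(mu_map: ImageVolume, scanner: ScannerModel) -> Sinogram:
    """Per-ray attenuation factors exp(-integral mu dl); mu-map in cm^-1."""
    if np.any(mu_map.data < -1e-12):
        raise ValueError("mu-map contains negative values")
    proj = get_projector(scanner, mu_map.grid)
    line = proj.forward(mu_map.data * 0.1)  # cm^-1 -> mm^-1
    return Sinogram(np.exp(-line), scanner, domain="attenuation")


def intrinsic_blur(volume: ImageVolume, scanner: ScannerModel) -> ImageVolume:
    """Isotropic Gaussian at the scanner's intrinsic resolution (image space)."""
    if scanner.intrinsic_fwhm == 0:
        return volume.with_data(volume.data.copy())
    sigma = [scanner.intrinsic_fwhm * FWHM_TO_SIGMA / s for s in volume.spacing]
    return volume.with_data(ndimage.gaussian_filter(volume.data, sigma=sigma, mode="nearest"))


def acquire(emission: ImageVolume, mu_map: ImageVolume, scanner: ScannerModel,
            noise: str = "none", total_counts: float | None = None,
            seed: int | None = None) -> Sinogram:
    """Simulate an acquisition: intrinsic blur, projection, attenuation.

    With ``noise="poisson"`` the noiseless sinogram is scaled so its sum
    equals ``total_counts``, Poisson-sampled bin-wise, and scaled back, so
    units are preserved while the noise level matches the requested count
    budget.
    """
    if np.any(emission.data < 0):
        raise ValueError("emission must be nonnegative")
    em_b = intrinsic_blur(emission, scanner)
    mu_b = intrinsic_blur(mu_map, scanner)
    _check_fov(em_b, scanner)
    att = attenuation_factors(mu_b, scanner)
    sino = forward_project(em_b, scanner, check_fov=False)
    values = att.values * sino.values
    if noise == "poisson":
        if total_counts is None or total_counts <= 0:
            raise ValueError("poisson noise requires total_counts > 0")
        scale = total_counts / values.sum()
        rng = np.random.default_rng(seed)
        values = rng.poisson(values * scale).astype(np.float64) / scale
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")
    return Sinogram(values, scanner, domain="emission")


def insert_point_source(emission: ImageVolume, voxel_index: tuple[int, ...],
                        amplitude: float) -> ImageVolume:
    """Return a copy of the emission with one voxel incremented by ``amplitude``."""
    if amplitude < 0:
        raise ValueError("point-source amplitude must be >= 0")
    out = emission.with_data(emission.data.copy())
    out.data[tuple(voxel_index)] += amplitude
    return out


def perturbation_contrast(difference: ImageVolume, recon_base: ImageVolume,
                          point_center_mm: tuple[float, ...],
                          voi_mask: np.ndarray) -> float:
    """Reconstructed point-source contrast.

    Mean of the difference image over the 3x3(x3) voxel neighbourhood of
    the point, divided by the mean unperturbed reconstruction over the
    VOI.  Perturbations are kept in the linear regime by requiring this to
    stay below a cap (0.1 by default in the estimation workflow).
    """
    grid = difference.grid
    fc = grid.center
    idx = []
    for a, (c0, c) in enumerate(zip(fc, point_center_mm)):
        i = int(np.floor((fc[a] + c - grid.origin[a]) / grid.spacing[a]))
        idx.append(np.clip(i, 1, grid.shape[a] - 2))
    sl = tuple(slice(i - 1, i + 2) for i in idx)
    neigh = float(difference.data[sl].mean())
    base = float(recon_base.data[np.asarray(voi_mask, bool)].mean())
    if base == 0:
        raise ValueError("unperturbed reconstruction is zero over the VOI")
    return neigh / base
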