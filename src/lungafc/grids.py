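"""Image-volume container and grid resampling utilities.

Volumes are plain ``numpy`` arrays tagged with voxel spacing (mm) and a
corner origin (mm).  Axes are ordered ``(x, y)`` in 2D and ``(x, y, z)``
in 3D, with the voxel centre of index ``i`` located at
``origin + (i + 0.5) * spacing`` along each axis.  Down-sampling between
nested grids uses exact interval-overlap (area/volume) averaging, which
preserves constants and total flux for any spacing ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageVolume", "Grid", "overlap_matrix", "resample_to_grid"]


@dataclass(frozen=True)
class Grid:
    """A regular voxel grid: shape in voxels, spacing and corner origin in mm."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...] | None = None

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != len(spacing):
            raise ValueError("shape and spacing dimensionality differ")
        origin = self.origin
        origin = tuple(0.0 for _ in shape) if origin is None else tuple(float(o) for o in origin)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent(self) -> tuple[float, ...]:
        """Physical side lengths in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center(self) -> tuple[float, ...]:
        return tuple(o + e / 2.0 for o, e in zip(self.origin, self.extent))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        n, s, o = self.shape[axis], self.spacing[axis], self.origin[axis]
        return o + (np.arange(n) + 0.5) * s

    def coordinate_mesh(self) -> list[np.ndarray]:
        """Broadcastable voxel-centre coordinate arrays, one per axis."""
        axes = [self.axis_centers(a) for a in range(self.ndim)]
        return list(np.meshgrid(*axes, indexing="ij", sparse=True))


@dataclass
class ImageVolume:
    """A scalar field on a regular grid.

    ``kind`` records value semantics (e.g. ``"activity"``, ``"lac_cm"``,
    ``"tissue_fraction"``, ``"suv"``); it is informational only.
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] | None = None
    kind: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != len(self.spacing):
            raise ValueError(
                f"data has {self.data.ndim} axes but spacing has {len(self.spacing)}"
            )
        if self.origin is None:
            self.origin = tuple(0.0 for _ in self.spacing)
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def voxel_volume(self) -> float:
        """Voxel measure: area (mm^2) in 2D, volume (mm^3) in 3D."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "ImageVolume":
        out = replace(self, data=np.asarray(data, dtype=np.float64))
        if kind is not None:
            out.kind = kind
        out.meta = dict(self.meta)
        return out

    def same_grid_as(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def overlap_matrix(n_src: int, s_src: float, o_src: float,
                   n_dst: int, s_dst: float, o_dst: float) -> np.ndarray:
    """Exact 1D interval-overlap averaging matrix ``W`` with shape (n_dst, n_src).

    ``W[i, j]`` is the length of the overlap between destination cell *i*
    and source cell *j*, divided by the destination cell length, so rows
    sum to 1 when the source grid covers the destination grid.
    """
    src_lo = o_src + np.arange(n_src) * s_src
    src_hi = src_lo + s_src
    dst_lo = o_dst + np.arange(n_dst) * s_dst
    dst_hi = dst_lo + s_dst
    lo = np.maximum(dst_lo[:, None], src_lo[None, :])
    hi = np.minimum(dst_hi[:, None], src_hi[None, :])
    w = np.clip(hi - lo, 0.0, None) / s_dst
    return w


def resample_to_grid(volume: ImageVolume, dst: Grid) -> ImageVolume:
    """Resample by separable exact overlap averaging onto ``dst``.

    Constants are preserved wherever the source grid fully covers the
    destination voxel; this is a pure block average for integer spacing
    ratios and flux-preserving linear overlap weighting otherwise.
    """
    if volume.ndim != dst.ndim:
        raise ValueError("dimensionality mismatch between volume and target grid")
    src = volume.grid
    for a in range(src.ndim):
        if dst.origin[a] < src.origin[a] - 1e-9 or (
            dst.origin[a] + dst.extent[a] > src.origin[a] + src.extent[a] + 1e-9
        ):
            raise ValueError(f"target grid extends beyond source grid on axis {a}")
    data = volume.data
    for a in range(src.ndim):
        w = overlap_matrix(
            src.shape[a], src.spacing[a], src.origin[a],
            dst.shape[a], dst.spacing[a], dst.origin[a],
        )
        data = np.moveaxis(np.tensordot(w, np.moveaxis(data, a, 0), axes=(1, 0)), 0, a)
    return ImageVolume(data, dst.spacing, dst.origin, kind=volume.kind, meta=dict(volume.meta))
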