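"""NIfTI volume I/O and YAML configuration loading."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import ImageVolume
from .phantom import Ellipsoid, InsertSphere, PhantomSpec

__all__ = ["read_volume", "write_volume", "load_phantom_spec"]


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write as NIfTI with mm spacing in the affine; 2D volumes are stored
    as single-slice 3D (unit z spacing) and recovered on read."""
    data = volume.data
    spacing = list(volume.spacing)
    origin = list(volume.origin)
    was_2d = data.ndim == 2
    if was_2d:
        data = data[..., None]
        spacing.append(1.0)
        origin.append(0.0)
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = origin
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(spacing)
    img.header["descrip"] = (f"lungafc:{volume.kind};2d={int(was_2d)}").encode()[:80]
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume; spacing comes from the header zooms (mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        raise ValueError("4D volumes are not supported; pass a single 3D frame")
    if data.ndim not in (2, 3):
        raise ValueError(f"unsupported dimensionality {data.ndim}")
    zooms = img.header.get_zooms()[: data.ndim]
    if any(z <= 0 for z in zooms):
        raise ValueError("volume is missing voxel-spacing metadata")
    origin = tuple(float(x) for x in img.affine[: data.ndim, 3])
    kind = ""
    descrip = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
    if descrip.startswith("lungafc:"):
        body = descrip[len("lungafc:"):]
        kind, _, flags = body.partition(";")
        if "2d=1" in flags and data.ndim == 3 and data.shape[-1] == 1:
            data = data[..., 0]
            zooms = zooms[:2]
            origin = origin[:2]
    return ImageVolume(data, tuple(float(z) for z in zooms), origin, kind=kind)


def _ellipsoid(d: dict) -> Ellipsoid:
    return Ellipsoid(tuple(d["center"]), tuple(d["radii"]))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a YAML file; omitted keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("pet_shape", "pet_spacing"):
        if key in raw:
            kwargs[key] = tuple(raw.pop(key))
    for key in ("body",):
        if key in raw:
            kwargs[key] = _ellipsoid(raw.pop(key))
    for key in ("lungs", "fibrotic_patches"):
        if key in raw:
            kwargs[key] = tuple(_ellipsoid(d) for d in raw.pop(key))
    if "voi_centers_healthy" in raw:
        kwargs["voi_centers_healthy"] = tuple(tuple(c) for c in raw.pop("voi_centers_healthy"))
    if "inserts" in raw:
        kwargs["inserts"] = tuple(
            InsertSphere(tuple(d["center"]), d["diameter"],
                         d.get("wall_mm", 1.0), d.get("fill", "pre"))
            for d in raw.pop("inserts"))
    kwargs.update(raw)  # remaining scalar fields
    return PhantomSpec(**kwargs)
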