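"""Procedural digital thorax phantom for AFC simulation studies.

Builds ground-truth emission, mu-map and tissue-fraction volumes on a
high-resolution (HR) grid: an elliptical soft-tissue body containing two
lungs whose tissue fraction V_t varies smoothly (a low-frequency Gaussian
random field around a healthy baseline) with denser ellipsoidal fibrotic
patches.  Lung uptake is uniform per gram of tissue, so the ground-truth
AF-corrected image is uniform at ``suv_afc`` by construction and the
mu-map satisfies the two-component mixture model exactly voxel by voxel.

Default whole-lung density (V_t x 1.0 g/cm^3) is calibrated to a mean of
about 0.24 g/cm^3 with a standard deviation of about 0.18 g/cm^3 — a
severely heterogeneous fibrotic lung at full inhale — so AFC divides by
small and strongly varying tissue fractions, the numerically demanding
case the method exists for.  Thin low-contrast vessel segments cross the
healthy VOIs so every VOI contains the anatomical structure a real
parenchymal region offers for resolution estimation.

Also provides a "digital twin" builder that turns a labelled segmentation
plus per-label activity/LAC tables into piecewise-constant emission and
mu-map volumes (the measured-data ground-truth construction), spherical
VOI masks, and the whole-lung analysis mask (down-sample + erode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import Grid, ImageVolume, resample_to_grid

__all__ = [
    "Ellipsoid",
    "VesselSegment",
    "InsertSphere",
    "PhantomSpec",
    "VOI",
    "VOISet",
    "PhantomBundle",
    "default_spec_2d",
    "default_spec_3d",
    "build_phantom",
    "digital_twin_from_labels",
    "make_voi",
    "lung_analysis_mask",
    "lung_density_stats",
]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipse (2D) or ellipsoid (3D); centre relative to FOV centre, mm."""

    center: tuple[float, ...]
    radii: tuple[float, ...]

    def contains(self, coords: list[np.ndarray], fov_center: tuple[float, ...]) -> np.ndarray:
        q = 0.0
        for x, c0, c, r in zip(coords, fov_center, self.center, self.radii):
            q = q + ((x - c0 - c) / r) ** 2
        return q <= 1.0


@dataclass(frozen=True)
class VesselSegment:
    """Cylindrical vessel segment: endpoints relative to FOV centre, radius mm.

    Vessels are tissue/blood (V_t ~ 1) and carry blood-pool activity
    consistent with the per-gram uptake model, so they are bright against
    aerated lung both pre- and post-AFC-consistently; they provide the
    fine anatomical contrast real parenchyma has.
    """

    p0: tuple[float, ...]
    p1: tuple[float, ...]
    radius: float = 1.0

    def distance(self, coords: list[np.ndarray], fov_center: tuple[float, ...]) -> np.ndarray:
        p0 = np.asarray(self.p0, float)
        d = np.asarray(self.p1, float) - p0
        L2 = float(d @ d)
        t = 0.0
        for x, c0, a, dd in zip(coords, fov_center, p0, d):
            t = t + (x - c0 - a) * dd
        t = np.clip(t / max(L2, 1e-12), 0.0, 1.0)
        q = 0.0
        for x, c0, a, dd in zip(coords, fov_center, p0, d):
            q = q + (x - c0 - a - t * dd) ** 2
        return np.sqrt(q)


@dataclass(frozen=True)
class InsertSphere:
    """Fillable sphere insert with an inactive Perspex wall.

    ``fill`` selects the interior activity: ``"pre"`` (matches the mean
    lung background emission, i.e. homogeneous before AFC), ``"post"``
    (background emission / background V_t, homogeneous after AFC), or a
    number (activity in the emission units).  Wall activity is always 0.
    """

    center: tuple[float, ...]
    diameter: float
    wall_mm: float = 1.0
    fill: str | float = "pre"


@dataclass
class PhantomSpec:
    """Full description of the procedural thorax phantom.

    The PET grid defines the reconstruction target; the ground-truth grid
    refines it by an integer factor ``hr_factor`` per axis so that
    down-sampling is an exact block average.
    """

    pet_shape: tuple[int, ...] = (96, 96)
    pet_spacing: tuple[float, ...] = (2.71, 2.71)
    hr_factor: int = 4
    body: Ellipsoid = field(default_factory=lambda: Ellipsoid((0.0, 0.0), (115.0, 85.0)))
    lungs: tuple[Ellipsoid, ...] = (
        Ellipsoid((-57.0, 0.0), (42.0, 58.0)),
        Ellipsoid((57.0, 0.0), (42.0, 58.0)),
    )
    fibrotic_patches: tuple[Ellipsoid, ...] = (
        Ellipsoid((-55.0, -30.0), (20.0, 16.0)),
        Ellipsoid((55.0, 25.0), (20.0, 16.0)),
        Ellipsoid((47.0, -25.0), (20.0, 16.0)),
    )
    voi_centers_healthy: tuple[tuple[float, ...], ...] = (
        (-55.0, 28.0), (-64.0, 5.0), (72.0, 0.0),
    )
    vessels: tuple[VesselSegment, ...] = (
        # left lung: trunk from the hilum plus apical/basal branches
        VesselSegment((-30.0, 0.0), (-75.0, 10.0)),
        VesselSegment((-45.0, 6.0), (-68.0, 42.0)),
        VesselSegment((-42.0, -4.0), (-70.0, -35.0)),
        VesselSegment((-58.0, 24.0), (-45.0, 48.0), 0.8),
        # right lung
        VesselSegment((30.0, 0.0), (82.0, 2.0)),
        VesselSegment((45.0, 4.0), (62.0, 44.0)),
        VesselSegment((44.0, -6.0), (70.0, -40.0), 0.8),
    )
    vessel_vt: float = 0.25
    voi_diameter: float = 20.0
    vt_healthy: float = 0.14
    vt_fibrotic: float = 0.66
    vt_rel_sd_healthy: float = 0.12
    vt_rel_sd_fibrotic: float = 0.13
    vt_corr_mm: float = 30.0
    vt_edge_mm: float = 4.0   # ground-glass-like ramp at fibrotic boundaries (sigma)
    pleural_rim_mm: float = 0.0   # optional subpleural dense rim width (off by default)
    vt_pleura: float = 0.45
    vt_min: float = 0.02
    suv_afc: float = 0.996
    suv_soft_tissue: float = 0.35
    mu_t: float = 0.096       # cm^-1, tissue at 511 keV
    mu_a: float = 0.0         # cm^-1, air
    mu_perspex: float = 0.11  # cm^-1, insert walls/stems
    inserts: tuple[InsertSphere, ...] = ()
    seed: int = 1234

    @property
    def ndim(self) -> int:
        return len(self.pet_shape)

    @property
    def pet_grid(self) -> Grid:
        return Grid(self.pet_shape, self.pet_spacing)

    @property
    def hr_grid(self) -> Grid:
        f = int(self.hr_factor)
        return Grid(
            tuple(n * f for n in self.pet_shape),
            tuple(s / f for s in self.pet_spacing),
        )

    def validate(self) -> None:
        if not (0.0 <= self.vt_healthy <= 1.0 and 0.0 <= self.vt_fibrotic <= 1.0):
            raise ValueError("tissue fractions must lie in [0, 1]")
        half = [e / 2.0 for e in self.pet_grid.extent]
        for prim in (self.body, *self.lungs, *self.fibrotic_patches):
            for c, r, h in zip(prim.center, prim.radii, half):
                if abs(c) + r > h + 1e-9:
                    raise ValueError(f"primitive {prim} does not fit inside the grid")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1:]:
                d = np.linalg.norm(np.subtract(a.center, b.center))
                if d < (a.diameter + b.diameter) / 2.0:
                    raise ValueError("overlapping inserts of incompatible classes")


def default_spec_2d(seed: int = 1234) -> PhantomSpec:
    """The default single-slice phantom used throughout the simulation study."""
    return PhantomSpec(seed=seed)


def default_spec_3d(seed: int = 1234, n_slices: int = 16) -> PhantomSpec:
    """A thin 3D variant: the 2D geometry extruded over a short axial stack."""
    z_half = n_slices * 3.27 / 2.0
    ext = lambda e, rz: Ellipsoid((*e.center, 0.0), (*e.radii, rz))  # noqa: E731
    spec2 = default_spec_2d(seed)
    return PhantomSpec(
        pet_shape=(96, 96, n_slices),
        pet_spacing=(2.71, 2.71, 3.27),
        body=ext(spec2.body, z_half * 0.95),
        lungs=tuple(ext(e, z_half * 0.8) for e in spec2.lungs),
        fibrotic_patches=tuple(ext(e, 12.0) for e in spec2.fibrotic_patches),
        voi_centers_healthy=tuple((*c, 0.0) for c in spec2.voi_centers_healthy),
        vessels=tuple(
            VesselSegment((*v.p0, 0.0), (*v.p1, 0.0), v.radius) for v in spec2.vessels),
        seed=seed,
    )


@dataclass
class VOI:
    name: str
    mask: np.ndarray
    tissue_class: str  # healthy | fibrotic | insert
    center: tuple[float, ...]
    diameter: float
    morphology: list[str] = field(default_factory=list)


@dataclass
class VOISet:
    vois: list[VOI]
    grid: Grid

    def __iter__(self):
        return iter(self.vois)

    def __len__(self):
        return len(self.vois)

    def __getitem__(self, name: str) -> VOI:
        for v in self.vois:
            if v.name == name:
                return v
        raise KeyError(name)

    def names(self) -> list[str]:
        return [v.name for v in self.vois]

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for v in self.vois:
            out |= v.mask
        return out


@dataclass
class PhantomBundle:
    """Everything :func:`build_phantom` produces, all on stated grids."""

    emission: ImageVolume      # HR grid, SUV units (pre-AFC)
    mu_map: ImageVolume        # HR grid, cm^-1
    vt_map: ImageVolume        # HR grid, tissue fraction
    lung_mask: ImageVolume     # HR grid, {0,1}
    vois: VOISet               # on the PET grid
    spec: PhantomSpec

    @property
    def pet_grid(self) -> Grid:
        return self.spec.pet_grid


def make_voi(center, diameter: float, grid: Grid,
             lung_mask: np.ndarray | None = None,
             on_partial_outside: str = "warn") -> np.ndarray:
    """Spherical (circular in 2D) VOI mask: voxel centres within diameter/2."""
    half = [e / 2.0 for e in grid.extent]
    for c, h in zip(center, half):
        if abs(c) + diameter / 2.0 > h + 1e-9:
            raise ValueError("VOI sphere extends outside the grid")
    coords = grid.coordinate_mesh()
    fc = grid.center
    d2 = 0.0
    for x, c0, c in zip(coords, fc, center):
        d2 = d2 + (x - c0 - c) ** 2
    mask = d2 <= (diameter / 2.0) ** 2
    if not mask.any():
        raise ValueError("VOI mask is empty at this grid spacing")
    if lung_mask is not None and np.any(mask & ~np.asarray(lung_mask, bool)):
        msg = "VOI extends outside the lung mask"
        if on_partial_outside == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return mask


def lung_analysis_mask(lung_mask_hr: ImageVolume, pet_grid: Grid,
                       erode_voxels: int = 2) -> np.ndarray:
    """Whole-lung analysis mask on the PET grid.

    Down-samples the HR lung mask by fractional occupancy (>= 0.5), then
    erodes isotropically (6-connected structuring element applied
    ``erode_voxels`` times) to avoid lung-edge effects.
    """
    if not np.any(lung_mask_hr.data):
        raise ValueError("empty lung mask")
    occ = resample_to_grid(lung_mask_hr.with_data(lung_mask_hr.data.astype(float)), pet_grid)
    mask = occ.data >= 0.5
    if erode_voxels > 0:
        structure = ndimage.generate_binary_structure(len(pet_grid.shape), 1)
        mask = ndimage.binary_erosion(mask, structure=structure, iterations=erode_voxels)
    if not mask.any():
        raise ValueError("erosion emptied the lung analysis mask")
    return mask


def _gaussian_random_field(shape, spacing, corr_mm, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    sigma_vox = [corr_mm / s for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    return f


def build_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate the ground-truth phantom volumes and the six study VOIs.

    Inside the lungs the mu-map is ``V_t * mu_t + (1 - V_t) * mu_a``
    exactly, and the emission is ``suv_afc * V_t``, so dividing emission
    by V_t recovers a perfectly uniform AF-corrected lung.
    """
    spec.validate()
    hr = spec.hr_grid
    coords = hr.coordinate_mesh()
    fc = hr.center

    body = spec.body.contains(coords, fc)
    lung = np.zeros(hr.shape, dtype=bool)
    for e in spec.lungs:
        lung |= e.contains(coords, fc)
    lung &= body
    fibrotic = np.zeros(hr.shape, dtype=bool)
    for e in spec.fibrotic_patches:
        fibrotic |= e.contains(coords, fc)
    fibrotic &= lung

    rng = np.random.default_rng(spec.seed)
    f = _gaussian_random_field(hr.shape, hr.spacing, spec.vt_corr_mm, rng)
    f = (f - f[lung].mean()) / f[lung].std()

    # fibrotic membership with a soft (ground-glass-like) boundary: disease
    # density does not step abruptly into healthy parenchyma
    member = fibrotic.astype(float)
    if spec.vt_edge_mm > 0:
        sig = [spec.vt_edge_mm / s for s in hr.spacing]
        member = ndimage.gaussian_filter(member, sigma=sig, mode="nearest")

    # multiplicative (lognormal) density fluctuations: V_t is positive by
    # construction and cold dips are shallower than hot excursions are tall,
    # as in real parenchyma
    vt = np.zeros(hr.shape)
    vt[body] = 1.0
    base = spec.vt_healthy + (spec.vt_fibrotic - spec.vt_healthy) * member
    s = spec.vt_rel_sd_healthy + (spec.vt_rel_sd_fibrotic - spec.vt_rel_sd_healthy) * member
    vt[lung] = base[lung] * np.exp(s[lung] * f[lung] - s[lung] ** 2 / 2.0)
    if spec.pleural_rim_mm > 0:
        # subpleural densification: V_t ramps up toward the pleural surface
        # instead of stepping abruptly from aerated lung to chest wall
        dist = ndimage.distance_transform_edt(lung, sampling=hr.spacing)
        w = np.clip(1.0 - dist / spec.pleural_rim_mm, 0.0, 1.0)
        rim_target = np.maximum(spec.vt_pleura, vt)
        vt = np.where(lung, vt + (rim_target - vt) * w, vt)
    if spec.vessels:
        vessel = np.zeros(hr.shape, dtype=bool)
        for seg in spec.vessels:
            vessel |= seg.distance(coords, fc) <= seg.radius
        vessel &= lung
        vt[vessel] = np.maximum(vt[vessel], spec.vessel_vt)
    # lung parenchyma is never pure air at this scale: clamp to a small
    # positive floor so emission/V_t stays defined everywhere in the lung
    n_out = int(np.count_nonzero((vt[lung] < spec.vt_min) | (vt[lung] > 1)))
    if n_out:
        warnings.warn(f"{n_out} lung V_t values outside [{spec.vt_min}, 1] clamped",
                      stacklevel=2)
        vt[lung] = np.clip(vt[lung], spec.vt_min, 1.0)

    mu = np.zeros(hr.shape)
    mu[body] = spec.mu_t
    mu[lung] = vt[lung] * spec.mu_t + (1.0 - vt[lung]) * spec.mu_a
    emission = np.zeros(hr.shape)
    emission[body] = spec.suv_soft_tissue
    emission[lung] = spec.suv_afc * vt[lung]

    mean_lung_em = float(emission[lung].mean())
    mean_lung_vt = float(vt[lung].mean())
    for k, ins in enumerate(spec.inserts):
        interior = make_voi(ins.center, ins.diameter - 2 * ins.wall_mm, hr)
        shell = make_voi(ins.center, ins.diameter, hr) & ~interior
        if not np.all(lung[shell | interior]):
            raise ValueError(f"insert {k} not fully inside the lung")
        if ins.fill == "pre":
            act = mean_lung_em
        elif ins.fill == "post":
            act = mean_lung_em / mean_lung_vt
        else:
            act = float(ins.fill)
        emission[interior] = act
        emission[shell] = 0.0
        mu[interior] = spec.mu_t
        mu[shell] = spec.mu_perspex
        vt[interior] = 1.0
        vt[shell] = 1.0
        lung[interior] = False
        lung[shell] = False

    pet = spec.pet_grid
    lung_hr = ImageVolume(lung.astype(float), hr.spacing, hr.origin, kind="mask")
    occ = resample_to_grid(lung_hr, pet)
    lung_pet = occ.data >= 0.5

    vois = []
    for i, c in enumerate(spec.voi_centers_healthy):
        m = make_voi(c, spec.voi_diameter, pet, lung_mask=lung_pet)
        vois.append(VOI(f"VOI{i + 1}_HL", m, "healthy", tuple(c), spec.voi_diameter))
    for i, e in enumerate(spec.fibrotic_patches):
        m = make_voi(e.center, spec.voi_diameter, pet, lung_mask=lung_pet)
        vois.append(VOI(f"VOI{i + 4}_IPF", m, "fibrotic", tuple(e.center), spec.voi_diameter))

    return PhantomBundle(
        emission=ImageVolume(emission, hr.spacing, hr.origin, kind="suv"),
        mu_map=ImageVolume(mu, hr.spacing, hr.origin, kind="lac_cm"),
        vt_map=ImageVolume(vt, hr.spacing, hr.origin, kind="tissue_fraction"),
        lung_mask=lung_hr,
        vois=VOISet(vois, pet),
        spec=spec,
    )


def digital_twin_from_labels(labels: ImageVolume, activity_table: dict,
                             lac_table: dict) -> tuple[ImageVolume, ImageVolume]:
    """Piecewise-constant emission and mu-map from a labelled segmentation.

    Mirrors the measured-data ground-truth construction: a segmented HRCT
    plus calibrator-measured activity concentrations per compartment.
    """
    lab = labels.data.astype(np.int64)
    present = np.unique(lab)
    missing = [int(v) for v in present if v not in activity_table or v not in lac_table]
    if missing:
        raise KeyError(f"labels missing from activity/LAC tables: {missing}")
    emission = np.zeros(lab.shape)
    mu = np.zeros(lab.shape)
    for v in present:
        emission[lab == v] = float(activity_table[v])
        mu[lab == v] = float(lac_table[v])
    return (
        labels.with_data(emission, kind="activity_kbq_ml"),
        labels.with_data(mu, kind="lac_cm"),
    )


def lung_density_stats(bundle: PhantomBundle, tissue_density: float = 1.0) -> tuple[float, float]:
    """Whole-lung density mean and SD in g/cm^3, with rho = V_t * tissue_density."""
    lung = bundle.lung_mask.data > 0.5
    rho = bundle.vt_map.data[lung] * tissue_density
    return float(rho.mean()), float(rho.std())
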