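"""Estimation of the resolution-matching kernel for AFC.

Three ways to find the Gaussian kernel with which the CT/mu-map should be
smoothed before air fraction correction, all grid searches over
transaxial/axial FWHM (5-15 mm in 0.1 mm steps by default):

``h_pts``
    point-source insertion-and-subtraction: a single ground-truth voxel
    perturbation is added to the emission, both datasets reconstructed,
    and the kernel chosen whose smoothed-and-down-sampled point image
    best fits the reconstruction difference (RMSE, amplitude-matched).
``h_PVC``
    smooth the ground-truth emission over the kernel grid and pick the
    kernel whose smoothed image best matches the reconstruction in the
    VOI (RMSE for noiseless simulations, noise-weighted nWMSE for
    measured data).
``h_AFC``
    AF-correct the reconstruction with the mu-map smoothed over the grid
    and pick the kernel minimising the RMSE to the ground-truth
    AF-corrected image in the VOI.

Per-VOI and pooled ("global") variants are provided, along with the
checkpointed-convergence profile (stability when successive mean-FWHM
changes fall below 0.5 mm) and a voxel sub-sampling uncertainty
estimator (SD over random half-VOI refits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .afc import KernelSpec, TissueFractionModel, smooth_downsample, tissue_fraction
from .grids import Grid, ImageVolume

__all__ = [
    "KernelSearchGrid",
    "KernelSearchResult",
    "SmoothedLibrary",
    "rmse",
    "nwmse",
    "estimate_h_pvc",
    "estimate_h_afc",
    "fit_h_pts",
    "global_kernel",
    "ConvergenceProfile",
    "convergence_profile",
    "UncertaintyResult",
    "subsample_uncertainty",
]


@dataclass(frozen=True)
class KernelSearchGrid:
    """FWHM search grid in mm.

    ``axes="coupled"`` searches isotropic kernels (fwhm_z = fwhm_xy);
    ``"decoupled"`` searches the full transaxial x axial product grid.
    ``search="coarse-fine"`` evaluates a coarse sub-grid first and then
    refines around its minimum at the fine step (the surfaces are smooth,
    so this matches the exhaustive search in practice); ``"exhaustive"``
    evaluates every grid point.
    """

    fwhm_min: float = 5.0
    fwhm_max: float = 15.0
    step: float = 0.1
    axes: str = "coupled"  # coupled | decoupled
    search: str = "exhaustive"  # exhaustive | coarse-fine
    coarse_step: float = 0.5

    def __post_init__(self):
        if self.fwhm_min < 0 or self.step <= 0 or self.fwhm_max < self.fwhm_min:
            raise ValueError("invalid kernel search grid")
        if self.axes not in ("coupled", "decoupled"):
            raise ValueError("axes must be 'coupled' or 'decoupled'")

    def values(self, step: float | None = None) -> np.ndarray:
        step = self.step if step is None else step
        n = int(round((self.fwhm_max - self.fwhm_min) / step))
        v = self.fwhm_min + step * np.arange(n + 1)
        return np.round(v, 6)

    def kernels(self, ndim: int, step: float | None = None) -> list[KernelSpec]:
        v = self.values(step)
        if ndim == 2:
            return [KernelSpec(f, None) for f in v]
        if self.axes == "coupled":
            return [KernelSpec(f, f) for f in v]
        return [KernelSpec(fxy, fz) for fxy in v for fz in v]


@dataclass
class KernelSearchResult:
    """Objective surface over the evaluated kernels and its argmin."""

    kernels: list[KernelSpec]
    objective: np.ndarray
    best: KernelSpec
    best_value: float
    objective_name: str
    voi_name: str = ""
    flat_fraction: float = 0.0
    uncertainty: "UncertaintyResult | None" = None

    def to_dict(self) -> dict:
        d = {
            "voi": self.voi_name,
            "objective": self.objective_name,
            "fwhm_xy": self.best.fwhm_xy,
            "fwhm_z": self.best.fwhm_z,
            "mean_fwhm_xyz": self.best.mean_fwhm_xyz,
            "objective_value": self.best_value,
            "flat_fraction": self.flat_fraction,
        }
        if self.uncertainty is not None:
            d["sd_fwhm_xy"] = self.uncertainty.sd_xy
            d["sd_fwhm_z"] = self.uncertainty.sd_z
        return d


def _vals(x) -> np.ndarray:
    return x.data if isinstance(x, ImageVolume) else np.asarray(x)


def rmse(a, b, mask, reference: float) -> float:
    """Root-mean-square difference over the mask, as percent of ``reference``.

    ``reference`` is the quantification scale: the ground-truth AF-corrected
    SUV in simulations, or the ground-truth VOI mean for measured data.
    """
    av, bv = _vals(a), _vals(b)
    m = np.asarray(mask, dtype=bool)
    if av.shape != bv.shape or av.shape != m.shape:
        raise ValueError("image and mask grids do not match")
    if not m.any():
        raise ValueError("empty mask")
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * float(np.sqrt(np.mean((av[m] - bv[m]) ** 2))) / reference


def nwmse(obs, true, mask, lesion_mean: float) -> float:
    """Noise-weighted MSE: mean((obs - true)^2 / obs) / lesion_mean.

    Weighting assumes the voxel variance is proportional to the observed
    mean (Poisson-like noise); nonpositive observed voxels are excluded
    (error if they exceed 1% of the mask).
    """
    ov, tv = _vals(obs), _vals(true)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    o, t = ov[m], tv[m]
    ok = o > 0
    n_bad = int(np.count_nonzero(~ok))
    if n_bad > 0.01 * o.size:
        raise ValueError(f"{n_bad} nonpositive observed voxels in the mask (> 1%)")
    return float(np.mean((o[ok] - t[ok]) ** 2 / o[ok])) / lesion_mean


class SmoothedLibrary:
    """Lazy cache of smooth-and-down-sample results over the kernel grid.

    One library per ground-truth volume lets every VOI, checkpoint and
    sub-sampling realisation share the expensive convolutions.  ``post``
    optionally transforms each down-sampled volume (e.g. mu-map ->
    tissue fraction).
    """

    def __init__(self, volume_hr: ImageVolume, pet_grid: Grid,
                 post: Callable[[ImageVolume], ImageVolume] | None = None):
        self.volume_hr = volume_hr
        self.pet_grid = pet_grid
        self.post = post
        self._cache: dict[tuple, ImageVolume] = {}

    def get(self, kernel: KernelSpec) -> ImageVolume:
        key = (round(kernel.fwhm_xy, 6),
               None if kernel.fwhm_z is None else round(kernel.fwhm_z, 6))
        if key not in self._cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # under-resolved-kernel warnings
                out = smooth_downsample(self.volume_hr, kernel, self.pet_grid)
            if self.post is not None:
                out = self.post(out)
                out.meta["kernel"] = kernel
            self._cache[key] = out
        return self._cache[key]


def _argmin_tiebreak(kernels: Sequence[KernelSpec], obj: np.ndarray) -> int:
    """Index of the minimum; ties go to the smallest mean FWHM, then fwhm_xy."""
    best = np.min(obj)
    tied = np.flatnonzero(obj <= best * (1 + 1e-12) + 1e-300)
    order = sorted(tied, key=lambda i: (kernels[i].mean_fwhm_xyz, kernels[i].fwhm_xy))
    return int(order[0])


def _flat_fraction(obj: np.ndarray) -> float:
    best = np.min(obj)
    return float(np.count_nonzero(obj <= best * 1.01 + 1e-15) / obj.size)


def _search(objective: Callable[[KernelSpec], float], grid: KernelSearchGrid,
            ndim: int, objective_name: str, voi_name: str) -> KernelSearchResult:
    cache: dict[tuple, float] = {}

    def ev(k: KernelSpec) -> float:
        key = (round(k.fwhm_xy, 6), None if k.fwhm_z is None else round(k.fwhm_z, 6))
        if key not in cache:
            cache[key] = float(objective(k))
        return cache[key]

    if grid.search == "coarse-fine":
        coarse = grid.kernels(ndim, step=grid.coarse_step)
        vals = np.array([ev(k) for k in coarse])
        k0 = coarse[_argmin_tiebreak(coarse, vals)]
        lo_xy = max(grid.fwhm_min, k0.fwhm_xy - grid.coarse_step)
        hi_xy = min(grid.fwhm_max, k0.fwhm_xy + grid.coarse_step)
        xs = np.round(np.arange(lo_xy, hi_xy + grid.step / 2, grid.step), 6)
        if ndim == 2:
            fine = [KernelSpec(f, None) for f in xs]
        elif grid.axes == "coupled":
            fine = [KernelSpec(f, f) for f in xs]
        else:
            lo_z = max(grid.fwhm_min, k0.fwhm_z - grid.coarse_step)
            hi_z = min(grid.fwhm_max, k0.fwhm_z + grid.coarse_step)
            zs = np.round(np.arange(lo_z, hi_z + grid.step / 2, grid.step), 6)
            fine = [KernelSpec(fxy, fz) for fxy in xs for fz in zs]
        for k in fine:
            ev(k)
        kernels = coarse + [k for k in fine if k not in coarse]
    else:
        kernels = grid.kernels(ndim)
        for k in kernels:
            ev(k)

    obj = np.array([ev(k) for k in kernels])
    if not np.all(np.isfinite(obj)):
        if not np.any(np.isfinite(obj)):
            raise ValueError("objective is non-finite for every kernel")
        obj = np.where(np.isfinite(obj), obj, np.inf)
    i = _argmin_tiebreak(kernels, obj)
    flat = _flat_fraction(obj)
    if flat > 0.5:
        warnings.warn(
            f"flat objective minimum ({flat:.0%} of grid within 1%): "
            "kernel estimate is ill-defined for this VOI",
            stacklevel=3,
        )
    return KernelSearchResult(list(kernels), obj, kernels[i], float(obj[i]),
                              objective_name, voi_name, flat)


def _objective_match(model_vals, target_vals, mask, objective, reference, lesion_mean):
    if objective == "rmse":
        ref = reference if reference is not None else max(abs(float(target_vals[mask].mean())), 1e-12)
        return rmse(model_vals, target_vals, mask, ref)
    if objective == "nwmse":
        lm = lesion_mean if lesion_mean is not None else max(float(target_vals[mask].mean()), 1e-12)
        return nwmse(target_vals, model_vals, mask, lm)
    raise ValueError(f"unknown objective {objective!r}")


def estimate_h_pvc(gt_emission_hr: ImageVolume, recon_pet: ImageVolume,
                   voi_mask: np.ndarray, grid: KernelSearchGrid = KernelSearchGrid(),
                   objective: str = "rmse", reference: float | None = None,
                   lesion_mean: float | None = None,
                   library: SmoothedLibrary | None = None,
                   voi_name: str = "") -> KernelSearchResult:
    """Ground-truth-matching kernel: smooth the GT emission to fit the recon."""
    mask = np.asarray(voi_mask, bool)
    if not mask.any():
        raise ValueError("empty VOI mask")
    lib = library or SmoothedLibrary(gt_emission_hr, recon_pet.grid)
    target = recon_pet.data

    def obj(k: KernelSpec) -> float:
        model = lib.get(k).data
        return _objective_match(model, target, mask, objective, reference, lesion_mean)

    return _search(obj, grid, recon_pet.ndim, objective, voi_name)


def make_vt_library(gt_mu_hr: ImageVolume, pet_grid: Grid,
                    tf_model: TissueFractionModel = TissueFractionModel()) -> SmoothedLibrary:
    return SmoothedLibrary(gt_mu_hr, pet_grid,
                           post=lambda v: tissue_fraction(v, tf_model))


def estimate_h_afc(gt_mu_hr: ImageVolume, gt_afc_ref_pet: ImageVolume,
                   recon_pet: ImageVolume, voi_mask: np.ndarray,
                   grid: KernelSearchGrid = KernelSearchGrid(),
                   tf_model: TissueFractionModel = TissueFractionModel(),
                   reference: float | None = None,
                   vt_library: SmoothedLibrary | None = None,
                   voi_name: str = "") -> KernelSearchResult:
    """Direct-AFC kernel: smooth the mu-map so the corrected image fits the GT.

    The reference image is the ground-truth AF-corrected PET (down-sampled
    GT emission divided by down-sampled GT tissue fraction).
    """
    mask = np.asarray(voi_mask, bool)
    if not mask.any():
        raise ValueError("empty VOI mask")
    lib = vt_library or make_vt_library(gt_mu_hr, recon_pet.grid, tf_model)
    ref_vals = gt_afc_ref_pet.data[mask]
    rec_vals = recon_pet.data[mask]
    scale = reference if reference is not None else max(float(ref_vals.mean()), 1e-12)

    def obj(k: KernelSpec) -> float:
        vt = lib.get(k).data[mask]
        corrected = rec_vals / vt
        return 100.0 * float(np.sqrt(np.mean((corrected - ref_vals) ** 2))) / scale

    return _search(obj, grid, recon_pet.ndim, "rmse", voi_name)


def fit_h_pts(difference_pet: ImageVolume, point_library: SmoothedLibrary,
              voi_mask: np.ndarray, grid: KernelSearchGrid = KernelSearchGrid(),
              voi_name: str = "") -> KernelSearchResult:
    """Point-source kernel fit: smoothed GT point vs the recon difference image.

    The smoothed point is scaled so its VOI sum matches the difference
    image's (the perturbation amplitude is a nuisance parameter); the
    objective is the RMSE within the VOI, as a fraction of the difference
    image's RMS so surfaces are comparable across amplitudes.
    """
    mask = np.asarray(voi_mask, bool)
    diff = difference_pet.data[mask]
    if not np.any(diff != 0):
        raise ValueError("difference image is identically zero in the VOI")
    norm = float(np.sqrt(np.mean(diff**2)))
    dsum = float(diff.sum())

    def obj(k: KernelSpec) -> float:
        model = point_library.get(k).data[mask]
        msum = float(model.sum())
        scaled = model * (dsum / msum) if msum != 0 else model
        return 100.0 * float(np.sqrt(np.mean((scaled - diff) ** 2))) / norm

    return _search(obj, grid, difference_pet.ndim, "rmse", voi_name)


def global_kernel(per_voi_inputs: Iterable, grid: KernelSearchGrid,
                  method: str, **kwargs) -> KernelSearchResult:
    """Single kernel from several VOIs combined.

    For ``pvc``/``afc`` the objective is evaluated on the union of the
    VOI masks (overlapping voxels counted once); inputs are the per-VOI
    masks plus the shared volumes passed as keyword arguments (same names
    as the per-VOI estimators).  For ``pts`` the inputs are per-VOI
    ``(difference_pet, point_library, mask)`` triples and the pooled
    objective is the voxel-count-weighted root of summed per-VOI squared
    errors (each VOI keeps its own amplitude scaling).
    """
    if method in ("pvc", "afc"):
        masks = [np.asarray(m, bool) for m in per_voi_inputs]
        if len(masks) < 2:
            raise ValueError("global kernel needs at least two VOIs")
        pooled = np.zeros_like(masks[0])
        for m in masks:
            pooled |= m
        if method == "pvc":
            return estimate_h_pvc(voi_mask=pooled, grid=grid, voi_name="global", **kwargs)
        return estimate_h_afc(voi_mask=pooled, grid=grid, voi_name="global", **kwargs)
    if method != "pts":
        raise ValueError(f"unknown method {method!r}")

    triples = list(per_voi_inputs)
    if len(triples) < 2:
        raise ValueError("global kernel needs at least two VOIs")

    def obj(k: KernelSpec) -> float:
        sse = 0.0
        n = 0
        for diff_img, lib, mask in triples:
            m = np.asarray(mask, bool)
            diff = diff_img.data[m]
            model = lib.get(k).data[m]
            msum = float(model.sum())
            scale = float(diff.sum()) / msum if msum != 0 else 1.0
            norm = float(np.sqrt(np.mean(diff**2)))
            sse += float(np.sum(((model * scale - diff) / max(norm, 1e-300)) ** 2))
            n += diff.size
        return 100.0 * np.sqrt(sse / n)

    ndim = triples[0][0].ndim
    return _search(obj, grid, ndim, "rmse", "global")


@dataclass
class ConvergenceProfile:
    """Kernel estimate vs reconstruction checkpoint, with a stability flag."""

    iterations: list[int]
    kernels: list[KernelSpec]
    threshold: float
    stable_from: int | None = None

    @property
    def mean_fwhms(self) -> list[float]:
        return [k.mean_fwhm_xyz for k in self.kernels]

    @property
    def deltas(self) -> list[float]:
        m = self.mean_fwhms
        return [abs(b - a) for a, b in zip(m, m[1:])]


def convergence_profile(series: dict[int, KernelSpec | KernelSearchResult],
                        threshold: float = 0.5) -> ConvergenceProfile:
    """Stability of the kernel estimate across MLEM checkpoints.

    ``stable_from`` is the first checkpoint after which every successive
    change in mean FWHM(xyz) stays below ``threshold`` (0.5 mm, the
    convergence criterion of the study).
    """
    if len(series) < 1:
        raise ValueError("need at least one checkpoint")
    its = sorted(series)
    kernels = [series[i].best if isinstance(series[i], KernelSearchResult) else series[i]
               for i in its]
    prof = ConvergenceProfile(its, kernels, threshold)
    d = prof.deltas
    stable_idx = None
    # the trailing checkpoint alone is not evidence of stability: require at
    # least one successive change below threshold
    for k in range(max(len(its) - 1, 1)):
        if all(x < threshold for x in d[k:]):
            stable_idx = k
            break
    prof.stable_from = None if stable_idx is None else its[stable_idx]
    return prof


@dataclass
class UncertaintyResult:
    sd_xy: float
    sd_z: float | None
    n_realisations: int
    n_failures: int = 0
    samples: list[KernelSpec] = field(default_factory=list)


def subsample_uncertainty(estimator: Callable[[np.ndarray], KernelSpec | KernelSearchResult],
                          voi_mask: np.ndarray, n_realisations: int = 100,
                          fraction: float = 0.5, seed: int = 0) -> UncertaintyResult:
    """Kernel-width uncertainty by voxel sub-sampling.

    Re-estimates the kernel on ``n_realisations`` random
    without-replacement subsets of ``fraction`` of the VOI voxels and
    returns the SD of the fitted FWHMs per axis.
    """
    mask = np.asarray(voi_mask, bool)
    idx = np.flatnonzero(mask.ravel())
    if idx.size < 20:
        raise ValueError("VOI too small for sub-sampling (need >= 20 voxels)")
    n_sub = int(np.floor(fraction * idx.size))
    rng = np.random.default_rng(seed)
    fits: list[KernelSpec] = []
    failures = 0
    for _ in range(n_realisations):
        sub = rng.choice(idx, size=n_sub, replace=False)
        m = np.zeros(mask.size, dtype=bool)
        m[sub] = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = estimator(m.reshape(mask.shape))
        except Exception:
            failures += 1
            continue
        fits.append(out.best if isinstance(out, KernelSearchResult) else out)
    if failures > 0.1 * n_realisations:
        raise RuntimeError(f"estimator failed in {failures}/{n_realisations} realisations")
    xy = np.array([k.fwhm_xy for k in fits])
    zs = [k.fwhm_z for k in fits]
    sd_z = None if any(z is None for z in zs) else float(np.std(np.array(zs), ddof=1))
    return UncertaintyResult(float(np.std(xy, ddof=1)), sd_z, n_realisations, failures, fits)
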