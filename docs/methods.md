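# Methods

## The tissue-fraction model and AFC

A lung voxel is modelled as a two-component mixture of tissue
(parenchyma plus blood) and air. Its 511 keV linear attenuation
coefficient is the volume-weighted average

    mu_l = V_t * mu_t + (1 - V_t) * mu_a,

so the tissue fraction is recovered voxel-wise as
`V_t = (mu_l - mu_a) / (mu_t - mu_a)`. Defaults: `mu_t = 0.096 cm^-1`
(water-equivalent tissue), `mu_a = 0` (a good approximation at 511 keV).
Air fraction correction divides the reconstructed PET image by `V_t`
inside the lung, converting activity per ml of lung into activity per ml
(approximately per gram) of tissue. `V_t` is clamped to `[floor, 1]`
with `floor = 0.01` by default; the floor is a guard against division
blow-up at lung boundaries and must sit below the smallest genuine
tissue fraction in the data (the default phantom's minimum is 0.02).
Clamps are counted and logged.

Because the mu-map derives from CT at much finer resolution than the
reconstructed PET, it is smoothed with an anisotropic Gaussian
(transaxial FWHM x, axial FWHM z) and down-sampled to the PET grid
before the division. Kernels are summarised by the arithmetic mean over
the three image axes, `FWHM(xyz) = (2 fwhm_xy + fwhm_z) / 3`, which
reduces to `fwhm_xy` in 2D.

## Kernel estimation

All three estimators are grid searches over FWHM, default 5–15 mm in
0.1 mm steps (a coarse 0.5 mm pass with 0.1 mm local refinement is
available for the decoupled transaxial/axial product grid; the surfaces
are smooth and the two modes agree, which a test asserts).

* `h_PVC`: smooth-and-down-sample the ground-truth emission with each
  candidate kernel; minimise the RMSE (noiseless data) or the
  noise-weighted `nWMSE = mean((obs - true)^2 / obs) / lesion_mean`
  (measured data; variance taken proportional to the observed mean)
  against the reconstruction inside the VOI.
* `h_AFC`: smooth the mu-map with each candidate, AF-correct the
  reconstruction with the resulting `V_t`, minimise the RMSE against
  the ground-truth AF-corrected reference. The reference is the
  down-sampled ground-truth emission divided by the down-sampled
  ground-truth `V_t` (exact division, no floor), which inside the lung
  equals the uniform per-gram uptake by construction.
* `h_pts`: insert a single ground-truth voxel perturbation at the VOI
  centre on top of the full emission background, reconstruct both
  datasets identically, and fit the smoothed-and-down-sampled point
  image to the post-filtered difference image. The perturbation
  amplitude is a nuisance parameter: the model point is rescaled so its
  VOI sum matches the difference image before the RMSE. The amplitude
  is calibrated so the reconstructed contrast — mean of the difference
  over the 3x3(x3) PET-voxel neighbourhood of the point divided by the
  mean unperturbed reconstruction over the VOI — stays below 0.1,
  keeping the perturbation in the linear range of the nonlinear MLEM
  mapping. An analytic first guess (expected total blur, Gaussian peak
  fraction over the neighbourhood) lands near contrast 0.05, so the
  calibration loop almost always runs a single reconstruction pair.

Ties in the objective go to the smallest mean FWHM, then the smallest
transaxial FWHM. Every search reports a flat-minimum diagnostic — the
fraction of the grid within 1% of the minimum — and warns above 50%,
because a VOI with little contrast cannot pin the kernel down (the
estimate is then stable only as far as the reconstruction itself is).

The global kernel pools the six VOIs: for `h_PVC`/`h_AFC` the objective
is evaluated on the union of the VOI masks (voxels counted once); for
`h_pts` the per-VOI squared residuals (each VOI keeping its own
amplitude scaling and RMS normalisation) are summed and weighted by
voxel count.

Convergence is profiled by re-estimating the kernel at each MLEM
checkpoint; the estimate counts as stable from the first checkpoint
after which every successive change in mean FWHM stays below 0.5 mm (a
trailing checkpoint alone is not evidence). Kernel-width uncertainty is
estimated by refitting on 100 (configurable) random without-replacement
subsets of half the VOI voxels and reporting the SD per axis; the
subsampling RNG is seeded and reproducible.

## Simulator and reconstruction

The forward model blurs the ground-truth emission and mu-map with an
isotropic Gaussian at the scanner's intrinsic resolution (4.7 mm FWHM
default), forward-projects, and multiplies by attenuation factors
`exp(-integral mu dl)`. The projector is ray-driven: each of 120 angles
over 180 degrees and 96 radial bins (3 mm pitch) is sampled at
half-voxel steps with bilinear interpolation, materialised as a sparse
matrix so the back-projector is the exact transpose (adjointness is
asserted to 1e-6 relative in tests, and holds to machine precision).
Axial planes are projected independently (single-slice-rebinned
geometry); axial coupling enters only through the 3D intrinsic blur.
Poisson noise is available (bins scaled to a requested total count,
sampled, scaled back) but off by default — the study design is
noiseless.

MLEM uses the standard multiplicative update with the system model
attenuation ∘ projection; resolution is deliberately *not* modelled in
the system matrix, so the converged image is the intrinsically blurred
emission, and the effective reconstructed resolution is intrinsic ⊗
post-filter plus whatever under-convergence adds. Attenuation
correction uses the mu-map smoothed to the intrinsic resolution. The
initial image is uniform inside the circular scanner FOV; voxels whose
sensitivity falls below 1e-8 of the maximum are frozen at zero. The
Poisson log-likelihood can be tracked and is non-decreasing (tested on
noiseless and noisy data). 1000 iterations with checkpoints at
10/30/50/100/200/300/500/1000 are the default; the 6 mm FWHM Gaussian
post-filter is applied to checkpoint copies only, iteration continues
unfiltered.

Down-sampling between nested grids uses exact 1D interval-overlap
averaging per axis — a pure block average for integer spacing ratios,
flux-preserving linear overlap weighting otherwise — so constants
survive resampling exactly. Gaussian filters are truncated at 8 sigma
so kernel-composition identities (smoothing twice with f equals once
with f*sqrt(2)) hold to 1e-6.

## The procedural thorax phantom

One transaxial slice (default; a thin extruded 3D variant exists) of an
elliptical soft-tissue body with two elliptical lungs on a 96x96 PET
grid at 2.71 mm pitch, refined 4x (0.6775 mm) for the ground truth so
down-sampling is an exact block average. Inside the lungs:

* a lognormal tissue-fraction field: healthy baseline `V_t = 0.14`
  with 12% relative SD and 30 mm correlation length (lognormal keeps
  `V_t` positive and makes cold dips shallower than hot excursions, as
  in real parenchyma);
* three elliptical fibrotic patches (`V_t = 0.66`, 13% relative SD)
  with a 4 mm-sigma soft boundary, mimicking the gradual ground-glass
  transition of fibrotic infiltrates;
* thin vessel segments (~2 mm diameter, `V_t = 0.25` — small vessels
  at partial volume on the ground-truth grid) crossing the healthy
  VOIs, supplying the anatomical contrast that real parenchyma offers
  for resolution estimation;
* an optional subpleural dense rim (off by default).

Lung uptake is uniform per gram: emission `= 0.996 * V_t` (the target
AF-corrected SUV), so the ground-truth AF-corrected lung is exactly
uniform and the mu-map satisfies the mixture model voxel by voxel —
both are asserted as exact invariants. Soft tissue has SUV 0.35
(muscle/fat-dominated background of a mid-thorax slice) and `V_t = 1`.
The defaults are calibrated so whole-lung density (`rho = V_t x 1.0
g/cm^3`) is 0.24 ± 0.18 g/cm^3 — a severely heterogeneous fibrotic
lung at full inhale — and a test asserts both moments within 10% for
the default seed. Six 20 mm VOIs (three healthy, three at fibrotic
patch centres) are placed away from lung boundaries; the whole-lung
analysis mask is the lung down-sampled by fractional occupancy (>= 0.5)
and eroded by two voxels with a 6-connected structuring element.
Optional sphere inserts with inactive Perspex-like walls (LAC 0.11
cm^-1, configurable) can be filled to be homogeneous before AFC (same
activity as the lung background) or after AFC (background activity
divided by background `V_t`), emulating physical thorax-phantom
experiments; the digital-twin builder produces piecewise-constant
emission/mu volumes from a labelled segmentation and per-label
activity/LAC tables.

What the generator does **not** emulate: respiratory or cardiac motion,
CT beam-hardening and HU noise, scatter and randoms, TOF, airway trees,
and fully 3D tomography (the 3D mode projects slice-wise). Passing
tests therefore demonstrate the estimators' correctness and the
resolution-matching logic under an idealised but numerically demanding
(V_t down to 0.02) lung, not performance on patient data.

## Problem sizes and runtime

The study configuration — 384^2 ground-truth grid, 96^2 PET grid, 120
angles x 96 bins, 1000 MLEM iterations, seven reconstructions (one
baseline plus six point-source pairs), three methods x six VOIs x eight
checkpoints of kernel search over 101 grid points — runs in about 40 s
on one CPU; smoothed-library caching makes each additional search a
handful of masked vector operations.

## Observed behaviour worth knowing

* All three methods converge to ~7.0–7.3 mm mean FWHM on the default
  phantom, bracketing from above the quadrature sum of intrinsic blur
  and post-filter (7.62 mm) during convergence; AF-corrected VOI RMSE
  at >= 200 iterations is well below 10% of the target SUV and the
  estimates are checkpoint-stable to < 0.5 mm.
* The global (pooled-VOI) kernel corrects the whole eroded lung below
  10% RMSE from 200 iterations on, and still corrects every individual
  VOI below 10% on the heavily under-converged 30-iteration image. At
  200–300 iterations its whole-lung RMSE can exceed that of the single
  best VOI kernel by up to ~0.8 percentage points (all values ~2–5%),
  because every per-VOI estimate clusters within ~0.5 mm of the pooled
  one and the ordering among near-identical kernels is noise; from 500
  iterations on the global kernel matches or beats every individual
  kernel. A pooled kernel can only *strictly* dominate when per-VOI
  estimates scatter widely, which is precisely the unstable regime the
  pooling is meant to repair.
* Healthy-lung VOIs without anatomical structure in the estimable band
  (no vessels, weak density variation) produce flat objective minima
  and wandering kernel estimates — the flat-minimum diagnostic flags
  these; estimates in fibrotic VOIs are anchored by patch contrast and
  stabilise earliest.
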