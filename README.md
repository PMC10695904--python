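# lungafc

Air fraction correction (AFC) for lung PET/CT, with the simulation
machinery needed to choose — and defend — the Gaussian kernel that
matches the CT to the reconstructed PET resolution.

## The problem

FDG uptake in diffuse parenchymal lung disease (IPF, COPD) is measured
per millilitre of *lung*, but most of a lung voxel is air. Dividing the
reconstructed PET image by the voxel-wise tissue fraction

```
V_t = (mu_l - mu_a) / (mu_t - mu_a)
```

(from the 511 keV linear attenuation coefficients of the lung voxel,
tissue and air; `mu_l = V_t mu_t + (1 - V_t) mu_a`) converts the signal
to uptake per millilitre — in effect per gram — of tissue. The catch is
resolution: the CT that supplies `mu_l` is far sharper than the
reconstructed PET, so the mu-map must first be smoothed with a 3D
Gaussian kernel of the right FWHM and down-sampled to the PET grid, or
the corrected image is full of edge artefacts.

This package estimates that kernel by grid search (5–15 mm FWHM, 0.1 mm
steps) with three methods:

* **h_pts** — point-source insertion and subtraction: a single-voxel
  perturbation is added to the ground-truth emission on top of the full
  background (reconstructed contrast kept below 0.1 so the perturbation
  stays linear), both datasets are reconstructed, and the kernel whose
  smoothed point image best fits the reconstruction difference wins.
* **h_PVC** — the ground-truth emission is smoothed over the kernel grid
  and compared with the reconstruction inside a VOI (plain RMSE for
  noiseless simulations; for measured data a noise-weighted MSE,
  `nWMSE = 1/N Σ_v (A_obs,v − A_true,v)² / A_obs,v`, normalised to the
  mean lesion value).
* **h_AFC** — the mu-map is smoothed over the grid, the reconstruction
  AF-corrected with each candidate, and the kernel minimising the RMSE
  to the ground-truth AF-corrected image wins.

Per-VOI and pooled ("global") variants are provided, along with
convergence profiling across MLEM checkpoints (stability when successive
mean-FWHM changes fall below 0.5 mm) and kernel-width uncertainties from
voxel sub-sampling (SD over random half-VOI refits).

Because the kernel depends on the reconstruction and its convergence,
the package ships a self-contained simulation stack: a procedural
digital thorax phantom (two lungs with lognormal tissue-fraction
fields, fibrotic patches, vessels, optional sphere inserts), a
ray-driven forward projector with attenuation and a 4.7 mm FWHM
intrinsic-resolution blur, and a non-TOF MLEM reconstructor with
checkpointing and a 6 mm Gaussian post-filter.

## Worked example

```python
from lungafc import (build_phantom, default_spec_2d, ScannerModel, ReconSettings,
                     acquire, mlem, estimate_h_pvc, KernelSearchGrid)

phantom = build_phantom(default_spec_2d(seed=1234))
scanner = ScannerModel()                      # 4.7 mm intrinsic FWHM, 120 angles
sino = acquire(phantom.emission, phantom.mu_map, scanner)
recon = mlem(sino, scanner, pet_shape=(96, 96), mu_map=phantom.mu_map,
             settings=ReconSettings(n_iterations=200, checkpoints=(200,)))

voi = phantom.vois["VOI4_IPF"]
result = estimate_h_pvc(phantom.emission, recon.checkpoints[200], voi.mask,
                        KernelSearchGrid())
print(f"{voi.name}: h_PVC = {result.best.fwhm_xy:.1f} mm FWHM "
      f"(objective {result.best_value:.2f}% RMSE)")
```

prints

```
VOI4_IPF: h_PVC = 7.0 mm FWHM (objective 0.03% RMSE)
```

i.e. in this fibrotic VOI, after 200 MLEM iterations, the reconstruction
looks like the ground truth seen through a 7.0 mm FWHM Gaussian — close
to the quadrature sum of the 4.7 mm intrinsic resolution and the 6 mm
post-filter (7.6 mm). Smoothing the mu-map with this kernel before the
voxel-wise division is what keeps the AF-corrected image artefact-free.

The full study — all three methods, six VOIs, per-VOI and global
kernels, AFC RMSE tables across checkpoints — runs in one call:

```
lungafc run --out results/ --seed 1234
```

or from Python via `lungafc.pipeline.run_experiment`. The CLI also
exposes the individual stages (`phantom`, `simulate`, `recon`,
`estimate`, `correct`, `report`) operating on NIfTI volumes.

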