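# sarmorph

Desk-scale study of how subject head morphometry affects parallel-transmit
(pTx) 7T head-coil SAR, on fully synthetic data:

- **Synthetic phantoms** (`sarmorph.phantoms`): nested-ellipsoid multi-tissue
  heads of controllable morphometry, synthetic T1-weighted images, and
  segmentation-perturbed variants (boundary flips, tissue splits, inserted
  layers).
- **Registration** (`sarmorph.registration`): brain-mask extraction, 6/12-DOF
  affine registration (masked NCC, multi-resolution Powell with progressive
  DOF release) and a demons-style nonlinear stage; Dice and tissue-property
  agreement metrics.
- **Surrogate coil fields** (`sarmorph.coilfields`): per-channel complex E and
  B1+ volumes for an 8-channel cylindrical loop array from magnetostatic loop
  kernels with skin-depth attenuation, normalised to 1 W deposited power per
  channel; strict linear superposition.
- **Dosimetry** (`sarmorph.dosimetry`): pointwise SAR (sigma|E|^2 / 2 rho),
  10g mass-averaged SAR by voxel-centred cube growing with fractional outer
  layer, total absorbed power, and CP-mode 2 uT isocentre normalisation.
- **Shimming / VOP** (`sarmorph.shimming`): 5000 random shims (uniform phase
  and magnitude, 5 W total conducted power), per-region Hermitian Q-matrices
  (w^H Q w = region 10g SAR), exhaustive per-shim maxima, and VOP compression
  with a provable <= 5 % overestimation bound.
- **Statistics** (`sarmorph.stats`): Bland-Altman, percent-difference
  summaries and percentiles, B1+ RMSE, segmentation-uncertainty comparison.
- **Pipeline/CLI** (`sarmorph.pipeline`, `sarmorph.cli`): seeded end-to-end
  runs over built-in reference/target subjects and rigid/affine/nonlinear
  registration, emitting CSV/JSON/NIfTI/HDF5 reports and a run manifest.

## CLI

```sh
sarmorph run-all --seed 1 --outdir out            # full morphometry study
sarmorph phantom --outdir out                     # phantoms + T1 as NIfTI
sarmorph fields --model out/reference_labels.nii.gz --out out/fields.h5
sarmorph cp --fields out/fields.h5 --model out/reference_labels.nii.gz --out out/cp.json
sarmorph shim-sar --fields out/fields.h5 --model out/reference_labels.nii.gz \
    --qset-out out/q.h5 --out out/series.csv
sarmorph vop --qset out/q.h5 --out out/vops.h5
sarmorph uncertainty --seed 1 --outdir out
sarmorph report --pairs out/pairs_subject_a_affine.csv --out out/report.json
```

Configuration is JSON/YAML (`--config`); see `sarmorph.pipeline.RunConfig`
for all knobs (phantom grid, registration methods, shim count/power, VOP
margin, 10g settings, seeds).

## Notes

- All volumes are NIfTI-1 (0-based voxel indices, 4x4 world affine in mm);
  field/Q/VOP stores are HDF5; tables are CSV.
- The field surrogate replaces a full-wave FDTD solver: it preserves linear
  superposition, tissue-dependent loss and the qualitative field structure,
  but makes no claim of field-pattern fidelity (coil coupling/tuning and
  permittivity-driven wavelength effects are not modelled).
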