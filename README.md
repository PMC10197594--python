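# gridfit

Model-based localization of intracranial electrode arrays from
post-implantation CT, and smooth brain-shift compensation of the resulting
coordinates.

Intracranial EEG (ECoG/sEEG) analyses need each contact's anatomical
position, but the post-implantation CT offers only clouds of metal-artifact
voxels — noisy, merging at low SNR, and contaminated by cables or
overlapping arrays — and the implanted brain is shifted by up to 10–20 mm
relative to the pre-implantation MRI. `gridfit` addresses both problems for
researchers and clinical teams working with subdural grids, strips, and
depth electrodes:

* **Array fitting.** All `NElec` contacts of an array are localized
  *simultaneously* by fitting a flexible spring-mesh model of the array to
  the thresholded voxel cloud `v, w`, minimizing

      E_Fit = kTrans·ETrans + kDef·EDef − kCorr·ECorr

  where `ETrans = (1/NMod) Σ ‖m0_j − m_j‖²` penalizes translation of the
  structural points, `EDef = (1/NConn) Σ α_jk ((d0_jk − d_jk)/d0_jk)²` the
  relative strain of the spring mesh, and
  `ECorr = (1/(NMod·W·σ√2π)) Σ_n Σ_j w_n u_j exp(−‖v_n − e_j‖²/2σ²)`
  rewards contacts sitting on bright voxels. Two minimization steps are
  used: a coarse pass (σ = D) constrained to a smooth surface/line
  approximation of the cloud, then a refinement (σ = D/4) under hard
  deformation bounds (10% neighbors / 25% all pairs), slab volume
  conservation, and optional user-fixed contacts.
* **Brain-shift compensation.** Grid/strip coordinates are projected to
  the smooth cortical envelope (SCE, the morphological closing of the pial
  surface) by minimizing a combination of translation, spring deformation,
  anchor attraction (orthogonal-projection targets), and the roughness of
  the deformation field, constrained to the envelope — alongside the
  classical Springs, grid-normal, and envelope-normal projections.
  Co-implanted depth electrodes inherit a Gaussian-weighted translation
  field from the projected arrays.
* **Synthetic validation.** A simulation module drapes arrays on curved
  phantoms, renders CT-resolution artifact blobs, displaces voxels with
  calibrated noise, adds overlap clutter, and scores fits against ground
  truth — the machinery used to calibrate the fitting weights and to
  validate the whole package without any patient data.

## Worked example

Simulate a hard scenario — a 4×8 grid at 10 mm spacing draped on a curved
phantom, high voxel noise, with a distractor from an overlapping array —
and localize it:

```python
from gridfit import ArrayGeometry, gridfit
from gridfit.simulate import SimCondition, make_scenario
from gridfit.metrics import ied_mad, localization_error

geometry = ArrayGeometry("grid", n_rows=4, n_cols=8, ied=10.0)
condition = SimCondition(geometry, noise_level="high", overlap=True)
scenario = make_scenario(condition, seed=13)
print(f"cloud: {scenario.cloud.n_voxels} voxels, W = {scenario.cloud.total_weight:.1f}")

fitted = gridfit(scenario.cloud, geometry)
report = localization_error(scenario.truth, fitted)
print(f"median error: {report.d_loc_med:.4f} IED "
      f"({report.d_loc_med * geometry.ied:.2f} mm)")
print(f"maximum error: {report.d_loc_max:.4f} IED")
print(f"IED MAD of the fit: {ied_mad(fitted):.3f} mm")
```

which prints:

```
cloud: 1143 voxels, W = 392.0
median error: 0.0275 IED (0.27 mm)
maximum error: 0.0719 IED
IED MAD of the fit: 0.176 mm
```

The median contact is localized within 0.27 mm (2.8% of the 10 mm
inter-electrode distance) despite the noise and the distractor; the worst
contact is within 0.72 mm; and the fitted lattice is regular (its
inter-electrode distances deviate from their mean by 0.18 mm on average).
Errors are reported normalized by the spacing because that is how batch
accuracy is defined: accuracy = 1 − median(d_loc_med) over arrays, so 98%
accuracy at 10 mm spacing means 0.2 mm typical error.

The same pipeline is available from the shell:

```bash
gridfit simulate --seed 3 --replicates 2 --out sim/
gridfit fit --cloud sim/0000_*_cloud.tsv --type grid --rows 4 --cols 4 --ied 10 --out fit.tsv
gridfit evaluate --truth sim/0000_*_truth.tsv --fitted fit.tsv --out report.json
gridfit project --method cepa --surface sce.gii --in fit.tsv --out projected.tsv
```

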