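# ecvatlas

Myocardial extracellular-volume (ECV) mapping from late-enhancement cardiac
CT, for imaging scientists who want a transparent, testable implementation
of ECV "atlas maps": from an iodine-concentration volume and the patient's
hematocrit to polar maps, median-filtered 34 × 72 atlas maps with
threshold-based lesion marking, pathologic-segment calls, and intermodality
agreement statistics. Everything runs end-to-end on a built-in synthetic
left-ventricle phantom, so no patient data is required to exercise or
validate any stage.

## The method

With an extracellular contrast agent at quasi-equilibrium, voxelwise ECV
follows from the iodine concentration ratio and the hematocrit (the plasma
fraction of blood):

    ECV = (1 − hct) · I_myo / I_blood

The left ventricle is described by a long axis, a base plane and an apex;
every myocardial voxel gets an axial position, an azimuth relative to the
anterior reference (the center of AHA segment 1), and a transmural depth
(0 = endocardium, 1 = epicardium). Radial collection of voxels then yields:

- **Polar maps** — the standard AHA 16-segment bullseye, one wheel each for
  the subendocardium (10–50 % depth) and subepicardium (50–90 %).
- **Atlas maps** — a much finer partition: 34 longitudinal layers × 72
  angular sectors × 3 transmural layers (≈ 2 × 2 mm cells on the surface).
  Each transmural layer is unrolled into a 34 × 72 matrix, cut open
  anteriorly, denoised with a 5 × 5 median filter (circular wrap along the
  sector axis), and thresholded at 45/40/35 % ECV as markers of descending
  lesion probability, annotated with the volume percentage of the layer
  above each threshold. On i.i.d. Gaussian noise the 5 × 5 median filter
  cuts the noise standard deviation about fourfold (closed form
  √(2n/π) ≈ 3.99 for n = 25), while lesions of ≥ 1 cm surface diameter are
  retained.

A segment-band is called **pathologic** if any criterion fires: a
6-connected cluster of voxels with ECV > 45 % (overlay), > 50 % of the
segment-band in unfiltered cells with mean ECV > 45 % (polar), or > 25 % in
filtered atlas cells with ECV > 40 % (atlas). Agreement with a reference
reading (e.g. MRI late gadolinium enhancement) is summarized with Cohen's
weighted κ, interpretation bins, and a total/partial/no concordance
taxonomy.

## Worked example

The built-in demo simulates a 55 % ECV transmural inferolateral infarct
(50° × 20 mm) in a 70 × 50 mm LV shell with 1 cm wall, blood iodine
5 mg/mL, hematocrit 0.40 and Gaussian iodine noise of 1.1 mg/mL (aortic
SNR ≈ 4.5), then runs the whole chain:

```bash
ecv-atlas run --out demo/ --seed 7
```

This writes `ecv.nii.gz`, `compartments.csv` (7,344 rows, one per
3 × 34 × 72 cell), `atlas.pdf`, `polar.pdf`, `calls.csv`, `agreement.json`
and `run.log`. The pathologic rows of `calls.csv`:

```
segment  band     pathologic  criteria       overlay_fraction  polar_fraction  atlas_fraction
11       subendo  1           atlas;overlay  0.322             0.343           0.302
11       subepi   1           atlas;overlay  0.319             0.341           0.298
12       subendo  1           atlas;overlay  0.327             0.353           0.314
12       subepi   1           atlas;overlay  0.330             0.350           0.308
```

The lesion straddles the mid-inferolateral/anterolateral boundary, so
segments 11 and 12 are called in both bands: about 30 % of each segment-band
lies in filtered atlas cells above 40 % ECV (> 25 %, atlas criterion) and
the supra-45 % voxel clusters are far above the 50-voxel floor (overlay
criterion); the polar criterion stays below its 50 % floor. Compartment
means inside the lesion recover the simulated value (e.g. layer 17,
sector 53: 55.8 % from 54 voxels), and `agreement.json` reports perfect
segment-level agreement with the phantom ground truth:

```json
{"kappa": 1.0, "interpretation": "almost perfect", "concordance": "total",
 "ct_segments": [11, 12], "reference_segments": [11, 12]}
```

The same stages are available individually (`ecv-atlas simulate | ecv |
atlas | polar | classify | agree | noise-sim`) and as library functions
(`generate_phantom`, `compute_ecv`, `build_compartments`, `build_atlas`,
`classify_segments`, `cohens_kappa`, ...).

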