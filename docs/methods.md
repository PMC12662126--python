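# Methods

## ECV model

ECV is computed voxelwise as `ECV = (1 − hct) · I_myo / I_blood`, where
`I_myo` is the late-enhancement iodine concentration (mg/mL), `I_blood` the
blood-pool concentration (a scalar, or the mean over an aortic ROI mask),
and `hct` the hematocrit in L/L. ECV is carried as a *fraction* everywhere
inside the package and converted to percent only for display and
thresholding; keeping a single internal unit removes an entire class of
threshold bugs. Noise pushes voxel values outside [0, 1]; those values are
clipped for rendering and volume export but kept unclipped in every
averaging step (clipping before averaging would bias low-signal regions
upward) — the out-of-range voxels are counted and logged.

## Synthetic left ventricle

The phantom myocardium is a half-capsule shell: a cylinder of length
`lv_length − outer_diameter/2` closed by a hemispherical apex cap, with an
open flat base perpendicular to the long axis. This is the simplest smooth
shape with a well-defined long axis, an apex, and a closed-form volume
(π(r_o² − r_i²)·L_cyl + ⅔π(r_o³ − r_i³)), which serves as the volume oracle
in the tests. Papillary muscles, trabeculation and the right ventricle are
not modeled; they do not enter any sampled quantity. Users with real data
substitute a myocardium label mask and a mask-derived wall model.

Defaults: 70 mm length, 50 mm outer diameter, 10 mm wall, 0.4 × 0.4 × 1.0 mm
voxels (≈ 514,000 myocardial voxels), background ECV 0.27 (inside the
< 30 % range considered normal), hematocrit 0.40 L/L, blood iodine
5.0 mg/mL in the late phase. Lesions are wedge regions defined by angular
extent, longitudinal extent and a transmural depth range, with an optional
nested hypo-enhancing core emulating microvascular obstruction. Voxel
membership is decided by voxel-center inclusion, and the same rule is used
by every oracle. Iodine is `ecv · blood / (1 − hct)` plus optional i.i.d.
Gaussian noise (mg/mL), seeded and bit-reproducible. The default noise
level used in the demo and in the classification robustness tests is
σ = 1.1 mg/mL, chosen so that the aortic SNR of a 5 mg/mL blood pool is
≈ 4.5 — a typical value for spectral late-enhancement imaging. An optional
cylindrical "aorta" insert carrying the blood-pool concentration exists
solely to exercise the SNR estimator.

What the phantom does *not* emulate: CT physics (beam hardening, spectral
decomposition, photon-counting detector effects), cardiac/respiratory
motion, partial-volume blur at tissue interfaces, registration error
between acquisitions, and anatomical variability of LV shape. Passing
tests therefore demonstrate correctness of the *sampling, filtering,
thresholding and statistics*, not robustness to acquisition artifacts.

## Coordinate frame and raytraced compartments

The LV frame is a long axis (unit vector, base point, base→apex length), an
anterior reference fixing azimuth 0 at the center of AHA segment 1, and a
wall model giving transmural depth. Azimuth increases in the AHA
counterclockwise numbering direction as viewed from the apex — the
direction of `cross(long_axis, anterior)`. Analytic depth is linear in the
radial (barrel) or spherical (apex cap) distance between the surfaces;
mask-derived depth is `d_endo / (d_endo + d_epi)` from Euclidean distance
transforms of the cavity and the exterior, which agrees with the analytic
value to within one voxel spacing of wall depth.

Compartmentalization is a pure radial assignment (no resampling or
interpolation): each in-band voxel goes to exactly one
(depth, layer, sector) cell — layers partition [base, apex] uniformly
(layer 1 = base, equal spacing assumed), sectors are 5° azimuthal bins from
the anterior cut, and depth bands divide the 10–90 % depth interval into
equal slices (three for atlas maps: 10–36.7/36.7–63.3/63.3–90 %; two for
polar maps: 10–50/50–90 %). The 10/90 % margins exclude blood-pool and
epicardial-fat partial volume at both surfaces; reusing them for both map
types keeps the two pipelines consistent. One shared floor-binning rule
(upper boundary closed) is used for layers, sectors, depth bands and AHA
rings, so the partition property — every in-band voxel in exactly one cell,
counts conserved — holds by construction and is asserted by brute force in
the tests. Voxels closer to the long axis than one voxel spacing have an
unstable azimuth (this occurs only in the apex cap); they are discarded and
counted. Cell means use unclipped ECV; empty cells carry NaN and count 0
and are excluded from all percentages. Internal indices are 0-based,
exports and documentation 1-based.

## Atlas maps

Each transmural layer is a 34 × 72 matrix, cut open at the anterior
reference. The median filter wraps circularly along the sector axis — the
cut position is arbitrary and filtering must commute with rotating the
ring, which the tests assert exactly — and replicates edges along the
longitudinal axis. NaN cells are excluded from each window's median (a
window of only NaNs stays NaN); otherwise apex rows would poison their
neighborhoods. The 5 × 5 kernel reduces i.i.d. Gaussian noise by a factor
of ≈ 4 (asymptotically √(2n/π) = 3.99 for n = 25; the finite-sample value
is slightly above), while a 3 × 3 kernel achieves only ≈ 2.45 — the reason
the larger kernel is the default ahead of thresholding. The cost of
filtering is spatial: rectangular lesion patches lose their corners
(about 12 cells regardless of size), isolated high-contrast spots smaller
than ~3 cells across vanish entirely — which is why thin MVO rims do not
survive into atlas maps — and lesions of ≥ 5 × 5 cells (≈ 1 cm on the
surface) keep their core values unchanged.

Thresholds (45/40/35 % ECV, descending lesion probability) are strict
(`>`), applied to full-precision filtered values in percent. Per-layer
volume percentages are voxel-count weighted, not cell-count weighted,
because cells carry unequal voxel counts. Scar volume is the sum of
`voxel_count × voxel_volume` over supra-threshold cells; with the default
geometry it recovers the in-band volume of a representative transmural
lesion to within ~15 % (corner erosion plus partially covered boundary
cells).

Rendering: atlas maps use three discrete alert levels over a neutral base
(not a continuous scale), one panel per layer with the base at the top,
annotated with the three volume percentages; polar maps use a continuous
colormap with a fixed 0–60 % range. Any perceptually ordered colormap
works; `turbo` is the default. PDF timestamps are suppressed so outputs are
byte-stable under a fixed seed.

## Pathologic-segment criteria

Calls are made per AHA segment and band (32 per study), OR-combined across
criteria:

- **overlay** (voxelwise ECV > 45 %): the raw criterion has no size floor,
  so a 6-connected cluster of ≥ 50 voxels (≈ 10 mm³ at default spacing)
  within the segment-band is required; configurable.
- **polar** (> 50 % of the segment-band above 45 %): evaluated on
  *unfiltered* compartment means in the matched two-band grid, mirroring
  the unfiltered polar-map display pipeline.
- **atlas** (> 25 % of the segment-band above 40 % filtered): the three
  atlas depth layers are apportioned to the two bands with the midwall
  contributing half its weight to each (`midwall_policy="split"`;
  `"both"` gives it full weight in both). The lower threshold compensates
  for the smoothing of the median filter.
- **visual**: reading the late-enhancement images is a human criterion; an
  externally supplied (16, 2) boolean vector is merged by OR.

All fractions are voxel-weighted. The criteria are monotone in ECV:
raising any voxel's ECV can never turn a positive call negative (asserted
in tests). At the default noise level the pipeline is both sensitive
(a transmural 55 % lesion covering ≥ 40 % of a segment is always called in
both bands) and specific (a lesion-free noisy heart produces no call in
any of the 32 segment-bands).

## Statistics

- **Cohen's κ** with linear weights by default; for the binary vectors used
  here linear, quadratic and unweighted coincide, so the choice is
  immaterial (and cross-checked against scikit-learn). κ is undefined when
  both raters are constant and identical; this raises a dedicated error
  rather than returning a number. Segment-level κ pools segments across
  patients; within-patient dependence of segment calls is negligible in
  this setting, so pooling is appropriate. Interpretation bins: < 0.20 no
  agreement, 0.20–0.39 minimal, 0.40–0.59 weak, 0.60–0.79 moderate,
  0.80–0.89 strong, 0.89–1.00 almost perfect — the top bin starts at 0.89,
  so values in [0.89, 0.90) bin as "almost perfect".
- **Concordance**: total iff the CT and reference segment sets are equal
  (two empty sets are total by convention); none iff CT found none of a
  non-empty reference set; partial otherwise.
- **Median/IQR**: the median is convention-free; quartiles are not, and the
  default is linear interpolation of order statistics (any numpy percentile
  method can be selected). Only medians are asserted against reference
  values in the tests, never quartiles.
- **Wilcoxon signed-rank**: zero differences dropped (classic policy),
  exact null distribution for ≤ 25 untied differences, tie-corrected normal
  approximation otherwise. An all-zero difference vector returns p = 1 with
  a warning. Pairing must be supplied explicitly.
- **Noise simulation**: generates an i.i.d. Gaussian matrix of the
  requested size, filters it, and reports input-std/output-std over
  interior cells (one kernel width of margin); warns below 10⁴ cells.

## Reference cohort tables

The package ships the per-participant pathologic-segment counts of a SCAD
(spontaneous coronary artery dissection) cohort — acute-phase and follow-up
late-enhancement CT, LGE MRI and MRI edema — as plain CSVs
(`ecvatlas/data/`). They drive regression tests of the median summaries
(acute LGE median 6, acute edema 3, follow-up CT 7, follow-up LGE 6,
follow-up edema 0, aggregate LGE 6) and can be reused for agreement
examples.

## Problem sizes and numerical choices

The default phantom (≈ 514,000 myocardial voxels) is used where the voxel
budget itself is the claim; geometry, map and classification tests run on
0.8 × 0.8 × 1.0 mm or 1.6 × 1.6 × 2.0 mm grids, which preserve every
geometric property at a fraction of the cost. The noise-reduction
simulation uses 10⁶ cells, giving reduction-factor estimates stable to
well under 0.05. All randomness flows through numpy's `default_rng` with
explicit seeds; the full pipeline is byte-deterministic under a fixed seed.

## Known limitations

- No image registration: iodine volume, mask and geometry are assumed
  co-registered (the phantom guarantees this by construction).
- No automatic LV segmentation from gray-scale CT; geometry comes from the
  analytic phantom or a supplied label mask.
- Mask-derived depth requires the volume grid to start at the base plane so
  the cavity is topologically separated from the exterior.
- Atlas maps deliberately trade small-feature sensitivity for noise
  suppression: thin rims and sub-centimeter foci (including MVO rims) can
  be filtered away, so they complement rather than replace the voxelwise
  overlay reading.
- DICOM ingestion is out of scope; volumes are NIfTI-1.
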