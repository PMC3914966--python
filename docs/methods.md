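# Methods

## Segmentation model

Cell detection is nucleus-seeded. Nuclei are found on the DNA-stain
channel by Gaussian smoothing (default σ = 1.5 px), a global threshold,
hole filling, and an optional distance-transform watershed that splits
touching nuclei (peak separation `split_min_distance_px`, default 8 px).
The global threshold is Otsu's, supplemented by a robust background cut
(background median + 6 MAD): with nuclei of heterogeneous brightness a
single Otsu threshold can sit above the dimmest nuclei, and the robust
cut recovers them. Because any global threshold biases object extent
when objects differ in brightness (bright objects spill outward under
smoothing, dim ones erode), each object is then re-thresholded at half
its own peak height above background — for a Gaussian-blurred step edge
the half-maximum contour coincides with the true boundary, so this
removes the brightness-dependent bias. Objects smaller than
`min_nucleus_area_um2` (default 20 µm², far below the 150 µm²
classification boundary so debris removal cannot absorb rule decisions)
are discarded.

One cell region is grown per nucleus on the whole-cell-stain channel by
a watershed on the inverted smoothed intensity, seeded at the nuclei and
confined to the union of the stain's Otsu foreground and the nucleus
pixels (a nucleus is never orphaned by dim cytoplasm). Boundaries
between adjacent cells therefore follow the dim valley between them.
Cells touching any image edge are removed together with their nuclei —
their areas would be censored — and the survivors are relabelled
contiguously with nucleus/cell pairing preserved. A cell region fully
claimed by neighbours (impossible under seeded watershed, guarded
anyway) is dropped with a logged warning.

Features per cell: nuclear area = nucleus pixel count × `pixel_size_um²`;
cell area likewise over the full cell region (nucleus included); mean
DNA intensity and maximum mitosis-marker intensity over the nucleus
pixels, in raw detector units with no rescaling or bit-depth assumption.
Pixel size is a required configuration value; a helper derives it from
image dimensions and the 510 × 675 µm field of view when that applies.

## Classification and endpoints

The abnormality rule is a disjunction of three strict comparisons (cell
area > 1350 µm², nuclear area < 150 µm², mean DNA intensity > 1500
units) and the mitosis rule a single strict comparison (max nuclear
phosphohistone-H3 > 1200 units). Values exactly at a threshold are
normal/non-mitotic. The two flags are independent because they derive
from different channels; a cell may carry both. Whether "cytoplasmic
area" means the full cell or the cell-minus-nucleus ring is genuinely
ambiguous in high-content practice; the default is the full cell (the
1350 µm² default threshold is calibrated to that reading) with
`cyto_area_mode = "ring"` as the alternative. Wells pool all fields
before summarisation; a well with zero cells reports missing
percentages rather than zeros.

## Screen statistics

Z′ = 1 − 3(σ_s + σ_c)/|μ_s − μ_c| and Z = (x − μ_c)/σ_c, with sample
SDs (n−1) throughout and CVs in percent. The hit cutoff |Z| ≥ 2 is
inclusive; the false-positive definition (negative wells with |Z| > 2)
and false-negative definition (positive wells with |Z| < 2) are strict.
This inclusive/strict asymmetry is kept deliberately: the two
definitions are quoted from different sentences of the assay's
description and only differ on a measure-zero event for continuous
endpoints. FP/FN rates score wells individually; hit calling aggregates
replicate wells per compound first (default: mean; `median` and
`per_well_any` are available for sensitivity analysis — note that a
mean of r replicates has a null Z SD of 1/√r, so aggregation shrinks
the null hit rate far below the per-well tail). Batch scope defaults to
"all plates processed together" (a 9-plate batch carries 72 negative
controls); per-plate scoring is available. Excluded wells are dropped
before any statistic.

A calibration fact worth stating precisely: when Z-scores use a mean
and SD *estimated* from n independent negative controls, the null
distribution of Z for an independent well is √(1+1/n) · t(n−1), so the
|Z| ≥ 2 rate is P(|t₇₁| ≥ 2/√(1+1/72)) ≈ 5.09% for n = 72, not the
asymptotic 2(1−Φ(2)) ≈ 4.55%. The acceptance script reports the
empirical rate under estimated batch controls; the test suite asserts
both regimes against their own exact expectations.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the assay's study conditions at two levels.

**Rendered fields** place elliptical cells with a minimum
centre-to-centre spacing (the well-spread monolayer regime of a
U2OS-like line) and require the *cell* ellipses to be disjoint: with
overlapping cells the painted ground-truth mask depends on paint order
and per-cell area recovery is ill-defined. Channels are built as
ellipse indicators times per-cell levels plus background, with Poisson
shot noise and Gaussian read noise (σ = 3 by default — high SNR, so
segmentation failures reflect geometry, not noise). Non-mitotic cells
carry a mitosis-marker level near 225 units, the documented negative
maximum; mitotic cells ~1900.

**Sampled tables** draw per-cell features from per-phenotype
distributions placed on the far side of each rule threshold: normal
nuclear area lognormal with median 270 µm² (inside the typical 200–350
µm² band) and mean DNA intensity ~600 units; enlarged cells with median
cell area 2200 µm²; condensed cells with median nuclear area 100 µm²;
DNA-bright cells at ~2400 units. Well cell counts are Poisson with a
lognormal well effect. Defaults for the control roles: negative wells
at full density with a 7% well CV; positive (taxol-like) wells at 54.6%
of the negative cell count with a 21% well CV and a 30%/8%
abnormal/mitotic mix. The 54.6% and 21% anchors are reported assay
facts; the 7% negative CV is an assumption chosen so that a
54.6%-of-control well sits near Z ≈ −6.5, the reported positive-control
extreme — the assay's description gives no negative-control dispersion
directly. Simulated screens use 96-well plates with 8 negative and 8
positive controls in columns 1 and 12 and compounds round-robined over
the remaining 80 wells, grouped into 9-plate batches.

Problem sizes default to one tenth of production density (4000
cells/well scaled by `scale = 0.1`, 512 × 512 px test fields rather
than full 510 × 675 µm fields); these sizes make the full suite run in
seconds while keeping every statistic's sampling error well inside the
asserted tolerances.

What passing tests on this generator do **not** show: robustness to
confluent or overlapping cells, illumination gradients, focus drift,
staining batch effects, or debris that mimics nuclei — none of which
the renderer produces. Results on real plates depend on those factors
and on the pixel-size and threshold configuration matching the
instrument.

## Numerical and design choices

- Thresholding a constant raster with Otsu returns zero objects rather
  than erroring (an empty field is valid data).
- Border contact means any object pixel in the first/last row or
  column; rasters are row-major, indexed from 0.
- The distance-transform watershed merges duplicate plateau peaks
  before seeding, preventing over-splitting of flat-topped nuclei.
- `control_stats` requires n ≥ 2; Z′ requires distinct control means;
  Z-scores require σ_c > 0 — all violations raise typed errors rather
  than returning NaN.
- Spearman's sign (not a fitted curve) flags dose-response trends;
  no EC50 model is fitted anywhere.
- Determinism: every stochastic routine takes a single integer seed (or
  a `numpy` Generator) and reruns are bit-identical; pipeline CSV
  artifacts are byte-identical across reruns.

## Known limitations

- Segmentation is classical (threshold + watershed); machine-learned
  instance segmentation is out of scope, as are 3-D stacks, tracking,
  texture features and illumination correction.
- No multiple-testing correction is applied to hit calls, matching the
  screening practice this implements; at |Z| ≥ 2 roughly 5% of null
  compounds are expected to be called per endpoint.
- The mitosis endpoint's controls overlap (Z′ < 0 under the default
  generator, as in the assay it emulates), so it is reported for QC but
  not scored in the default screen run.
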