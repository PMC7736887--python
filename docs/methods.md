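# Methods

`petpair` re-implements, as a tested library, the quantitative analysis
used to compare [¹⁸F]FDG uptake between a high-resolution dedicated
breast PET (dbPET, ~1 mm voxels) and a conventional whole-body PET
(wbPET, ~4 mm voxels) of the same breast tumor. Because paired patient
scans of this kind are not publicly available, the package ships a
digital phantom and acquisition simulator that reproduces the
*measurement situation* — one ground-truth lesion imaged at two
resolutions and point-spread-function (PSF) widths — so every
downstream stage can be exercised and validated end to end.

## Phantom and acquisition model

The ground truth is a fine-grid (0.5 mm) activity map on an
80 × 80 × 144 mm domain: an ellipsoidal breast containing one spherical
lesion, and an ellipsoidal liver placed above the breast so that it is
seen only by the whole-body field of view. Activity is expressed on an
SUV-equivalent scale and converted to Bq/mL through each simulated
patient's injected dose and body weight, so the SUV conversion
round-trips exactly.

Per-phantom draws emulate inter-patient variability:

| parameter | default | rationale |
|---|---|---|
| parenchyma uptake | U(0.3, 1.5) SUV | normal breast background, consistent with the tumor-to-background ratios the pipeline reports |
| liver uptake | U(1.8, 2.6) SUV | typical hepatic FDG levels used as a reference region |
| lesion base uptake | U(4, 15) SUV | locally advanced breast tumors |
| lesion diameter | mixture: 40% U(2.0, 2.5) cm, 60% U(2.6, 5.6) cm | trial-like cohort with a 2 cm inclusion floor, ~40% of lesions at or below the 2.5 cm stratification cutoff |
| intratumoral heterogeneity | amplitude U(0.15, 0.4), correlation length U(4, 10) mm | moderate heterogeneity: a correlated Gaussian random field scaled and clipped to the amplitude, multiplying the base uptake |
| body weight / height | N(66, 4²) kg / N(1.62, 0.06²) m (clipped) | all-female cohort of typical habitus |
| injected dose | U(121, 199.8) MBq (db), U(229.4, 392.6) MBq (wb) | the two modalities use separate injections on separate days |

Acquisition is an image-domain abstraction: isotropic Gaussian PSF blur
(FWHM 2 mm db / 7 mm wb by default), block-averaging onto the output
grid (1 mm db / 4 mm wb; block averaging rather than interpolation so
total activity is conserved exactly), then additive Gaussian noise with
standard deviation `c·√signal` on the SUV-equivalent scale, clipped at
zero. The noise coefficient defaults to 0.10 (db) and 0.05 (wb): the
dedicated scanner trades higher resolution for higher background noise.
Defining the coefficient on the SUV scale keeps it dimensionless; on raw
Bq/mL the square root would be unit-dependent. Sinogram-level physics,
iterative reconstruction, attenuation/scatter correction, respiratory
motion and prone/supine deformation are deliberately out of scope. An
optional myocardial hot region near the chest wall can be enabled to
emulate cross-talk; it is off by default.

What the simulator does **not** emulate: reconstruction artifacts,
scanner-specific noise texture and resolution anisotropy, a true
contralateral breast (the phantom has one breast; the "contralateral"
background VOI is placed at a fixed normal-parenchyma point distant from
the lesion), multi-focal disease, and non-spherical lesion shapes.
Passing tests therefore demonstrate correctness of the quantification
chain and the *direction* of resolution-driven effects, not calibration
to any patient population.

## Quantification

* **SUV**: `C_decay-corrected / (dose/weight)` with dose in Bq, weight
  in g. Decay correction is a single exponential with the F-18
  half-life (109.77 min); the reference interval is configurable and
  defaults to zero (simulated images are already decay-corrected).
* **SUL**: SUV × LBM/weight. The lean-body-mass formula defaults to
  Janmahasatian (female form: `9270·W / (8780 + 244·BMI)`), with James
  and identity variants selectable.
* **Segmentation**: seeded 26-connected component of the
  supra-threshold SUV set, thresholds 3.0 (db) and 2.5 (wb); the seed
  point stands in for the operator's click of a semi-automated workflow.
* **SUL_peak**: maximum over tumor voxels of the mean within a 1.2 cm
  *diameter* spherical kernel (the ~1 mL PERCIST sphere), membership by
  voxel-center inclusion; the kernel may extend beyond the tumor mask
  but is truncated at the image boundary.
* **Background VOIs**: 1.2 cm sphere (liver and contralateral breast on
  wb) and a 1.2 cm diameter × 1.2 cm height cylinder, axis along the
  image's third axis (contralateral breast on db). Tumor-background
  ratio = tumor SUL_peak / background SUL_mean; a non-positive
  background mean yields an undefined (not infinite) ratio.
* **MTV/TLG**: MTV sums voxel volumes with SUV ≥ 40% of the VOI mean;
  TLG = MTV × mean SUV over the MTV sub-region (the prevailing
  convention; a switch selects the VOI mean instead — the defining
  sentence is ambiguous between the two).

Known bias: with a fixed SUV threshold, PSF blur moves the apparent
lesion boundary by a sub-millimeter amount that depends on lesion
contrast. For 2 cm lesions under the 2 mm-FWHM configuration this puts
MTV typically within ~12% of the true volume (noise-free), but
individual small, high-contrast lesions can exceed 15%.

## Radiomic features

Twenty features in four groups, computed after trilinear resampling of
image and mask to a 2 mm isotropic grid (mask re-binarized at 0.5) and
fixed-bin-width discretization with `level = floor(SUV/0.5) + 1`. Bins
are anchored at zero — absolute uptake bins are comparable across
patients and modalities — and half-open, so a value exactly on an edge
belongs to the upper bin. Features are computed on the SUV image; the
50-bin QC histograms use SUL.

* **Morphology**: mesh volume, surface area and sphericity
  `(36π V²)^{1/3}/A` from the 0.5-level marching-cubes surface of the
  mask. The binary mask is pre-smoothed with a 0.8-voxel Gaussian
  before meshing to suppress the staircase artifact, which otherwise
  inflates surface area by several percent on digitized smooth shapes;
  a thin mask that vanishes under smoothing falls back to the raw
  binary surface, and a degenerate (single-voxel) mask to a voxel-box
  estimate, flagged by a warning. Maximum 3D diameter is the largest
  pairwise distance between surface-voxel centers — a deliberate
  deviation from mesh-vertex conventions, chosen so the value does not
  depend on mesher details.
* **Intensity**: entropy (bits) and uniformity on the discretized-level
  histogram; standard deviation, skewness and kurtosis as population
  (uncorrected) moments of the raw in-mask values. Kurtosis is the
  un-excess Pearson form (Gaussian ≈ 3). A zero-variance region
  returns skewness = kurtosis = 0.
* **GLCM**: for each of the 13 unique 3D directions at Chebyshev
  distance 1, a symmetric co-occurrence matrix over in-mask pairs,
  normalized per direction and averaged over directions with at least
  one pair (matrices, not per-direction feature values, are averaged;
  empty directions are dropped). Features: contrast, correlation
  (defined as 1 for a constant region), inverse difference, inverse
  difference normalized by N_g, joint energy, joint entropy.
* **NGTDM**: 26-neighborhood means restricted to in-mask voxels;
  voxels with no in-mask neighbor are excluded from the count. Features:
  busyness, coarseness (capped at 10⁶ for flat regions), complexity,
  contrast, strength.

Every GLCM/NGTDM/intensity feature is verified against an independent
plain-loop brute-force implementation to 1e-10 relative error on dozens
of random ROIs.

## Paired inference

Differences are db − wb per case. The Wilcoxon signed-rank test drops
zero differences and ranks |d| with midranks; the two-sided p-value is
**exact** whenever feasible — tie-free n ≤ 20 via the rank-generating
polynomial, tied n ≤ 14 by enumerating all 2ⁿ sign patterns — and
otherwise uses the normal approximation with tie-variance and
continuity corrections. The location estimate is the Hodges–Lehmann
median of Walsh averages; its CI takes the C+1-th smallest/largest
Walsh averages with C from the exact signed-rank null, giving
conservative coverage ≥ the nominal level (n ≤ 5 cannot support a 95%
interval; the widest attainable interval is returned, flagged). No
multiplicity adjustment by default (matching the source analysis); a
Holm flag is available. Quartiles are linear-interpolated order
statistics; the stratified summary splits at d_MRI = 2.5 cm and reports
fold changes as ratios of stratum medians.

## Problem sizes and numerical choices

The validation suite uses 20-case simulated cohorts (one with default
noise, one noise-free), 50 random 5–6³ ROIs for texture-oracle
equivalence, 2000 simulated null cohorts of n = 10 for type-I-error
calibration, and a radius-15-voxel digitized ball for morphology
accuracy — sizes chosen so the whole suite runs comfortably on a single
CPU. Tolerances: exact identities (TLG, SUL scaling, GLCM normalization)
at 1e-12; oracle equivalence at 1e-10 relative; mesh volume of the
digitized ball within 2% of analytic. Resampling clamps to the nearest
edge voxel in the half-voxel boundary band where an output center
precedes the first input center; mesh quantities carry a small
(≲1e-6 relative) translation dependence from floating-point rounding of
vertex coordinates, and a mesher-order dependence on pathological
scattered masks that is negligible for connected tumor masks.

## Limitations

Single spherical lesion per phantom (no agglomerates), no response
(multi-timepoint) workflow, no DICOM ingestion (NIfTI only), no
harmonization across scanners, and the feature set is fixed to the 20
features above rather than a full IBSI catalog.
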