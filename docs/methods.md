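# Methods

## The phantom model

Real FT-IR tissue images are unavailable to a test suite, so the package
generates synthetic specimens whose statistical structure matches what the
analysis assumes, and every accuracy claim in the tests refers to these
phantoms, not to measured tissue.

**Spectra.** Each of the seven tissue classes is a sum of 14 Gaussian bands
on a shared skeleton of centers and widths — Amide A+B (3290 cm⁻¹), CH₃/CH₂
stretches, an ester carbonyl (1742 cm⁻¹), Amide I (1655 cm⁻¹, amplitude ≈ 1,
the largest band), Amide II (1548 cm⁻¹), CH bending, COO⁻, collagen markers
at 1337 and 1204 cm⁻¹, Amide III (1240 cm⁻¹), carbohydrate bands at 1160 and
1030 cm⁻¹ and the nucleic-acid phosphate band at 1080 cm⁻¹ — plus a low-order
polynomial drift. Classes differ only in band amplitudes: fiber is rich in
the collagen bands, cancer in the 1080 cm⁻¹ phosphate band with depleted
carbohydrate, PanIN in mucin-like carbohydrate bands, blood is almost pure
protein, necrosis lipid-rich with lowered protein. Sharing the skeleton
makes between-class contrast a single dial: `scale_separability(models, s)`
interpolates all amplitudes toward the benign reference, with s = 0 exactly
chance-level downstream.

Amplitude contrasts were set large relative to the per-mouse batch spread
(below) so that the default cohort is separable under leave-one-mouse-out
validation — the regime the pipeline is designed for; shrink `separability`
or raise the noise to study the degraded regimes.

**Geometry and axis.** Default frames are 64×64 pixels (a typical focal
plane array tile) with a wavenumber axis 900–3850 cm⁻¹ at 4 cm⁻¹ spacing
(the effective point spacing of an 8 cm⁻¹-resolution interferogram with one
level of zero filling), i.e. 738 bands. Class regions are contiguous blobs
grown by seeded dilation to exactly the requested area fractions, so the
majority filter and edge exclusion see spatially coherent labels as in
histology; the remainder of the frame is background at a flat 0.02
absorbance.

**Degradations.** Per pixel the clean class spectrum is multiplied by a
smooth thickness field (default range 0.6–1.4 — section thickness varies by
roughly a factor of two across a real section); then spatially correlated
noise (σ = 0.004 absorbance, Gaussian correlation length 3 px — detector
and interferometer structure that MNF can isolate) and white noise
(σ = 0.008) are added. Each mouse carries a multiplicative log-normal batch
effect (σ = 0.05) on every band amplitude, shared across its classes; this
is what makes leave-one-mouse-out strictly harder than pixel-level splits.
The noise-free, thickness- and batch-scaled cube is retained as
`clean_cube` so denoising can be scored against ground truth.

**Cohort.** 19 mice by default — 5 control (no lesions), 7 KC (PanIN but
no cancer), 7 KPC (PanIN and cancer) — with per-genotype class-fraction
tables (e.g. controls are 50% benign with some fiber, inflammation and
blood; KPC adds 13% cancer, 8% PanIN and 4% necrosis). A mouse is
"pathological" iff its mask contains any cancer or PanIN pixel. Per-mouse
seeds derive deterministically from the cohort seed, so cohorts are
byte-reproducible.

**What the phantom does not model:** Mie and resonant-Mie scattering,
transflection standing-wave artifacts, spectrally correlated (pink) noise,
within-class biochemical gradients, lesion-grade substructure (low/high
PanIN), and annotation error. Passing tests therefore demonstrate that the
pipeline's machinery is correct and self-consistent, not that real tissue
reaches these accuracies.

## Preprocessing choices

**MNF.** Noise covariance uses the shift-difference estimator (covariance
of horizontal+vertical neighbor-difference spectra, halved) computed per
cube; the generalized eigenproblem is solved after adding a ridge
`1e-10·tr(Σ_noise)/B + 1e-12·tr(Σ_data)/B` to the noise covariance, which
keeps near-noiseless phantoms well-posed while preserving linearity of the
transform in the data (`denoise(a·X) = a·denoise(X)`). Spectra are
mean-centered before projection. Only masked (tissue) pixels are
transformed; background passes through. k = 20 retained components is the
default.

**Regions.** The default table has 42 rows: the named biochemical regions —
Amide A+B 3600–3000, Amide I 1762–1585 (the normalization region), Amide II
1585–1473, collagen 1346–1325, 1180–1140, carbohydrate/nucleic-acid
1180–980, and the C–H stretch window split at 2900 — plus a uniform 34-tile
partition of the 1473–900 fingerprint region (~17 cm⁻¹ tiles, ≥ 4 grid
points each at default spacing). Regions are closed intervals on the
ascending axis and may overlap. The table is a package surrogate, fully
replaceable by a TSV (`name, lo_cm1, hi_cm1, is_amide1`) with exactly one
Amide I row.

**Rubber-band baseline.** The lower convex hull is built by Andrew's
monotone chain (collinear vertices dropped) and linearly interpolated; the
corrected segment is clipped at zero. Metrics are computed on corrected
values — the maximum is corrected peak height, not raw absorbance. A
degenerate segment with zero corrected mass (flat or exactly linear) would
make the center of gravity 0/0; it returns the region midpoint instead,
keeping all features finite (logged at debug level).

**Normalization.** All three metrics, including the center of gravity, are
divided by their Amide I counterparts. Normalizing a band *position* by
another band's position is unusual — the cog ratio is dimensionless and
compresses its dynamic range — but it is applied uniformly so that every
feature is strictly invariant under per-pixel spectral scaling; the
division is trivially switchable at the one site where it happens.

**Edge pixels.** The tissue mask is eroded with the full 3×3 structuring
element (8-connectivity); border pixels are excluded from training and
validation but still appear in prediction maps.

## Classifiers

scikit-learn `RandomForestClassifier` with the pinned tree counts —
detailed 50, rapid 25, importance 100 — and library defaults for all other
hyperparameters (recorded via the pinned library version; guessing
undocumented settings would be less reproducible than naming the
implementation). Training folds are balanced by seeded per-class
downsampling to the smallest class. The rapid model maps cancer and PanIN
to a single pathology class and excludes blood, inflammation and necrosis
from training; at prediction time such pixels must land in one of the three
rapid classes, which is why even healthy specimens carry a nonzero floor of
false pathology pixels (their inflammation). The metric-count sweep refits
the rapid model on the top-k ranked metrics for each k with leave-one-mouse-
out accuracy, and chooses the smallest k within 0.5 accuracy points of the
curve's maximum — a concrete form of "best performance at low feature
count". Ties in importance rank keep feature-column order (stable sort).

## Evaluation

Pixel confusion matrices pool test pixels across all folds (per-fold
matrices are also emitted). The majority filter takes the modal label over
the window restricted to tissue; ties keep the center label; background
neither votes nor changes. The tissue ROC sweeps "pathological iff count >
t" over the distinct counts; the trapezoid AUC over that path equals the
Mann–Whitney U/(n₁n₂) with ties counted ½ (verified exhaustively in the
tests). The AUC standard error is Hanley–McNeil with Q₁ = A/(2−A),
Q₂ = 2A²/(1+A), isolated in `auc_se` so another estimator can be swapped
in. The operating threshold is the maximum healthy-group count — the
smallest threshold with zero training false positives.

## Problem sizes

The shipped defaults (64×64×738 cubes, 19 mice, full LOMO with per-fold
importance ranking) run in ~4–5 minutes on one CPU; unit tests use 32×32
frames and, where no spectral-region arithmetic is involved, a coarser
8 cm⁻¹ axis. These sizes are the package's chosen test conditions; all of
them scale up through `PhantomParams`.

## Known limitations

- ENVI support is read-only and limited to uncompressed BSQ/BIL/BIP pairs
  with a `wavelength` field; HDF5 is the canonical container.
- The 42 default regions and the per-class band amplitudes are plausible
  surrogates, not fits to measured mean spectra.
- The rapid model's pathology count conflates cancer and PanIN with
  whatever excluded-class pixels fall nearest in feature space;
  inflammation-heavy healthy tissue raises the screening floor.
- `tissue_roc` requires both outcomes present; single-outcome cohorts are
  rejected rather than given a degenerate AUC.
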