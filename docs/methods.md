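# Methods

`cesmcad` implements a segmentation-free computer-aided diagnosis (CADx)
pipeline for contrast-enhanced spectral mammography (CESM).  A CESM exam
yields a low-energy image (LE, comparable to a digital mammogram) and a
recombined image (RC) that highlights iodine uptake.  The pipeline takes a
rectangular region of interest (ROI) cut identically from both images,
summarizes it with 464 radiomic features, ranks the features by how often
repeated wrapper selection keeps them, and evaluates a Random-Forest
classifier under repeated cross-validation.  This note records the model
choices, conventions and scaled problem sizes, and what the synthetic
phantoms do and do not establish.

## Feature extraction (464 features per LE/RC pair)

All extractors are size-agnostic; ROIs are used at native resolution.

**STAT (22).** Eleven first-order statistics per source image: mean,
standard deviation, their ratio, variance, skewness, histogram entropy,
relative smoothness, kurtosis, minimum, maximum and range.  Conventions:
population moments (ddof = 0); kurtosis non-excess (Gaussian → 3);
skewness/kurtosis and the mean/std ratio defined as 0 for constant input;
entropy in bits from a 256-bin histogram over the data range; relative
smoothness is the Gonzalez–Woods descriptor R = 1 − 1/(1 + σ²) with σ²
computed on intensities min–max rescaled to [0, 1], so R ∈ [0, 1).

**COUNT (10).** The number of detections of five classical detectors per
image, run on the ROI min–max rescaled to 8 bits: SIFT scale-space extrema,
Shi–Tomasi minimum-eigenvalue corners and FAST segment-test corners
(scikit-image); a BRISK-style detection stage (FAST corners over a coarse
scale pyramid with per-scale non-maximum suppression); and MSER, computed
on the component tree of both polarities by locating local minima of the
area-variation ratio q(t) = (|R(t+Δ)| − |R(t−Δ)|)/|R(t)| with Δ = 5 gray
levels, area in [10 px, 25 % of the ROI] and q < 0.25.  Only counts are
used; descriptors are never computed.  A ROI too flat or too small for a
detector scores 0 (logged) rather than raising.

**GRAD (24).** Six statistics (mean, variance, skewness, entropy, relative
smoothness, kurtosis — same conventions as STAT) of the Sobel gradient
magnitude and direction per image.  Unnormalized 3×3 Sobel kernels with
reflect padding; direction is atan2(fy, fx) in radians, set to 0 where the
magnitude is 0 (a plain arctangent of fy/fx is undefined at fx = 0).

**HAAR (96).** The same six statistics on each of the eight sub-bands of a
two-level orthonormal Haar pyramid (LL/HL/LH/HH at levels 1–2; level 2 is
computed from LL1, which is itself retained).  Orthonormal filters make the
transform energy-preserving (Parseval, tested at 1e-8); odd dimensions are
edge-padded to even size before each level, after which the transform is
the exact non-overlapping 2×2 block transform.  Sub-band names are
(row-filter, column-filter): LH responds to vertical edges.

**GLCM (312).** Thirteen co-occurrence statistics (contrast, correlation,
cluster prominence, cluster shade, dissimilarity, energy, entropy,
homogeneity, sum average, sum variance, sum entropy, difference entropy,
normalized inverse difference moment; formulas documented in
`features/glcm.py`) on each level-1 Haar detail band (HL1, LH1, HH1) of
each image, in four directions (0°, 45°, 90°, 135°, standard compass with
45° up-right) at displacement D = 1.  Each band is min–max rescaled to
8 bits and then linearly quantized to 8 gray levels; min–max rather than
fixed-range quantization because Haar detail coefficients are signed.
Matrices are symmetric and normalized; logs are base 2 with 0·log 0 = 0;
correlation is 0 when a marginal variance vanishes.

Canonical feature names are `SET:Statistic[_Subband][_direction]_SRC`
(e.g. `GLCM:ClusterProminence_HL1_90_RC`), so selection reports can be
read set-by-set.

## Feature selection

1. **Wilcoxon–Mann–Whitney pre-screen** per feature, two-sided, at
   α = 0.05 without multiple-testing correction (the screen only removes
   uninformative columns; the wrapper does the real selection).  Exact
   enumeration when both groups have ≤ 10 tie-free samples, otherwise the
   normal approximation with tie correction.  Constant features get p = 1.
2. **Sequential backward selection** wrapped around Gaussian Naive Bayes
   with stratified 10-fold CV accuracy as the criterion.  Starting from the
   full screened set, the removal that most increases the criterion is
   applied; removal continues while the criterion does not get *worse*
   (ties included) and stops when every remaining removal strictly lowers
   it.  On a discrete accuracy criterion plateaus are the norm; pruning
   through them is what produces small per-round subsets — under a
   strict-improvement rule the first sweep stalls and every round returns
   the full set, which would make the occurrence frequencies meaningless.
   Because Gaussian-NB log-posteriors are sums of per-feature
   log-likelihood contributions, each candidate removal is scored exactly
   by subtracting one precomputed term; variance smoothing (1e-9 times the
   largest training variance) is computed once over the candidate pool so
   the criterion is stable under removal.  Ties between equally good
   removals fall to the lowest column index.
3. **Frequency ranking** over R rounds of SBS with re-randomized folds
   (fold re-randomization is the only thing that differs between rounds);
   features are ranked by the percentage of rounds in which they survive,
   alphabetical tie-break.
4. **Null-model significance**: the observed frequency of each feature is
   compared with frequencies obtained by rerunning the whole protocol on
   label-permuted data; p is the fraction of null frequencies ≥ observed.
   The protocol leaves the null unspecified in principle; label permutation
   is the natural exchangeable choice.

## Classifier evaluation

Random Forest with 100 trees; the number of split candidates is
min(20, p) — a forest on 4 features cannot draw 20 candidates per split.
Scores are the fraction of trees voting for the positive class.  Per CV
round: a stratified 10-fold split (stratified because 24-per-class samples
make unstratified folds degenerate), out-of-fold scores pooled, ROC AUC by
the rank formulation (ties get half credit), operating threshold by
Youden's J = sensitivity + specificity − 1 over the midpoints of
consecutive distinct scores (ties broken toward higher sensitivity — the
clinical context penalizes false negatives), and
sensitivity/specificity/accuracy/MCC from the thresholded confusion
matrix.  MCC uses the standard convention of 0 when a denominator factor
vanishes; its range is [−1, 1].  Metrics are summarized as median and IQR
over rounds.  Per-BPE subgroup metrics reuse the same pooled thresholded
predictions (one model, one threshold across classes).  Class imbalance is
handled by seeded random under-sampling of the majority class, fixed once
per experiment.

Feature screening can run *inside* each training partition
(`selection={"mode": "inside", ...}`) for leakage-free evaluation, or the
caller may evaluate a pre-selected column set (the classical protocol, in
which the ranking is computed once on the full balanced set — optimistic
by construction, used for the accuracy-vs-n-features curve).

## Synthetic phantoms

The generator emulates the data regime, not the physics: no X-ray or
contrast-kinetics simulation, no DICOM metadata realism.

* LE background: smoothed Gaussian random field (σ = 4 px, amplitude 20)
  around a baseline of 120, plus N(0, 6²) noise.
* RC background: baseline 15 plus patchy enhancement — a positive-clipped
  smoothed field (σ = 6 px) normalized so the pre-noise RC mean hits the
  documented target of the BPE class: 30 (I, minimal), 55 (II, mild),
  90 (III–IV, moderate/marked) intensity units.  Patch variance grows with
  the class amplitude.  BPE is modeled only on RC; enhancement is a
  contrast phenomenon.
* Lesions: star-convex blobs — a random ellipse (radius 16–22 % of the ROI
  side, aspect 0.7–1) whose boundary radius is perturbed by a low-order
  Fourier series scaled by the margin-irregularity parameter, filled with
  1 + heterogeneity × smooth noise.  Added to RC at the lesion contrast
  (default 60) and to LE attenuated by the masking factor (default 0.7):
  on LE the lesion hides in dense parenchyma, on RC it enhances.
* Class contrast: benign uses margin irregularity 0.08 and texture
  heterogeneity 0.10; malignant 0.35 and 0.40.  The contrast amplitude is
  class-independent, so the separable signal is morphology and texture,
  the axes the radiomic features target.  One consequence worth noting:
  under per-band min–max quantization, the malignant class *lowers* the
  quantized HH1 co-occurrence contrast (heavy-tailed lesion-edge
  coefficients set the range and compress the noise bulk into fewer bins);
  the class signal is strong but its sign is a quantization artifact, as
  it would be on real data.

What passing phantom tests show: the protocol separates classes that
differ in margin/texture statistics, stays at chance under the null, and
responds monotonically to the effect-size dial.  What they do not show:
performance on real CESM images, whose texture families, acquisition
artifacts and biological variability the phantoms do not model.

## Problem sizes and numerical choices

The published protocol uses 100 selection rounds and 100×10-fold CV; the
package defaults and the acceptance script run 20 rounds of each on the
48-pair phantom design — the package's chosen experiment size, which keeps
the medians stable while making the full pipeline cheap to rerun.  The
effect-size monotonicity check runs at 40-px ROIs, 10 pairs per class,
contrast levels (0, 20, 35, 50, 65), 8 paired seeds, 6×5-fold CV with 50
trees.  Tolerances: GLCM/Haar oracle equivalence at 1e-10/1e-10,
Parseval at 1e-8, SBS plateau tolerance 1e-12.  All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; two runs with
the same config and seed are bit-identical.

## Known limitations

* The COUNT detectors are count-compatible but not parameter-identical to
  any specific historical implementation; thresholds are documented in
  `KeypointConfig` and exposed in the configuration.
* The MSER implementation evaluates stability on the component tree per
  polarity without the diversity pruning of full MSER; nested regions a
  few levels apart can each count once.
* Gaussian NB variance smoothing is anchored to the candidate pool of a
  round, not to each candidate subset, so the wrapper criterion is
  subset-consistent but differs (at the 1e-9 level) from refitting a
  fresh classifier per subset.
* The accuracy-vs-n curve inherits the optimistic bias of ranking features
  on the same balanced set it evaluates on; the leakage-free mode exists
  and is tested, but the curve deliberately mirrors the classical
  protocol.
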