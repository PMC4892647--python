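# Methods

## Study design and measurement model

The package analyses a repeated-sampling design: n patients (default 27),
k tumour samples per patient (default 3, taken from distinct luminal
localisations of the same tumour), a panel of five target miRNAs (miR-21,
miR-31, miR-125b, miR-145, miR-630) and three reference miRNAs
(miR-193a-5p, miR-27a, let-7g), each qPCR reaction run in triplicate. Four
of the targets (all but miR-31, which is not detectable by ISH) are also
quantified on adjacent sections by chromogenic ISH.

The reliability model is one-way random effects on the analysis scale:

    y_ij = mu + b_i + e_ij,  b_i ~ N(0, sigma_b^2), e_ij ~ N(0, sigma_w^2)

with ICC_single = sigma_b^2 / (sigma_b^2 + sigma_w^2) and the
Spearman-Brown step-up ICC_mean = k*ICC / (1 + (k-1)*ICC) for the mean of
k samples. The analysis scale is the linear 2^-dCq value for qPCR and the
area fraction for ISH; the ICC is therefore a statement about the scale on
which the expression estimates are actually used.

## RT-qPCR quantification

- **Triplicate aggregation.** Replicates are averaged after an outlier
  screen: with >= 2 detected replicates, the single replicate whose absolute
  deviation from the triplicate median exceeds the threshold (default 0.5
  cycles) is dropped; at most one replicate per triplicate. Ties in
  deviation are broken toward the higher Cq so the rule is
  permutation-invariant. The threshold is a declared convention — a
  conservative, deterministic screen typical for qPCR triplicates — and is
  exposed in configuration.
- **Undetected handling.** A replicate that never crosses the fluorescence
  threshold is a blank cell; an all-blank triplicate is an undetected
  sample. Undetected targets are *excluded* from downstream analysis for
  that miRNA (the design becomes unbalanced) rather than imputed at a
  ceiling Cq, and every exclusion is logged with a reason code.
- **Normalisation order.** Replicates are aggregated first, then dCq is
  formed from mean Cqs (dCq of means, not mean of dCqs), then linearised
  with base 2 (amplification efficiency fixed at 100%, not configurable).
  A sample missing any reference triplicate is flagged non-normalisable
  and excluded, reported, for all its targets.

## ISH quantification

- **Classifier.** A deterministic nearest-centroid classifier replaces the
  interactive trained pixel classifier such studies typically use. Pixels
  are embedded as (s·cos 2πh, s·sin 2πh, v) — circular hue weighted by
  saturation plus value — so grey/white pixels are matched on brightness
  alone; class centroids are RGB triplets in configuration, with optional
  per-class distance scales and a helper that fits centroids from labelled
  pixel samples. Every ROI pixel gets exactly one of six labels
  (iB, wB, pB, nuclear red, unstained, tissue-free).
- **Areas and fractions.** Areas are pixel counts times
  (pixel_size/1000)^2 mm²; the default pixel size of 0.22 µm is typical
  x20 scanner resolution and only affects the mm² ROI filter, never the
  fractions. TBp = iB+wB+pB over ROI; wpB = TBp − iB-fraction, used for
  the miRNA whose intense-blue class marks cancer-independent structures
  (enteric neurons; miR-125b in the default panel).
- **ROI filter.** Records with ROI area strictly below 2 mm² are flagged
  `small_roi` (a record at exactly 2.0 mm² is retained) and a per-miRNA
  patient-exclusion report is emitted; a patient leaves a miRNA's
  reliability analysis entirely when any of their samples is excluded.
- **Artefacts / tabular bypass.** An optional artefact mask is subtracted
  from the ROI before classification. When only a pre-quantified area
  table is available, records are built from it directly.

## Reliability estimation

One-way ANOVA mean squares with the unbalanced effective group size
k0 = (N − Σk_i²/N)/(n_groups − 1); variance components
var_within = MSW, var_between = max(0, (MSB − MSW)/k0). ICC_single uses k0
in its denominator; ICC_mean = (MSB − MSW)/MSB. For balanced designs the
two are linked exactly by Spearman-Brown, a property tested to 1e-12
(relative near the estimator's pole at −1/(k−1), where ICC_mean diverges
and absolute error is meaningless). Constant data yields NaN ("undefined")
rather than a number. Negative estimates are reported as computed and
flagged, not truncated at zero — truncation would hide estimation noise.
Exact-F confidence intervals for ICC_single are available as an extension
(approximate for unbalanced designs). Spearman-Brown reporting keeps the
design k = 3 even when exclusions make groups smaller.

## Concordance

Spearman rank correlation (average ranks for ties; delegated to
scipy.stats.spearmanr, with an independent average-rank oracle in the
tests) on complete (qPCR, ISH) pairs per patient; pairs use TBp on the ISH
side for all miRNAs because qPCR measures total expression regardless of
cellular localisation. Aggregations: patient mean over available samples,
and the deepest-invasion section (pairing within sample_id). No p-values
are attached. The common plotting scale standardises each miRNA×modality
series across all samples of all patients with the sample SD (n−1) — the
population that makes a shared axis meaningful; zero-spread input is an
error, not a silent zero.

## Synthetic data generator

The generator emulates the study conditions, not arbitrary data:

- **qPCR.** Variance components are specified on the Cq scale, where qPCR
  noise is approximately Gaussian. Per-miRNA mean Cq and total SD are
  anchored to observed raw-Cq ranges (mean ± 2 SD; e.g. the miR-21-like
  channel spans 17.4–21.6 cycles), with the between/within split set to
  the per-miRNA reliabilities in the 0.13–0.78 range the design is built
  around. Reference channels get small components (sigma_b 0.30, sigma_w
  0.15 cycles) befitting reference genes selected for stability;
  triplicate technical noise defaults to 0.15 cycles; replicates above
  the detection ceiling (37 cycles) are blanked, so the highest-Cq channel
  occasionally yields undetected samples, as in real data. Values are not
  truncated to the anchor band: Gaussian tails may graze its edges, and the
  tests assert coverage, not strict containment.
- **Linear-scale truth.** Because the chain is Gaussian on the Cq scale,
  the observable triplicate-mean linear value is exactly lognormal, and
  the population ICC on the linear analysis scale has the closed form
  implemented in `true_linear_icc` (within-variance sigma_w² + tech²/3).
  This linear-scale ICC — lower than the Cq-scale ICC because the
  exponential transform inflates within-group spread — is the recovery
  target reported in every truth record, and is cross-checked against a
  large-sample Monte-Carlo estimate in the tests. Parameter-recovery
  studies use a vectorized replicate engine (`simulate_icc_recovery`)
  implementing the same model equations, which makes 4 scenarios × 500
  replicate studies run in seconds.
- **ISH.** The per-patient ISH latent mixes the standardized qPCR patient
  effect (sign-flipped: low Cq = high expression) with an independent
  normal via the latent-sharing weight w in [0, 1], so cross-modality
  concordance is tunable ground truth: w = 1 with no noise gives rho = 1,
  w = 0 gives rho ≈ 0. Log area fractions get patient scale 0.65 and
  within-patient SD 0.72 (a patient variance share of ≈ 0.45, mid-range of
  the ISH reliabilities the design targets) and are clipped to each
  miRNA's observed plausibility band; the iB-split miRNA receives a
  separate uniform intense-blue compartment on top of its banded wpB
  fraction. ROI areas are lognormal (median 5 mm², log-SD 0.55), putting
  ≈ 5 % of samples under the 2 mm² filter — a realistic exclusion rate of
  three to five patients per miRNA.
- **Images.** Synthetic ISH images are hard-edged ellipses at the class
  centroid colours, placed without overlap on a nuclear-red background
  until each class's pixel share is within 0.5 percentage points of
  target (the per-class tolerance is split so the summed TBp also lands
  within tolerance); realized fractions come from exact pixel
  bookkeeping, so fraction recovery can be asserted tightly. Hard edges
  are a deliberate simplification — no anti-aliasing, texture, scanner
  noise or batch effects — sufficient to exercise classification and
  area accounting. `gen_paired_study` emits tabular ISH records by
  default and renders per-record images on request (`render_images=True`),
  since hundreds of images per study add runtime without adding coverage
  beyond the dedicated image tests.
- **Determinism.** All randomness flows from one seed through a single
  `numpy` generator; the same seed reproduces tables and images
  bit-identically.

What passing tests on synthetic data do *not* show: real tissue has
textured, anti-aliased staining, artefacts, and a commercial classifier's
colour definitions that a nearest-centroid stand-in will not reproduce
bit-identically; real Cq noise has outliers beyond the Gaussian model that
the outlier screen only partially addresses. Synthetic recovery validates
the estimators and plumbing, not scanner- or assay-specific behaviour.

## Numerical and design choices

- Problem sizes in the test suite: 1000 random matrices for the ANOVA
  oracle check, 500 replicate studies per recovery scenario, 192×192
  synthetic images — chosen so the full suite runs in well under a minute
  while keeping Monte-Carlo error far below the asserted bands.
- Reports are written with a fixed float format so reruns are
  byte-identical; exclusion logs are sorted for the same reason.
- The single-to-mean transform refuses ICC values at or below the pole
  −1/(k−1), where the mean-of-k reliability is undefined.
- Published single/mean reliability pairs verify the transform to their
  printed 3-decimal precision; one pair (single 0.632, mean 0.838) sits
  half a printed ULP off because the published single value is itself
  rounded — the transform gives 0.8375, consistent with any unrounded
  single in [0.6320, 0.6325).

## Known limitations

- No two-way ICC models (consistency/agreement), no mixed-model or
  Bayesian estimation, no amplification-efficiency estimation or standard
  curves, no whole-slide pyramidal image formats, no stain deconvolution
  or cell segmentation, no Bland-Altman or Lin's concordance.
- The deepest-section pairing assumes qPCR and ISH sections share
  sample_id (adjacent sections from the same block).
- Whether negative ICCs should be truncated for comparison with software
  defaults used elsewhere is a reporting choice; the `negative_icc` flag
  makes truncation easy downstream.
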