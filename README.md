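# mirhet

Intratumoral heterogeneity analysis of miRNA expression measured by two
modalities — RT-qPCR and chromogenic *in situ* hybridization (ISH) — on
repeated samples from the same tumours.

When a biomarker is quantified from a single biopsy, the clinical question is
whether that one sample is representative of the patient's tumour. `mirhet`
answers it for miRNA panels measured on *k* tumour samples per patient by
estimating the one-way random-effects intraclass correlation coefficient
(ICC): the share of total measurement variance attributable to differences
*between* patients rather than within a tumour. It is aimed at molecular
pathology / biostatistics groups running sampling-reliability studies on
FFPE material.

## The model

qPCR measurements enter on the relative linear scale. Triplicate Cq values
are averaged (with a median-deviation outlier rule), normalised against the
arithmetic mean Cq of three reference miRNAs (miR-193a-5p, miR-27a, let-7g),
and linearised assuming ~100 % amplification efficiency:

    ΔCq = Cq_target − mean(Cq_ref),    linear value = 2^(−ΔCq)

ISH measurements enter as area fractions: pixels inside a region of interest
(ROI) are assigned by nearest-centroid colour classification to intense blue
(iB), weak blue (wB), purple blue (pB), nuclear-red counterstain, unstained
tissue or tissue-free glass, and

    TBp = (iB + wB + pB) / ROI area,    wpB = TBp − iB/ROI area

ROIs smaller than 2 mm² are excluded. For miR-125b the wpB fraction is used
for reliability analysis (its iB class marks enteric neurons, present
regardless of cancer); cross-modality comparison always uses TBp.

Reliability is the one-way random-effects ICC estimated from ANOVA mean
squares, with the effective group size k₀ for unbalanced data:

    ICC_single = (MS_B − MS_W) / (MS_B + (k₀ − 1) MS_W)
    ICC_mean   = (MS_B − MS_W) / MS_B
             = k·ICC_single / (1 + (k−1)·ICC_single)   (balanced, Spearman–Brown)

Cross-modality agreement is the Spearman rank correlation of paired patient
values (patient means, or the section containing the deepest tumour
invasion), and a per-miRNA×modality z-normalisation puts both modalities on
one plotting scale.

A synthetic-study generator produces the whole design — triplicate Cq
tables, ISH area tables, ISH images with exact known class fractions — from
a seed, with ground-truth variance components and a tunable cross-modality
latent-sharing weight, so every pipeline stage is testable without data
downloads.

## Worked example

```bash
mirhet simulate --out-dir demo --seed 1        # S1/S2-style tables + truth.json
mirhet run --qpcr-table demo/qpcr_s1.csv --ish-table demo/ish_s2.csv --out demo/out
```

`demo/out/icc_report.csv` (27 synthetic patients × 3 samples):

```
mirna_id modality signal_type  icc_single  icc_mean  n_patients  n_excluded
miR-125b     qpcr      linear       0.527     0.769          27           0
 miR-145     qpcr      linear      -0.019    -0.058          27           0
  miR-21     qpcr      linear       0.437     0.700          27           0
  miR-31     qpcr      linear       0.746     0.898          27           0
 miR-630     qpcr      linear       0.090     0.226          27           1
miR-125b      ish         wpB       0.505     0.754          25           2
 miR-145      ish         TBp       0.293     0.554          22           6
  miR-21      ish         TBp       0.423     0.687          24           3
 miR-630      ish         TBp       0.844     0.942          22           6
```

Reading it: miR-31 by qPCR has ICC_single 0.746 — a single sample is already
fairly reliable — while miR-145's near-zero (slightly negative, reported
untruncated) ICC says within-tumour variation swamps between-patient
differences, so one biopsy is not representative. `icc_mean` is the
reliability of averaging the three samples; `n_excluded` counts undetected
triplicates (qPCR) or small-ROI samples (ISH). `demo/out/concordance.csv`
holds the per-miRNA Spearman correlations between modalities, and
`demo/out/exclusions.csv` logs every excluded record with a reason code.

The library surface mirrors the CLI: `mirhet.aggregate_triplicate`,
`mirhet.build_expression_table`, `mirhet.classify_pixels`,
`mirhet.oneway_anova`, `mirhet.icc_single` / `icc_mean` / `spearman_brown`,
`mirhet.concordance_report`, `mirhet.gen_paired_study`, and so on — see
`docs/methods.md` for the modelling details.

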