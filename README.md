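# mirindex — serum miRNA diagnostic indices for brain tumors

Circulating microRNAs are stable in serum and measurable on intensity
microarrays, which makes them attractive for minimally invasive brain-tumor
screening: diffuse glioma has no population screening test, and glioblastoma
(GBM), primary CNS lymphoma (PCNSL) and metastatic brain tumors can look alike
on imaging while needing very different treatment.  `mirindex` implements, as
a tested Python library plus a set of analysis drivers, the two classifier
constructions used in that setting, exercised end to end on synthetic serum
cohorts with planted ground truth:

1. **A two-group glioma index.**  After microarray preprocessing, a panel of
   miRNAs is combined by Fisher linear discriminant analysis into a score

   *index(x) = Σⱼ wⱼ · xⱼ + b*,  with  *w ∝ Σ̂⁻¹(μ̂₊ − μ̂₋)*,

   where *xⱼ* are log2 normalized signals, Σ̂ the pooled within-class
   covariance and μ̂± the class means.  Panels are searched by a deterministic
   beam search ranked on leave-one-out cross-validated (LOOCV) accuracy; panel
   growth stops when the AUC gain over the previous size is no longer
   significant (paired DeLong test), and the intercept is recentred so the
   Youden-optimal cutoff (max sensitivity + specificity − 1) sits exactly at
   0, with score ≥ 0 calling disease.

2. **A 3-tumor index.**  Three one-vs-rest L1-penalized logistic models
   (GBM, PCNSL, metastatic vs the rest) are fitted by coordinate descent with
   10-fold cross-validated penalty selection over 50 repeated stratified 4:1
   splits.  Two binary models with distinct positive classes compose into a
   3-class rule: (+,−) → A, (−,+) → B, (−,−) → residual class,
   (+,+) → *not determined*.  The representative model is the candidate with
   the best training-set 3-class accuracy (ties to the sparser panel).

Preprocessing follows the serum microarray conventions: *positive call*
(signal strictly above background), background subtraction, division by the
per-sample mean of three internal-control miRNAs (miR-149-3p, miR-2861,
miR-4463) rescaled to stay in intensity units, and a robustness filter keeping
miRNAs above 64 intensity units in more than half of each group's samples.
The published 3-miRNA glioma index
(2.09406 × miR-4763-3p) + (1.35369 × miR-1915-3p) + (−0.378659 × miR-3679-5p)
− 32.11268 ships as a frozen scorer (`mirindex.lda_index.published_glioma_index`).

## Layout

- `src/mirindex/` — the library: `io_formats` (TSV matrices, annotations,
  YAML model documents), `preprocess`, `lda_index`, `performance`,
  `lasso_logistic`, `three_tumor`, `simulate` (synthetic cohort generator
  with planted markers), `validation` (recovery studies), `workflow`
  (end-to-end study replica).
- `analysis/01…05_*.py` — numbered drivers: simulate cohorts, preprocess,
  train/validate the glioma index, build the 3-tumor index, run the full
  replica.  Small tables go to `results/`, bulky matrices to `scratch/`.
- `scripts/acceptance.py` — recomputes the headline quantities (below).

## Worked example

```sh
python analysis/03_glioma_index.py --seed 1
```

prints (simulated cohort: 157 glioma vs 157 + 157 control sera, split 100:57
into training and validation; three markers planted at log2 fold changes
+1.5, +1.2, −1.0):

```
278 miRNAs passed the robustness filter
per-size best panels (LOOCV accuracy / apparent AUC / P vs previous):
  1: miR-sim-0001  acc=0.883  auc=0.9584  p=None
  2: miR-sim-0001,miR-sim-0002  acc=0.963  auc=0.9905  p=0.000225
  3: miR-sim-0001,miR-sim-0002,miR-sim-0010  acc=0.970  auc=0.9910  p=0.460453
  ...
chosen panel (2 miRNAs): miR-sim-0001, miR-sim-0002
planted markers: {'diffuse_glioma': ['miR-sim-0001', 'miR-sim-0002', 'miR-sim-0003']}
validation set: sensitivity 0.95 [0.889399, 1.0], specificity 0.95 [0.906378, 0.988359], AUC 0.992 [0.985091, 0.999828]
```

Reading this: the size-1 → size-2 panel growth is a significant AUC
improvement (DeLong P ≈ 0.0002) but size 3 adds nothing (P ≈ 0.46), so the
procedure keeps the 2-miRNA panel — both are planted markers — and the
Youden-recentred index then classifies the held-out validation sera with 0.95
sensitivity and 0.95 specificity (Wald 95% CIs in brackets).  The weakest
planted marker (−1.0 log2 fold change) is not needed at these effect sizes.
`analysis/04_three_tumor_index.py` does the analogous 3-class run (68/34/23
training vs 17/8/5 validation), printing per-contrast held-out AUCs, the
mean accuracy of each model pairing, and Table-style cross tabulations.

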