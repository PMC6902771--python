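# Methods

## Measurement model and preprocessing

Serum miRNA microarrays report a non-negative intensity per probe together
with a background estimate.  The pipeline order is fixed: **positive call**
(a probe is detected iff its signal strictly exceeds its background estimate;
ties are not detected), **background subtraction** on detected cells
(non-detected cells are zeroed and carry no information downstream),
**internal-control normalization**, then the **robustness filter**.

Normalization divides each sample *j* by the arithmetic mean *mⱼ* of the
background-subtracted signals of the internal-control miRNAs (defaults
miR-149-3p, miR-2861, miR-4463 — controls chosen for stable detection in
serum; configurable) and multiplies by the cohort constant *M = meanⱼ(mⱼ)*.
The arithmetic (not geometric) mean is used, matching the convention of
dividing by "the mean signals" of the controls.  Rescaling by *M* keeps the
result in intensity units, which the downstream "greater than 64 intensity
units" filter presupposes; pure ratios would not preserve that scale.  A
control that is undetected or non-positive in any sample is a hard error
naming the sample and control.  The robustness filter keeps a miRNA iff, in
*every* group, strictly more than 50% of samples exceed 64 units (both
comparisons strict; the group fraction exactly at the cutoff drops the miRNA).

Discriminant models operate on log2 of the normalized intensity with a floor
of 1 intensity unit (log2_signal = log2(max(norm, 1))).  The modeling scale is
a design choice: coefficients of magnitude ≈ 1–2 with an intercept near −32
are only plausible when features live on a log2 scale of signals in the
2⁸–2¹⁴ range, so linear-intensity modeling was rejected.

## Two-group index construction

`fit_fisher_lda` computes w = Σ̂⁻¹(μ̂₊ − μ̂₋) with Σ̂ the unweighted pooled
within-class covariance (no class priors) and sets the intercept so the score
is zero at the midpoint of the projected class means.  A singular Σ̂ receives
a ridge of 1e-6 · trace(Σ̂)/p on the diagonal (LOOCV refits on small classes
would otherwise fail sporadically); well-conditioned fits are untouched.

Panel search is a deterministic beam search (default width 50; width ∞
recovers exhaustive search and is used as a test oracle).  Each subset is
scored by LOOCV accuracy with ties broken by higher apparent (training-fit)
AUC, then lexicographically by miRNA id, so the search has no internal
randomness.  The LOOCV refits inside the search are computed exactly by
rank-one Sherman–Morrison downdates of the pooled scatter matrix (numba
kernel); the tests pin this kernel to an explicit leave-one-out refit loop.
Panel growth stops at the last significant improvement: the chosen size k* is
the smallest k whose successor's paired DeLong P value (computed on the
training-fit scores of consecutive winners) is ≥ 0.05.  Finally the intercept
is shifted so the Youden-optimal threshold — scanned over midpoints of
adjacent distinct scores plus sentinels beyond the extremes, ties to the
smallest threshold — becomes exactly 0.  Score ≥ 0 calls disease: the index
is a screening tool, so exact ties go to the sensitive side.

Known behavior worth remembering: the LOOCV accuracy of a *selected* winner
is optimistically biased, and the bias grows with the candidate-pool size
(measured on null data at n = 60: mean winner accuracy ≈ 0.56 with 2
candidates, 0.60 with 5, 0.64 with 20).  Unselected LOOCV accuracy on null
data is itself slightly pessimistic (≈ 0.49 at n = 50) because removing a
sample shifts its own class mean away from it.  Validation-set performance is
the honest quantity; the replica reports it separately.

## Diagnostic performance

Sensitivity, specificity and accuracy carry Wald 95% intervals
p ± 1.96·√(p(1−p)/m) clipped to [0,1] (Wilson available behind a flag).  Wald
was chosen because recomputing from printed (proportion, denominator) pairs
reproduces the published intervals (e.g. 0.96 at n = 100 → 0.92–1.00).  AUC
is the Mann–Whitney statistic (ties count ½) with a DeLong-variance interval;
DeLong rather than bootstrap keeps evaluation deterministic.  AUC differences
between nested panels on the same samples use the paired DeLong test; a
zero-variance difference returns P = 1 with a warning.

## L1-logistic building block

The penalized logistic fit minimizes (1/n)·Σ deviance + λ‖β‖₁ with an
unpenalized intercept, by outer IRLS (weights floored at 1e-5) and inner
cyclic coordinate descent on standardized features (zero mean, unit population
SD; coefficients are reported back on the original scale).  Convergence is a
maximum coefficient change < 1e-7 on the standardized scale; full sweeps
alternate with active-set sweeps for speed.  λ_max = maxⱼ|⟨xⱼ, y − ȳ⟩|/n gives
the exactly-null model.  Solutions are verified in tests against the KKT
subgradient conditions, an unpenalized IRLS fit (statsmodels) at λ = 0, and an
independent saga L1 solver at moderate λ.

Penalty selection: stratified 10-fold CV over 50 log-spaced λ from λ_max down
to 0.01·λ_max, minimizing mean held-out binomial deviance.  The min-deviance
rule is the default (the denser fits it produces match a published
representative model using 48 miRNAs across three contrasts); λ within one
standard error of the minimum is exposed as `one_se=True`.  On pure noise the
min rule is optimistic — its *median* selected panel collapses to ≤ 1 feature,
but individual replicates can keep several; the 1-SE rule is the sparse
choice and is the one guaranteed near-empty on null data.

## 3-tumor composition

Two one-vs-rest models with distinct positive classes (A, B) compose into the
only consistent 4-outcome rule: (+,−) → A, (−,+) → B, (−,−) → residual class
C, (+,+) → not determined (a cross tabulation with a "not determined" row
requires the fourth outcome, and the residual class must be reachable).
Binary calls threshold probability at 0.5.

The cohort (85 GBM, 42 PCNSL, 28 metastatic) is first split 4:1 with ceiling
allocation per class — giving exactly 68/34/23 training and 17/8/5 validation
— and validation set 2 is then never touched until the final evaluation.
Within training set 2, 50 seeded stratified 4:1 divisions are drawn; per
division each contrast is fitted on the 4/5 part (10-fold CV penalty
selection) and its AUC recorded on the held-out 1/5.  All three pairings of
each division's binary models yield 150 combined candidates; per-pairing mean
training accuracies are reported, and the representative model maximizes
training-set-2 accuracy (not-determined counts as an error), ties going to
the smaller miRNA union, then to candidate order.  The whole procedure is a
pure function of (data, master seed, configuration).

## Synthetic cohorts

Per miRNA *i* and sample *j*: log2 signal = bᵢ + effectᵢ(groupⱼ) + sⱼ + o_c(j)
+ ε, with baseline bᵢ ~ U(4, 13) log2 units, per-sample scale sⱼ ~ N(0, 0.5)
(the multiplicative factor normalization must remove), cohort offset o_c
(defaults 0 for the −20 °C biobank arm shared by cases and the first control
cohort, +0.3 for the −80 °C clinic arm of the second control cohort), and
biological noise ε ~ N(0, 0.6).  Internal controls have zero group effect and
noise SD 0.1.  On the linear scale the recorded signal is 2^(log2) plus
truncated-Gaussian background noise (mean 32, SD 8), and the background
estimate is an independent draw from the same distribution, so dim probes are
censored by the positive call exactly as on a real chip.  Controls and
planted markers draw their baselines from the bright part of the range
(≥ 2⁸) so that controls satisfy the normalization precondition in every
sample and markers survive the 64-unit filter.

Default study conditions: 359 miRNAs; 157 glioma + 157 + 157 control sera
split 100:57 per group (training set of 100 + 200, validation of 57 + 114);
glioma markers at log2 fold changes +1.5, +1.2, −1.0 — chosen so that the
best single marker reaches AUC ≈ 0.95 and the combined panel ≈ 0.99, the
regime the two-group index was designed for; and 20 markers per one-vs-rest
contrast at |log2 FC| = 1 (alternating signs) for the 3-tumor cohort,
matching the 16–23-miRNA panels the repeated LASSO fits settle on.  With 20
independent markers per class the simulated 3-class task is easier than real
serum data (held-out AUCs saturate near 1.0, against 0.86–0.97 reported on
real cohorts); the synthetic cohorts validate the machinery — recovery of
planted truth, calibration, determinism — not clinical attainability.
miRNAs are simulated independently: real serum co-expression, probe
cross-hybridization and spatial chip artifacts are out of scope, so passing
recovery tests says nothing about marker identifiability under correlated
expression.

Randomness: one master seed per run; numpy SeedSequence children are spawned
per block (features / samples / noise / metadata), so regenerating a cohort
with the same seed is bit-identical.

## Recovery studies (`mirindex.validation`)

* Single marker: log2 FC 2.0, biological SD 0.5, 49 null miRNAs, n = 40 + 40;
  the planted marker should win the size-1 search in ≥ 95% of 100 cohorts.
* Panel: three markers at |log2 FC| 1.5 among 200 nulls, n = 100 + 200; the
  final selected panel should contain ≥ 2 of the 3 in ≥ 90% of 50 cohorts
  (at these effect sizes size selection typically stops at 2, so exactly 2
  recovered is the common outcome).
* Null: permuted-label LOOCV accuracy (n = 50, 3 features) should average
  0.5 ± 0.05 over 200 replicates.

## Numerical choices and degenerate inputs

Strict inequalities everywhere the contracts say "greater than" (positive
call, robustness filter, threshold rule score ≥ 0 → positive at the
boundary).  Constant scores: AUC falls back to 0.5 with a warning; Youden
calibration leaves the intercept unchanged with a warning.  Identical class
means give a zero discriminant direction.  Proportion CIs are clipped to
[0, 1].  Model documents are YAML with a format-version field; floats
round-trip bit-exactly (the TSV readers parse with correctly-rounded float
conversion for the same reason).  Problem sizes in the shipped analysis runs
and acceptance script are the full study dimensions (359 miRNAs, 471- and
155-sample cohorts, 50 repeated splits); the recovery studies use the
dimensions listed above.
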