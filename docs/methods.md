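# Methods

## Problem and model

Microsatellite instability (MSI) — the hallmark of mismatch-repair
deficiency (dMMR) — shows up in sequencing data as shifted indel-length
distributions at microsatellite loci. `msiscreen` scores a tumor sample
without a paired normal by learning, per locus, what the *full*
max-normalized length distribution looks like in mismatch-repair
proficient (pMMR) versus deficient (dMMR) samples, rather than reducing
the distribution to a single summary statistic such as a peak count.

Per locus the pipeline is:

1. **Read filtering.** Keep primary, non-duplicate alignments with
   MAPQ ≥ `min_mapq` (20) whose aligned span covers the tract plus
   `flank_bases` (5) on each side. Soft/hard-clipped reads that do not
   cover the full flanked interval are excluded.
2. **Length extraction.** The observed tract length of a read is
   `ref_length + insertions − deletions` restricted to the tract
   interval `[start, end)`, computed by walking the CIGAR. Indels in the
   flanks are ignored: they reflect unrelated variation, and MSI shifts
   are defined on the tract itself. An insertion at the left tract
   boundary counts as inside, at the right boundary as outside
   (half-open consistency).
3. **Distribution cleaning.** Lengths with a count of at most
   `singleton_cutoff` (1) are removed, reducing spurious complexity
   from stray reads.
4. **Normalization.** Each count is divided by the maximum count across
   lengths at that locus, so the modal length maps to exactly 1.0 and
   all values lie in [0, 1]. This makes profiles comparable across
   depths.
5. **Vectorization.** Values are embedded at fixed offsets
   −`window` … +`window` around the reference tract length
   (window = 20, vector length 41). Published MSI shifts on small
   panels are far below 20 bp, so clipping (with a warning) is rare.
   A locus is *evaluable* when the post-cleaning depth is ≥ `min_depth`
   (30). Applying the depth gate after cleaning is the stricter reading;
   it only matters within a read or two of the boundary.

## Training and locus selection

Sample-level dMMR/pMMR labels (immunohistochemistry truth in clinical
use) are inherited by every locus of the sample. The cohort is split
into train/validation/test thirds, stratified by label so small cohorts
keep both classes everywhere (plain random splitting is the obvious
alternative; stratification only constrains it).

Loci must be evaluable in ≥ `coverage_fraction` (75%) of training
samples. For each surviving locus, a logistic regression and an SVC are
fitted with hyperparameters chosen by grid search (C ∈ {0.01, 0.1, 1,
10, 100}; SVC also linear vs RBF kernel) maximizing 3-fold
cross-validated AUC. Both use balanced class weighting because dMMR is
the minority class (the published operating cohort trains on 45 pMMR vs
16 dMMR). The fold assignment is computed once per training cohort and
shared across loci and model kinds, so model comparisons are not
confounded by fold composition; at a given locus the shared folds are
restricted to the samples that pass the depth filter there. A locus is
retained only if **both** models reach validation AUC ≥ `locus_auc_min`
(0.60).

A wider model zoo (isolation forest, local outlier factor, one-class
SVM, random forest, naive Bayes) is available behind the same interface
for comparison experiments; the outlier kinds are fitted on stable
samples only. These use fixed, conventional hyperparameters rather than
per-kind grids: an AUC-scored grid search is not defined for one-class
fits without extra machinery, and the zoo never enters a model bundle —
only the logistic-regression/SVC pair does (random forest in particular
overfits small per-locus cohorts).

## Scoring and classification

A new sample is scored with the bundle's own config snapshot. Each
evaluable retained locus gets each model's native binary call (decision
function sign / probability ≥ 0.5); the **combined** call is unstable
only when both models agree. The sample score is the fraction of
evaluable loci called unstable, which guarantees
`score_combined ≤ min(score_logreg, score_svc)`.

Classification uses the combined score: in binary mode MSI iff
`score > 0.26` (strict inequality, the published single cutoff); in
dual mode a rule-out cutoff `low` and rule-in cutoff `high` (each
derived for 95% specificity on a test set via `dual_thresholds`)
bracket a gray zone where classification is deferred. A result with
fewer evaluable loci than `min_evaluable_loci` (default: half the
retained panel) is flagged low-confidence but still reported — clinical
users need the result plus the caveat, not a refusal.

## Evaluation

AUC is the tie-aware pairwise probability that an unstable sample
outranks a stable one, with a DeLong (structural components) confidence
interval — the analytic method matching common clinical ROC software;
the brute-force pairwise computation is kept as an independent oracle in
the test suite. Diagnostic metrics use strict `score > cutoff` positive
calls, exact (Clopper–Pearson) binomial intervals, and likelihood ratios
+LR = sens/(1−spec) (flagged infinite at 100% specificity) and
−LR = (1−sens)/spec.

The robustness driver repeats training at stated per-class
train/validation sizes (e.g. "20-10:10-5" = 20 pMMR + 10 dMMR train,
10 + 5 validation), drawing *without replacement* — the experiment
constructs nested subsets, not classic with-replacement bootstraps — and
evaluates each replicate on the untouched remainder.

## Synthetic data generator

The generator is the test and demo substrate standing in for clinical
cohorts. It emulates:

* **PCR/sequencing stutter**: a read reports the wrong tract length
  with probability `stutter_p` (0.05); slip magnitude is geometric with
  decay `stutter_decay` (0.5); slips are contractions with probability
  `deletion_bias` (0.8), reflecting the predominance of left-shifted
  distributions in real microsatellite data.
* **Instability with purity dilution**: at a shifted locus of a dMMR
  sample, a `purity` (0.5) fraction of reads centres on an allele
  `msi_shift` (6) bases below the reference tract length with the same
  stutter; the rest follow the stable process. dMMR samples shift a
  random `unstable_locus_fraction` (0.8) of panel loci; pMMR samples
  shift none.
* Depth is Poisson(`depth_mean` = 200) per locus; reads are single-end
  (the method consumes per-read tract lengths only). Optional BAM
  output encodes each simulated indel in the CIGAR at MAPQ 60, plus
  configurable decoy reads that each violate exactly one read filter.

What it does **not** model: substitution errors, base qualities, FFPE
artifacts, locus-specific stutter rates, mixed allele populations
beyond the two-component purity mixture, or coverage heterogeneity
along the panel. Passing tests therefore demonstrate that the pipeline
recovers a known shifted-mixture signal through the full BAM → score
path — not that clinical performance on real tumors is reproduced.
Defaults (shift 6 bp, purity 0.5, depth 200×) describe a clearly
unstable tumor at moderate purity on an adequately covered panel; the
end-to-end separation they produce is correspondingly clean.

## Problem sizes used by the test suite and acceptance script

Synthetic experiments run on a 10-locus panel (15 bp tracts) with a
133 pMMR + 46 dMMR cohort, the size of the published model set. The
end-to-end recovery check reports the median over 15 independent
seeds; the robustness comparison runs 10 simulations per design for the
smallest (20-10:10-5) and full-size (45-16:43-15) designs; determinism
is checked on a 24 + 12 cohort over 6 loci. These sizes are the
package's own choice of a desk-scale experiment that still exercises
every stage at realistic per-locus depth.

## Numerical and degenerate-input choices

* Thresholds are strict (`>`); selection boundaries (AUC 0.60, 75%
  coverage, MAPQ 20, 30× depth) are inclusive.
* Normalization of an empty (fully cleaned-away) distribution is an
  error at the operation level; pipeline callers map it to a
  non-evaluable locus instead of aborting the sample.
* `dual_thresholds` clamps `low` to `high` with a warning if the
  rule-out cutoff would exceed the rule-in cutoff; with fully separated
  classes both collapse to the same point and the gray zone is empty.
* Grid-search and fold RNGs are seeded from the single pipeline seed;
  a fixed seed reproduces byte-identical bundle manifests (manifests
  carry no timestamps).
* Reference skips (CIGAR `N`) are treated like deletions in length
  extraction; they do not occur in DNA panel data.

## Known limitations

* Tumor purity is not estimated; very low purity dilutes the shifted
  component below what per-locus classifiers can see (the same failure
  mode reported for peak-based tools).
* The per-locus decision threshold is each model's native 0.5/0-point;
  no per-locus calibration is attempted.
* Amplicon vs capture chemistry differences are not modeled; a bundle
  trained on one chemistry should be applied only to that chemistry.
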