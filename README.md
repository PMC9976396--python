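# msiscreen

Microsatellite-instability (MSI) screening on small-panel, tumor-only
NGS data, for molecular diagnostics labs that sequence solid tumors
with targeted gene panels and need a dMMR screen without paired normal
tissue or a fixed reference set.

Tumors with deficient DNA mismatch repair (dMMR) accumulate expansions
and contractions at microsatellite loci. In aligned reads this appears
as a shifted indel-length distribution at each locus. Most screening
tools reduce that distribution to a single parameter (e.g. a peak
count) before scoring; `msiscreen` instead feeds the *full*
max-normalized distribution to machine-learning models.

## Method

For each microsatellite locus in a user-supplied BED panel:

* reads are filtered (primary, non-duplicate, MAPQ ≥ 20, spanning the
  tract + 5 bp flanks) and each read's tract length is extracted from
  its CIGAR (reference length + net indel inside the tract);
* the length histogram is cleaned (singleton lengths removed) and
  divided by its maximum count, giving a profile *x* ∈ [0, 1]⁴¹ over
  length offsets −20 … +20, evaluable at ≥ 30× depth;
* a per-locus logistic regression and SVC (grid-searched, 3-fold CV,
  balanced class weights) are trained against sample-level dMMR/pMMR
  labels; loci are auto-selected by coverage (evaluable in ≥ 75% of
  training samples) and by validation AUC ≥ 0.60 **in both models**.

At prediction time each evaluable locus votes: it is *unstable* only if
both models call it unstable. The sample score is

  s = (# loci called unstable) / (# evaluable loci)

and the sample is classified MSI if s > 0.26 (single published cutoff),
or MSS / gray zone / MSI with dual 95%-specificity cutoffs. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

No clinical BAMs are required: the built-in simulator generates a
cohort with known truth (slippage stutter, tumor purity, MSI length
shifts) and can emit sorted, indexed BAMs.

```
msiscreen simulate --bed examples/demo_panel.bed \
    --n-stable 18 --n-unstable 9 --seed 7 --out cohort --bam
msiscreen train --bams cohort/bams --labels cohort/truth.tsv \
    --bed examples/demo_panel.bed --out bundle --seed 7
msiscreen predict --bam cohort/bams/S0027.bam --bundle bundle --out pred
msiscreen predict --bam cohort/bams/S0001.bam --bundle bundle --out pred
```

prints

```
27 samples written to cohort
bundle written to bundle (2 loci retained)
S0027	score=1.0000	MSI
S0001	score=0.0000	MSS
```

(the last two lines read: sample S0027, a simulated dMMR tumor, has
both demo loci called unstable by both models — sample score 1.0,
classified MSI; S0001, a simulated pMMR sample, scores 0.0 and is MSS).
`pred/` contains a one-row summary TSV and a per-locus call table per
sample; add `--plots` for per-locus images of the sample profile over
the stable-training-set envelope. `msiscreen evaluate` computes
ROC/AUC (DeLong CI), sensitivity/specificity and likelihood ratios at a
cutoff, or dual thresholds; `msiscreen robustness` re-trains on
repeated subsets of decreasing size.

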