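# Methods

`cfrefrag` profiles the fragmentation of cell-free DNA (cfDNA) over
repeat-element ("cfRE") regions of the genome and uses those profiles for two
predictions: cancer vs. healthy plasma, and — among cancers — the tissue of
origin (TOO).  This note records the models, the numerical choices, and what
the built-in synthetic cohort does and does not establish.

## Fragment qualification

A fragment is one sequenced cfDNA molecule, stored as a 0-based half-open
genomic interval with mapping quality and (optionally) its read sequence.
Qualification requires mapping quality ≥ 30, no supplementary alignment, not
a PCR duplicate, and both ends mapped.  Dropped records are attributed to the
*first* failing criterion in the fixed order mapq → supplementary → duplicate
→ unpaired, so QC tallies are deterministic and always satisfy
`kept + Σ dropped = input records`.

In BAM mode a fragment is the template span of a read pair: the leftmost
mate's start plus |TLEN|, emitted once per template.  Pairs with TLEN = 0 are
treated as not both-ends-mapped; secondary alignments are never "uniquely
mapped" and are excluded outright.  QC is applied per record, so a template
whose leftmost mate qualifies is emitted even if its mate alone would not —
an accepted simplification at the depths this tool targets.  For discordant
pairs the fragment length is the template length, not the read span.

## The cfRE catalog

Repeat annotation is read from RepeatMasker-style tables (the full UCSC rmsk
table or a 7-column dialect).  `Simple_repeat` rows whose name encodes a
motif as `(MOTIF)n` become STR loci with unit length `n1 = len(motif)` and
reference unit count `n2 = round(span / n1)`; the span is allowed to deviate
from `n1·n2` by up to one unit.  All other rows are grouped by their repeat
family (falling back to the class when the family is unnamed).

Regions become catalog members only after a five-step filter, applied in
this order with a per-step removal audit:

1. regions that cannot be classified (class/family `Unknown`, `Unspecified`
   or carrying a `?` suffix — standard rmsk semantics for uncertain calls);
2. regions on sex chromosomes or overlapping the exclusion (blacklist) BED;
3. regions with zero fragment coverage in **strictly more than** 80% of the
   discovery-cohort samples;
4. regions with zero coverage in a designated reference-plasma sample (this
   step can be disabled when no reference is available);
5. families whose genome-wide instance count falls below a minimum
   (500 for a human-genome-scale annotation; the count is taken from the
   *unfiltered* input so it measures genome-wide frequency, and the toy
   cohort uses a threshold of 10 matched to its scale).

"Coverage" always means a shared base pair under half-open interval
intersection.  The 80% rule is applied per region, as stated; the family
count denominator is the pre-filter annotation.

STR loci are additionally partitioned into sub-groups keyed by
`(unit length, span bin)`, with span bins `[0,20), [20,30), …, [190,200),
[200,∞)` bp by default — unit lengths 1–6 crossed with the span range where
STRs concentrate.  The binning is configurable; the sub-group count on a
real annotation depends on the assembly and cohort and is not a constant of
the method.

## The five fragmentomic scores

Per sample and per family (Alu and Simple_repeat/STR by default — the two
families that dominate plasma repeat signal):

* **FR (fragment ratio)** — fragments overlapping the family's regions over
  all qualified fragments.  A fragment overlapping several families counts
  once in each family's numerator, so FR is a per-family enrichment, not a
  partition.
* **FL (length ratio)** — short (<150 bp) over long (≥150 bp) fragment
  counts within the family.  150 bp itself counts as long so the dichotomy
  partitions all lengths; FL is missing when the family has no long
  fragment, and missing values are median-imputed from training data at
  modelling time (label-blind).
* **FD (distribution)** — fraction of the family's regions with non-zero
  coverage.
* **FC (complexity)** — median linguistic complexity of the read sequences
  mapped to the family (an even count averages the central pair).  The
  linguistic complexity of a length-L read is
  `LC = Σ_k U_k / Σ_k min(4^k, L−k+1)` over k = 1..L, where `U_k` counts
  distinct k-mers: the observed substring vocabulary over the maximum
  possible one.  This is the classical vocabulary-based complexity for DNA;
  it is computed with a suffix automaton (linear in L) and verified exactly
  against exhaustive substring enumeration.  k-mers containing non-ACGT
  letters are not vocabulary, but the read length still sets the
  denominator.  To bound cost, the FC median may be taken over a capped
  read subset (default cap 200 per family in the pipeline) selected by
  sorted fragment name, which keeps the score independent of input order.
* **FE (STR expansion)** — described next.

## STR expansion and the FE score

A read *witnesses* the unit count of an STR locus as the longest run of
consecutive exact copies of the locus motif — any cyclic rotation — in the
part of its sequence facing the locus padded by one unit on each side.
Counting on the sequence (rather than CIGAR insertions) behaves identically
for BED+FASTA and BAM inputs; reads overlapping a locus by less than one
full unit are skipped, and a read is *expanded* iff its observed count
strictly exceeds the reference `n2`.  Reads spanning the locus with fewer
units are tallied as contractions and reported, but the expansion score
deliberately counts expansions only.

Per sub-group g the expansion score is the pooled ratio
`score_g = Σ N_ETR / Σ N` over member loci (ratio of sums, which is stable
when individual loci are sparse), where N counts evaluated reads and N_ETR
the expanded ones.  N_ETR counts expanded *reads*: the score's denominator
is a read count, so a read count in the numerator keeps the ratio in [0,1]
(counting expanded units instead would not).  Sub-group weights are the
impurity variable importances of a 500-tree random forest averaged over the
training folds of 5-fold stratified cross-validation, floored at zero and
normalised to sum to one; the per-sample score is `FE = Σ_g W_g · score_g`.
Sub-groups with no evaluated reads contribute 0 and are flagged.  FE is
therefore in [0,1] and monotone in every sub-group score.

## Cancer classification

The model matrix holds FR/FL/FD/FC per whitelisted family plus FE.
Imputation (median) and z-scoring are fitted inside each training fold of a
stratified cross-validation, and all reported scores are strictly
out-of-fold, so AUCs are honest.  The default model is logistic regression
with a LASSO penalty whose strength is re-chosen by inner 5-fold CV within
every outer fold; an ensemble mode compares eight standard algorithms
(lasso-logistic, elastic-net, random forest, gradient boosting, SVM, kNN,
Gaussian naive Bayes, LDA) by out-of-fold AUC, breaking ties by algorithm
name for determinism.  The operating threshold maximises Youden's J
(sensitivity + specificity − 1) with ties resolved to the lowest threshold,
and the usual confusion-matrix metrics are reported (a metric with an empty
denominator is missing, not zero).  When a sample sheet provides an explicit
train/test split column the tool honours it rather than inventing one.

Sequencing-depth robustness is probed with per-fragment Bernoulli
downsampling (seed-reproducible; equivalent in expectation to read-level
resampling) and, per feature type, the Spearman correlation between the
feature vector at each retained fraction and its full-depth value, median
over replicates.  The correlation vectors span families, STR sub-group
coverage shares (FR/FD) and per-unit-length STR groups (FC/FL); family-level
vectors alone have too few dimensions for a stable rank correlation.

Differential regions between cohorts are flagged when
`|z| = |case mean − healthy mean| / healthy sd > 1` and the two-sided
Wilcoxon rank-sum p-value, Benjamini–Hochberg adjusted, falls below 0.05;
regions with zero healthy variance are skipped with a warning.  BH is used
because no particular adjustment is canonical here, and the choice is
recorded in the output.

## Tissue of origin

Candidate regulatory cfRE regions per cancer type are Alu/STR catalog
regions supported by at least two of H3K27ac / H3K4me1 / H3K4me3, where a
mark supports a region when strictly more than half of that mark's ChIP
samples carry an overlapping peak (the majority rule is applied per
(type, mark) across that mark's ChIP samples).  Type specificity uses
Fisher's exact test on one-vs-rest 2×2 tables counting *samples* with vs.
without fragment coverage (a region-level count is a noted alternative);
the cross-product odds ratio gets a Haldane 0.5 correction when a cell is
zero, p-values are BH-adjusted within each type's candidate list, and a
region is assigned to a type iff OR > 1 and adjusted p < 0.05.

TOO features re-apply the FR/FL/FD/FC (and optionally FE, with uniform
sub-group weights by default) operators restricted to each type's region
set; samples with an empty region set for some type are flagged, and a
sample with no usable region set at all is excluded with a reason.  The
multiclass model is a random forest (multinomial logistic regression is
available), evaluated by out-of-fold predictions; overall accuracy is the
confusion-table trace over its total.

## The synthetic cohort

The generator builds a toy genome (two autosomes + chrX, ~0.7 Mb total,
i.i.d. uniform A/C/G/T background so complexity contrasts are controlled)
with non-overlapping planted regions: Alu-like, L1-like, STR loci for every
unit length 1–6 (reference = motif repeated exactly n2 times, flanked by
guard bases so the reference run is exactly n2 units), low-complexity
stretches, a rare family, unclassified regions, blacklisted regions,
chrX regions and dormant (never covered) regions — the last five exist to
exercise each filter step.  Default study conditions (the shipped config):

| parameter | healthy | cancer | rationale |
|---|---|---|---|
| per-region coverage λ | 8 | ×1.6 for Alu/STR | mid-depth WGS scale; family enrichment in tumours |
| short-fragment probability | 0.20 | 0.45 | excess sub-150 bp fragments in cancer |
| length modes (bp) | 145 / 167, sd 10, truncated [50, 400] | same | bimodal cfDNA lengths straddling the 150 bp dichotomy |
| STR expansion rate / read | 0.01 | 0.08 | somatic repeat instability |
| extra units per expansion | 1 + Poisson(1) | same | small insertions dominate |
| low-complexity read replacement | 0 | 0.25 of Alu reads | degraded sequence complexity in tumour-derived reads |
| TOO regions: matched / other cancers | ×1 | ×3 / ×0.05 | tumour-type-specific regulatory accessibility |
| background fragments / sample | 400 | same | off-repeat genome coverage |

Fragment counts per region are Poisson; fragment lengths are discretised
truncated normals; STR-overlapping reads carry `n2 + k` units with the
label-dependent expansion probability, realised by inserting `k` extra motif
copies mid-locus into the read sequence (the BED interval keeps the genomic
span; the sequence sidecar carries the insertion).  ChIP peak sets are
generated per (cancer type, mark, ChIP sample) so the majority rule is
genuinely exercisable: designated regions draw a supporting-sample count
above the majority threshold for 2–3 marks, all other regions only ever a
minority.  One extra healthy sample at double depth serves as the
reference-plasma sample for filter step iv.  Identical config + seed gives
byte-identical output files (gzip members are written with a fixed
timestamp).

Effect sizes are the implementer's choice — no magnitudes are established
for real plasma — and were chosen to make a 30 + 30 cohort comfortably
separable.  Passing the recovery checks therefore shows that the pipeline
*detects what was planted*; it says nothing about effect sizes, confounders
(age, batch, extraction chemistry), GC or mappability bias, sequencing
error, or alignment artefacts in real data, none of which are modelled.
There is also no read-level error model and no BAM emission.

## Problem sizes and evaluation defaults

The shipped evaluation uses 30 healthy + 30 cancer samples (~2,000
qualified fragments each) for classification, the same cohort Bernoulli-
thinned to 0.1× for the low-depth rerun, and 45 cancer samples (15 per
type, 3 types) for TOO.  Permutation nulls use 200 label permutations with
a lightweight L1-logistic scorer for the binary task and 100 permutations
with a 100-tree forest for TOO — the null distribution of an honest CV
score does not depend on the tuning effort spent on the permuted labels.

## Known limitations

* Record-level BAM QC (see above) can admit a template whose rightmost mate
  would have failed QC alone.
* The unit counter demands exact motif matches; a sequencing error inside a
  long run splits it and undercounts, biasing FE downward at high error
  rates.
* Reads cannot witness expansions of loci longer than themselves, so FE is
  blind to long-locus expansions at short cfDNA lengths; sub-group weighting
  learns to discount such sub-groups rather than correct them.
* Fisher specificity on binarised coverage saturates at high depth (every
  sample covers every region); at the depths simulated here, and at low-pass
  depths generally, binary coverage is informative.
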