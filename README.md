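# cfrefrag

Repeat-element fragmentomics of cell-free DNA (cfDNA) for liquid-biopsy
cancer detection and tissue-of-origin prediction.

Repetitive elements — Alu, LINE-1, short tandem repeats (STRs),
low-complexity stretches — cover a large share of the genome and are
remodelled early in tumourigenesis.  `cfrefrag` intersects qualified plasma
cfDNA fragments with a RepeatMasker-style catalog and summarises each repeat
family with five fragmentation scores per sample:

* **FR** — fraction of qualified fragments mapped to the family's regions;
* **FL** — short/long fragment-count ratio within the family (short < 150 bp);
* **FD** — fraction of the family's regions with non-zero coverage;
* **FC** — median linguistic complexity of the mapped reads,
  `LC = Σ_k U_k / Σ_k min(4^k, L−k+1)` with `U_k` the distinct k-mer count;
* **FE** — weighted STR expansion score `Σ_g W_g · (Σ N_ETR / Σ N)_g` over
  STR sub-groups g (unit length × span bin), where a read is *expanded* when
  it witnesses more motif units than the reference count n₂ and the weights
  W_g are cross-validated random-forest importances.

These features feed a cross-validated cancer-vs-healthy classifier
(LASSO-logistic by default, an eight-algorithm ensemble optionally) with a
Youden-index operating threshold, and a multiclass tissue-of-origin model
built on cancer-type-specific regulatory repeat regions selected from
histone-mark ChIP consensus peaks (H3K27ac/H3K4me1/H3K4me3) and Fisher's
exact test.  A built-in synthetic-cohort generator makes the entire pipeline
runnable and testable end to end with no external data.  See
`docs/methods.md` for the full model description.

Intended users: genomics/bioinformatics researchers prototyping cfDNA
fragmentomics analyses, and method developers who need a transparent,
fully simulatable reference implementation.

## Worked example

```python
from cfrefrag import train_lasso
from cfrefrag.simulate import SimulationConfig, simulate_cohort
from cfrefrag.pipeline import extract_features

cohort = simulate_cohort(SimulationConfig(seed=1))   # 30 healthy + 30 cancer
cf = extract_features(cohort, seed=1)                # QC -> filter -> features

print(cf.catalog.audit)
result = train_lasso(cf.X, cf.y, folds=10, seed=1)
print(f"CV AUC {result.auc:.3f}  threshold {result.threshold:.3f}")
print({k: round(v, 3) for k, v in result.metrics.items()})
```

prints

```
{'i_unclassified': 6, 'ii_excluded': 10, 'iii_zero_coverage': 4,
 'iv_reference_zero': 0, 'v_rare_family': 4}
CV AUC 1.000  threshold 0.814
{'sensitivity': 1.0, 'specificity': 1.0, 'ppv': 1.0, 'npv': 1.0, 'accuracy': 1.0}
```

The audit shows what each catalog-filter step removed from the 157 planted
regions: 6 unclassifiable regions, 10 on chrX or in the blacklist, 4 never
covered, 4 from a family too rare genome-wide.  The out-of-fold AUC of 1.0
reflects the deliberately comfortable planted effect sizes of the default
synthetic cohort (documented in `docs/methods.md`); the 0.814 threshold is
the Youden-index cut on the out-of-fold scores, and at that cut all 60
samples are called correctly.

The same stages are available from the shell:

```bash
cfrefrag simulate --out cohort/ --seed 1
cfrefrag qc --in cohort/fragments/H000.bed.gz --seqs cohort/fragments/H000.fa.gz \
            --out qc.bed.gz --report qc.json
cfrefrag filter-regions --rmsk cohort/rmsk.tsv --samples cohort/samples.tsv \
            --reference-sample REF --exclude cohort/exclusion.bed \
            --min-family-instances 10 --out catalog/
cfrefrag features --catalog catalog/ --samples cohort/samples.tsv \
            --out features_nofe.tsv --scores-out str_scores.tsv
cfrefrag fe-weights --scores str_scores.tsv --samples cohort/samples.tsv \
            --seed 1 --out weights.json
cfrefrag features --catalog catalog/ --samples cohort/samples.tsv \
            --weights weights.json --out features.tsv
cfrefrag train --features features.tsv --samples cohort/samples.tsv \
            --seed 1 --out model/
cfrefrag predict --model model/ --features features.tsv --out preds.tsv
cfrefrag too-regions --catalog catalog/ --peaks cohort/peaks_manifest.tsv \
            --samples cohort/samples.tsv --out too/
```

All stages are seed-reproducible down to the byte.

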