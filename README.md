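# aphidx

Dosage-compensation and open-chromatin (FAIRE) analysis for X0/XX systems,
built around the pea-aphid situation: males carry a single X (X0), females
two (XX), and the X is *masculinized* — male-biased genes outnumber
female-biased ones roughly 3:1 and are largely male-specific. The package
asks two linked questions on such data:

1. **Is the single male X transcriptionally compensated?** Measured by the
   X/A ratio — median expression of X-linked genes over median expression of
   autosomal genes per morph — under rising expression-threshold filters,
   with a two-sided Wilcoxon rank-sum test comparing the two gene sets. A
   morph is called compensated at a threshold when 0.95 ≤ X/A ≤ 1.05 and
   p > 0.05.
2. **Is compensation visible in chromatin?** FAIRE (open-chromatin) coverage
   is 1×-normalized and divided by naked-DNA control coverage in 10-bp bins;
   metagene profiles (500-bp flanks, gene bodies length-equalized to 1500 bp)
   and summit-centered windows (±1000 bp) are averaged over genes with 99%
   percentile-bootstrap confidence bands (1000 resamples).

Supporting machinery: TMM between-library normalization with CPM/RPKM/TPM
conversion; gene classification into *unexpressed* (CPM < 1 in ≥ 3 of 6
libraries), *male-biased* / *female-biased* (genewise negative-binomial
exact test, common dispersion, BH-FDR < 0.05) and *unbiased*; peak
annotation against promoter/TSS/UTR/CDS/intron/intergenic features with
peaks-per-Mb densities; control-coverage ploidy checks (autosome/X mean
coverage ≈ 2 in males, ≈ 1 in females); and a **synthetic-data generator**
that emulates the whole system — NB counts for 3 male + 3 female libraries
with the four gene classes and the 3:1 masculinization excess, a dose term
with optional per-copy doubling of male X transcription, copy-number-
proportional control fragments, and expression-coupled TSS enrichment with
a per-copy accessibility multiplier on the male X — so every stage is
testable without any sequencing data.

## Worked example

```python
import aphidx
from aphidx import SimConfig
from aphidx.simulate import simulate_annotation, simulate_counts

cfg = SimConfig(seed=11)                       # compensated X0/XX default
ann = simulate_annotation(cfg)
expr, truth = simulate_counts(ann, cfg)
tpm = aphidx.normalize(expr.values, ann.lengths_kb(), unit="tpm", morphs=expr.morphs)
sweep = aphidx.threshold_sweep(tpm, ann.gene_chrom_class(),
                               [0, 25, 50, 75, 100], filter_mode="per_morph")
print(sweep[sweep.morph == "male"][["threshold", "ratio", "wilcoxon_p", "compensated"]])
```

prints (seed 11):

```
 threshold  ratio  wilcoxon_p  compensated
         0  0.765       0.018        False
        25  1.071       0.413        False
        50  1.048       0.829         True
        75  1.028       0.641         True
       100  1.016       0.668         True
```

With all genes included the male ratio is dragged far below 1 by the mass of
lowly/unexpressed X genes; once weakly expressed genes are filtered out the
ratio settles inside the compensation band with a non-significant rank-sum
test. Rerunning with `SimConfig(seed=11, compensated=False)` — no per-copy
doubling on the single male X — pins the male ratio near 0.5 at every
threshold (0.49–0.54) with p ≈ 0, and the call stays `False`.

The `examples/` directory holds one short script per capability (synthetic
data, ratio sweep, gene classes, chromatin profiles, peak features, full
pipeline); each prints its numbers with a line on what they mean. A thin CLI
mirrors the pipeline stages:

```sh
aphidx simulate --seed 1 --out-dir sim
aphidx classify --counts sim/counts.tsv --out classes.tsv
aphidx run-all --seed 1 --out-dir run    # all stages + manifest.json
```

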