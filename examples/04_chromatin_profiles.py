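"""FAIRE open-chromatin metagene profiles with bootstrap confidence bands.

Builds the input-normalized signal (1x-normalized FAIRE / Control per 10-bp
bin, autosome-anchored so the X0 male's haploid X does not skew the scaling
constant), assembles metagene matrices (500-bp flanks, gene bodies
length-equalized to 150 bins) and prints the TSS-proximal mean with its 99%
bootstrap CI per sex and chromosome class — the male X stands out.
"""
import aphidx
from aphidx import SimConfig, chromatin
from aphidx.simulate import simulate_annotation, simulate_counts, simulate_faire_and_control

cfg = SimConfig(seed=5, n_genes_A=400, n_genes_X=300, scaffold_length=2_600_000,
                n_frags_faire=800_000, n_frags_control=500_000)
ann = simulate_annotation(cfg)
_, truth = simulate_counts(ann, cfg)
sim = simulate_faire_and_control(ann, truth, cfg)

print(f"{'sex':<8}{'chrom':<7}{'TSS mean':>9}{'99% CI':>18}")
for sex in ("male", "female"):
    faire_n = chromatin.depth_normalize(sim.tracks[("faire", sex)],
                                        anchor="autosomes", chrom_class=ann.chrom_class)
    control_n = chromatin.depth_normalize(sim.tracks[("control", sex)],
                                          anchor="autosomes", chrom_class=ann.chrom_class)
    ratio = chromatin.signal_ratio(faire_n, control_n)
    for chrom in ("A", "X"):
        genes = [g for g in ann.genes if ann.chrom_class[g.scaffold] == chrom]
        mat = chromatin.metagene(ratio, genes, annotation=ann)
        ci = chromatin.profile_ci(mat, n_boot=1000, level=0.99, seed=5)
        peak = ci["mean"].iloc[40:61].idxmax()  # within +/-100 bp of the TSS column
        row = ci.loc[peak]
        print(f"{sex:<8}{chrom:<7}{row['mean']:>9.2f}"
              f"   [{row['lower']:.2f}, {row['upper']:.2f}]")
print("\nAutosomal means coincide between sexes; the male X TSS signal clearly")
print("exceeds the female X's (per-copy accessibility doubling on the single")
print("male X) with non-overlapping 99% bootstrap confidence intervals.")
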