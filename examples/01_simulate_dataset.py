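"""Generate a small synthetic X0/XX dataset and write every file the pipeline reads.

The generator plants known structure: a masculinized X (3:1 male- vs
female-biased genes), optional per-copy doubling of male X transcription
(dosage compensation), copy-number-proportional control DNA coverage and
expression-coupled FAIRE enrichment at TSSs.
"""
from pathlib import Path

from aphidx import SimConfig
from aphidx.io_formats import write_annotation, write_bedgraph, write_counts, write_peaks
from aphidx.simulate import simulate_annotation, simulate_counts, simulate_faire_and_control

out = Path("example_output/sim")
out.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=7, n_genes_A=240, n_genes_X=160, scaffold_length=1_500_000,
                lib_sizes=(800_000,) * 6, n_frags_faire=400_000,
                n_frags_control=250_000, n_intergenic_sites=40)
ann = simulate_annotation(cfg)
expr, truth = simulate_counts(ann, cfg)
faire = simulate_faire_and_control(ann, truth, cfg)

write_annotation(ann, out / "annotation.gff3", out / "chrom_map.tsv")
write_counts(expr.values, out / "counts.tsv")
truth.to_csv(out / "truth.tsv", sep="\t")
for (assay, sex), track in faire.tracks.items():
    write_bedgraph(track, out / f"{assay}_{sex}.bedgraph")
for sex in ("male", "female"):
    write_peaks([p for p in faire.peaks if p.sex == sex], out / f"peaks_{sex}.bed")

print(f"wrote {len(ann.genes)} genes on {len(ann.scaffolds)} scaffolds to {out}")
print("true class counts:")
print(truth.groupby(["chrom_class", "label"]).size().unstack(fill_value=0))
print("Rows: chromosome class; columns: planted expression class. The X row")
print("shows the 3:1 male-biased : female-biased masculinization excess.")
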