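"""Synthetic X0/XX genome, RNA-seq counts and FAIRE/Control coverage generator.

The generator inverts the analysis model so every downstream stage can be
tested without any download:

* one autosomal and one X scaffold, with structured genes (5′UTR, CDS exons,
  introns, 3′UTR, mixed strands);
* negative-binomial counts for 3 male + 3 female libraries with four gene
  classes; male-biased genes outnumber female-biased ones 3:1 on the X (the
  masculinized-X structure), and biased genes sit at the shared base level
  in the favored sex and at base/``bias_fold`` in the other, so the
  disfavored sex shows a distinct lowly-expressed gene group;
* an X dose term: females carry two X copies, males one, with male X
  per-copy transcription doubled when ``compensated`` is on;
* Control sequencing fragments placed uniformly at a rate proportional to
  copy number (male X haploid), and FAIRE fragments with Gaussian TSS
  enrichment proportional to log-expression, scaled on the male X by the
  ``accessibility_mult_maleX`` per-copy accessibility factor.

Per-gene base expression levels are drawn from a deterministic lognormal
quantile grid per chromosome (then randomly matched to gene positions), and
class labels are stratified across the expression-ranked grid, so the X and
A gene populations are exchangeable apart from the modeled effects.
Randomness enters through NB count sampling, gene placement, strands and
fragment sampling; everything is reproducible from ``seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal

from .io_formats import GeneModel, GenomeAnnotation, Peak, SignalTrack, track_from_per_base
from .norm import ExpressionMatrix

LIBRARIES = ("male_1", "male_2", "male_3", "female_1", "female_2", "female_3")
MORPH_OF_LIB = {lib: lib.split("_")[0] for lib in LIBRARIES}


@dataclass
class SimConfig:
    """All knobs of the synthetic system; defaults encode the emulated study design."""

    seed: int = 0
    n_genes_A: int = 1200
    n_genes_X: int = 800
    frac_unexpressed_A: float = 0.30
    frac_unexpressed_X: float = 0.40
    frac_malebias_A: float = 0.10
    frac_femalebias_A: float = 0.10
    frac_malebias_X: float = 0.15   # 3:1 male- vs female-biased on X (masculinized X)
    frac_femalebias_X: float = 0.05
    bias_fold: float = 50.0         # favored-sex : disfavored-sex expression fold
    compensated: bool = True        # per-copy doubling of male X transcription
    nb_dispersion: float = 0.1      # NB variance = mu + phi * mu^2 (edgeR convention)
    lib_sizes: tuple = (2_500_000, 3_000_000, 3_500_000, 2_800_000, 3_200_000, 3_000_000)
    scaffold_length: int = 8_000_000
    faire_enrichment: float = 8.0   # TSS bump amplitude scale (fold over background)
    accessibility_mult_maleX: float = 2.0
    frag_mean: int = 200            # fragment length (bp)
    # ancillary knobs of the emulation (not part of the biological model)
    expr_grid_mean_log2: float = 8.0   # mean log2 CPM-scale base rate
    expr_grid_sd_log2: float = 1.5
    unexpressed_scale: float = 1e-3    # unexpressed genes keep a tiny rate (exercises CPM<1)
    n_frags_faire: int = 2_000_000
    n_frags_control: int = 1_000_000
    n_intergenic_sites: int = 150      # enrichment sites per scaffold
    tss_sigma: float = 100.0           # Gaussian bump width (bp)

    def validate(self) -> None:
        for chrom in ("A", "X"):
            tot = (getattr(self, f"frac_unexpressed_{chrom}")
                   + getattr(self, f"frac_malebias_{chrom}")
                   + getattr(self, f"frac_femalebias_{chrom}"))
            if not 0 <= tot <= 1:
                raise ValueError(f"class fractions on {chrom} sum to {tot}, outside [0, 1]")
        if self.bias_fold <= 1:
            raise ValueError("bias_fold must exceed 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if len(self.lib_sizes) != 6 or any(s <= 0 for s in self.lib_sizes):
            raise ValueError("lib_sizes must be 6 positive integers (3 male, 3 female)")
        if self.frag_mean <= 0 or self.scaffold_length <= 0:
            raise ValueError("frag_mean and scaffold_length must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


SCAFFOLDS = {"A": "A1", "X": "X1"}


def _place_gene(rng: np.random.Generator, gid: str, scaffold: str, cursor: int) -> tuple[GeneModel, int]:
    """Lay out one gene left-to-right: UTR exon, CDS exons with introns, UTR exon."""
    strand = "+" if rng.random() < 0.5 else "-"
    utr_a = int(rng.integers(100, 300))
    utr_b = int(rng.integers(150, 400))
    n_cds = int(rng.integers(2, 5))
    cds_lens = rng.integers(200, 600, size=n_cds)
    intron_lens = rng.integers(100, 400, size=n_cds + 1)
    pieces = [("utr", utr_a)]
    for k in range(n_cds):
        pieces.append(("intron", int(intron_lens[k])))
        pieces.append(("cds", int(cds_lens[k])))
    pieces.append(("intron", int(intron_lens[-1])))
    pieces.append(("utr", utr_b))

    pos = cursor
    exons, cds = [], []
    utr_exons = []
    for kind, length in pieces:
        iv = (pos, pos + length)
        if kind != "intron":
            exons.append(iv)
            if kind == "cds":
                cds.append(iv)
            else:
                utr_exons.append(iv)
        pos += length
    # transcript orientation decides which terminal UTR is 5' vs 3'
    first, last = utr_exons[0], utr_exons[-1]
    utr5, utr3 = ([first], [last]) if strand == "+" else ([last], [first])
    gene = GeneModel(gid, scaffold, strand, cursor, pos,
                     exons=exons, cds=cds, utr5=utr5, utr3=utr3)
    return gene, pos


def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Non-overlapping structured genes on one A and one X scaffold (seeded)."""
    config.validate()
    rng = config.rng(1)
    genes: list[GeneModel] = []
    scaffolds, chrom_class = {}, {}
    for chrom, scaf in SCAFFOLDS.items():
        n = getattr(config, f"n_genes_{chrom}")
        L = config.scaffold_length
        scaffolds[scaf] = L
        chrom_class[scaf] = chrom
        # spread genes with random intergenic gaps; leave room for promoters and flanks
        cursor = int(rng.integers(2000, 4000))
        for i in range(n):
            gene, end = _place_gene(rng, f"g{chrom}{i:04d}", scaf, cursor)
            if end > L - 2000:
                raise ValueError(
                    f"genes do not fit on scaffold {scaf} ({i} of {n} placed); "
                    "increase scaffold_length"
                )
            genes.append(gene)
            cursor = end + int(rng.integers(800, 4000))
    ann = GenomeAnnotation(scaffolds=scaffolds, chrom_class=chrom_class, genes=genes)
    ann.validate()
    return ann


def _stratified_labels(n: int, fracs: dict[str, float]) -> np.ndarray:
    """Deterministically interleave class labels across n expression-ranked slots."""
    slots = {lab: int(round(f * n)) for lab, f in fracs.items()}
    slots["unbiased"] = n - sum(slots.values())
    keys, labs = [], []
    for lab, k in slots.items():
        keys.extend((j + 0.5) / k for j in range(k))
        labs.extend([lab] * k)
    order = np.argsort(np.asarray(keys), kind="stable")
    return np.asarray(labs, dtype=object)[order]


def _gene_truth(annotation: GenomeAnnotation, config: SimConfig,
                rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene truth table: class label, base rate and per-sex relative rates."""
    rows = []
    for chrom, scaf in SCAFFOLDS.items():
        genes = annotation.genes_on(scaf)
        n = len(genes)
        z = _normal.ppf((np.arange(n) + 0.5) / n)
        base = 2.0 ** (config.expr_grid_mean_log2 + config.expr_grid_sd_log2 * z)
        labels = _stratified_labels(n, {
            "unexpressed": getattr(config, f"frac_unexpressed_{chrom}"),
            "male_biased": getattr(config, f"frac_malebias_{chrom}"),
            "female_biased": getattr(config, f"frac_femalebias_{chrom}"),
        })
        perm = rng.permutation(n)  # detach expression rank from genomic position
        for k, g in enumerate(genes):
            i = perm[k]
            lab = labels[i]
            b_m = b_f = 1.0
            if lab == "male_biased":
                b_f = 1.0 / config.bias_fold
            elif lab == "female_biased":
                b_m = 1.0 / config.bias_fold
            elif lab == "unexpressed":
                b_m = b_f = config.unexpressed_scale
            d_f = 2.0
            d_m = 2.0 if (chrom == "A" or config.compensated) else 1.0
            rows.append({
                "gene": g.id, "scaffold": scaf, "chrom_class": chrom,
                "label": lab, "base_rate": base[i], "length_kb": g.length_kb,
                "bias_male": b_m, "bias_female": b_f,
                "dose_male": d_m, "dose_female": d_f,
                "w_male": base[i] * g.length_kb * b_m * d_m,
                "w_female": base[i] * g.length_kb * b_f * d_f,
            })
    truth = pd.DataFrame(rows).set_index("gene")
    for sex in ("male", "female"):
        w = truth[f"w_{sex}"]
        truth[f"cpm_true_{sex}"] = w / truth["length_kb"] / (w / truth["length_kb"]).sum() * 1e6
    return truth


def simulate_counts(annotation: GenomeAnnotation, config: SimConfig
                    ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """NB counts for 3 male + 3 female libraries, plus the truth table.

    Expected count: μ_gj = C · (lib_size_j / mean lib size) · w_g,sex(j) with
    w = base rate × exonic length × bias × dose and a single global constant
    C matching the mean library total to the mean configured depth.
    """
    config.validate()
    rng = config.rng(2)
    truth = _gene_truth(annotation, config, rng)
    lib_sizes = np.asarray(config.lib_sizes, dtype=float)
    s = lib_sizes / lib_sizes.mean()
    w = truth[["w_male", "w_female"]].to_numpy()
    # single global constant C: the mean library total matches the mean configured depth
    scale = lib_sizes.mean() / ((w[:, 0].sum() + w[:, 1].sum()) / 2.0)
    phi = config.nb_dispersion
    counts = np.empty((len(truth), 6), dtype=np.int64)
    for j, lib in enumerate(LIBRARIES):
        sex = MORPH_OF_LIB[lib]
        mu = scale * s[j] * truth[f"w_{sex}"].to_numpy()
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    df = pd.DataFrame(counts, index=truth.index, columns=list(LIBRARIES))
    expr = ExpressionMatrix(df, unit="counts", morphs=dict(MORPH_OF_LIB))
    return expr, truth


# ---------------------------------------------------------------------------
# FAIRE / Control coverage


@dataclass
class FaireSim:
    """Simulated chromatin data: 10-bp tracks per (assay, sex), peaks and site truth."""

    tracks: dict[tuple[str, str], SignalTrack]
    peaks: list[Peak]
    sites: pd.DataFrame  # enrichment-site truth (position, kind, sexes)
    per_base: dict[tuple[str, str], dict[str, np.ndarray]] = field(default_factory=dict)


def _copy_number(chrom: str, sex: str) -> float:
    return 1.0 if (chrom == "X" and sex == "male") else 2.0


def _intergenic_positions(annotation: GenomeAnnotation, scaf: str, n: int,
                          rng: np.random.Generator, margin: int = 2500) -> np.ndarray:
    L = annotation.scaffolds[scaf]
    spans = sorted((g.start - margin, g.end + margin) for g in annotation.genes_on(scaf))
    free = []
    cursor = 0
    for s, e in spans:
        if s > cursor:
            free.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < L:
        free.append((cursor, L))
    lens = np.array([e - s for s, e in free], dtype=float)
    picks = rng.choice(len(free), size=n, p=lens / lens.sum())
    offs = rng.random(n)
    return np.array([int(free[i][0] + offs[k] * lens[i]) for k, i in enumerate(picks)])


def simulate_faire_and_control(annotation: GenomeAnnotation, truth: pd.DataFrame,
                               config: SimConfig, bin_size: int = 10,
                               keep_per_base: bool = False) -> FaireSim:
    """Sample Control and FAIRE fragment coverage for both sexes, plus peak calls.

    Control fragment midpoints are uniform within scaffolds at a rate
    proportional to copy number.  FAIRE adds Gaussian TSS bumps whose
    amplitude grows with log1p of the true expression of the gene in that
    sex, and intergenic enrichment sites (some shared, some sex-specific);
    the whole male-X rate is multiplied by ``accessibility_mult_maleX``.
    """
    config.validate()
    rng = config.rng(3)
    sigma = config.tss_sigma
    half_frag = config.frag_mean // 2

    # intergenic enrichment sites with paper-like sharing structure
    site_rows = []
    for chrom, scaf in SCAFFOLDS.items():
        pos = _intergenic_positions(annotation, scaf, config.n_intergenic_sites, rng)
        kinds = np.array(["shared"] * (config.n_intergenic_sites * 2 // 5)
                         + ["male_only"] * (config.n_intergenic_sites * 3 // 10))
        kinds = np.concatenate([kinds, np.array(
            ["female_only"] * (config.n_intergenic_sites - len(kinds)))])
        for p, k in zip(pos, kinds):
            site_rows.append({"scaffold": scaf, "chrom_class": chrom,
                              "position": int(p), "kind": k})
    sites = pd.DataFrame(site_rows)

    gene_by_id = {g.id: g for g in annotation.genes}
    tracks: dict[tuple[str, str], SignalTrack] = {}
    per_base_out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    peaks: list[Peak] = []

    for sex in ("male", "female"):
        rates: dict[str, np.ndarray] = {}
        for chrom, scaf in SCAFFOLDS.items():
            L = annotation.scaffolds[scaf]
            copy = _copy_number(chrom, sex)
            acc = config.accessibility_mult_maleX if (chrom == "X" and sex == "male") else 1.0
            rate = np.ones(L)
            # genic TSS bumps
            for gid, row in truth[truth["scaffold"] == scaf].iterrows():
                amp = config.faire_enrichment * np.log1p(row[f"cpm_true_{sex}"]) / np.log(1e3)
                if amp <= 0.05:
                    continue
                g = gene_by_id[gid]
                lo = max(int(g.tss - 3 * sigma), 0)
                hi = min(int(g.tss + 3 * sigma) + 1, L)
                x = np.arange(lo, hi)
                rate[lo:hi] += amp * np.exp(-0.5 * ((x - g.tss) / sigma) ** 2)
            # intergenic sites
            want = {"shared", f"{sex}_only"}
            for _, srow in sites[sites["scaffold"] == scaf].iterrows():
                if srow["kind"] not in want:
                    continue
                p = srow["position"]
                lo, hi = max(p - int(3 * sigma), 0), min(p + int(3 * sigma) + 1, L)
                x = np.arange(lo, hi)
                rate[lo:hi] += config.faire_enrichment * np.exp(-0.5 * ((x - p) / sigma) ** 2)
            rates[scaf] = copy * acc * rate

        for assay, n_frags in (("faire", config.n_frags_faire),
                               ("control", config.n_frags_control)):
            if n_frags <= 0:
                raise ValueError("fragment counts must be positive")
            if assay == "control":
                use = {scaf: np.full(annotation.scaffolds[scaf],
                                     _copy_number(annotation.chrom_class[scaf], sex))
                       for scaf in SCAFFOLDS.values()}
            else:
                use = rates
            scafs = list(use)
            concat = np.concatenate([use[s] for s in scafs])
            offsets = np.cumsum([0] + [len(use[s]) for s in scafs])
            mids = rng.choice(len(concat), size=n_frags, p=concat / concat.sum())
            cov: dict[str, np.ndarray] = {}
            for i, scaf in enumerate(scafs):
                L = annotation.scaffolds[scaf]
                m = mids[(mids >= offsets[i]) & (mids < offsets[i + 1])] - offsets[i]
                starts = np.clip(m - half_frag, 0, L)
                ends = np.clip(m + half_frag, 0, L)
                delta = np.bincount(starts, minlength=L + 1).astype(np.int64)
                delta -= np.bincount(ends, minlength=L + 1)
                cov[scaf] = np.cumsum(delta)[:-1].astype(float)
            tracks[(assay, sex)] = track_from_per_base(cov, bin_size=bin_size)
            if keep_per_base:
                per_base_out[(assay, sex)] = cov

        # peak calls: TSS sites of clearly expressed genes (detectable
        # enrichment over background) + this sex's intergenic sites; the
        # cutoff scales with the overall expression level so it is
        # independent of the number of simulated genes
        # anchor on the upper quartile: unlike the median it is insensitive
        # to the unexpressed/disfavored-sex low-expression mixture
        call_threshold = 0.1 * float(truth[f"cpm_true_{sex}"].quantile(0.75))
        for gid, row in truth.iterrows():
            if row[f"cpm_true_{sex}"] < call_threshold:
                continue
            g = gene_by_id[gid]
            L = annotation.scaffolds[g.scaffold]
            start, end = max(g.tss - 200, 0), min(g.tss + 200, L)
            peaks.append(Peak(g.scaffold, start, end, g.tss, sex))
        for _, srow in sites.iterrows():
            if srow["kind"] in ("shared", f"{sex}_only"):
                p = srow["position"]
                L = annotation.scaffolds[srow["scaffold"]]
                peaks.append(Peak(srow["scaffold"], max(p - 200, 0), min(p + 200, L), p, sex))

    peaks.sort(key=lambda p: (p.sex, p.scaffold, p.start))
    return FaireSim(tracks=tracks, peaks=peaks, sites=sites, per_base=per_base_out)
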