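"""End-to-end orchestration: simulate → normalize → classify → sweep → signal → peaks.

A :class:`RunConfig` (YAML-loadable) drives one reproducible run: every
stage's seed is recorded and a manifest with parameter values and output
checksums is written next to the result tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, diffexpr, dosage, peaks as peakmod
from .io_formats import (GenomeAnnotation, read_annotation, read_counts, read_coverage,
                         read_peaks, write_annotation, write_bedgraph, write_counts,
                         write_peaks)
from .norm import ExpressionMatrix, normalize
from .simulate import MORPH_OF_LIB, SimConfig, simulate_annotation, simulate_counts, \
    simulate_faire_and_control

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "aphidx_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # paths used when simulate is off
    gff3: str | None = None
    chrom_map: str | None = None
    counts: str | None = None
    morphs: dict[str, str] = field(default_factory=lambda: dict(MORPH_OF_LIB))
    faire_bedgraph: dict[str, str] = field(default_factory=dict)    # sex -> path
    control_bedgraph: dict[str, str] = field(default_factory=dict)  # sex -> path
    peaks_bed: dict[str, str] = field(default_factory=dict)         # sex -> path
    # analysis choices
    unit: str = "tpm"
    filter_mode: str = "per_morph"
    tpm_thresholds: tuple = tuple(range(0, 101, 5))
    rpkm_thresholds: tuple = (0, 1, 2, 3, 4)
    fdr: float = 0.05
    pseudocount: float = 0.5
    flank: int = 500
    body_bins: int = 150
    summit_flank: int = 1000
    n_boot: int = 1000
    ci_level: float = 0.99
    use_tmm: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig(**data.pop("sim", {}))
        cfg = cls(sim=sim, **data)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> Path:
    """Run the full pipeline, returning the output directory.

    Emits: simulated inputs (when simulating), normalized expression tables,
    the gene class table, TPM/RPKM ratio sweeps, class-stratified ratio
    summaries, peak feature densities, the sex-overlap table, the control
    A/X coverage ratio, and metagene/summit profile CI tables — plus
    ``manifest.json`` with parameters, seeds and output checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.6g", **kw)
        written.append(path)

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            ann = simulate_annotation(sim)
            expr_counts, truth = simulate_counts(ann, sim)
            fsim = simulate_faire_and_control(ann, truth, sim)
            write_annotation(ann, out / "annotation.gff3", out / "chrom_map.tsv")
            write_counts(expr_counts.values, out / "counts.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t")
            written += [out / "annotation.gff3", out / "chrom_map.tsv",
                        out / "counts.tsv", out / "truth.tsv"]
            tracks = fsim.tracks
            for (assay, sex), track in tracks.items():
                write_bedgraph(track, out / f"{assay}_{sex}.bedgraph")
                written.append(out / f"{assay}_{sex}.bedgraph")
            peaks_by_sex = {
                sex: [p for p in fsim.peaks if p.sex == sex] for sex in ("male", "female")
            }
            for sex, plist in peaks_by_sex.items():
                write_peaks(plist, out / f"peaks_{sex}.bed")
                written.append(out / f"peaks_{sex}.bed")
        else:
            if not (config.gff3 and config.chrom_map and config.counts):
                raise ValueError("simulation disabled but gff3/chrom_map/counts paths missing")
            ann = read_annotation(config.gff3, config.chrom_map)
            counts_df = read_counts(config.counts)
            expr_counts = ExpressionMatrix(counts_df, unit="counts", morphs=config.morphs)
            tracks = {}
            for sex, path in config.faire_bedgraph.items():
                tracks[("faire", sex)] = read_coverage(path, ann)
            for sex, path in config.control_bedgraph.items():
                tracks[("control", sex)] = read_coverage(path, ann)
            peaks_by_sex = {sex: read_peaks(path, sex)
                            for sex, path in config.peaks_bed.items()}
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    chrom_class = ann.gene_chrom_class()
    lengths = ann.lengths_kb()

    # ---- expression -------------------------------------------------------
    stage = "expression"
    try:
        rpkm = normalize(expr_counts.values, lengths, unit="rpkm",
                         use_tmm=config.use_tmm, morphs=expr_counts.morphs)
        tpm = normalize(expr_counts.values, lengths, unit="tpm",
                        use_tmm=config.use_tmm, morphs=expr_counts.morphs)
        emit(rpkm.values, "rpkm.tsv", index_label="gene")
        emit(tpm.values, "tpm.tsv", index_label="gene")

        classes = diffexpr.classify(expr_counts.values, expr_counts.morphs,
                                    fdr=config.fdr, use_tmm=config.use_tmm)
        emit(classes, "classes.tsv", index_label="gene")

        sweep_tpm = dosage.threshold_sweep(tpm, chrom_class, config.tpm_thresholds,
                                           filter_mode=config.filter_mode)
        emit(sweep_tpm, "sweep_tpm.tsv", index=False)
        sweep_rpkm = dosage.threshold_sweep(rpkm, chrom_class, config.rpkm_thresholds,
                                            filter_mode="joint_mean")
        emit(sweep_rpkm, "sweep_rpkm.tsv", index=False)

        class_summary = dosage.class_ratio_summary(rpkm, classes, chrom_class)
        emit(class_summary, "class_ratio_summary.tsv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- chromatin --------------------------------------------------------
    stage = "chromatin"
    try:
        have_signal = all(("faire", s) in tracks and ("control", s) in tracks
                          for s in ("male", "female"))
        if have_signal:
            fmap = peakmod.build_feature_map(ann)
            density = peakmod.peak_density(
                [p for sex in peaks_by_sex for p in peaks_by_sex[sex]], fmap)
            emit(density, "peak_density.tsv", index=False)
            venn = peakmod.overlap_sets(peaks_by_sex.get("male", []),
                                        peaks_by_sex.get("female", []))
            venn_df = pd.DataFrame([{k: v for k, v in venn.items() if k != "union"}])
            emit(venn_df, "peak_overlap.tsv", index=False)

            ratios = []
            for sex in ("male", "female"):
                ratios.append({
                    "sex": sex,
                    "A_over_X_control_coverage":
                        peakmod.chrom_coverage_ratio(tracks[("control", sex)],
                                                     ann.chrom_class),
                })
            emit(pd.DataFrame(ratios), "control_coverage_ratio.tsv", index=False)

            rpkm_means = dosage.morph_mean(rpkm)
            profile_rows = []
            for sex in ("male", "female"):
                # autosome-anchored 1x scaling: the X0 male's haploid X halves
                # its DNA share, confounding a genome-wide mean across sexes
                faire_n = chromatin.depth_normalize(tracks[("faire", sex)],
                                                    anchor="autosomes",
                                                    chrom_class=ann.chrom_class)
                control_n = chromatin.depth_normalize(tracks[("control", sex)],
                                                      anchor="autosomes",
                                                      chrom_class=ann.chrom_class)
                ratio_track = chromatin.signal_ratio(faire_n, control_n,
                                                     config.pseudocount)
                for chrom in ("A", "X"):
                    genes = [g for g in ann.genes if ann.chrom_class[g.scaffold] == chrom]
                    mat = chromatin.metagene(ratio_track, genes, flank=config.flank,
                                             body_bins=config.body_bins, annotation=ann)
                    ci = chromatin.profile_ci(mat, n_boot=config.n_boot,
                                              level=config.ci_level, seed=config.seed)
                    ci.insert(0, "bin", np.arange(len(ci)))
                    ci.insert(0, "chrom_class", chrom)
                    ci.insert(0, "sex", sex)
                    profile_rows.append(ci)
                inter = peakmod.intergenic_peaks(peaks_by_sex.get(sex, []), fmap)
                if len(inter) >= 2:
                    smat = chromatin.summit_matrix(ratio_track, inter,
                                                   flank=config.summit_flank)
                    sci = chromatin.profile_ci(smat, n_boot=config.n_boot,
                                               level=config.ci_level, seed=config.seed)
                    sci.insert(0, "bin", np.arange(len(sci)))
                    sci.insert(0, "chrom_class", "all")
                    sci.insert(0, "sex", f"{sex}_summits")
                    profile_rows.append(sci)
            emit(pd.concat(profile_rows, ignore_index=True), "profiles_ci.tsv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in written if p.exists()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
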