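"""Peak annotation against genomic features, densities, sex overlap and ploidy checks.

Feature windows follow the upstream-anchored convention: the TSS feature is
the 200 bp immediately upstream of the first base of the 5′UTR (or of the
gene when no 5′UTR is annotated), and the promoter extends from 1300 bp
upstream down to the TSS window.  By default the promoter is trimmed to
[TSS−1300, TSS−200) so the two features tile disjoint ground, while a peak
still counts toward every feature it overlaps by at least one base.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeAnnotation, Peak, SignalTrack

FEATURES = ("promoter", "tss", "utr5", "cds", "intron", "utr3", "intergenic")


def merge_intervals(intervals) -> np.ndarray:
    """Merge overlapping/adjacent half-open intervals into a sorted (n, 2) array."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return np.empty((0, 2), dtype=np.int64)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def complement(merged: np.ndarray, length: int) -> np.ndarray:
    """Complement of merged intervals within [0, length)."""
    out = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            out.append((cursor, min(s, length)))
        cursor = max(cursor, e)
    if cursor < length:
        out.append((cursor, length))
    return np.asarray(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def total_bp(merged: np.ndarray) -> int:
    return int((merged[:, 1] - merged[:, 0]).sum()) if len(merged) else 0


def _overlaps(merged: np.ndarray, start: int, end: int) -> bool:
    """>=1 bp overlap between [start, end) and sorted merged intervals."""
    if len(merged) == 0:
        return False
    i = int(np.searchsorted(merged[:, 0], end))  # intervals starting before `end`
    return i > 0 and merged[i - 1, 1] > start


def _upstream_windows(gene: GeneModel, promoter_bp: int, tss_bp: int,
                      trim_promoter: bool, scaffold_len: int):
    """(tss_window, promoter_window) in scaffold coordinates, clipped to the scaffold."""
    if gene.strand == "+":
        anchor = gene.utr5[0][0] if gene.utr5 else gene.start
        tss_iv = (anchor - tss_bp, anchor)
        prom_iv = (anchor - promoter_bp, anchor - tss_bp if trim_promoter else anchor)
    else:
        anchor = gene.utr5[-1][1] - 1 if gene.utr5 else gene.end - 1
        tss_iv = (anchor + 1, anchor + 1 + tss_bp)
        prom_iv = (anchor + 1 + tss_bp if trim_promoter else anchor + 1,
                   anchor + 1 + promoter_bp)
    clip = lambda iv: (max(iv[0], 0), min(iv[1], scaffold_len))
    return clip(tss_iv), clip(prom_iv)


@dataclass
class FeatureMap:
    """Merged labeled intervals per scaffold, with genome-wide lengths per feature."""

    intervals: dict[str, dict[str, np.ndarray]]  # feature -> scaffold -> (n, 2)
    lengths_bp: dict[str, int]
    flagged_genes: list[str]  # genes whose TSS fell back to the gene 5' end

    def length_mb(self, feature: str) -> float:
        return self.lengths_bp[feature] / 1e6


def build_feature_map(annotation: GenomeAnnotation, promoter_bp: int = 1300,
                      tss_bp: int = 200, trim_promoter: bool = True,
                      skip_utrless: bool = False) -> FeatureMap:
    """Label the genome into promoter/TSS/5′UTR/CDS/intron/3′UTR/intergenic.

    Genes without an annotated 5′UTR anchor their TSS and promoter windows
    at the gene's 5′ end and are flagged (or skipped if ``skip_utrless``).
    Intergenic is the exact complement of all gene-derived features.
    """
    raw: dict[str, dict[str, list]] = {f: {s: [] for s in annotation.scaffolds}
                                       for f in FEATURES}
    flagged = []
    for g in annotation.genes:
        L = annotation.scaffolds[g.scaffold]
        if not g.utr5:
            if skip_utrless:
                continue
            flagged.append(g.id)
        tss_iv, prom_iv = _upstream_windows(g, promoter_bp, tss_bp,
                                            trim_promoter, L)
        raw["tss"][g.scaffold].append(tss_iv)
        raw["promoter"][g.scaffold].append(prom_iv)
        raw["utr5"][g.scaffold].extend(g.utr5)
        raw["cds"][g.scaffold].extend(g.cds)
        raw["utr3"][g.scaffold].extend(g.utr3)
        exonic = merge_intervals(g.exons)
        for s, e in complement(exonic, L):
            if g.start < e and s < g.end:  # intron = gene span minus exons
                raw["intron"][g.scaffold].append((max(s, g.start), min(e, g.end)))

    intervals: dict[str, dict[str, np.ndarray]] = {f: {} for f in FEATURES}
    for f in FEATURES:
        if f == "intergenic":
            continue
        for scaf in annotation.scaffolds:
            intervals[f][scaf] = merge_intervals(raw[f][scaf])
    for scaf, L in annotation.scaffolds.items():
        genic = np.concatenate([intervals[f][scaf] for f in FEATURES[:-1]
                                if len(intervals[f][scaf])] or
                               [np.empty((0, 2), dtype=np.int64)])
        intervals["intergenic"][scaf] = complement(merge_intervals(genic), L)

    lengths = {f: sum(total_bp(intervals[f][s]) for s in annotation.scaffolds)
               for f in FEATURES}
    return FeatureMap(intervals=intervals, lengths_bp=lengths, flagged_genes=flagged)


def peak_density(peaks: list[Peak], feature_map: FeatureMap) -> pd.DataFrame:
    """Peaks per Mb per feature per sex; a peak counts toward every feature it overlaps."""
    sexes = sorted({p.sex for p in peaks})
    rows = []
    for feature in FEATURES:
        length_mb = feature_map.length_mb(feature)
        for sex in sexes:
            count = sum(
                1 for p in peaks if p.sex == sex and
                _overlaps(feature_map.intervals[feature].get(p.scaffold,
                                                             np.empty((0, 2))),
                          p.start, p.end)
            )
            rows.append({
                "feature": feature, "sex": sex, "peak_count": count,
                "length_mb": length_mb,
                "density_per_mb": count / length_mb if length_mb > 0 else float("nan"),
                "undefined": length_mb == 0,
            })
    return pd.DataFrame(rows)


def intergenic_peaks(peaks: list[Peak], feature_map: FeatureMap) -> list[Peak]:
    """Peaks overlapping no gene-derived feature (their summit window is intergenic)."""
    out = []
    for p in peaks:
        genic = any(
            _overlaps(feature_map.intervals[f].get(p.scaffold, np.empty((0, 2))),
                      p.start, p.end)
            for f in FEATURES[:-1]
        )
        if not genic:
            out.append(p)
    return out


def overlap_sets(peaks_male: list[Peak], peaks_female: list[Peak]) -> dict:
    """Sex-specificity of peak calls plus the merged union interval set.

    ``shared_regions`` counts merged union intervals containing peaks from
    both sexes (symmetric); ``male_shared``/``female_shared`` count
    individual peaks overlapping at least one peak of the other sex.
    """
    def by_scaffold(peaks):
        d: dict[str, list] = {}
        for p in peaks:
            d.setdefault(p.scaffold, []).append((p.start, p.end))
        return {s: merge_intervals(iv) for s, iv in d.items()}

    merged_m, merged_f = by_scaffold(peaks_male), by_scaffold(peaks_female)
    male_shared = sum(1 for p in peaks_male
                      if _overlaps(merged_f.get(p.scaffold, np.empty((0, 2))), p.start, p.end))
    female_shared = sum(1 for p in peaks_female
                        if _overlaps(merged_m.get(p.scaffold, np.empty((0, 2))), p.start, p.end))

    union: dict[str, np.ndarray] = {}
    for scaf in set(merged_m) | set(merged_f):
        both = list(merged_m.get(scaf, [])) + list(merged_f.get(scaf, []))
        union[scaf] = merge_intervals(both)
    shared_regions = sum(
        1
        for scaf, ivs in union.items()
        for s, e in ivs
        if _overlaps(merged_m.get(scaf, np.empty((0, 2))), s, e)
        and _overlaps(merged_f.get(scaf, np.empty((0, 2))), s, e)
    )
    n_union = sum(len(v) for v in union.values())
    return {
        "n_male": len(peaks_male), "n_female": len(peaks_female),
        "male_shared": male_shared, "female_shared": female_shared,
        "male_specific": len(peaks_male) - male_shared,
        "female_specific": len(peaks_female) - female_shared,
        "shared_regions": shared_regions, "n_union_regions": n_union,
        "union": union,
    }


def chrom_coverage_ratio(control: SignalTrack, chrom_class: dict[str, str]) -> float:
    """Autosome-to-X ratio of mean per-bin Control coverage (ploidy check)."""
    a_bins = [control.values[s] for s, c in chrom_class.items()
              if c == "A" and s in control.values]
    x_bins = [control.values[s] for s, c in chrom_class.items()
              if c == "X" and s in control.values]
    if not a_bins or not x_bins:
        raise ValueError("both chromosome classes must have scaffolds in the track")
    return float(np.mean(np.concatenate(a_bins)) / np.mean(np.concatenate(x_bins)))
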