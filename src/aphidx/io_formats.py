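"""Readers, writers and validated in-memory models for the formats the pipeline touches.

All internal coordinates are 0-based half-open. GFF3 (1-based, fully closed)
is converted on read and write; BED and bedGraph already use the internal
convention and pass through unchanged.

The central containers are :class:`GenomeAnnotation` (scaffolds, their
chromosome class X/A, and gene models with exon/CDS/UTR structure),
:class:`SignalTrack` (per-scaffold 10-bp-binned coverage or signal-ratio
arrays) and :class:`Peak` (an interval with a summit and a sex flag).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Interval = tuple[int, int]

_GFF_FEATURES = {
    "gene": None,
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


class ParseError(ValueError):
    """Raised for malformed input lines; message names the file and line number."""


# ---------------------------------------------------------------------------
# gene / annotation model


@dataclass
class GeneModel:
    """One gene: location, strand and exonic substructure.

    ``exons``/``cds``/``utr5``/``utr3`` are sorted lists of half-open
    intervals in scaffold coordinates regardless of strand.
    """

    id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def tss(self) -> int:
        """Transcription start: span start on ``+``, span end − 1 on ``-``."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exonic_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def length_kb(self) -> float:
        """Summed exon length in kb, the gene length used for RPKM/TPM."""
        return self.exonic_bp / 1000.0

    def validate(self, scaffold_length: int | None = None) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.id}: empty or negative span")
        if scaffold_length is not None and self.end > scaffold_length:
            raise ValueError(
                f"gene {self.id}: span [{self.start}, {self.end}) exceeds "
                f"scaffold length {scaffold_length}"
            )
        exons = sorted(self.exons)
        if exons != self.exons:
            raise ValueError(f"gene {self.id}: exons not sorted")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"gene {self.id}: overlapping exons")
        for name in ("cds", "utr5", "utr3"):
            for s, e in getattr(self, name):
                if not any(es <= s and e <= ee for es, ee in exons):
                    raise ValueError(
                        f"gene {self.id}: {name} interval [{s}, {e}) not "
                        "contained in any exon"
                    )


@dataclass
class GenomeAnnotation:
    """Scaffold lengths, scaffold→chromosome-class map and gene models."""

    scaffolds: dict[str, int]
    chrom_class: dict[str, str]  # scaffold -> "X" | "A"
    genes: list[GeneModel]

    def validate(self) -> None:
        for scaf, cls in self.chrom_class.items():
            if cls not in ("X", "A"):
                raise ValueError(f"scaffold {scaf}: chromosome class {cls!r} not in X/A")
        for scaf in self.scaffolds:
            if scaf not in self.chrom_class:
                raise ValueError(f"scaffold {scaf} has no chromosome class")
        for g in self.genes:
            if g.scaffold not in self.scaffolds:
                raise ValueError(f"gene {g.id}: unknown scaffold {g.scaffold}")
            g.validate(self.scaffolds[g.scaffold])

    # convenience accessors used across the pipeline ------------------------

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def lengths_kb(self) -> pd.Series:
        return pd.Series({g.id: g.length_kb for g in self.genes}, name="length_kb")

    def gene_chrom_class(self) -> pd.Series:
        return pd.Series(
            {g.id: self.chrom_class[g.scaffold] for g in self.genes}, name="chrom_class"
        )

    def genes_on(self, scaffold: str) -> list[GeneModel]:
        return [g for g in self.genes if g.scaffold == scaffold]


# ---------------------------------------------------------------------------
# GFF3


def _fmt_gff_line(scaf, source, ftype, start, end, strand, attrs):
    # internal half-open -> GFF3 1-based inclusive
    return f"{scaf}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"


def write_annotation(annotation: GenomeAnnotation, gff3_path, chrom_map_path=None) -> None:
    """Write a GenomeAnnotation as GFF3 (+ optional scaffold→class map TSV)."""
    lines = ["##gff-version 3"]
    for scaf, length in annotation.scaffolds.items():
        lines.append(f"##sequence-region {scaf} 1 {length}")
    for g in annotation.genes:
        lines.append(
            _fmt_gff_line(g.scaffold, "aphidx", "gene", g.start, g.end, g.strand, f"ID={g.id}")
        )
        for ftype, attr in (("exon", "exons"), ("CDS", "cds"),
                            ("five_prime_UTR", "utr5"), ("three_prime_UTR", "utr3")):
            for s, e in getattr(g, attr):
                lines.append(
                    _fmt_gff_line(g.scaffold, "aphidx", ftype, s, e, g.strand, f"Parent={g.id}")
                )
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if chrom_map_path is not None:
        write_chrom_map(annotation.chrom_class, chrom_map_path)


def write_chrom_map(chrom_class: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for scaf, cls in chrom_class.items():
            fh.write(f"{scaf}\t{cls}\n")


def read_chrom_map(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("X", "A"):
                raise ParseError(f"{path}: line {i}: expected 'scaffold<TAB>X|A'")
            out[parts[0]] = parts[1]
    return out


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        if item and "=" in item:
            k, _, v = item.partition("=")
            out[k.strip()] = v.strip()
    return out


def read_annotation(gff3_path, chrom_map_path) -> GenomeAnnotation:
    """Read genes/exons/CDS/UTRs from GFF3 plus a scaffold→{X,A} map.

    Genes on scaffolds absent from the map are dropped (a warning reports the
    count).  GFF3 coordinates (1-based inclusive) are converted to the
    internal 0-based half-open convention.
    """
    chrom_class = read_chrom_map(chrom_map_path)
    scaffolds: dict[str, int] = {}
    genes: dict[str, GeneModel] = {}
    children: list[tuple[str, str, int, int]] = []

    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(f"{gff3_path}: line {lineno}: bad sequence-region")
                scaffolds[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{gff3_path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            scaf, _source, ftype, start1, end1, _score, strand, _frame, attrs = fields
            if ftype not in _GFF_FEATURES:
                continue
            try:
                start = int(start1) - 1  # to half-open
                end = int(end1)
            except ValueError as exc:
                raise ParseError(f"{gff3_path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ParseError(f"{gff3_path}: line {lineno}: invalid interval")
            attr = _parse_attrs(attrs)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ParseError(f"{gff3_path}: line {lineno}: gene without ID")
                genes[gid] = GeneModel(gid, scaf, strand, start, end)
            else:
                parent = attr.get("Parent")
                if parent is None:
                    raise ParseError(f"{gff3_path}: line {lineno}: {ftype} without Parent")
                children.append((parent, _GFF_FEATURES[ftype], start, end))

    for parent, slot, start, end in children:
        if parent in genes:
            getattr(genes[parent], slot).append((start, end))

    kept, dropped = [], 0
    for g in genes.values():
        for slot in ("exons", "cds", "utr5", "utr3"):
            getattr(g, slot).sort()
        if g.scaffold not in chrom_class:
            dropped += 1
            continue
        kept.append(g)
    if dropped:
        log.warning("dropped %d gene(s) on scaffolds absent from the chromosome map", dropped)
    kept.sort(key=lambda g: (g.scaffold, g.start, g.id))

    for g in kept:  # infer scaffold lengths if the header was absent
        scaffolds.setdefault(g.scaffold, 0)
        scaffolds[g.scaffold] = max(scaffolds[g.scaffold], g.end)
    scaffolds = {s: L for s, L in scaffolds.items() if s in chrom_class}

    ann = GenomeAnnotation(scaffolds=scaffolds, chrom_class={s: chrom_class[s] for s in scaffolds},
                           genes=kept)
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# signal tracks / bedGraph


@dataclass
class SignalTrack:
    """Per-scaffold binned nonnegative signal (coverage or FAIRE/Control ratio).

    ``values[scaffold]`` has ``ceil(L / bin_size)`` entries; the last bin may
    cover fewer than ``bin_size`` bases and is averaged over its real width.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    kind: str = "coverage"  # or "ratio"
    normalized: bool = False
    lengths: dict[str, int] | None = None  # true scaffold lengths (bp), for partial last bins

    def genome_mean(self) -> float:
        return float(np.mean(np.concatenate([v for v in self.values.values()])))

    def scaffold_length(self, scaf: str) -> int:
        if self.lengths and scaf in self.lengths:
            return self.lengths[scaf]
        return len(self.values[scaf]) * self.bin_size

    def copy(self) -> "SignalTrack":
        return replace(self, values={s: v.copy() for s, v in self.values.items()})


def bin_per_base(per_base: np.ndarray, bin_size: int) -> np.ndarray:
    """Average a per-base array into bins; the last partial bin keeps its real width."""
    L = len(per_base)
    starts = np.arange(0, L, bin_size)
    sums = np.add.reduceat(per_base.astype(float), starts)
    widths = np.minimum(bin_size, L - starts)
    return sums / widths


def track_from_per_base(per_base: dict[str, np.ndarray], bin_size: int = 10,
                        kind: str = "coverage") -> SignalTrack:
    return SignalTrack(bin_size=bin_size, kind=kind,
                       values={s: bin_per_base(v, bin_size) for s, v in per_base.items()},
                       lengths={s: len(v) for s, v in per_base.items()})


def read_coverage(bedgraph_path, annotation: GenomeAnnotation, bin_size: int = 10) -> SignalTrack:
    """Read a bedGraph into a binned SignalTrack.

    The value of a bin is the length-weighted mean of overlapping bedGraph
    intervals; uncovered bases count as 0.  Intervals beyond a scaffold end
    are an error.
    """
    df = pd.read_csv(
        bedgraph_path, sep="\t", comment="#", header=None,
        names=["scaffold", "start", "end", "value"],
        dtype={"scaffold": str, "start": np.int64, "end": np.int64, "value": float},
    )
    values: dict[str, np.ndarray] = {}
    for scaf, L in annotation.scaffolds.items():
        sub = df[df["scaffold"] == scaf]
        per_base = np.zeros(L)
        if len(sub):
            if (sub["end"] > L).any() or (sub["start"] < 0).any():
                raise ValueError(f"{bedgraph_path}: interval outside scaffold {scaf} [0, {L})")
            if (sub["start"] >= sub["end"]).any():
                raise ValueError(f"{bedgraph_path}: empty interval on {scaf}")
            delta = np.zeros(L + 1)
            np.add.at(delta, sub["start"].to_numpy(), sub["value"].to_numpy())
            np.add.at(delta, sub["end"].to_numpy(), -sub["value"].to_numpy())
            per_base = np.cumsum(delta)[:-1]
        values[scaf] = bin_per_base(per_base, bin_size)
    unknown = set(df["scaffold"]) - set(annotation.scaffolds)
    if unknown:
        raise ValueError(f"{bedgraph_path}: unknown scaffold(s) {sorted(unknown)}")
    return SignalTrack(bin_size=bin_size, values=values, lengths=dict(annotation.scaffolds))


def write_bedgraph(per_base_or_track, path) -> None:
    """Write per-base arrays (dict) or a SignalTrack as a run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        if isinstance(per_base_or_track, SignalTrack):
            t = per_base_or_track
            for scaf, vals in t.values.items():
                starts = np.arange(len(vals)) * t.bin_size
                ends = np.minimum(starts + t.bin_size, t.scaffold_length(scaf))
                _write_runs(fh, scaf, starts, ends, vals)
        else:
            for scaf, arr in per_base_or_track.items():
                arr = np.asarray(arr, dtype=float)
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                _write_runs(fh, scaf, starts, ends, arr[starts])


def _write_runs(fh, scaf, starts, ends, vals) -> None:
    keep = np.asarray(vals) != 0
    for s, e, v in zip(np.asarray(starts)[keep], np.asarray(ends)[keep], np.asarray(vals)[keep]):
        fh.write(f"{scaf}\t{int(s)}\t{int(e)}\t{v:g}\n")


# ---------------------------------------------------------------------------
# peaks (BED / narrowPeak)


@dataclass(frozen=True)
class Peak:
    """A called open-chromatin region with its summit and originating sex."""

    scaffold: str
    start: int
    end: int
    summit: int
    sex: str = "NA"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak on {self.scaffold}: start {self.start} >= end {self.end}")
        if not self.start <= self.summit < self.end:
            raise ValueError(f"peak on {self.scaffold}: summit {self.summit} outside span")


def read_peaks(bed_path, sex: str = "NA") -> list[Peak]:
    """Read BED (0-based half-open) peaks, sorted by (scaffold, start).

    narrowPeak-style input (10 columns) provides the summit as an offset from
    the start in the last column; plain BED peaks default to the interval
    midpoint, ``floor((start + end) / 2)``.
    """
    peaks = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{bed_path}: line {lineno}: fewer than 3 BED fields")
            scaf, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(f"{bed_path}: line {lineno}: start >= end")
            if len(parts) >= 10 and parts[9] not in (".", "-1"):
                summit = start + int(parts[9])
            else:
                summit = (start + end) // 2
            peaks.append(Peak(scaf, start, end, summit, sex))
    peaks.sort(key=lambda p: (p.scaffold, p.start, p.end))
    return peaks


def write_peaks(peaks: list[Peak], path) -> None:
    """Write peaks as narrowPeak-like BED10 (summit offset in the last column)."""
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.scaffold, p.start, p.end)):
            fh.write(
                f"{p.scaffold}\t{p.start}\t{p.end}\t{p.sex}\t0\t.\t0\t-1\t-1\t{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path) -> pd.DataFrame:
    """Read a counts TSV: gene-id column named ``gene`` + one integer column per library."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ParseError(f"{path}: missing 'gene' column")
    df = df.set_index("gene")
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")
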