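"""Input-normalized open-chromatin signal and profile statistics.

The signal of interest is the per-10-bp-bin ratio of 1×-depth-normalized
FAIRE coverage to Control (naked DNA) coverage, stabilized by a pseudocount.
Profiles are built either as metagene matrices (50 flank bins upstream of
the TSS, gene body length-equalized to 150 bins, 50 bins downstream of the
TES, oriented 5′→3′) or as raw 200-bin windows centered on peak summits.
Column means carry percentile bootstrap confidence bands over genes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io_formats import GeneModel, GenomeAnnotation, Peak, SignalTrack


def depth_normalize(track: SignalTrack, anchor: str = "genome",
                    chrom_class: dict[str, str] | None = None) -> SignalTrack:
    """Scale a coverage track so the mean bin value over the anchor region is 1.

    ``anchor="genome"`` is plain 1× normalization.  ``anchor="autosomes"``
    (requires ``chrom_class``) scales to mean 1 over autosomal bins only:
    in an X0 male the genome-wide mean is confounded by the haploid X's
    halved DNA content, so cross-sex signal comparisons anchor the scaling
    on the autosomes, which are diploid in both sexes.
    """
    if anchor == "genome":
        mean = track.genome_mean()
    elif anchor == "autosomes":
        if chrom_class is None:
            raise ValueError("autosome anchoring needs the scaffold chromosome classes")
        bins = [v for s, v in track.values.items() if chrom_class.get(s) == "A"]
        if not bins:
            raise ValueError("no autosomal scaffolds in the track")
        mean = float(np.mean(np.concatenate(bins)))
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    if mean == 0:
        raise ValueError("cannot depth-normalize an all-zero track")
    out = track.copy()
    for scaf in out.values:
        out.values[scaf] = out.values[scaf] / mean
    out.normalized = True
    return out


def signal_ratio(faire: SignalTrack, control: SignalTrack,
                 pseudocount: float = 0.5) -> SignalTrack:
    """Per-bin (FAIRE + ε) / (Control + ε) ratio track."""
    if faire.bin_size != control.bin_size or set(faire.values) != set(control.values):
        raise ValueError("FAIRE and Control tracks have mismatched binning or scaffolds")
    values = {}
    for scaf, f in faire.values.items():
        c = control.values[scaf]
        if f.shape != c.shape:
            raise ValueError(f"scaffold {scaf}: FAIRE and Control bin counts differ")
        values[scaf] = (f + pseudocount) / (c + pseudocount)
    return SignalTrack(bin_size=faire.bin_size, values=values, kind="ratio",
                       normalized=faire.normalized, lengths=faire.lengths)


@dataclass
class MetageneMatrix:
    """Rows of per-gene (or per-peak) profile bins with aligned metadata."""

    values: np.ndarray          # rows × columns, NaN where clipped/flagged
    meta: pd.DataFrame          # one row per matrix row (id, scaffold, flags, ...)
    n_upstream: int
    n_body: int                 # 0 for summit windows
    n_downstream: int

    @property
    def n_columns(self) -> int:
        return self.n_upstream + self.n_body + self.n_downstream


def _resample_body(vals: np.ndarray, n_out: int) -> np.ndarray:
    """Length-weighted averaging of input bins onto n_out equal output bins.

    Conserves the mean exactly and maps constant input to constant output.
    """
    g = len(vals)
    cum = np.concatenate(([0.0], np.cumsum(vals)))
    edges = np.linspace(0.0, g, n_out + 1)
    cum_at = np.interp(edges, np.arange(g + 1), cum)
    return np.diff(cum_at) / (g / n_out)


def _slice_bins(arr: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """arr[lo:hi] with out-of-range bins as NaN."""
    out = np.full(hi - lo, np.nan)
    a, b = max(lo, 0), min(hi, len(arr))
    if b > a:
        out[a - lo: b - lo] = arr[a:b]
    return out


def metagene(signal: SignalTrack, genes: list[GeneModel] | GenomeAnnotation,
             flank: int = 500, body_bins: int = 150,
             annotation: GenomeAnnotation | None = None) -> MetageneMatrix:
    """Per-gene profile matrix: flank bins, length-equalized body, flank bins, 5′→3′.

    Flank bins are raw track bins (never resampled); scaffold-edge clipping
    yields NaN columns.  Genes shorter than one bin are flagged and left NaN.
    """
    if isinstance(genes, GenomeAnnotation):
        annotation = genes
        genes = genes.genes
    bs = signal.bin_size
    n_flank = flank // bs
    rows, meta = [], []
    for g in genes:
        arr = signal.values[g.scaffold]
        b0, b1 = g.start // bs, -(-g.end // bs)  # bins touching the gene span
        short = (g.end - g.start) < bs
        if short:
            row = np.full(2 * n_flank + body_bins, np.nan)
        else:
            left = _slice_bins(arr, b0 - n_flank, b0)
            body = _resample_body(arr[b0:b1], body_bins)
            right = _slice_bins(arr, b1, b1 + n_flank)
            row = np.concatenate([left, body, right])
            if g.strand == "-":
                row = row[::-1]
        rows.append(row)
        meta.append({
            "id": g.id, "scaffold": g.scaffold, "strand": g.strand,
            "chrom_class": annotation.chrom_class[g.scaffold] if annotation else "NA",
            "short": short,
        })
    return MetageneMatrix(np.array(rows), pd.DataFrame(meta), n_flank, body_bins, n_flank)


def summit_matrix(signal: SignalTrack, peaks: list[Peak], flank: int = 1000) -> MetageneMatrix:
    """Raw bin windows of ±``flank`` bp centered on peak summits (no resampling)."""
    bs = signal.bin_size
    n = flank // bs
    rows, meta = [], []
    for p in peaks:
        arr = signal.values[p.scaffold]
        c = p.summit // bs
        rows.append(_slice_bins(arr, c - n, c + n))
        meta.append({"id": f"{p.scaffold}:{p.start}-{p.end}", "scaffold": p.scaffold,
                     "sex": p.sex, "summit": p.summit})
    return MetageneMatrix(np.array(rows), pd.DataFrame(meta), n, 0, n)


def profile_ci(matrix: MetageneMatrix | np.ndarray, n_boot: int = 1000,
               level: float = 0.99, seed: int = 0) -> pd.DataFrame:
    """Column means with percentile bootstrap confidence bounds over rows.

    Rows are resampled with replacement (resample size = row count, matching
    the number of genes in each resampled set); NaN cells are excluded per
    column.  The reported mean is the plain column mean — the bootstrap
    affects the bounds only.
    """
    vals = matrix.values if isinstance(matrix, MetageneMatrix) else np.asarray(matrix, float)
    if vals.shape[0] < 2:
        raise ValueError("profile CI needs at least 2 rows")
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n_rows = vals.shape[0]
    finite = np.isfinite(vals)
    filled = np.where(finite, vals, 0.0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(filled, axis=0) / finite.sum(axis=0)
    # multinomial row weights make each bootstrap replicate a matrix product
    weights = rng.multinomial(n_rows, np.full(n_rows, 1.0 / n_rows), size=n_boot)
    boot_sums = weights @ filled
    boot_ns = weights @ finite.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot_means = boot_sums / boot_ns
    alpha = (1.0 - level) / 2.0
    lo = np.nanquantile(boot_means, alpha, axis=0)
    hi = np.nanquantile(boot_means, 1.0 - alpha, axis=0)
    out = pd.DataFrame({"mean": mean, "lower": lo, "upper": hi,
                        "n": finite.sum(axis=0)})
    out.attrs.update({"n_boot": n_boot, "level": level, "seed": seed})
    return out


def expression_rank_order(matrix: MetageneMatrix, expression: pd.Series) -> np.ndarray:
    """Row ordering for expression-ranked heatmaps.

    Rows are sorted by descending expression within each chromosome class
    (classes in X-then-A blocks as plotted), ties broken by gene id.
    """
    meta = matrix.meta.copy()
    meta["expression"] = expression.reindex(meta["id"]).to_numpy()
    if meta["expression"].isna().any():
        raise ValueError("expression undefined for some rows")
    meta["_pos"] = np.arange(len(meta))
    meta = meta.sort_values(["chrom_class", "expression", "id"],
                            ascending=[True, False, True], kind="stable")
    return meta["_pos"].to_numpy()


def plot_heatmap(matrix: MetageneMatrix, order: np.ndarray, path, vmax: float | None = None):
    """Render an expression-ranked profile heatmap to ``path`` (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(matrix.values[order], aspect="auto", interpolation="nearest",
                   cmap="viridis", vmax=vmax)
    ax.set_xlabel("profile bin (5'->3')")
    ax.set_ylabel("genes (ranked by expression)")
    fig.colorbar(im, ax=ax, label="signal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile(ci_tables: dict[str, pd.DataFrame], path, title: str = ""):
    """Render mean ± CI profile curves (one per labeled table) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, tab in ci_tables.items():
        x = np.arange(len(tab))
        ax.plot(x, tab["mean"], label=label)
        ax.fill_between(x, tab["lower"], tab["upper"], alpha=0.25)
    ax.set_xlabel("profile bin")
    ax.set_ylabel("signal")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def library_correlation(coverage: dict[str, SignalTrack],
                        union_peaks: list[tuple[str, int, int]]):
    """Pearson correlation of per-library bin coverage over union-peak bins.

    Returns (correlation DataFrame, average-linkage table on 1 − r).
    A zero-variance library vector is an error naming the library.
    """
    if len(coverage) < 2:
        raise ValueError("need at least two libraries")
    names = list(coverage)
    bs = next(iter(coverage.values())).bin_size
    idx: dict[str, np.ndarray] = {}
    for scaf, start, end in union_peaks:
        b = np.arange(start // bs, -(-end // bs))
        idx[scaf] = np.union1d(idx.get(scaf, np.empty(0, dtype=int)), b)
    vectors = []
    for name in names:
        t = coverage[name]
        v = np.concatenate([t.values[scaf][idx[scaf]] for scaf in sorted(idx)])
        if np.std(v) == 0:
            raise ValueError(f"library {name!r} has zero variance over peak bins")
        vectors.append(v)
    r = np.corrcoef(np.array(vectors))
    r_df = pd.DataFrame(r, index=names, columns=names)
    dist = squareform(np.clip(1.0 - r, 0.0, None), checks=False)
    return r_df, linkage(dist, method="average")
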