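"""Between-library (TMM) and within-library (CPM/RPKM/TPM) normalization.

TMM follows Robinson & Oshlack: pairwise log-ratios (M) against a reference
library, trimmed by 30% on M and 5% on A, combined by precision (inverse
asymptotic variance) weighting, with factors rescaled to geometric mean 1.
The reference library is the one whose upper-quartile CPM is closest to the
mean upper quartile across libraries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

MORPHS = ("male", "female")


@dataclass
class ExpressionMatrix:
    """Genes × libraries expression values with a unit tag and library→morph map."""

    values: pd.DataFrame
    unit: str  # counts | cpm | rpkm | tpm
    morphs: dict[str, str] = field(default_factory=dict)  # library -> male | female

    def __post_init__(self):
        for lib, morph in self.morphs.items():
            if morph not in MORPHS:
                raise ValueError(f"library {lib}: unknown morph {morph!r}")
            if lib not in self.values.columns:
                raise ValueError(f"morph map names unknown library {lib!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    def libraries(self, morph: str | None = None) -> list[str]:
        if morph is None:
            return list(self.values.columns)
        return [c for c in self.values.columns if self.morphs.get(c) == morph]


# ---------------------------------------------------------------------------
# TMM


def _quantile_depth_factor(counts: np.ndarray, lib_sizes: np.ndarray, p: float = 0.75):
    return np.quantile(counts / lib_sizes, p, axis=0)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """Trimmed, precision-weighted mean of M-values of one library against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, ref_library: str | None = None) -> pd.Series:
    """Per-library TMM scaling factors with geometric mean 1.

    Genes with a zero count in either compared library are excluded pairwise.
    A library with all-zero counts is an error.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    lib_sizes = x.sum(axis=0)
    if (lib_sizes == 0).any():
        bad = counts.columns[lib_sizes == 0].tolist()
        raise ValueError(f"library with all-zero counts: {bad}")
    if ref_library is None:
        f75 = _quantile_depth_factor(x, lib_sizes)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_library)
    factors = np.array([
        _tmm_pair(x[:, j], x[:, ref_idx], lib_sizes[j], lib_sizes[ref_idx])
        for j in range(x.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# unit conversion


def normalize(counts: pd.DataFrame, lengths_kb: pd.Series | None = None,
              unit: str = "tpm", use_tmm: bool = True,
              morphs: dict[str, str] | None = None) -> ExpressionMatrix:
    """Convert raw counts to CPM, RPKM or TPM.

    Effective depth is library size × TMM factor when ``use_tmm``; RPKM and
    TPM additionally divide by exonic gene length (kb).  TPM columns each sum
    to 10⁶ by construction.
    """
    unit = unit.lower()
    if unit not in ("cpm", "rpkm", "tpm"):
        raise ValueError(f"unknown unit {unit!r}")
    x = counts.to_numpy(dtype=float)
    depth = x.sum(axis=0)
    if (depth == 0).any():
        raise ValueError("library with all-zero counts")
    if use_tmm:
        depth = depth * tmm_factors(counts).to_numpy()
    if unit in ("rpkm", "tpm"):
        if lengths_kb is None:
            raise ValueError(f"unit {unit!r} requires gene lengths")
        lens = lengths_kb.reindex(counts.index).to_numpy(dtype=float)
        if np.isnan(lens).any() or (lens <= 0).any():
            raise ValueError("missing or non-positive gene length")
    if unit == "cpm":
        vals = x * 1e6 / depth
    elif unit == "rpkm":
        vals = x * 1e6 / depth / lens[:, None]
    else:  # tpm: length-normalized rate, renormalized to 1e6 per library
        rate = x / depth / lens[:, None]
        vals = rate * 1e6 / rate.sum(axis=0)
    out = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(out, unit=unit, morphs=dict(morphs or {}))


def cpm(counts: pd.DataFrame, use_tmm: bool = False) -> pd.DataFrame:
    """Plain counts-per-million (raw library depth unless ``use_tmm``)."""
    return normalize(counts, unit="cpm", use_tmm=use_tmm).values


def morph_mean(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene arithmetic mean per morph plus the joint mean of the two morph means."""
    cols = {}
    for morph in MORPHS:
        libs = expr.libraries(morph)
        if not libs:
            raise ValueError(f"no libraries labeled {morph!r}")
        cols[morph] = expr.values[libs].mean(axis=1)
    out = pd.DataFrame(cols)
    out["joint"] = (out["male"] + out["female"]) / 2.0
    return out
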