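"""X-to-autosome expression ratios, threshold sweeps and the compensation criterion.

The ratio statistic is the ratio of per-gene expression medians (X over A),
compared distributionally with a two-sided Wilcoxon rank-sum test.  A morph
is called dosage compensated at a filter threshold when its X/A ratio lies
in [0.95, 1.05] and the rank-sum p exceeds 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .norm import ExpressionMatrix, morph_mean

RATIO_LO, RATIO_HI, ALPHA = 0.95, 1.05, 0.05


def wilcoxon_rank_sum(x, y, exact_max_n: int = 50) -> float:
    """Two-sided rank-sum p: exact enumeration for small untied samples,
    normal approximation with tie and continuity correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and not has_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def xa_ratio(values: pd.Series, chrom_class: pd.Series,
             statistic: str = "median") -> tuple[float, float, int, int]:
    """(ratio, wilcoxon_p, n_X, n_A) of per-gene expression for one morph.

    ``values`` is already filtered to the genes under consideration; an empty
    chromosome class yields a NaN ratio and p.
    """
    cls = chrom_class.reindex(values.index)
    x = values[cls == "X"].to_numpy()
    a = values[cls == "A"].to_numpy()
    if len(x) == 0 or len(a) == 0:
        return float("nan"), float("nan"), len(x), len(a)
    stat = np.median if statistic == "median" else np.mean
    denom = stat(a)
    ratio = float(stat(x) / denom) if denom > 0 else float("nan")
    p = wilcoxon_rank_sum(x, a)
    return ratio, p, len(x), len(a)


def compensation_call(ratio: float, p: float,
                      lo: float = RATIO_LO, hi: float = RATIO_HI,
                      alpha: float = ALPHA) -> bool:
    """True iff the X/A ratio lies in [lo, hi] and the rank-sum p exceeds alpha."""
    if np.isnan(ratio) or np.isnan(p):
        return False
    return bool(lo <= ratio <= hi and p > alpha)


def threshold_sweep(expr: ExpressionMatrix, chrom_class: pd.Series, thresholds,
                    filter_mode: str = "per_morph",
                    statistic: str = "median") -> pd.DataFrame:
    """X/A ratio, rank-sum p, retained counts and compensation call per threshold.

    ``joint_mean`` filters all morphs on the joint male+female mean exceeding
    the threshold; ``per_morph`` filters each morph on its own mean.  Rows
    where a chromosome class empties out carry NaN ratios and a flag.
    """
    if filter_mode not in ("joint_mean", "per_morph"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    means = morph_mean(expr)
    rows = []
    for t in thresholds:
        for morph in ("male", "female"):
            key = "joint" if filter_mode == "joint_mean" else morph
            retained = means.index[means[key] > t]
            ratio, p, n_x, n_a = xa_ratio(means.loc[retained, morph], chrom_class,
                                          statistic=statistic)
            rows.append({
                "threshold": t, "filter_mode": filter_mode, "morph": morph,
                "ratio": ratio, "wilcoxon_p": p, "n_X": n_x, "n_A": n_a,
                "compensated": compensation_call(ratio, p),
                "undefined": bool(np.isnan(ratio)),
            })
    return pd.DataFrame(rows)


def class_ratio_summary(expr: ExpressionMatrix, classes: pd.DataFrame,
                        chrom_class: pd.Series) -> pd.DataFrame:
    """Per expression class (all expressed, male/female-biased, unbiased):
    per-morph median log2(RPKM+1) by chromosome class, linear-scale X/A
    ratio, rank-sum p and gene counts.
    """
    labels = classes["label"].reindex(expr.values.index)
    means = morph_mean(expr)
    groups = {
        "all_expressed": labels.index[labels != "unexpressed"],
        "male_biased": labels.index[labels == "male_biased"],
        "female_biased": labels.index[labels == "female_biased"],
        "unbiased": labels.index[labels == "unbiased"],
    }
    cls = chrom_class.reindex(expr.values.index)
    rows = []
    for name, idx in groups.items():
        for morph in ("male", "female"):
            vals = means.loc[idx, morph]
            ratio, p, n_x, n_a = xa_ratio(vals, chrom_class)
            logx = np.log2(vals[cls.reindex(idx) == "X"] + 1.0)
            loga = np.log2(vals[cls.reindex(idx) == "A"] + 1.0)
            rows.append({
                "class": name, "morph": morph,
                "median_log2_X": float(np.median(logx)) if len(logx) else float("nan"),
                "median_log2_A": float(np.median(loga)) if len(loga) else float("nan"),
                "ratio": ratio, "wilcoxon_p": p, "n_X": n_x, "n_A": n_a,
                "empty": bool(len(idx) == 0),
            })
    return pd.DataFrame(rows)


def parse_thresholds(spec: str) -> list[float]:
    """Parse a CLI threshold spec: ``"1:100:1"`` (start:stop:step, inclusive)
    or an explicit comma list ``"0,1,2,3,4"``."""
    if ":" in spec:
        start, stop, step = (float(x) for x in spec.split(":"))
        return list(np.arange(start, stop + step / 2, step))
    return [float(x) for x in spec.split(",")]
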