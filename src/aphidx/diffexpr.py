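"""Four-way gene classification: unexpressed / male-biased / female-biased / unbiased.

Biased classes come from a genewise conditional exact test for a difference
in means between two groups of negative-binomially distributed counts
(common dispersion, variance μ + φμ²), with Benjamini–Hochberg control at
FDR < 0.05.  A gene is *unexpressed* when fewer than 1 count per million is
observed in at least ``min_low_libraries`` of the libraries (3 of 6 by
default), and that label takes precedence over the test outcome.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

from .norm import cpm, tmm_factors

LABELS = ("unexpressed", "male_biased", "female_biased", "unbiased")


def flag_unexpressed(counts: pd.DataFrame, min_cpm: float = 1.0,
                     min_low_libraries: int = 3) -> pd.Series:
    """True for genes with CPM < ``min_cpm`` in at least ``min_low_libraries`` libraries."""
    low = (cpm(counts) < min_cpm).sum(axis=1)
    return (low >= min_low_libraries).rename("unexpressed")


def _group_columns(counts: pd.DataFrame, groups: dict[str, str]):
    labels = sorted({g for g in groups.values()})
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    cols = {lab: [c for c in counts.columns if groups.get(c) == lab] for lab in labels}
    return labels, cols


def equalize_depth(counts: pd.DataFrame, use_tmm: bool = True) -> pd.DataFrame:
    """Rescale each library to the geometric-mean effective depth (round half-to-even)."""
    depth = counts.sum(axis=0).to_numpy(dtype=float)
    if use_tmm:
        depth = depth * tmm_factors(counts).to_numpy()
    target = np.exp(np.mean(np.log(depth)))
    scaled = counts.to_numpy(dtype=float) * (target / depth)
    return pd.DataFrame(np.round(scaled).astype(np.int64),
                        index=counts.index, columns=counts.columns)


def common_dispersion(counts: pd.DataFrame, groups: dict[str, str],
                      use_tmm: bool = True) -> float:
    """Single moment-matched NB dispersion φ from within-group variability.

    On depth-equalized counts, E[s²] = μ + φμ² within a group; φ is the
    ratio-of-sums estimate pooled over genes and groups,
    Σ(s² − m) / Σ(m² − s²/n), clipped at 0.
    """
    _, cols = _group_columns(counts, groups)
    eq = equalize_depth(counts, use_tmm=use_tmm)
    num = 0.0
    den = 0.0
    any_replicated = False
    for libs in cols.values():
        if len(libs) < 2:
            continue
        any_replicated = True
        x = eq[libs].to_numpy(dtype=float)
        m = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        num += float(np.sum(s2 - m))
        den += float(np.sum(np.maximum(m ** 2 - s2 / len(libs), 0.0)))
    if not any_replicated:
        raise ValueError("dispersion estimation needs >= 2 replicates in some group")
    if den == 0.0:
        return 0.0
    return max(num / den, 0.0)


def _exact_p(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Conditional two-sided exact p for a split (y1, y2) of t = y1 + y2 reads.

    Under equal means the group sums are NB with sizes n1/φ, n2/φ (Poisson
    in the φ → 0 limit); conditioning on t, p is the total probability of
    splits no more probable than the observed one.
    """
    t = y1 + y2
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi <= 0:
        logf = binom.logpmf(a, t, n1 / (n1 + n2))  # Poisson limit: conditional is binomial
        log_z = 0.0
    else:
        r1, r2 = n1 / phi, n2 / phi
        mu = t / (n1 + n2)
        p1 = r1 / (r1 + n1 * mu)
        p2 = r2 / (r2 + n2 * mu)
        logf = nbinom.logpmf(a, r1, p1) + nbinom.logpmf(t - a, r2, p2)
        log_z = logsumexp(logf)
    obs = logf[y1]
    keep = logf <= obs + 1e-10
    return float(min(np.exp(logsumexp(logf[keep]) - log_z), 1.0))


def nb_exact_test(counts: pd.DataFrame, groups: dict[str, str], phi: float,
                  use_tmm: bool = True) -> pd.Series:
    """Two-sided NB exact-test p-value per gene (depth-equalized group sums)."""
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    labels, cols = _group_columns(counts, groups)
    eq = equalize_depth(counts, use_tmm=use_tmm)
    y1 = eq[cols[labels[0]]].sum(axis=1).to_numpy()
    y2 = eq[cols[labels[1]]].sum(axis=1).to_numpy()
    n1, n2 = len(cols[labels[0]]), len(cols[labels[1]])
    pvals = np.array([_exact_p(int(a), int(b), n1, n2, phi) for a, b in zip(y1, y2)])
    return pd.Series(pvals, index=counts.index, name="p_value")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in p-rank)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify(counts: pd.DataFrame, groups: dict[str, str], phi: float | None = None,
             fdr: float = 0.05, use_tmm: bool = True, min_cpm: float = 1.0,
             min_low_libraries: int = 3) -> pd.DataFrame:
    """Full classification table: label, p, q, log2 fold change (male / female).

    Precedence: *unexpressed* first; then q < ``fdr`` with the male group
    higher → male_biased, lower → female_biased; everything else unbiased
    (q == fdr exactly is unbiased — the threshold is a strict inequality).
    """
    if phi is None:
        phi = common_dispersion(counts, groups, use_tmm=use_tmm)
    unexpr = flag_unexpressed(counts, min_cpm=min_cpm, min_low_libraries=min_low_libraries)
    p = nb_exact_test(counts, groups, phi, use_tmm=use_tmm)
    q = pd.Series(bh_fdr(p.to_numpy()), index=p.index, name="q_value")

    labels_, cols = _group_columns(counts, groups)
    eq = equalize_depth(counts, use_tmm=use_tmm)
    means = {lab: eq[libs].mean(axis=1) for lab, libs in cols.items()}
    male_lab = "male" if "male" in means else labels_[0]
    female_lab = [lab for lab in means if lab != male_lab][0]
    logfc = np.log2((means[male_lab] + 0.5) / (means[female_lab] + 0.5))
    direction = np.sign(means[male_lab] - means[female_lab])

    label = np.where(
        unexpr, "unexpressed",
        np.where((q < fdr) & (direction > 0), "male_biased",
                 np.where((q < fdr) & (direction < 0), "female_biased", "unbiased")),
    )
    return pd.DataFrame({
        "label": label,
        "p_value": p,
        "q_value": q,
        "log2fc_male_vs_female": logfc,
        "direction": direction,
    }, index=counts.index)
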