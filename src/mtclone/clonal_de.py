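"""Clonal differential expression: Wilcoxon DE and the equal-group bootstrap.

Two procedures share one result schema:

- :func:`wilcoxon_de` is a single-pass rank-sum comparison with the usual
  single-cell conventions: genes must be detected in at least ``min_pct`` of
  one group and show |log2FC| above a threshold before testing; p-values are
  BH-adjusted over the tested genes. log2FC is computed on library-size-
  normalized (scale 10,000) group means with pseudocount 1.

- :func:`bootstrapped_de` addresses badly unbalanced comparisons (a small
  clone against a large background): each of ``n_iter`` iterations
  subsamples the larger group without replacement down to the smaller
  group's size (normalization recomputed on the subsample), reruns the
  Wilcoxon pass, and aggregates mean log2FC, mean adjusted p and the
  frequency of significance. A gene is *robust* when it is significant
  (adjusted p < 0.05) in at least half the iterations and its mean |log2FC|
  exceeds 0.25.

Rank-sum p-values use the normal approximation with tie correction except
for very small groups without ties, where the exact null distribution is
enumerated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from ._rng import substream
from .io_formats import ExpressionMatrix
from .snv_concordance import bh_adjust

__all__ = ["wilcoxon_de", "bootstrapped_de", "select_top_overlap"]

_NORM_SCALE = 1e4

_COLUMNS = [
    "gene_id",
    "mean_log2fc",
    "mean_adj_p",
    "freq_significant",
    "robust",
    "pct_group1",
    "pct_group2",
]


def _check_groups(em: ExpressionMatrix, group1, group2) -> tuple[list[str], list[str]]:
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    overlap = set(g1) & set(g2)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    known = set(em.cell_ids)
    missing = [c for c in g1 + g2 if c not in known]
    if missing:
        raise KeyError(f"cells absent from expression matrix: {missing[:5]}")
    return g1, g2


def _normalized(em: ExpressionMatrix, rows: np.ndarray) -> np.ndarray:
    """Library-size normalize the selected cells (dense, cells x genes)."""
    X = np.asarray(em.counts[rows].todense(), dtype=float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return X / lib * _NORM_SCALE


def _rank_sum_p(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = len(x1), len(x2)
    pooled = np.concatenate([x1, x2])
    exact = max(n1, n2) <= 8 and len(np.unique(pooled)) == len(pooled)
    res = mannwhitneyu(
        x1, x2, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def wilcoxon_de(
    em: ExpressionMatrix,
    group1,
    group2,
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    positive_only: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-pass Wilcoxon rank-sum differential expression.

    Returns one row per *tested* gene with log2 fold-change (group1 over
    group2), BH-adjusted p, detection fractions, and a significance flag
    (``robust`` = adjusted p below ``alpha`` and |log2FC| > 0.25).
    """
    g1, g2 = _check_groups(em, group1, group2)
    cell_index = {c: i for i, c in enumerate(em.cell_ids)}
    r1 = np.array([cell_index[c] for c in g1])
    r2 = np.array([cell_index[c] for c in g2])

    X1, X2 = _normalized(em, r1), _normalized(em, r2)
    pct1 = (X1 > 0).mean(axis=0)
    pct2 = (X2 > 0).mean(axis=0)
    log2fc = np.log2(X1.mean(axis=0) + 1.0) - np.log2(X2.mean(axis=0) + 1.0)

    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(log2fc) > logfc_threshold)
    if positive_only:
        tested &= log2fc > 0
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(columns=_COLUMNS)

    pvals = np.array([_rank_sum_p(X1[:, j], X2[:, j]) for j in idx])
    adj = bh_adjust(pvals)
    sig = adj < alpha
    return pd.DataFrame(
        {
            "gene_id": [em.gene_ids[j] for j in idx],
            "mean_log2fc": log2fc[idx],
            "mean_adj_p": adj,
            "freq_significant": sig.astype(float),
            "robust": sig & (np.abs(log2fc[idx]) > 0.25),
            "pct_group1": pct1[idx],
            "pct_group2": pct2[idx],
        }
    )


def bootstrapped_de(
    em: ExpressionMatrix,
    group1,
    group2,
    n_iter: int = 100,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    positive_only: bool = True,
    alpha: float = 0.05,
    with_replacement: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Equal-group bootstrapped Wilcoxon DE for unbalanced comparisons.

    Each iteration samples the larger group (without replacement by default)
    down to the smaller group's size and reruns :func:`wilcoxon_de` on the
    subsample. Per-gene aggregates over all iterations: mean log2FC (over
    every iteration, tested or not), mean adjusted p (untested iterations
    count as 1), and the fraction of iterations significant. ``robust``
    requires significance in at least half the iterations and mean |log2FC|
    above 0.25.
    """
    g1, g2 = _check_groups(em, group1, group2)
    n_small = min(len(g1), len(g2))
    if n_small < 3:
        raise ValueError(f"smaller group has {n_small} cells; need at least 3")
    rng = substream(seed, "bootstrap-de")
    cell_index = {c: i for i, c in enumerate(em.cell_ids)}
    genes = list(em.gene_ids)
    n_genes = len(genes)

    sum_lfc = np.zeros(n_genes)
    sum_adj = np.zeros(n_genes)
    n_sig = np.zeros(n_genes)
    for _ in range(n_iter):
        s1 = list(rng.choice(g1, size=n_small, replace=with_replacement)) if len(g1) > n_small else g1
        s2 = list(rng.choice(g2, size=n_small, replace=with_replacement)) if len(g2) > n_small else g2
        r1 = np.array([cell_index[c] for c in s1])
        r2 = np.array([cell_index[c] for c in s2])
        X1, X2 = _normalized(em, r1), _normalized(em, r2)
        lfc = np.log2(X1.mean(axis=0) + 1.0) - np.log2(X2.mean(axis=0) + 1.0)
        sum_lfc += lfc
        pct = np.maximum((X1 > 0).mean(axis=0), (X2 > 0).mean(axis=0))
        tested = (pct >= min_pct) & (np.abs(lfc) > logfc_threshold)
        if positive_only:
            tested &= lfc > 0
        idx = np.flatnonzero(tested)
        adj_full = np.ones(n_genes)
        if idx.size:
            pvals = np.array([_rank_sum_p(X1[:, j], X2[:, j]) for j in idx])
            adj_full[idx] = bh_adjust(pvals)
        sum_adj += adj_full
        n_sig += adj_full < alpha

    mean_lfc = sum_lfc / n_iter
    freq = n_sig / n_iter
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_log2fc": mean_lfc,
            "mean_adj_p": sum_adj / n_iter,
            "freq_significant": freq,
            "robust": (freq >= 0.5) & (np.abs(mean_lfc) > 0.25),
            "pct_group1": np.asarray((em.counts[np.array([cell_index[c] for c in g1])] > 0).mean(axis=0)).ravel(),
            "pct_group2": np.asarray((em.counts[np.array([cell_index[c] for c in g2])] > 0).mean(axis=0)).ravel(),
        }
    )
    return out


def select_top_overlap(
    dysp_vs_be: pd.DataFrame, clonal: pd.DataFrame, n_top: int = 10
) -> list[str]:
    """Top overlapping genes between the two DE analyses.

    Intersects the significant genes of both tables (``robust`` flag), ranks
    by the clonal analysis's mean adjusted p ascending with ties broken by
    |mean log2FC| descending then gene id, and returns the first ``n_top``.
    """
    sig1 = set(dysp_vs_be.loc[dysp_vs_be["robust"], "gene_id"])
    sig2 = clonal.loc[clonal["robust"]].copy()
    overlap = sig2[sig2["gene_id"].isin(sig1)]
    if overlap.empty:
        return []
    overlap = overlap.assign(_abs_lfc=overlap["mean_log2fc"].abs())
    overlap = overlap.sort_values(
        ["mean_adj_p", "_abs_lfc", "gene_id"], ascending=[True, False, True]
    )
    return overlap["gene_id"].head(n_top).tolist()
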