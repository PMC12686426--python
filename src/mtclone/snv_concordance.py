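"""Nuclear-SNV concordance validation of mitochondrial clone calls.

Clone membership inferred from mitochondrial heteroplasmy is checked against
independent nuclear evidence: per-cell SNV read counts from scRNA-seq. For
each SNV surviving depth/cell filters, Otsu's method splits cells into high-
and low-VAF groups, a 2x2 contingency table of clone membership against VAF
state is tested with Fisher's exact test (two-sided), and p-values are BH
adjusted. The control group is deliberately restricted to non-clone cells
from the same (sample, cell type) strata as the clone, and the whole
analysis is re-run under stratified label permutations to provide an
empirical null.

Conventions surfaced here because the procedure leaves them open: cells with
zero informative reads at an SNV are excluded from that SNV's table (their
VAF is undefined) rather than counted as low-VAF, and "two-sided" Fisher
means summing hypergeometric point probabilities no larger than the observed
table's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .io_formats import CellAnnotation, SNVCountTable

__all__ = [
    "SNVTestResult",
    "OtsuResult",
    "PermutationNull",
    "filter_snvs",
    "build_matched_control",
    "otsu_vaf_threshold",
    "fisher_exact_2x2",
    "bh_adjust",
    "snv_concordance_test",
    "stratified_permutation_null",
]


class OtsuResult(NamedTuple):
    threshold: float
    degenerate: bool


@dataclass
class SNVTestResult:
    snv_id: str
    otsu_threshold: float
    contingency: np.ndarray  # rows: clone/non-clone, cols: high/low VAF
    fisher_p: float
    bh_q: float
    n_cells_used: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.contingency = np.asarray(self.contingency, dtype=np.int64)
        if self.contingency.shape != (2, 2) or (self.contingency < 0).any():
            raise ValueError("contingency must be a non-negative 2x2 table")
        if int(self.contingency.sum()) != self.n_cells_used:
            raise ValueError("contingency total differs from n_cells_used")
        for p in (self.fisher_p, self.bh_q):
            if not 0.0 <= p <= 1.0:
                raise ValueError("p/q outside [0, 1]")


@dataclass
class PermutationNull:
    """Stratified permutation null for the SNV concordance analysis."""

    null_p: pd.DataFrame  # SNVs x iterations of Fisher p-values
    frac_null_le_obs: pd.Series  # per SNV: fraction of null p <= observed p
    observed_p: pd.Series
    n_permutations: int

    def pooled(self) -> np.ndarray:
        return self.null_p.to_numpy().ravel()


def filter_snvs(
    t: SNVCountTable, min_depth: int = 3, min_cells: int = 4
) -> SNVCountTable:
    """Depth and recurrence filters.

    Drops (cell, SNV) records with fewer than ``min_depth`` informative
    reads, then drops SNVs expressed (alt > 0) in fewer than ``min_cells`` of
    the remaining cells.
    """
    df = t.records
    df = df[(df["ref_reads"] + df["alt_reads"]) >= min_depth]
    expressed = df[df["alt_reads"] > 0].groupby("snv_id")["cell_id"].nunique()
    keep = set(expressed.index[expressed >= min_cells])
    return SNVCountTable(df[df["snv_id"].isin(keep)].reset_index(drop=True))


def build_matched_control(
    ann: CellAnnotation, clone_cells: set[str]
) -> tuple[list[str], list[str]]:
    """Clone cells and their stratum-matched controls.

    Controls are all non-clone cells whose (sample, cell type) pair occurs
    among the clone cells, so sample- and cell-type-specific expression
    cannot masquerade as clonal signal.
    """
    idx = ann.indexed()
    missing = [c for c in clone_cells if c not in idx.index]
    if missing:
        raise KeyError(f"clone cells absent from annotation: {missing[:5]}")
    group1 = sorted(clone_cells)
    strata = {
        (idx.loc[c, "sample_id"], idx.loc[c, "cell_type"]) for c in group1
    }
    pairs = list(zip(idx["sample_id"], idx["cell_type"]))
    in_strata = pd.Series([p in strata for p in pairs], index=idx.index)
    group2 = sorted(idx.index[in_strata & ~idx.index.isin(group1)])
    if not group2:
        raise ValueError("no control cells share a (sample, cell type) stratum with the clone")
    return group1, group2


def otsu_vaf_threshold(
    vafs, nbins: int = 256, method: str = "histogram"
) -> OtsuResult:
    """Otsu's threshold on VAFs.

    ``method='histogram'`` (default) maximizes between-class variance over a
    fixed ``nbins``-level histogram of [0, 1], the image-processing
    convention; ``method='exact'`` searches all midpoints between sorted
    distinct values, minimizing intra-class variance directly. Both split
    cells into low (vaf <= threshold) and high (vaf > threshold). A constant
    input has no threshold: its value is returned flagged degenerate.
    """
    v = np.asarray(vafs, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two VAF values")
    if ((v < 0) | (v > 1)).any():
        raise ValueError("VAF outside [0, 1]")
    if np.ptp(v) == 0:
        return OtsuResult(float(v[0]), True)

    if method == "histogram":
        hist, edges = np.histogram(v, bins=nbins, range=(0.0, 1.0))
        w = hist / hist.sum()
        centers = 0.5 * (edges[:-1] + edges[1:])
        w0 = np.cumsum(w)[:-1]
        w1 = 1.0 - w0
        m0 = np.cumsum(w * centers)[:-1]
        mtot = float((w * centers).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            mu0 = m0 / w0
            mu1 = (mtot - m0) / w1
            between = w0 * w1 * (mu0 - mu1) ** 2
        between[~np.isfinite(between)] = -np.inf
        cut = int(np.argmax(between))  # ties: lowest cut
        return OtsuResult(float(edges[cut + 1]), False)
    if method == "exact":
        u = np.unique(v)
        cuts = 0.5 * (u[:-1] + u[1:])
        best, best_obj = cuts[0], np.inf
        for c in cuts:
            lo, hi = v[v <= c], v[v > c]
            obj = (len(lo) * lo.var() + len(hi) * hi.var()) / v.size
            if obj < best_obj - 1e-15:
                best, best_obj = c, obj
        return OtsuResult(float(best), False)
    raise ValueError(f"unknown Otsu method {method!r}")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities no larger than the observed table's.
    A zero row or column margin leaves no association to test: p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(min(_scipy_fisher(t, alternative="two-sided")[1], 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _test_one_snv(
    sub: pd.DataFrame, group1: set[str], nbins: int, otsu_method: str
) -> tuple[float, np.ndarray, float, bool]:
    vaf = (sub["alt_reads"] / (sub["ref_reads"] + sub["alt_reads"])).to_numpy()
    in_clone = sub["cell_id"].isin(group1).to_numpy()
    if len(vaf) < 2 or in_clone.all() or not in_clone.any():
        return float("nan"), np.zeros((2, 2), dtype=np.int64), 1.0, True
    thr, degenerate = otsu_vaf_threshold(vaf, nbins=nbins, method=otsu_method)
    high = vaf > thr
    table = np.array(
        [
            [int((in_clone & high).sum()), int((in_clone & ~high).sum())],
            [int((~in_clone & high).sum()), int((~in_clone & ~high).sum())],
        ]
    )
    return thr, table, fisher_exact_2x2(table), degenerate


def snv_concordance_test(
    t: SNVCountTable,
    ann: CellAnnotation,
    clone_cells: set[str],
    nbins: int = 256,
    otsu_method: str = "histogram",
) -> list[SNVTestResult]:
    """Otsu + Fisher + BH concordance test for every SNV in the table.

    Cells outside the matched clone/control groups (and cells without
    informative reads at an SNV) do not enter that SNV's table.
    """
    group1, group2 = build_matched_control(ann, set(clone_cells))
    used = set(group1) | set(group2)
    g1 = set(group1)

    df = t.records[t.records["cell_id"].isin(used)]
    rows = []
    for snv_id, sub in df.groupby("snv_id", sort=True):
        thr, table, p, degenerate = _test_one_snv(sub, g1, nbins, otsu_method)
        rows.append((snv_id, thr, table, p, int(table.sum()), degenerate))
    if not rows:
        return []
    qs = bh_adjust([r[3] for r in rows])
    return [
        SNVTestResult(
            snv_id=snv_id,
            otsu_threshold=thr,
            contingency=table,
            fisher_p=p,
            bh_q=float(q),
            n_cells_used=n_used,
            degenerate=degenerate,
        )
        for (snv_id, thr, table, p, n_used, degenerate), q in zip(rows, qs)
    ]


def stratified_permutation_null(
    t: SNVCountTable,
    ann: CellAnnotation,
    clone_cells: set[str],
    n_perm: int = 100,
    seed: int = 0,
    nbins: int = 256,
    otsu_method: str = "histogram",
) -> PermutationNull:
    """Stratified permutation null for the concordance analysis.

    Per iteration, clone/control labels are reshuffled uniformly *within*
    each (sample, cell type) stratum, preserving per-stratum group sizes, and
    the Otsu + Fisher analysis is rerun per SNV. Returns the per-SNV null
    p-value matrix and, per SNV, the fraction of null p-values at or below
    the observed one.
    """
    group1, group2 = build_matched_control(ann, set(clone_cells))
    used = sorted(set(group1) | set(group2))
    idx = ann.indexed().loc[used]
    strata = list(zip(idx["sample_id"], idx["cell_type"]))
    in_clone = pd.Series([c in set(group1) for c in used], index=used)

    # validate stratum capacity
    sdf = pd.DataFrame({"stratum": strata, "in_clone": in_clone.to_numpy()}, index=used)
    for s, grp in sdf.groupby("stratum"):
        if grp["in_clone"].sum() > len(grp):
            raise ValueError(f"stratum {s} smaller than its clone-cell count")

    df = t.records[t.records["cell_id"].isin(set(used))]
    snv_ids = sorted(df["snv_id"].unique())
    observed = {}
    for snv_id, sub in df.groupby("snv_id", sort=True):
        _, _, p, _ = _test_one_snv(sub, set(group1), nbins, otsu_method)
        observed[snv_id] = p

    rng = substream(seed, "snv-permutation")
    null = np.ones((len(snv_ids), n_perm))
    groups = df.groupby("snv_id", sort=True)
    for it in range(n_perm):
        perm_clone: set[str] = set()
        for s, grp in sdf.groupby("stratum"):
            cells = grp.index.to_numpy()
            k = int(grp["in_clone"].sum())
            perm_clone.update(rng.choice(cells, size=k, replace=False))
        for si, snv_id in enumerate(snv_ids):
            sub = groups.get_group(snv_id)
            _, _, p, _ = _test_one_snv(sub, perm_clone, nbins, otsu_method)
            null[si, it] = p

    null_df = pd.DataFrame(null, index=pd.Index(snv_ids, name="snv_id"))
    obs = pd.Series(observed).loc[snv_ids]
    frac = pd.Series(
        [(null_df.loc[s] <= obs[s]).mean() for s in snv_ids],
        index=pd.Index(snv_ids, name="snv_id"),
        name="frac_null_le_obs",
    )
    return PermutationNull(
        null_p=null_df, frac_null_le_obs=frac, observed_p=obs, n_permutations=n_perm
    )
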