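"""Clone inference from the single-cell heteroplasmy matrix.

Cells are clustered on their allele-frequency profiles over the significant
variants: a k-nearest-neighbor graph under cosine distance is converted to a
shared-nearest-neighbor (SNN) graph with Jaccard edge weights (the Seurat
convention, pruning below 1/15), and communities are found by seeded Leiden
optimization of Reichardt-Bornholdt configuration-null modularity with a
resolution parameter. Cells whose profile is entirely zero (or entirely
missing) carry no lineage signal; they are excluded from the neighbor search
and receive the sentinel label -1 rather than being imputed into a clone.

Note that modularity resolution is scale-dependent: a community of internal
weight ~w(n-1)n survives splitting only while the total graph weight 2m
exceeds roughly ``resolution * (n-1)^2 * w``. High resolutions such as the
default 3.0 are meaningful on biopsy-scale graphs with many clusters and will
shatter small toy graphs with only two blobs; choose the resolution to match
the graph, not the other way around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .io_formats import AlleleCountMatrix, CellAnnotation

__all__ = [
    "SENTINEL_CLUSTER",
    "HeteroplasmyMatrix",
    "CloneLabels",
    "build_heteroplasmy_matrix",
    "cluster_clones",
    "lineage_prevalence",
    "detect_crossing_lineages",
]

#: Label assigned to cells excluded from clustering (all-zero profiles).
SENTINEL_CLUSTER = -1


@dataclass
class HeteroplasmyMatrix:
    """Cells x significant-variants allele-frequency matrix.

    ``af`` holds alt/coverage with 0 where coverage is 0; ``missing`` marks
    those zero-coverage entries so that downstream code can distinguish
    "absent" from "not measured".
    """

    cell_ids: list[str]
    variant_ids: list[str]
    af: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.af = np.asarray(self.af, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (len(self.cell_ids), len(self.variant_ids))
        if self.af.shape != shape or self.missing.shape != shape:
            raise ValueError("heteroplasmy matrix shape inconsistent with id lists")
        if ((self.af < 0) | (self.af > 1)).any():
            raise ValueError("allele frequencies outside [0, 1]")


@dataclass
class CloneLabels:
    """Cell -> integer cluster assignment plus the parameters that made it."""

    labels: pd.Series
    params: dict = field(default_factory=dict)

    def cluster_ids(self, include_sentinel: bool = False) -> list[int]:
        ids = sorted(set(self.labels))
        if not include_sentinel:
            ids = [c for c in ids if c != SENTINEL_CLUSTER]
        return ids

    def cells_in(self, cluster_id: int) -> list[str]:
        return self.labels.index[self.labels == cluster_id].tolist()


def build_heteroplasmy_matrix(
    m: AlleleCountMatrix, significant: list[str]
) -> HeteroplasmyMatrix:
    """Restrict the allele matrix to significant variants, as AF.

    Column order follows ``significant``.
    """
    if not significant:
        raise ValueError("empty significant-variant list")
    cols = [m.variant_index(v) for v in significant]
    af = m.allele_frequency()[:, cols]
    missing = m.coverage[:, cols] == 0
    return HeteroplasmyMatrix(list(m.cell_ids), list(significant), af, missing)


def cluster_clones(
    h: HeteroplasmyMatrix,
    k: int = 10,
    resolution: float = 3.0,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
    n_iterations: int = 2,
) -> CloneLabels:
    """SNN-graph community detection on the heteroplasmy matrix.

    Deterministic given ``seed``. Clusters are relabeled 0, 1, ... by
    decreasing size (ties by first cell index); all-zero cells get the
    sentinel label.
    """
    nonzero = (h.af > 0).any(axis=1)
    X = h.af[nonzero]
    n = len(X)
    if n < k + 1:
        raise ValueError(f"{n} cells with nonzero heteroplasmy; need at least k+1={k + 1}")

    nn = NearestNeighbors(n_neighbors=k, metric="cosine").fit(X)
    _, knn_idx = nn.kneighbors(X)

    # SNN: Jaccard overlap of k-neighbor sets, pruned
    adj = np.zeros((n, n), dtype=bool)
    adj[np.arange(n)[:, None], knn_idx] = True
    inter = adj.astype(np.int32) @ adj.T.astype(np.int32)
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = inter / (2 * k - inter)
    jac[jac < prune] = 0.0
    np.fill_diagonal(jac, 0.0)

    src, dst = np.nonzero(np.triu(jac))
    g = ig.Graph(n, list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = jac[src, dst].tolist()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=n_iterations,
    )
    membership = np.asarray(part.membership)

    # stable relabeling: by size descending, then by first occurrence
    sizes = pd.Series(membership).value_counts()
    first = {c: int(np.flatnonzero(membership == c)[0]) for c in sizes.index}
    order = sorted(sizes.index, key=lambda c: (-sizes[c], first[c]))
    remap = {c: i for i, c in enumerate(order)}

    labels = np.full(len(h.cell_ids), SENTINEL_CLUSTER, dtype=int)
    labels[np.flatnonzero(nonzero)] = [remap[c] for c in membership]
    return CloneLabels(
        labels=pd.Series(labels, index=pd.Index(h.cell_ids, name="cell_id")),
        params={
            "metric": "cosine",
            "k": k,
            "resolution": resolution,
            "seed": int(seed),
            "prune": prune,
            "scaling": "none (cosine distance is per-cell scale invariant)",
            "n_excluded_all_zero": int((~nonzero).sum()),
        },
    )


def lineage_prevalence(
    calls: pd.DataFrame,
    ann: CellAnnotation,
    variant_id: str,
    min_cov: int = 5,
) -> pd.Series:
    """Per-sample fraction of cells carrying the variant.

    Numerator: significant cells for the variant. Denominator: cells with
    coverage of at least ``min_cov`` at the variant (the same eligibility
    rule used for AF displays). Samples with no eligible cell give NaN.
    """
    sub = calls[calls["variant_id"] == variant_id]
    if sub.empty:
        raise KeyError(f"variant {variant_id!r} absent from call table")
    idx = ann.indexed()
    sub = sub.assign(sample_id=idx.loc[sub["cell_id"], "sample_id"].to_numpy())
    out = {}
    for sample, grp in sub.groupby("sample_id", sort=True):
        eligible = grp["coverage"] >= min_cov
        n_eligible = int(eligible.sum())
        if n_eligible == 0:
            out[sample] = float("nan")
        else:
            out[sample] = float((grp["significant"] & eligible).sum() / n_eligible)
    return pd.Series(out, name=variant_id).rename_axis("sample_id")


def detect_crossing_lineages(
    calls: pd.DataFrame,
    ann: CellAnnotation,
    min_cells_per_tissue: int = 3,
) -> list[tuple[str, list[str]]]:
    """Variants whose significant cells span two or more tissues.

    A tissue counts only with at least ``min_cells_per_tissue`` significant
    cells. Returns (variant_id, sorted tissue list) pairs.
    """
    idx = ann.indexed()
    sig = calls[calls["significant"]]
    out = []
    for vid, grp in sig.groupby("variant_id", sort=True):
        tissues = idx.loc[grp["cell_id"], "tissue"]
        counts = tissues.value_counts()
        spanned = sorted(counts.index[counts >= min_cells_per_tissue])
        if len(spanned) >= 2:
            out.append((vid, spanned))
    return out
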