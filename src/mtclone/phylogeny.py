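"""Clone phylogenies with permutation-calibrated bootstrap support.

Clone centroids (per-cluster mean heteroplasmy profiles) are related by a
neighbor-joining tree built on cosine distances. Topological confidence is
assessed by resampling cells *within* each cluster with replacement
(preserving cluster sizes), rebuilding the tree, and scoring each internal
bipartition of the base tree by the fraction of replicate trees containing
it; a bipartition and its mirror image are the same split.

Raw bootstrap supports on centroid trees can be high by chance — centroids
of randomly assembled cell sets still differ, and those accidental
differences persist across bootstrap replicates. Supports are therefore
calibrated against an explicit null: cells are randomly reassigned between
clusters (sizes preserved), the full bootstrap analysis is repeated, and the
maximum support observed per permutation forms a null distribution whose
95th percentile is the significance threshold. An edge is flagged
significant only when both its own support and its parent edge's support
exceed that threshold (for edges adjacent to the root the parent condition
is vacuous and flagged as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from ._rng import substream
from .clones import SENTINEL_CLUSTER, CloneLabels, HeteroplasmyMatrix

__all__ = [
    "CloneTree",
    "SupportCalibration",
    "cluster_distance_matrix",
    "neighbor_joining",
    "bipartitions",
    "bootstrap_support",
    "permutation_null_threshold",
    "annotate_significant_edges",
]


@dataclass
class CloneTree:
    """An (unrooted or rooted) clone tree backed by an skbio ``TreeNode``.

    ``supports`` maps canonical bipartition keys to bootstrap support; after
    :func:`annotate_significant_edges` each internal node additionally
    carries ``support``, ``significant`` and ``parent_vacuous`` attributes.
    """

    tree: TreeNode
    leaf_names: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    rooted: bool = False
    threshold: float | None = None

    def bipartition_keys(self) -> list[frozenset]:
        return bipartitions(self.tree, self.leaf_names)

    def support_of(self, key: frozenset) -> float:
        return self.supports.get(_canonical(key, self.leaf_names), float("nan"))

    def significant_edges(self) -> list[frozenset]:
        out: list[frozenset] = []
        for node in self.tree.non_tips(include_self=False):
            if getattr(node, "significant", False):
                key = _canonical(frozenset(t.name for t in node.tips()), self.leaf_names)
                if key not in out:  # both root-adjacent edges carry one split
                    out.append(key)
        return out


@dataclass
class SupportCalibration:
    """Null distribution of maximum supports under label permutation."""

    n_bootstrap: int
    n_permutations: int
    null_max_supports: list[float]
    threshold: float

    def __post_init__(self) -> None:
        if len(self.null_max_supports) != self.n_permutations:
            raise ValueError("one null maximum per permutation required")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold outside [0, 1]")


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------


def _centroids(h: HeteroplasmyMatrix, label_array: np.ndarray, cluster_ids: list[int]) -> np.ndarray:
    return np.vstack([h.af[label_array == c].mean(axis=0) for c in cluster_ids])


def cluster_distance_matrix(
    h: HeteroplasmyMatrix, labels: CloneLabels
) -> tuple[list[str], np.ndarray]:
    """Cosine distances between per-cluster mean heteroplasmy profiles."""
    cluster_ids = labels.cluster_ids()
    if len(cluster_ids) < 3:
        raise ValueError(f"need at least 3 clusters, have {len(cluster_ids)}")
    lab = labels.labels.loc[h.cell_ids].to_numpy()
    cent = _centroids(h, lab, cluster_ids)
    norms = np.linalg.norm(cent, axis=1)
    if (norms == 0).any():
        bad = cluster_ids[int(np.flatnonzero(norms == 0)[0])]
        raise ValueError(f"cluster {bad} has a zero-norm centroid; cosine distance undefined")
    d = squareform(pdist(cent, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    return [str(c) for c in cluster_ids], d


def neighbor_joining(d: np.ndarray, ids: list[str]) -> CloneTree:
    """Classic neighbor joining (Saitou-Nei Q criterion).

    Negative branch lengths are clamped to zero; the pre-clamp value is kept
    on the node as ``raw_length``. The returned tree is unrooted with a
    trifurcating root node.
    """
    d = np.asarray(d, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValueError(f"distance matrix shape {d.shape} does not match {n} ids")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes = [TreeNode(name=str(i)) for i in ids]
    d = d.copy()
    active = list(range(n))

    def set_length(node: TreeNode, length: float) -> None:
        node.raw_length = float(length)
        node.length = float(max(length, 0.0))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        li = 0.5 * sub[i_loc, j_loc] + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = sub[i_loc, j_loc] - li
        parent = TreeNode()
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)), constant_values=0.0)
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    root = TreeNode()
    set_length(nodes[i], 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    set_length(nodes[j], 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    set_length(nodes[k], 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root.extend([nodes[i], nodes[j], nodes[k]])
    return CloneTree(tree=root, leaf_names=[str(i) for i in ids])


# ---------------------------------------------------------------------------
# bipartitions
# ---------------------------------------------------------------------------


def _canonical(side: frozenset, leaf_names: list[str]) -> frozenset:
    """Canonical key for a split: the side not containing the smallest leaf.

    Identical and reverse-ordered bipartitions map to the same key.
    """
    anchor = min(leaf_names)
    if anchor in side:
        return frozenset(leaf_names) - side
    return frozenset(side)


def bipartitions(tree: TreeNode, leaf_names: list[str]) -> list[frozenset]:
    """Canonical keys of all internal (non-trivial) bipartitions."""
    n = len(leaf_names)
    keys = []
    seen = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            key = _canonical(side, leaf_names)
            if key not in seen:
                seen.add(key)
                keys.append(key)
    return keys


# ---------------------------------------------------------------------------
# bootstrap and permutation calibration
# ---------------------------------------------------------------------------


def _tree_from_centroids(cent: np.ndarray, ids: list[str]) -> CloneTree:
    d = squareform(pdist(cent, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    return neighbor_joining(d, ids)


def bootstrap_support(
    h: HeteroplasmyMatrix,
    labels: CloneLabels,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> CloneTree:
    """Base NJ tree with within-cluster resampling bootstrap supports.

    Each replicate resamples cells with replacement within every cluster
    (sizes preserved), recomputes centroids and the NJ tree, and each base
    bipartition's support is the fraction of replicates containing it.
    Clusters of a single cell resample to themselves every time.
    """
    ids, d = cluster_distance_matrix(h, labels)
    base = neighbor_joining(d, ids)
    keys = base.bipartition_keys()
    counts = dict.fromkeys(keys, 0)

    cluster_ids = labels.cluster_ids()
    lab = labels.labels.loc[h.cell_ids].to_numpy()
    members = [np.flatnonzero(lab == c) for c in cluster_ids]
    rng = substream(seed, "bootstrap")

    for _ in range(n_bootstrap):
        cent = np.empty((len(cluster_ids), h.af.shape[1]))
        for ci, rows in enumerate(members):
            take = rows[rng.integers(0, len(rows), size=len(rows))]
            cent[ci] = h.af[take].mean(axis=0)
        if (np.linalg.norm(cent, axis=1) == 0).any():
            continue  # unusable replicate: a resampled centroid lost all signal
        rep = _tree_from_centroids(cent, ids)
        rep_keys = set(rep.bipartition_keys())
        for key in keys:
            if key in rep_keys:
                counts[key] += 1

    base.supports = {k: counts[k] / n_bootstrap for k in keys}
    for node in base.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(ids) - 2:
            node.support = base.supports[_canonical(side, ids)]
    return base


def permutation_null_threshold(
    h: HeteroplasmyMatrix,
    labels: CloneLabels,
    n_permutations: int = 100,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> SupportCalibration:
    """Null distribution of maximum bootstrap support under label shuffling.

    Each permutation randomly reassigns clustered cells between clusters
    (cluster sizes preserved; sentinel cells stay excluded), reruns the full
    bootstrap analysis, and records the maximum internal-bipartition support.
    The threshold is the 95th percentile of those maxima.
    """
    rng = substream(seed, "permutation")
    lab = labels.labels.copy()
    clustered = lab.index[lab != SENTINEL_CLUSTER]
    values = lab.loc[clustered].to_numpy()

    maxima: list[float] = []
    for it in range(n_permutations):
        shuffled = lab.copy()
        shuffled.loc[clustered] = values[rng.permutation(len(values))]
        perm_labels = CloneLabels(labels=shuffled, params=dict(labels.params))
        rep = bootstrap_support(
            h, perm_labels, n_bootstrap=n_bootstrap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        maxima.append(max(rep.supports.values(), default=0.0))
    threshold = float(np.percentile(maxima, 95)) if maxima else 0.0
    return SupportCalibration(
        n_bootstrap=n_bootstrap,
        n_permutations=n_permutations,
        null_max_supports=maxima,
        threshold=threshold,
    )


def annotate_significant_edges(
    tree: CloneTree,
    calib: SupportCalibration,
    root_policy: str = "midpoint",
    outgroup: str | None = None,
) -> CloneTree:
    """Root the tree and flag statistically supported edges.

    An internal edge is significant when its own support and its parent
    edge's support both exceed the calibration threshold; edges whose parent
    is the root have no parent edge, the condition holds vacuously and the
    node is marked ``parent_vacuous``.

    ``root_policy`` is ``"midpoint"`` or ``"outgroup"`` (with ``outgroup``
    naming a leaf).
    """
    if root_policy == "midpoint":
        try:
            rooted = tree.tree.root_at_midpoint()
        except Exception:  # fully degenerate (zero-length) trees have no midpoint
            rooted = tree.tree.copy()
    elif root_policy == "outgroup":
        if outgroup is None:
            raise ValueError("outgroup rooting requires an outgroup leaf name")
        rooted = tree.tree.copy()
        rooted = rooted.root_at(rooted.find(outgroup).parent)
    else:
        raise ValueError(f"unknown root policy {root_policy!r}")

    out = CloneTree(
        tree=rooted,
        leaf_names=list(tree.leaf_names),
        supports=dict(tree.supports),
        rooted=True,
        threshold=calib.threshold,
    )
    n = len(out.leaf_names)
    thr = calib.threshold
    for node in rooted.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not 2 <= len(side) <= n - 2:
            node.support = None
            node.significant = False
            continue
        node.support = out.supports.get(_canonical(side, out.leaf_names), float("nan"))
        parent = node.parent
        if parent.is_root():
            node.parent_vacuous = True
            node.significant = bool(node.support > thr)
        else:
            node.parent_vacuous = False
            pside = frozenset(t.name for t in parent.tips())
            if 2 <= len(pside) <= n - 2:
                psup = out.supports.get(_canonical(pside, out.leaf_names), float("nan"))
            else:
                psup = 1.0  # trivial (single-leaf complement) splits are certain
            node.significant = bool(node.support > thr and psup > thr)
    return out
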