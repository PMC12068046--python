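"""Hierarchical clustering of quantitative morphological signatures.

Perturbation signatures (vectors of per-shape Z-scores) are compared with
the *uncentered* Pearson correlation — the cosine of the angle between the
raw vectors, without mean-centering — and agglomerated with average linkage
on the distance ``1 - similarity``.  "Phenoclusters" are the maximal
subtrees whose root merge similarity exceeds a threshold (default 0.73);
leaves outside every such subtree are reported as singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "uncentered_pearson",
    "Dendrogram",
    "Phenocluster",
    "hierarchical_cluster",
    "cut_phenoclusters",
    "to_newick",
]

DEFAULT_PCC_THRESHOLD = 0.73


def uncentered_pearson(x, y) -> float:
    """Uncentered Pearson correlation sum(x*y)/sqrt(sum(x^2)*sum(y^2)).

    Identical to the cosine similarity of the raw vectors; no mean is
    subtracted, so two proportional vectors score 1 regardless of offset
    structure.

    Raises
    ------
    ValueError
        If the vectors differ in length, are shorter than 2, or either
        has zero norm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    nx = np.sqrt(np.sum(x * x))
    ny = np.sqrt(np.sum(y * y))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("zero-norm vector has undefined uncentered correlation")
    return float(np.sum(x * y) / (nx * ny))


def _similarity_matrix(mat: np.ndarray) -> np.ndarray:
    norms = np.sqrt(np.sum(mat * mat, axis=1))
    if np.any(norms == 0.0):
        raise ValueError("zero-norm signature row")
    sim = (mat @ mat.T) / np.outer(norms, norms)
    return np.clip(sim, -1.0, 1.0)


@dataclass
class Dendrogram:
    """Agglomeration result over condition signatures.

    ``linkage`` is a scipy linkage matrix on distance 1 - uncentered PCC;
    ``merge_similarity`` re-expresses each merge height as a similarity.
    """

    labels: list[str]
    linkage: np.ndarray
    merge_similarity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.merge_similarity = 1.0 - self.linkage[:, 2]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]


@dataclass
class Phenocluster:
    cluster_id: int
    members: list[str]
    similarity: float  # root merge similarity; 1.0 for singletons


def hierarchical_cluster(qms: pd.DataFrame, linkage_method: str = "average") -> Dendrogram:
    """Agglomerate signature rows on distance 1 - uncentered PCC.

    Parameters
    ----------
    qms
        Signatures, one row per condition (index = condition labels).
    linkage_method
        ``"average"`` (default) or ``"complete"``.
    """
    if qms.index.has_duplicates:
        dups = qms.index[qms.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate condition labels: {dups}")
    mat = np.asarray(qms, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 conditions to cluster")
    if not np.all(np.isfinite(mat)):
        raise ValueError("non-finite signature entries")
    dist = 1.0 - _similarity_matrix(mat)
    np.fill_diagonal(dist, 0.0)
    # symmetrize against floating round-off before condensing
    dist = np.maximum(0.5 * (dist + dist.T), 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return Dendrogram(labels=[str(i) for i in qms.index], linkage=z)


def cut_phenoclusters(dendrogram: Dendrogram, threshold: float = DEFAULT_PCC_THRESHOLD) -> list[Phenocluster]:
    """Cut into phenoclusters: maximal subtrees with root similarity > threshold.

    A leaf not covered by any qualifying subtree becomes a singleton
    cluster.  Clusters are numbered in leaf-order of their first member.
    """
    if not (-1.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (-1, 1)")
    z = dendrogram.linkage
    n = dendrogram.n_leaves
    sim = dendrogram.merge_similarity

    # members[k] = leaves under internal node n+k
    members: list[list[int]] = []
    for k in range(z.shape[0]):
        a, b = int(z[k, 0]), int(z[k, 1])
        la = [a] if a < n else members[a - n]
        lb = [b] if b < n else members[b - n]
        members.append(la + lb)

    assigned = np.full(n, -1, dtype=int)
    clusters: list[list[int]] = []
    # scan merges root-down (decreasing height) so the *highest* qualifying
    # node claims its leaves first
    for k in range(z.shape[0] - 1, -1, -1):
        if sim[k] > threshold:
            leaves = [i for i in members[k] if assigned[i] < 0]
            if leaves and len(leaves) == len(members[k]):
                cid = len(clusters)
                clusters.append(leaves)
                for i in leaves:
                    assigned[i] = cid
    for i in range(n):
        if assigned[i] < 0:
            assigned[i] = len(clusters)
            clusters.append([i])

    # similarity of the cluster's root merge; singletons report 1.0
    root_sim = {}
    for k in range(z.shape[0]):
        key = frozenset(members[k])
        root_sim[key] = sim[k]

    out = []
    ordered = sorted(range(len(clusters)), key=lambda c: min(clusters[c]))
    for new_id, c in enumerate(ordered):
        leaves = sorted(clusters[c])
        s = root_sim.get(frozenset(leaves), 1.0) if len(leaves) > 1 else 1.0
        out.append(
            Phenocluster(
                cluster_id=new_id,
                members=[dendrogram.labels[i] for i in leaves],
                similarity=float(s),
            )
        )
    return out


def assignments_frame(clusters: list[Phenocluster]) -> pd.DataFrame:
    """Flat condition -> cluster table ready for CSV export."""
    rows = [
        {"condition": m, "cluster": c.cluster_id, "cluster_similarity": c.similarity,
         "cluster_size": len(c.members)}
        for c in clusters
        for m in c.members
    ]
    return pd.DataFrame(rows)


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string (branch lengths = distance)."""
    tree = hierarchy.to_tree(dendrogram.linkage)

    def rec(node) -> str:
        if node.is_leaf():
            return f"{dendrogram.labels[node.id]}:{node.dist:.6g}"
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"
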