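"""Module detection on phylogenetic profiles.

Hierarchical clustering over a series of group numbers, PCA-based grouping,
the gene-gene Pearson correlation matrix, and a co-clustering consensus
across methods and group numbers.  Genes that are gained and lost together
land in the same group; agreement across the six distance measures (and
across cuts of the merge tree) marks robust evolutionary modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .distances import DistanceMatrix

LINKAGES = ("single", "complete", "average", "ward")
DEFAULT_GROUP_NUMBERS = tuple(range(5, 51, 5))


@dataclass
class ClusterResult:
    method: str
    k: int
    assignment: dict[str, int]

    def labels(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.assignment[g] for g in gene_ids])


def linkage_tree(dm: DistanceMatrix, linkage: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) of a distance matrix.

    Only off-diagonal entries enter the condensed form, so methods whose
    self-distance convention is nonzero (mutual information on unbalanced
    vectors, Pearson on constant vectors) cluster on pair distances alone.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = len(dm.gene_ids)
    if n < 2:
        raise ValueError("need at least two genes to build a merge tree")
    return hierarchy.linkage(dm.condensed(), method=linkage)


def _cut(Z: np.ndarray, k: int, gene_ids: list[str], method: str) -> ClusterResult:
    labels = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    return ClusterResult(method, k, dict(zip(gene_ids, (int(v) for v in labels))))


def hierarchical_cluster(dm: DistanceMatrix, linkage: str, k: int) -> ClusterResult:
    """Cut the merge tree to exactly k groups (all nonempty)."""
    n = len(dm.gene_ids)
    if not (1 <= k <= n):
        raise ValueError(f"group number k={k} out of range [1, {n}]")
    Z = linkage_tree(dm, linkage)
    return _cut(Z, k, dm.gene_ids, f"{dm.method}/{linkage}")

def cut_series(dm: DistanceMatrix, linkage: str, ks: list[int]) -> list[ClusterResult]:
    """One partition per group number, all cut from a single merge tree, so
    the partition at a larger k refines the one at a smaller k."""
    if not ks:
        raise ValueError("ks must be nonempty")
    n = len(dm.gene_ids)
    for k in ks:
        if not (1 <= k <= n):
            raise ValueError(f"group number k={k} out of range [1, {n}]")
    if n == 1:
        return [ClusterResult(f"{dm.method}/{linkage}", 1, {dm.gene_ids[0]: 0}) for _ in ks]
    Z = linkage_tree(dm, linkage)
    return [_cut(Z, k, dm.gene_ids, f"{dm.method}/{linkage}") for k in ks]


def pca_groups(
    profiles: pd.DataFrame,
    k: int,
    n_components: int = 2,
    seed: int = 0,
) -> ClusterResult:
    """Seeded centroid clustering of genes on their top principal components.

    The binary matrix is column-centered, genes are projected onto the top
    ``n_components`` PCs, and k-means (deterministic under the seed)
    partitions the scores into k groups.
    """
    n = len(profiles.index)
    if not (1 <= k <= n):
        raise ValueError(f"group number k={k} out of range [1, {n}]")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = profiles.to_numpy(dtype=float)
    comps = min(n_components, min(X.shape))
    scores = PCA(n_components=comps, random_state=seed).fit_transform(X)
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(scores)
    return ClusterResult(f"pca{comps}/kmeans", k, dict(zip(profiles.index, map(int, labels))))


def correlation_matrix(
    profiles: pd.DataFrame,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Pearson coefficients between gene profiles.

    Returns the coefficient matrix and a boolean Series flagging constant
    genes, whose rows/columns are NaN by construction rather than silently:
    callers must consult the flag.
    """
    sub = profiles.loc[genes] if genes is not None else profiles
    if len(sub.index) < 2:
        raise ValueError("correlation matrix needs at least two genes")
    X = sub.to_numpy(dtype=float)
    constant = pd.Series(X.std(axis=1) == 0, index=sub.index, name="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(X)
    return pd.DataFrame(cor, index=sub.index, columns=sub.index), constant


@dataclass
class ConsensusMatrix:
    """Fraction of runs in which each gene pair shared a group."""

    gene_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


def consensus_modules(
    results: list[ClusterResult],
    f: float,
) -> tuple[list[set[str]], ConsensusMatrix]:
    """Disjoint gene sets whose every pair co-clusters in >= f of the runs.

    Sets are grown greedily in gene order: each unassigned gene seeds a set
    and absorbs every later gene co-clustering (at frequency >= f) with all
    current members.  With identical runs this returns that partition at
    any f; with fully disagreeing runs and f = 1 it returns singletons.
    """
    if not results:
        raise ValueError("empty result list")
    if not (0 < f <= 1):
        raise ValueError("consensus threshold f must lie in (0, 1]")
    genes = sorted(results[0].assignment)
    for res in results:
        if sorted(res.assignment) != genes:
            raise ValueError("all cluster results must cover the same gene set")
    n = len(genes)
    co = np.zeros((n, n))
    for res in results:
        lab = res.labels(genes)
        co += (lab[:, None] == lab[None, :]).astype(float)
    co /= len(results)
    agree = co >= f
    assigned = np.zeros(n, dtype=bool)
    sets: list[set[str]] = []
    for i in range(n):
        if assigned[i]:
            continue
        members = [i]
        for j in range(i + 1, n):
            if not assigned[j] and all(agree[j, m] for m in members):
                members.append(j)
        for m in members:
            assigned[m] = True
        sets.append({genes[m] for m in members})
    return sets, ConsensusMatrix(genes, co)


def tree_to_newick(dm: DistanceMatrix, linkage: str = "average") -> str:
    """Export the merge tree as Newick with merge heights as branch lengths."""
    Z = linkage_tree(dm, linkage)
    tree = hierarchy.to_tree(Z)
    names = dm.gene_ids

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
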