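"""Hierarchical clustering (SAHN), cophenetic analysis, tree comparison,
silhouette-guided k-means, and PCA.

The agglomeration is a direct O(n^3) sequential-agglomerative (SAHN) loop
with Lance-Williams updates and a fully deterministic tie-break: among
minimum-distance cluster pairs, the pair whose (smallest-leaf-label,
smallest-leaf-label) pair sorts first lexicographically is merged.

Height conventions: UPGMA records merge heights at half the average
between-cluster distance, so the cophenetic distance 2*h equals the
original average distance and ``cophenetic(upgma(D)) == D`` exactly for
ultrametric D.  Complete and Ward linkage record the merge distance
itself as the height.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .errors import AlignmentError, ConfigError, DegenerateDataError, FormatError
from .io import Dendrogram, DistanceMatrix

__all__ = [
    "Partition",
    "PcaResult",
    "KmeansSelection",
    "DendrogramComparison",
    "upgma",
    "hierarchical",
    "cophenetic",
    "cut_tree",
    "compare_dendrograms",
    "kmeans_select",
    "pca",
]

#: mean-silhouette level below which a k >= 2 structure is not considered
#: supported by the data
SILHOUETTE_SUPPORT_THRESHOLD = 0.25


@dataclass
class Partition:
    """Accession -> cluster index (1..k), with contiguous indices."""

    assignments: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        if not self.assignments:
            raise FormatError("empty partition")
        idx = sorted(set(self.assignments.values()))
        if idx != list(range(1, self.k + 1)):
            raise FormatError(f"cluster indices {idx} not contiguous 1..{self.k}")

    def labels_for(self, accessions: list[str]) -> np.ndarray:
        return np.array([self.assignments[a] for a in accessions])

    def members(self, cluster: int) -> list[str]:
        return [a for a, c in self.assignments.items() if c == cluster]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"accession": list(self.assignments),
                             "cluster": list(self.assignments.values())})


@dataclass
class PcaResult:
    scores: pd.DataFrame      # accession x component
    loadings: pd.DataFrame    # trait x component
    eigenvalues: np.ndarray
    percent_variance: np.ndarray


@dataclass
class KmeansSelection:
    partition: Partition
    best_k: int
    silhouette: pd.DataFrame  # columns: k, mean_silhouette
    supported: bool           # max mean silhouette >= threshold


@dataclass
class DendrogramComparison:
    cophenetic_correlation: float
    cut_agreement: pd.DataFrame  # columns: k, ari, n_mismatched


# ---------------------------------------------------------------------------
# SAHN agglomeration
# ---------------------------------------------------------------------------

def hierarchical(distance: DistanceMatrix, linkage: str = "upgma") -> Dendrogram:
    """Agglomerative clustering with deterministic lexicographic tie-breaks."""
    if linkage not in ("upgma", "complete", "ward"):
        raise ConfigError(f"unknown linkage {linkage!r}")
    n = distance.n
    if n < 2:
        raise FormatError("need at least two leaves to cluster")
    labels = list(distance.labels)
    # working metric: squared distances for ward, raw otherwise
    work = distance.values.astype(float).copy()
    if linkage == "ward":
        work = work ** 2
    active: list[int] = list(range(n))           # node ids of live clusters
    minlab: dict[int, str] = {i: labels[i] for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    # dist between live clusters, keyed by frozenset of node ids
    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(work[i, j])

    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best: tuple[str, str] | None = None
        best_pair: tuple[int, int] | None = None
        best_d = np.inf
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                d = dist[frozenset((a, b))]
                key = tuple(sorted((minlab[a], minlab[b])))
                if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15
                                          and (best is None or key < best)):
                    best_d, best, best_pair = d, key, (a, b)
        a, b = best_pair  # type: ignore[misc]
        if minlab[b] < minlab[a]:
            a, b = b, a
        new = n + step
        if linkage == "upgma":
            height = best_d / 2.0
        elif linkage == "complete":
            height = best_d
        else:
            height = float(np.sqrt(best_d))
        # monotonicity guard against round-off
        if merges and height < merges[-1][2]:
            height = merges[-1][2]
        merges.append((a, b, height))

        na, nb = size[a], size[b]
        for c in active:
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            if linkage == "upgma":
                d_new = (na * dac + nb * dbc) / (na + nb)
            elif linkage == "complete":
                d_new = max(dac, dbc)
            else:
                nc = size[c]
                d_new = ((na + nc) * dac + (nb + nc) * dbc
                         - nc * dist[frozenset((a, b))]) / (na + nb + nc)
            dist[frozenset((new, c))] = d_new
        dist.pop(frozenset((a, b)))
        active = [c for c in active if c not in (a, b)] + [new]
        minlab[new] = min(minlab[a], minlab[b])
        size[new] = na + nb
    return Dendrogram(labels=tuple(labels), merges=tuple(merges))


def upgma(distance: DistanceMatrix) -> Dendrogram:
    """Average-linkage SAHN tree; merge height = average distance / 2."""
    return hierarchical(distance, "upgma")


def cophenetic(tree: Dendrogram) -> DistanceMatrix:
    """c(i, j) = 2 x height of the lowest common ancestor of i and j."""
    n = tree.n_leaves
    c = np.zeros((n, n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for m, (left, right, h) in enumerate(tree.merges):
        for i in members[left]:
            for j in members[right]:
                c[i, j] = c[j, i] = 2.0 * h
        members[n + m] = members.pop(left) + members.pop(right)
    return DistanceMatrix(tree.labels, c)


def cut_tree(tree: Dendrogram, k: int) -> Partition:
    """Partition into exactly k clusters by undoing the k-1 highest merges.

    Merges are applied in ascending height order (ties toward the lower
    height, stable in merge order), so any k in [1, n] is attainable.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ConfigError(f"k must lie in [1, {n}], got {k}")
    order = sorted(range(n - 1), key=lambda m: (tree.merges[m][2], m))
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in order[: n - k]:
        left, right, _ = tree.merges[m]
        node = n + m
        for child in (left, right):
            parent[find(child)] = find(node)
    # descend unapplied merges' nodes to their surviving leaf components
    roots = [find(i) for i in range(n)]
    seen: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen) + 1
        assignments[tree.labels[i]] = seen[r]
    return Partition(assignments=assignments, k=len(seen))


def compare_dendrograms(d1: Dendrogram, d2: Dendrogram,
                        k_range: tuple[int, int] = (2, 10)) -> DendrogramComparison:
    """Cophenetic Pearson correlation plus per-k cut agreement (adjusted
    Rand index and the number of accessions whose pairwise co-membership
    differs between the two trees)."""
    if set(d1.labels) != set(d2.labels):
        raise AlignmentError("dendrograms have different leaf sets")
    order = list(d1.labels)
    c1 = cophenetic(d1)
    c2 = cophenetic(d2).reorder(order)
    v1, v2 = c1.condensed(), c2.condensed()
    if v1.std() == 0 or v2.std() == 0:
        raise DegenerateDataError("constant cophenetic matrix; correlation undefined")
    r = float(np.corrcoef(v1, v2)[0, 1])

    rows = []
    n = len(order)
    for k in range(k_range[0], min(k_range[1], n - 1) + 1):
        p1 = cut_tree(d1, k).labels_for(order)
        p2 = cut_tree(d2, k).labels_for(order)
        ari = float(adjusted_rand_score(p1, p2))
        co1 = p1[:, None] == p1[None, :]
        co2 = p2[:, None] == p2[None, :]
        mismatched = int(np.sum((co1 != co2).any(axis=1)))
        rows.append([k, ari, mismatched])
    table = pd.DataFrame(rows, columns=["k", "ari", "n_mismatched"])
    return DendrogramComparison(cophenetic_correlation=r, cut_agreement=table)


# ---------------------------------------------------------------------------
# Partitional clustering and ordination
# ---------------------------------------------------------------------------

def kmeans_select(data: pd.DataFrame, k_range: tuple[int, int] = (2, 10),
                  n_restarts: int = 25, seed: int = 0) -> KmeansSelection:
    """Lloyd k-means over a k grid; the k maximizing the mean silhouette
    width wins (ties toward smaller k).  Deterministic given the seed."""
    x = data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise DegenerateDataError("k-means selection needs at least 3 points")
    if np.all(x == x[0]):
        raise DegenerateDataError("all points identical; k undefined")
    lo, hi = int(k_range[0]), min(int(k_range[1]), n - 1)
    if lo < 2 or lo > hi:
        raise ConfigError(f"invalid k_range {k_range} for n={n}")
    rows = []
    best: tuple[float, int, np.ndarray] | None = None
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                    algorithm="lloyd")
        labels = km.fit_predict(x)
        if len(set(labels)) < 2:
            sil = float("-inf")
        else:
            sil = float(silhouette_score(x, labels))
        rows.append([k, sil])
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, labels)
    assert best is not None
    sil_best, k_best, labels = best
    # renumber clusters 1..k by order of first appearance
    remap: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for acc, lab in zip(data.index, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignments[str(acc)] = remap[lab]
    return KmeansSelection(
        partition=Partition(assignments=assignments, k=len(remap)),
        best_k=k_best,
        silhouette=pd.DataFrame(rows, columns=["k", "mean_silhouette"]),
        supported=sil_best >= SILHOUETTE_SUPPORT_THRESHOLD,
    )


def pca(data: pd.DataFrame, scale: bool = True) -> PcaResult:
    """Eigendecomposition of the correlation (``scale=True``, default) or
    covariance matrix.  Component signs are fixed by making each
    component's largest-magnitude loading positive."""
    x = data.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise FormatError("PCA needs at least two traits")
    sd = x.std(axis=0, ddof=0)
    zero = np.where(sd == 0)[0]
    if scale and zero.size:
        raise DegenerateDataError(
            f"zero-variance trait(s) with scaling: "
            f"{[data.columns[i] for i in zero]}")
    centered = x - x.mean(axis=0)
    z = centered / sd if scale else centered
    cov = (z.T @ z) / x.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    percent = 100.0 * eigval / eigval.sum() if eigval.sum() > 0 else eigval
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    scores = pd.DataFrame(z @ eigvec, index=data.index, columns=comps)
    loadings = pd.DataFrame(eigvec, index=data.columns, columns=comps)
    return PcaResult(scores=scores, loadings=loadings, eigenvalues=eigval,
                     percent_variance=percent)
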