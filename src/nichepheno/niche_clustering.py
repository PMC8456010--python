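"""Niche-overlap statistics between suitability maps and niche clustering.

Per-population habitat-suitability surfaces are compared with the standard
overlap statistics: I (one minus half the squared Hellinger distance
between the surfaces normalized to sum to one), Schoener's D (one minus
half their L1 distance) and the plain Pearson correlation of cell values.
Sampling sites are then grouped into environmental niches by agglomerative
hierarchical clustering of the overlap matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

LINKAGES = ("ward", "complete", "average", "single")


def overlap_stats(map_a: np.ndarray, map_b: np.ndarray
                  ) -> tuple[float, float, float]:
    """(I, D, r) between two aligned suitability maps.

    NaN cells must coincide; values are compared over the shared data
    cells.  I and D use the surfaces normalized to sum to one; r is the
    Pearson correlation of the unnormalized values.  Identical maps give
    I = D = r = 1; disjoint supports give I = D = 0.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share the same grid")
    va, vb = np.isnan(a), np.isnan(b)
    if not np.array_equal(va, vb):
        raise ValueError("maps must share the same no-data mask")
    p = a[~va].ravel()
    q = b[~vb].ravel()
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("cannot normalize an all-zero suitability map")
    pn = p / p.sum()
    qn = q / q.sum()
    i_stat = 1.0 - 0.5 * float(np.sum((np.sqrt(pn) - np.sqrt(qn)) ** 2))
    d_stat = 1.0 - 0.5 * float(np.sum(np.abs(pn - qn)))
    if p.std() == 0 or q.std() == 0:
        r = 1.0 if np.allclose(p, q) else 0.0
    else:
        r = float(pearsonr(p, q).statistic)
    return i_stat, d_stat, r


@dataclass
class OverlapMatrix:
    populations: list[str]
    I: pd.DataFrame
    D: pd.DataFrame
    r: pd.DataFrame


def pairwise_overlap(maps: dict[str, np.ndarray]) -> OverlapMatrix:
    """All pairwise overlap statistics; each pair computed once, so the
    matrices are symmetric by construction with unit diagonal."""
    pops = list(maps)
    if len(pops) < 2:
        raise ValueError("need at least two maps")
    n = len(pops)
    mi = np.eye(n)
    md = np.eye(n)
    mr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            I, D, r = overlap_stats(maps[pops[i]], maps[pops[j]])
            mi[i, j] = mi[j, i] = I
            md[i, j] = md[j, i] = D
            mr[i, j] = mr[j, i] = r
    mk = lambda m: pd.DataFrame(m, index=pops, columns=pops)
    return OverlapMatrix(pops, mk(mi), mk(md), mk(mr))


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree with its agglomerative coefficient.

    ``Z`` is a scipy linkage matrix over ``labels``; AC is the mean over
    leaves of one minus the ratio of the leaf's first merge height to the
    final merge height (0 for n=2, approaching 1 for strong structure).
    """

    Z: np.ndarray
    labels: list[str]
    method: str
    ac: float

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in sch.leaves_list(self.Z)]

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge-height differences."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.Z):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            new = n + idx
            node[new] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[new] = h
        return node[n + len(self.Z) - 1] + ";"


def agglomerative_coefficient(Z: np.ndarray) -> float:
    n = Z.shape[0] + 1
    if n < 2:
        raise ValueError("need at least two leaves")
    final = Z[-1, 2]
    if final <= 0:
        return 0.0
    first = np.full(n, np.nan)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for idx, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        for side in (a, b):
            if side < n and np.isnan(first[side]):
                first[side] = h
        members[n + idx] = members.pop(a) + members.pop(b)
    return float(np.mean(1.0 - first / final))


def hcluster(dist: np.ndarray | pd.DataFrame, method: str = "ward",
             labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    ``dist`` is a full symmetric matrix with zero diagonal.  Ward follows
    the squared-distance (ward.D2) convention of the common
    implementations.  Heights are non-decreasing for the monotone linkages
    (ward, complete, average).
    """
    if method not in LINKAGES:
        raise ValueError(f"method must be one of {LINKAGES}")
    if isinstance(dist, pd.DataFrame):
        labels = labels or list(dist.index)
        dist = dist.to_numpy()
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(dist) != 0) or np.any(dist < 0):
        raise ValueError("distances must be non-negative with zero diagonal")
    labels = labels or [str(i) for i in range(n)]
    condensed = squareform(dist, checks=False)
    Z = sch.linkage(condensed, method=method)
    return Dendrogram(Z, list(labels), method, agglomerative_coefficient(Z))


def overlap_distance(overlap: OverlapMatrix | pd.DataFrame,
                     mode: str = "rows") -> pd.DataFrame:
    """Distance matrix for niche clustering from an overlap matrix.

    ``rows`` (default): Euclidean distance between the populations' rows of
    the similarity matrix, i.e. two populations are close when they relate
    to all others alike.  ``one_minus_i``: direct 1 - I dissimilarity.
    """
    sim = overlap.I if isinstance(overlap, OverlapMatrix) else overlap
    if mode == "one_minus_i":
        d = 1.0 - sim.to_numpy()
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
    elif mode == "rows":
        d = squareform(pdist(sim.to_numpy()))
    else:
        raise ValueError("mode must be 'rows' or 'one_minus_i'")
    return pd.DataFrame(d, index=sim.index, columns=sim.columns)


def assign_niches(dend: Dendrogram, k: int | None = None,
                  height: float | None = None) -> pd.Series:
    """Cut the tree into niches, numbered by dendrogram left-to-right order.

    Give either ``k`` (number of groups) or ``height`` (cut level); a
    height above the root yields a single group with a warning.
    """
    n = len(dend.labels)
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError("k must be between 1 and the number of leaves")
        raw = sch.fcluster(dend.Z, t=k, criterion="maxclust")
    elif height is not None:
        if height > dend.Z[-1, 2]:
            warnings.warn("cut height is above the root; single cluster")
        raw = sch.fcluster(dend.Z, t=height, criterion="distance")
    else:
        raise ValueError("give k or height")
    order = sch.leaves_list(dend.Z)
    relabel: dict[int, int] = {}
    for leaf in order:
        c = raw[leaf]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    labels = pd.Series([relabel[c] for c in raw], index=dend.labels,
                       name="niche")
    return labels


def cluster_niches(overlap: OverlapMatrix, k: int = 3, mode: str = "rows",
                   method: str = "ward"):
    """Full niche-clustering step: distances, tree (with AC for every
    linkage), and the k-group assignment."""
    d = overlap_distance(overlap, mode)
    dend = hcluster(d, method=method)
    acs = {m: hcluster(d, method=m).ac for m in LINKAGES}
    niches = assign_niches(dend, k=k)
    return dend, niches, acs
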