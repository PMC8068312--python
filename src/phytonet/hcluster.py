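"""Hierarchical clustering of plants by binary chemical profile.

Each plant is represented by the set of chemicals it contains (a 0/1
indicator vector over the chemical layer). Distances are Bray–Curtis:

    d(u, v) = Σ_j |u_j − v_j| / Σ_j (|u_j| + |v_j|)
            = |profile symmetric difference| / (deg u + deg v)

which on binary profiles equals one minus the Dice similarity. The metric
is scale-free — chemicals connected to neither plant do not enter — and
bounded in [0, 1], with d < 1 exactly when the plants share at least one
chemical.

Agglomeration uses complete linkage (cluster distance = farthest pair), so
cutting the tree at any height h ≤ 1 yields clusters in which every pair of
plants is at distance < h; in particular every within-cluster pair shares a
chemical ("shared-chemical guarantee").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .network import MultipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ChemicalProfile",
    "PlantDendrogram",
    "PlantCluster",
    "bray_curtis",
    "distance_matrix",
    "complete_linkage_tree",
    "cut_clusters",
    "tally_classes",
    "DEFAULT_CUT_HEIGHT",
]

# largest cut that still preserves the shared-chemical guarantee: merges at
# exactly 1 (disjoint profiles) stay separate
DEFAULT_CUT_HEIGHT = 1.0 - 1e-9


@dataclass(frozen=True)
class ChemicalProfile:
    """Sparse binary chemical profile of one plant."""

    plant_id: str
    chemicals: frozenset[str]

    @classmethod
    def from_network(cls, net: MultipartiteNetwork, plant_id: str) -> "ChemicalProfile":
        return cls(plant_id, net.chemical_profile(plant_id))


def bray_curtis(u: ChemicalProfile, v: ChemicalProfile) -> float:
    """Bray–Curtis distance between two binary profiles.

    |symmetric difference| / (|u| + |v|). Raises on two empty profiles
    (0/0), which cannot occur after degree-zero pruning.
    """
    du, dv = len(u.chemicals), len(v.chemicals)
    if du + dv == 0:
        raise ValueError(
            f"Bray-Curtis undefined for two empty profiles "
            f"({u.plant_id}, {v.plant_id})"
        )
    sym_diff = du + dv - 2 * len(u.chemicals & v.chemicals)
    return sym_diff / (du + dv)


def distance_matrix(net: MultipartiteNetwork) -> tuple[list[str], np.ndarray]:
    """Pairwise Bray–Curtis distances over all plants, lexicographic order.

    Returns (plant ids, square symmetric matrix with zero diagonal).
    """
    plants = sorted(net.plants)
    if not plants:
        return plants, np.zeros((0, 0))
    chems = sorted(net.chemicals)
    col = {c: j for j, c in enumerate(chems)}
    X = np.zeros((len(plants), len(chems)), dtype=float)
    for i, p in enumerate(plants):
        for c in net.chemical_profile(p):
            X[i, col[c]] = 1.0
    if len(plants) == 1:
        return plants, np.zeros((1, 1))
    D = squareform(pdist(X, metric="braycurtis"))
    return plants, D


@dataclass
class PlantDendrogram:
    """Complete-linkage merge tree over plants.

    ``Z`` is a scipy linkage matrix over ``leaves`` (lexicographically
    sorted plant ids); merge heights are Bray–Curtis distances in [0, 1]
    and non-decreasing along every root path.
    """

    leaves: list[str]
    Z: np.ndarray  # shape (n-1, 4); empty for a single leaf

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2] if self.Z.size else np.zeros(0)

    def to_newick(self) -> str:
        from .io import linkage_to_newick

        return linkage_to_newick(self.Z, self.leaves)


@dataclass
class PlantCluster:
    """A set of plants plus the union C_P of their chemical profiles."""

    cluster_id: int
    members: frozenset[str]
    chemical_union: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_network(
        cls, cluster_id: int, members: Sequence[str], net: MultipartiteNetwork
    ) -> "PlantCluster":
        union: set[str] = set()
        for p in members:
            union |= net.chemical_profile(p)
        return cls(cluster_id, frozenset(members), frozenset(union))


def complete_linkage_tree(
    plants: Sequence[str], D: np.ndarray
) -> PlantDendrogram:
    """Agglomerate with complete linkage (farthest-pair cluster distance).

    Leaves are sorted lexicographically before agglomeration so the result
    is reproducible for a given distance matrix regardless of input order.
    """
    plants = list(plants)
    n = len(plants)
    if n == 0:
        raise ValueError("no plants to cluster")
    order = np.argsort(np.array(plants, dtype=object))
    leaves = [plants[i] for i in order]
    if n == 1:
        return PlantDendrogram(leaves=leaves, Z=np.zeros((0, 4)))
    D = np.asarray(D, dtype=float)
    if D.shape != (n, n):
        raise ValueError(f"distance matrix shape {D.shape} does not match {n} plants")
    D = D[np.ix_(order, order)]
    Z = linkage(squareform(D, checks=False), method="complete")
    return PlantDendrogram(leaves=leaves, Z=Z)


def cut_clusters(
    dendrogram: PlantDendrogram,
    h_max: float = DEFAULT_CUT_HEIGHT,
    net: Optional[MultipartiteNetwork] = None,
) -> list[PlantCluster]:
    """Extract the maximal subtrees whose merge heights are all < ``h_max``.

    The inequality is strict, so ``h_max = 1`` still guarantees every
    within-cluster plant pair shares a chemical (a merge at height exactly 1
    joins disjoint profiles and is never applied). Merges at height exactly
    0 — identical chemical profiles, e.g. the same species with different
    used parts — are always applied, so ``h_max = 0`` yields singletons
    except for exact-duplicate profiles aggregated at the bottom level.

    If ``net`` is given, each cluster carries its chemical union C_P.
    Clusters are numbered 1..m by decreasing size, ties by smallest member.
    """
    if h_max < 0:
        raise ValueError(f"h_max must be >= 0, got {h_max}")
    n = dendrogram.n_leaves
    # union-find over linkage rows with height < h_max
    parent = list(range(2 * n - 1 if n > 1 else 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row_idx, row in enumerate(dendrogram.Z):
        a, b, h = int(row[0]), int(row[1]), float(row[2])
        node = n + row_idx
        if h < h_max or h == 0.0:
            parent[find(a)] = node
            parent[find(b)] = node
        # merges at >= h_max leave children as separate roots

    groups: dict[int, list[str]] = {}
    for i, leaf in enumerate(dendrogram.leaves):
        groups.setdefault(find(i), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    clusters = []
    for cid, members in enumerate(ordered, start=1):
        if net is not None:
            clusters.append(PlantCluster.from_network(cid, members, net))
        else:
            clusters.append(PlantCluster(cid, frozenset(members)))
    return clusters


def tally_classes(
    cluster: PlantCluster,
    annotations: Optional[pd.DataFrame],
    levels: Sequence[str] = ("subclass", "direct_parent"),
) -> dict[str, dict[str, int]]:
    """Count chemical-classification labels among a cluster's chemicals.

    For each requested level, returns {label: number of C_P chemicals with
    that label}; chemicals without an annotation row (or with an empty
    label) count under "unclassified". The number of distinct labels per
    level is just ``len`` of each mapping.
    """
    out: dict[str, dict[str, int]] = {}
    for level in levels:
        counts: dict[str, int] = {}
        for chem in sorted(cluster.chemical_union):
            label = "unclassified"
            if annotations is not None and chem in annotations.index:
                value = str(annotations.loc[chem, level]).strip()
                if value:
                    label = value
            counts[label] = counts.get(label, 0) + 1
        out[level] = counts
    return out
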