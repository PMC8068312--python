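"""Spectral co-clustering, partition quality, and structural statistics.

Because plants and targets both attach only to chemicals, the tripartite
network is bipartite between (plants ∪ targets) and chemicals. Co-clustering
therefore operates on the incidence matrix with rows = plants ∪ targets and
columns = chemicals: the degree-normalized incidence is decomposed by a
truncated SVD, rows and columns are embedded jointly, and k-means assigns
both to the same k clusters (Dhillon-style bipartite spectral graph
partitioning, which approximately minimizes the normalized cut). Row and
column clusters with the same index together form one subnetwork.

Two partition-quality functionals are provided:

* ``normalized_cut`` — (1/k) Σ_i cut(V_i, V̄_i) / vol(V_i); lower means the
  clusters are more weakly interconnected.
* ``modularity`` — (1/2E) Σ_i Σ_{m,n ∈ V_i} (w_mn − d_m d_n / 2E), the
  Newman modularity with the double sum over ordered pairs including the
  diagonal; the number of clusters is chosen at its maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import SpectralCoclustering

from .network import MultipartiteNetwork, NetworkStats

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "ModularityCurve",
    "spectral_cocluster",
    "normalized_cut",
    "modularity",
    "select_k",
    "structural_stats",
]


@dataclass
class Partition:
    """Assignment of every network node to one of k disjoint clusters.

    Cluster indices are contiguous integers starting at 1. ``k`` counts the
    nonempty clusters actually produced (k-means may return fewer clusters
    than requested on degenerate inputs).
    """

    k: int
    assignment: dict[str, int]
    normalized_cut: float = float("nan")
    modularity: float = float("nan")

    def members(self, cluster: int) -> set[str]:
        return {n for n, c in self.assignment.items() if c == cluster}

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for n, c in self.assignment.items():
            out.setdefault(c, set()).add(n)
        return out


@dataclass
class ModularityCurve:
    """Modularity as a function of the requested cluster count k."""

    entries: list[tuple[int, float]] = field(default_factory=list)

    @property
    def k_best(self) -> int:
        if not self.entries:
            raise ValueError("empty modularity curve")
        best_k, best_q = self.entries[0]
        for k, q in self.entries[1:]:
            if q > best_q or (q == best_q and k < best_k):
                best_k, best_q = k, q
        return best_k


def _relabel_contiguous(labels: Mapping[str, int]) -> tuple[int, dict[str, int]]:
    """Relabel cluster ids to contiguous 1..k, ordered by first appearance
    over sorted node ids (deterministic)."""
    mapping: dict[int, int] = {}
    out: dict[str, int] = {}
    for node in sorted(labels):
        raw = labels[node]
        if raw not in mapping:
            mapping[raw] = len(mapping) + 1
        out[node] = mapping[raw]
    return len(mapping), out


def spectral_cocluster(
    net: MultipartiteNetwork, k: int, seed: int = 0, n_init: int = 10
) -> Partition:
    """Partition the network into k subnetworks by spectral co-clustering.

    Deterministic for a fixed ``seed`` (which controls both the randomized
    SVD and the k-means restarts). ``k`` may not exceed the number of
    nonzero rows or columns of the incidence matrix. ``k = 1`` is the
    trivial partition (normalized cut 0; modularity 0 when the network has
    edges).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not net.nodes:
        raise ValueError("cannot cluster an empty network")
    rows, cols, A = net.incidence()
    if k == 1:
        assignment = {n: 1 for n in net.nodes}
        part = Partition(k=1, assignment=assignment)
        part.normalized_cut = normalized_cut(net, part)
        part.modularity = modularity(net, part) if net.n_edges else 0.0
        return part
    row_deg = np.asarray(A.sum(axis=1)).ravel()
    col_deg = np.asarray(A.sum(axis=0)).ravel()
    n_rows_eff = int((row_deg > 0).sum())
    n_cols_eff = int((col_deg > 0).sum())
    if k > min(n_rows_eff, n_cols_eff):
        raise ValueError(
            f"k={k} exceeds the incidence rank bound "
            f"min({n_rows_eff} nonempty rows, {n_cols_eff} nonempty columns)"
        )
    if (row_deg == 0).any() or (col_deg == 0).any():
        raise ValueError(
            "network contains degree-zero nodes; prune before co-clustering"
        )
    model = SpectralCoclustering(
        n_clusters=k, n_init=n_init, random_state=seed, svd_method="randomized"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # SVD convergence chatter on tiny inputs
        model.fit(A)
    labels = {node: int(lab) for node, lab in zip(rows, model.row_labels_)}
    labels.update({node: int(lab) for node, lab in zip(cols, model.column_labels_)})
    k_eff, assignment = _relabel_contiguous(labels)
    if k_eff < k:
        logger.warning("requested k=%d but only %d nonempty clusters found", k, k_eff)
    part = Partition(k=k_eff, assignment=assignment)
    part.normalized_cut = normalized_cut(net, part)
    part.modularity = modularity(net, part)
    return part


def _check_cover(net: MultipartiteNetwork, partition: Partition) -> None:
    missing = net.nodes - partition.assignment.keys()
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")


def normalized_cut(net: MultipartiteNetwork, partition: Partition) -> float:
    """(1/k) Σ_i cut(V_i, V̄_i) / vol(V_i).

    cut(V_i, V̄_i) is the number of edges leaving cluster i and vol(V_i) the
    total degree inside it. Clusters of zero volume contribute 0 with a
    warning. Equals 0 exactly when no edge crosses clusters (and for k=1).
    """
    _check_cover(net, partition)
    clusters = partition.clusters()
    k = len(clusters)
    adj = net.adjacency
    total = 0.0
    for members in clusters.values():
        vol = sum(len(adj[n]) for n in members)
        if vol == 0:
            logger.warning("cluster with zero volume contributes 0 to normalized cut")
            continue
        cut = sum(
            1 for n in members for nb in adj[n] if nb not in members
        )
        total += cut / vol
    return total / k


def modularity(net: MultipartiteNetwork, partition: Partition) -> float:
    """Newman modularity of the partition.

    Q = (1/2E) Σ_i Σ_{m,n ∈ V_i} (w_mn − d_m d_n / 2E) with the inner sum
    over ordered node pairs including m = n. Per cluster this reduces to
    (within-edge count)/E − (vol/2E)², so the one-cluster partition scores
    exactly 0. Undefined (raises) on an edgeless network.
    """
    _check_cover(net, partition)
    E = net.n_edges
    if E == 0:
        raise ValueError("modularity is undefined on a network with no edges")
    adj = net.adjacency
    q = 0.0
    for members in partition.clusters().values():
        within = sum(1 for n in members for nb in adj[n] if nb in members)  # = 2·E_in
        vol = sum(len(adj[n]) for n in members)
        q += within / (2 * E) - (vol / (2 * E)) ** 2
    return q


def select_k(
    net: MultipartiteNetwork,
    k_range: Iterable[int] = range(2, 21),
    seed: int = 0,
) -> tuple[ModularityCurve, dict[int, Partition]]:
    """Scan k, score each partition by modularity, pick the maximum.

    Ties break toward the smallest k (parsimony). Returns the curve and the
    partitions keyed by requested k, so the winning partition needs no
    refit.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    curve = ModularityCurve()
    partitions: dict[int, Partition] = {}
    for k in ks:
        part = spectral_cocluster(net, k, seed=seed)
        partitions[k] = part
        curve.entries.append((k, part.modularity))
    logger.info("modularity maximum at k=%d", curve.k_best)
    return curve, partitions


# -- structural statistics -------------------------------------------------


def _degree_histogram(degrees: Iterable[int]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def structural_stats(net: MultipartiteNetwork) -> NetworkStats:
    """Diameter (largest component), average bipartite clustering
    coefficient, degree assortativity, and per-layer degree histograms.

    The bipartite clustering coefficient of a node u averages, over u's
    second neighbors v, the neighborhood overlap |N(u)∩N(v)| / |N(u)∪N(v)|;
    the network value averages over all nodes. Assortativity is the Pearson
    correlation of endpoint degrees over edges and is None when degenerate
    (zero degree variance).
    """
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        return NetworkStats(0, 0, 0, 0, 0, 0.0, 0, 0.0, None, {})
    if g.number_of_edges() == 0:
        diameter = 0
        avg_cc = 0.0
        assort: Optional[float] = None
    else:
        lcc = max(nx.connected_components(g), key=len)
        diameter = nx.diameter(g.subgraph(lcc))
        cc = nx.algorithms.bipartite.clustering(g, mode="dot")
        avg_cc = float(sum(cc.values()) / len(cc)) if cc else 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                a = nx.degree_assortativity_coefficient(g)
                assort = None if not np.isfinite(a) else float(a)
            except (ValueError, ZeroDivisionError):
                assort = None
    hists = {
        "plant": _degree_histogram(net.degree(n) for n in net.plants),
        "chemical": _degree_histogram(net.degree(n) for n in net.chemicals),
        "target": _degree_histogram(net.degree(n) for n in net.targets),
    }
    return NetworkStats(
        n_plants=net.n_plants,
        n_chemicals=net.n_chemicals,
        n_targets=net.n_targets,
        n_pc_edges=len(net.pc_edges),
        n_ct_edges=len(net.ct_edges),
        density=net.density(),
        diameter_lcc=int(diameter),
        avg_bipartite_clustering=avg_cc,
        degree_assortativity=assort,
        degree_histograms=hists,
    )
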