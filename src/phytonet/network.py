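"""Core domain types: plant records, target predictions, and the tripartite network.

The central object is :class:`MultipartiteNetwork`, an undirected, unweighted
graph over three disjoint node layers — plants, chemicals, and protein
targets — in which edges exist only between plants and chemicals (membership
of a chemical in a plant) and between chemicals and targets (predicted
bioactivity). Plants and targets never touch each other directly; every
plant–target relationship is mediated by shared chemistry, which is what the
downstream clustering and scoring exploit.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "PlantRecord",
    "TargetPrediction",
    "MultipartiteNetwork",
    "NetworkStats",
    "build_network",
    "multipartite_density",
]


class Category(str, enum.Enum):
    """Organism category of a raw record.

    Raw medicinal-material inventories mix true plants with fungi, animals
    (including corals) and minerals; only plants and fungi are retained by
    preprocessing.
    """

    PLANT = "plant"
    FUNGUS = "fungus"
    ANIMAL = "animal"
    MINERAL = "mineral"
    OTHER = "other"

    @classmethod
    def coerce(cls, value: object) -> "Category":
        """Map arbitrary input to a category; unknown values become OTHER."""
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        try:
            return cls(text)
        except ValueError:
            return cls.OTHER


@dataclass(frozen=True)
class PlantRecord:
    """One row of the plant inventory.

    ``record_id`` is an opaque identifier unique within a record set. The
    triple (scientific_name, latin_name, use_target) is the deduplication
    key: the same species listed with a different used part (root vs leaf)
    counts as a distinct medicinal material.
    """

    record_id: str
    scientific_name: str
    latin_name: str
    use_target: str
    category: Category = Category.PLANT

    @property
    def dedup_key(self) -> tuple[str, str, str]:
        return (self.scientific_name, self.latin_name, self.use_target)


@dataclass(frozen=True)
class TargetPrediction:
    """A predicted chemical–target activity with probability in [0, 1]."""

    chemical_id: str
    target_id: str
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(
                f"probability must lie in [0, 1], got {self.probability!r} "
                f"for ({self.chemical_id}, {self.target_id})"
            )


def multipartite_density(
    n_plants: int, n_chemicals: int, n_targets: int, n_edges: int
) -> float:
    """Density of a tripartite plant–chemical–target network.

    Defined as E / (Np*Nc + Nc*Nt): the realized edge count over the number
    of edges possible under the layer constraint (plants and targets may
    only link to chemicals). A zero denominator yields 0.0 with a warning.
    """
    denom = n_plants * n_chemicals + n_chemicals * n_targets
    if denom == 0:
        if n_edges:
            logger.warning("density denominator is zero with %d edges", n_edges)
        return 0.0
    return n_edges / denom


class MultipartiteNetwork:
    """Tripartite unweighted graph over plants, chemicals, and targets.

    Edges are stored as two sets: ``pc_edges`` (plant, chemical) and
    ``ct_edges`` (chemical, target). Layers are pairwise disjoint; layer
    purity (every edge touches exactly one chemical) is enforced at
    construction. Nodes of degree zero are permitted — preprocessing prunes
    them explicitly — so the node sets may be larger than the edge support.
    """

    def __init__(
        self,
        plants: Iterable[str],
        chemicals: Iterable[str],
        targets: Iterable[str],
        pc_edges: Iterable[tuple[str, str]],
        ct_edges: Iterable[tuple[str, str]],
        node_attrs: Optional[Mapping[str, Mapping[str, object]]] = None,
    ) -> None:
        self.plants: frozenset[str] = frozenset(plants)
        self.chemicals: frozenset[str] = frozenset(chemicals)
        self.targets: frozenset[str] = frozenset(targets)
        self.pc_edges: frozenset[tuple[str, str]] = frozenset(
            (str(p), str(c)) for p, c in pc_edges
        )
        self.ct_edges: frozenset[tuple[str, str]] = frozenset(
            (str(c), str(t)) for c, t in ct_edges
        )
        self.node_attrs: dict[str, dict[str, object]] = {
            k: dict(v) for k, v in (node_attrs or {}).items()
        }
        self._adj: Optional[dict[str, set[str]]] = None
        self._validate()

    def _validate(self) -> None:
        if self.plants & self.chemicals or self.plants & self.targets or (
            self.chemicals & self.targets
        ):
            overlap = (self.plants & self.chemicals) | (
                self.plants & self.targets
            ) | (self.chemicals & self.targets)
            raise ValueError(f"layers are not disjoint; shared ids: {sorted(overlap)[:5]}")
        for p, c in self.pc_edges:
            if p not in self.plants or c not in self.chemicals:
                raise ValueError(
                    f"plant-chemical edge ({p}, {c}) has an endpoint outside its layer"
                )
        for c, t in self.ct_edges:
            if c not in self.chemicals or t not in self.targets:
                raise ValueError(
                    f"chemical-target edge ({c}, {t}) has an endpoint outside its layer"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_chemicals(self) -> int:
        return len(self.chemicals)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_edges(self) -> int:
        return len(self.pc_edges) + len(self.ct_edges)

    @property
    def nodes(self) -> frozenset[str]:
        return self.plants | self.chemicals | self.targets

    def layer_of(self, node: str) -> str:
        if node in self.plants:
            return "plant"
        if node in self.chemicals:
            return "chemical"
        if node in self.targets:
            return "target"
        raise KeyError(node)

    @property
    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for p, c in self.pc_edges:
                adj[p].add(c)
                adj[c].add(p)
            for c, t in self.ct_edges:
                adj[c].add(t)
                adj[t].add(c)
            self._adj = adj
        return self._adj

    def degree(self, node: str) -> int:
        return len(self.adjacency[node])

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self.adjacency[node])

    def chemical_profile(self, plant_id: str) -> frozenset[str]:
        """Set of chemicals connected to a plant (the binary profile support)."""
        if plant_id not in self.plants:
            raise KeyError(f"unknown plant {plant_id!r}")
        return frozenset(self.adjacency[plant_id])

    def target_chemicals(self, target_id: str) -> frozenset[str]:
        """Set C_T of chemicals connected to a target."""
        if target_id not in self.targets:
            raise KeyError(f"unknown target {target_id!r}")
        return frozenset(self.adjacency[target_id])

    def density(self) -> float:
        return multipartite_density(
            self.n_plants, self.n_chemicals, self.n_targets, self.n_edges
        )

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for layer, nodes in (
            ("plant", self.plants),
            ("chemical", self.chemicals),
            ("target", self.targets),
        ):
            for n in sorted(nodes):
                g.add_node(n, layer=layer, **self.node_attrs.get(n, {}))
        g.add_edges_from(sorted(self.pc_edges))
        g.add_edges_from((c, t) for c, t in sorted(self.ct_edges))
        return g

    def incidence(self) -> tuple[list[str], list[str], sp.csr_matrix]:
        """Bipartite incidence with rows = plants ∪ targets, columns = chemicals.

        Because plants and targets both attach only to chemicals, the whole
        tripartite graph is bipartite between (plants ∪ targets) and
        chemicals; this is the matrix spectral co-clustering operates on.
        """
        rows = sorted(self.plants) + sorted(self.targets)
        cols = sorted(self.chemicals)
        row_index = {n: i for i, n in enumerate(rows)}
        col_index = {n: j for j, n in enumerate(cols)}
        r, c = [], []
        for p, ch in self.pc_edges:
            r.append(row_index[p])
            c.append(col_index[ch])
        for ch, t in self.ct_edges:
            r.append(row_index[t])
            c.append(col_index[ch])
        data = np.ones(len(r), dtype=float)
        mat = sp.csr_matrix((data, (r, c)), shape=(len(rows), len(cols)))
        return rows, cols, mat

    def subnetwork(self, nodes: Iterable[str]) -> "MultipartiteNetwork":
        """Induced subnetwork on a node subset (attributes carried over)."""
        keep = set(nodes)
        return MultipartiteNetwork(
            plants=self.plants & keep,
            chemicals=self.chemicals & keep,
            targets=self.targets & keep,
            pc_edges=[(p, c) for p, c in self.pc_edges if p in keep and c in keep],
            ct_edges=[(c, t) for c, t in self.ct_edges if c in keep and t in keep],
            node_attrs={n: a for n, a in self.node_attrs.items() if n in keep},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultipartiteNetwork):
            return NotImplemented
        return (
            self.plants == other.plants
            and self.chemicals == other.chemicals
            and self.targets == other.targets
            and self.pc_edges == other.pc_edges
            and self.ct_edges == other.ct_edges
        )

    def __repr__(self) -> str:
        return (
            f"MultipartiteNetwork(plants={self.n_plants}, "
            f"chemicals={self.n_chemicals}, targets={self.n_targets}, "
            f"pc_edges={len(self.pc_edges)}, ct_edges={len(self.ct_edges)})"
        )


@dataclass
class NetworkStats:
    """Structural summary of a (sub)network.

    ``degree_assortativity`` is None when undefined (zero degree variance,
    e.g. a single edge). ``diameter_lcc`` is measured on the largest
    connected component.
    """

    n_plants: int
    n_chemicals: int
    n_targets: int
    n_pc_edges: int
    n_ct_edges: int
    density: float
    diameter_lcc: int
    avg_bipartite_clustering: float
    degree_assortativity: Optional[float]
    degree_histograms: dict[str, dict[int, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_plants": self.n_plants,
            "n_chemicals": self.n_chemicals,
            "n_targets": self.n_targets,
            "n_pc_edges": self.n_pc_edges,
            "n_ct_edges": self.n_ct_edges,
            "density": self.density,
            "diameter_lcc": self.diameter_lcc,
            "avg_bipartite_clustering": self.avg_bipartite_clustering,
            "degree_assortativity": self.degree_assortativity,
            "degree_histograms": {
                layer: {str(k): v for k, v in hist.items()}
                for layer, hist in self.degree_histograms.items()
            },
        }
        return d


def build_network(
    records: Sequence[PlantRecord] | Iterable[str],
    pc_edges: Iterable[tuple[str, str]],
    ct_edges: Iterable[tuple[str, str]],
    *,
    chemicals: Optional[Iterable[str]] = None,
    targets: Optional[Iterable[str]] = None,
    strict: bool = False,
) -> MultipartiteNetwork:
    """Assemble the tripartite network from relation tables.

    Plants are taken from ``records`` (PlantRecord objects or bare ids);
    chemicals and targets are registered from the edge lists, optionally
    extended by explicit ``chemicals``/``targets`` registries so that
    degree-zero nodes survive until an explicit pruning step. Edge
    multiplicity collapses to 1. Plant ids appearing only in edges are
    auto-registered with a warning, or rejected when ``strict`` is set.

    Raises ValueError if an edge would join two nodes of the same layer or
    a plant directly to a target.
    """
    plant_ids: set[str] = set()
    node_attrs: dict[str, dict[str, object]] = {}
    for rec in records:
        if isinstance(rec, PlantRecord):
            plant_ids.add(rec.record_id)
            node_attrs[rec.record_id] = {
                "scientific_name": rec.scientific_name,
                "latin_name": rec.latin_name,
                "use_target": rec.use_target,
                "category": rec.category.value,
            }
        else:
            plant_ids.add(str(rec))

    pc = {(str(p), str(c)) for p, c in pc_edges}
    ct = {(str(c), str(t)) for c, t in ct_edges}

    chem_ids = set(map(str, chemicals)) if chemicals is not None else set()
    chem_ids |= {c for _, c in pc} | {c for c, _ in ct}
    target_ids = set(map(str, targets)) if targets is not None else set()
    target_ids |= {t for _, t in ct}

    unknown_plants = {p for p, _ in pc} - plant_ids
    if unknown_plants:
        if strict:
            raise ValueError(
                f"plant-chemical edges reference unknown plant ids: "
                f"{sorted(unknown_plants)[:5]}"
            )
        logger.warning(
            "auto-registering %d plant ids found only in edges", len(unknown_plants)
        )
        plant_ids |= unknown_plants

    # layer-purity checks before constructing (clearer errors than the
    # disjointness failure the constructor would raise)
    for p, c in pc:
        if p in target_ids or c in target_ids:
            raise ValueError(f"edge ({p}, {c}) would join the plant and target layers")
        if c in plant_ids:
            raise ValueError(f"edge ({p}, {c}) would join two plant-layer nodes")
    for c, t in ct:
        if t in plant_ids or c in plant_ids:
            raise ValueError(f"edge ({c}, {t}) would join the plant and target layers")

    return MultipartiteNetwork(
        plants=plant_ids,
        chemicals=chem_ids,
        targets=target_ids,
        pc_edges=pc,
        ct_edges=ct,
        node_attrs=node_attrs,
    )
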