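"""Target Potency Score (TPS) and bidirectional subnetwork retrieval.

TPS measures how much of a target's predicted chemistry a plant cluster
covers:

    TPS(P, T) = |C_P ∩ C_T| / |C_T|

where C_P is the set of chemicals connected to at least one plant in
cluster P and C_T the set of chemicals connected to target T. It lies in
[0, 1], is 1 when the cluster contains all of the target's chemicals, 0
when it contains none, and is monotone non-decreasing as the cluster grows.
TPS is a connectivity fraction — a screening index, not a pharmacological
effect size.

Two retrieval modes: rank the targets for a given plant cluster (with a
minimum-|C_T| reliability filter, default 20 chemicals), or find the plant
cluster best covering a given target. A multi-target report decomposes the
shared chemistry of several targets (pairwise and full intersections, with
the plants carrying each shared chemical).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .hcluster import PlantCluster
from .network import MultipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TPSResult",
    "MultiTargetReport",
    "tps_score",
    "rank_targets_for_cluster",
    "best_cluster_for_target",
    "multi_target_report",
    "extract_subnetwork",
    "DEFAULT_MIN_TARGET_CHEMICALS",
]

DEFAULT_MIN_TARGET_CHEMICALS = 20


@dataclass
class TPSResult:
    cluster_id: int
    target_id: str
    tps: float
    n_target_chemicals: int
    n_overlap: int
    overlap_chemicals: frozenset[str] = field(default_factory=frozenset)

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "target_id": self.target_id,
            "tps": self.tps,
            "n_target_chemicals": self.n_target_chemicals,
            "n_overlap": self.n_overlap,
            "overlap_chemicals": sorted(self.overlap_chemicals),
        }


def tps_score(
    cluster: PlantCluster, target_id: str, net: MultipartiteNetwork
) -> TPSResult:
    """TPS(P, T) = |C_P ∩ C_T| / |C_T| by exact set arithmetic."""
    c_t = net.target_chemicals(target_id)
    if not c_t:
        raise ValueError(
            f"target {target_id!r} has no connected chemicals; TPS undefined"
        )
    overlap = cluster.chemical_union & c_t
    return TPSResult(
        cluster_id=cluster.cluster_id,
        target_id=target_id,
        tps=len(overlap) / len(c_t),
        n_target_chemicals=len(c_t),
        n_overlap=len(overlap),
        overlap_chemicals=frozenset(overlap),
    )


def rank_targets_for_cluster(
    cluster: PlantCluster,
    net: MultipartiteNetwork,
    tps_min: float,
    min_target_chemicals: int = DEFAULT_MIN_TARGET_CHEMICALS,
) -> list[TPSResult]:
    """Targets for one plant cluster, highest TPS first.

    Targets with fewer than ``min_target_chemicals`` connected chemicals
    are excluded before thresholding (small denominators make the fraction
    unreliable); survivors must reach ``tps_min``. Ties break by target
    identifier. An empty result is legitimate.
    """
    if not (0.0 <= tps_min <= 1.0):
        raise ValueError(f"tps_min must lie in [0, 1], got {tps_min!r}")
    results = []
    for target in sorted(net.targets):
        c_t = net.target_chemicals(target)
        if len(c_t) < min_target_chemicals:
            continue
        res = tps_score(cluster, target, net)
        if res.tps >= tps_min:
            results.append(res)
    results.sort(key=lambda r: (-r.tps, r.target_id))
    return results


def best_cluster_for_target(
    clusters: Sequence[PlantCluster],
    target_id: str,
    net: MultipartiteNetwork,
) -> TPSResult:
    """The plant cluster with maximal TPS for one target.

    Ties break toward the smaller cluster (fewest plants), then by
    lexicographically smallest member — deterministic and biased against
    trivially-large clusters, whose TPS is inflated by monotonicity.
    """
    if not clusters:
        raise ValueError("no clusters supplied")
    if target_id not in net.targets:
        raise KeyError(f"unknown target {target_id!r}")
    scored = [(tps_score(c, target_id, net), c) for c in clusters]
    scored.sort(key=lambda rc: (-rc[0].tps, len(rc[1].members), min(rc[1].members)))
    return scored[0][0]


@dataclass
class MultiTargetReport:
    """Shared-chemistry decomposition for a set of targets."""

    targets: list[str]
    target_chemicals: dict[str, frozenset[str]]
    pairwise_overlap: dict[tuple[str, str], int]
    common_chemicals: frozenset[str]
    chemical_plants: dict[str, list[str]]  # common chemical -> carrier plants

    def to_dict(self) -> dict:
        return {
            "targets": self.targets,
            "n_target_chemicals": {t: len(s) for t, s in self.target_chemicals.items()},
            "pairwise_overlap": {
                f"{a}|{b}": n for (a, b), n in self.pairwise_overlap.items()
            },
            "common_chemicals": sorted(self.common_chemicals),
            "chemical_plants": self.chemical_plants,
        }


def multi_target_report(
    target_ids: Sequence[str],
    net: MultipartiteNetwork,
    clusters: Optional[Sequence[PlantCluster]] = None,
) -> MultiTargetReport:
    """Pairwise and full chemical-set intersections for >= 2 targets.

    For every chemical shared by all the targets, lists the plants
    connected to it (restricted to cluster members when ``clusters`` is
    given), mirroring a chemical-to-source-plant lookup.
    """
    targets = list(dict.fromkeys(target_ids))
    if len(targets) < 2:
        raise ValueError("multi-target report needs at least 2 distinct targets")
    sets: dict[str, frozenset[str]] = {}
    for t in targets:
        c_t = net.target_chemicals(t)
        if not c_t:
            raise ValueError(f"target {t!r} has no connected chemicals")
        sets[t] = c_t
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(targets)
        for b in targets[i + 1 :]
    }
    common = frozenset(set.intersection(*(set(s) for s in sets.values())))
    allowed_plants: Optional[set[str]] = None
    if clusters is not None:
        allowed_plants = set()
        for c in clusters:
            allowed_plants |= c.members
    chem_plants: dict[str, list[str]] = {}
    for chem in sorted(common):
        plants = [p for p in net.neighbors(chem) if p in net.plants]
        if allowed_plants is not None:
            plants = [p for p in plants if p in allowed_plants]
        chem_plants[chem] = sorted(plants)
    return MultiTargetReport(
        targets=targets,
        target_chemicals=sets,
        pairwise_overlap=pairwise,
        common_chemicals=common,
        chemical_plants=chem_plants,
    )


def extract_subnetwork(
    cluster: PlantCluster,
    target_ids: Sequence[str],
    net: MultipartiteNetwork,
) -> MultipartiteNetwork:
    """Induced subnetwork linking a plant cluster to chosen targets.

    Keeps the cluster's plants, the listed targets, and exactly the
    chemicals connected to at least one cluster plant AND at least one
    listed target, with their incident edges inside the selection. Chemicals
    (all of which lie in the overlap) carry a ``tps_overlap`` attribute for
    rendering. May be empty, with a warning.
    """
    targets = [t for t in dict.fromkeys(target_ids)]
    for t in targets:
        if t not in net.targets:
            raise KeyError(f"unknown target {t!r}")
    target_chems: set[str] = set()
    for t in targets:
        target_chems |= net.target_chemicals(t)
    chems = cluster.chemical_union & target_chems
    keep = set(cluster.members) | set(targets) | chems
    sub = net.subnetwork(keep)
    if sub.n_edges == 0:
        logger.warning(
            "cluster %s shares no chemical with targets %s; empty subnetwork",
            cluster.cluster_id, targets,
        )
    for chem in chems:
        sub.node_attrs.setdefault(chem, {})["tps_overlap"] = True
    return sub
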