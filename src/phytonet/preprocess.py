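"""Preprocessing cascade from raw relation tables to the analysis network.

The cascade runs in a fixed order, with a stage report (node counts, edge
counts, density) recorded after each step:

1. raw data — every record and every prediction, unthresholded;
2. non-plant removal — minerals and animals dropped, fungi kept;
3. deduplication — records identical on (scientific name, Latin name, use
   target) collapse to the first occurrence, whose plant–chemical edges
   become the union over the duplicates;
4. probability threshold — a chemical–target interaction requires prediction
   probability strictly above ``p_min`` (default 0.9); targets with no
   surviving prediction leave the network at this stage;
5. pruning — all remaining degree-zero nodes (plants, chemicals, or
   targets) are removed. Pruning deletes nodes only, never edges.

Density at every stage is E / (Np*Nc + Nc*Nt), the edge count over the
number of edges the layer constraint permits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .network import (
    MultipartiteNetwork,
    PlantRecord,
    TargetPrediction,
    build_network,
    multipartite_density,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StageReport",
    "filter_non_plants",
    "deduplicate_plants",
    "threshold_predictions",
    "prune_isolated",
    "stage_report",
    "run_preprocess",
    "STAGE_NAMES",
]

STAGE_NAMES = (
    "raw",
    "without_non_plants",
    "without_duplicates",
    "probability_threshold",
    "preprocessed",
)

KEPT_CATEGORIES = frozenset({"plant", "fungus"})


@dataclass
class StageReport:
    stage_name: str
    n_plants: int
    n_chemicals: int
    n_targets: int
    n_pc_edges: int
    n_ct_edges: int
    density: float

    @property
    def n_total_nodes(self) -> int:
        return self.n_plants + self.n_chemicals + self.n_targets

    @property
    def n_total_edges(self) -> int:
        return self.n_pc_edges + self.n_ct_edges

    def to_dict(self) -> dict:
        return {
            "stage_name": self.stage_name,
            "n_plants": self.n_plants,
            "n_chemicals": self.n_chemicals,
            "n_targets": self.n_targets,
            "n_total_nodes": self.n_total_nodes,
            "n_pc_edges": self.n_pc_edges,
            "n_ct_edges": self.n_ct_edges,
            "n_total_edges": self.n_total_edges,
            "density": self.density,
        }


def filter_non_plants(records: Sequence[PlantRecord]) -> list[PlantRecord]:
    """Keep plants and fungi; drop animals, minerals, and unknowns.

    Order is preserved. Category is taken from the explicit record field —
    curation of ambiguous materials is an input concern, not replicated
    here.
    """
    kept = [r for r in records if r.category.value in KEPT_CATEGORIES]
    if len(kept) < len(records):
        logger.info("filtered %d non-plant records", len(records) - len(kept))
    return kept


def deduplicate_plants(
    records: Sequence[PlantRecord],
) -> tuple[list[PlantRecord], dict[str, str]]:
    """Collapse records identical on (scientific_name, latin_name, use_target).

    The first occurrence in input order survives. Returns the kept records
    and a mapping {removed record_id -> surviving record_id} so that the
    removed duplicates' plant–chemical edges can be merged into the
    survivor.
    """
    first_by_key: dict[tuple[str, str, str], str] = {}
    kept: list[PlantRecord] = []
    remap: dict[str, str] = {}
    for rec in records:
        survivor = first_by_key.get(rec.dedup_key)
        if survivor is None:
            first_by_key[rec.dedup_key] = rec.record_id
            kept.append(rec)
        else:
            remap[rec.record_id] = survivor
    if remap:
        logger.info("removed %d duplicate records", len(remap))
    return kept, remap


def threshold_predictions(
    predictions: Iterable[TargetPrediction], p_min: float = 0.9
) -> list[tuple[str, str]]:
    """Chemical-target edges whose probability is strictly above ``p_min``.

    The inequality is strict: a prediction at exactly ``p_min`` is
    discarded.
    """
    if not (0.0 <= p_min <= 1.0):
        raise ValueError(f"p_min must lie in [0, 1], got {p_min!r}")
    return [
        (p.chemical_id, p.target_id) for p in predictions if p.probability > p_min
    ]


def prune_isolated(
    net: MultipartiteNetwork,
) -> tuple[MultipartiteNetwork, dict[str, list[str]]]:
    """Remove degree-zero nodes; report the removals per layer.

    A single pass suffices: removing an unconnected node deletes no edges,
    so no new isolates can appear.
    """
    adj = net.adjacency
    removed = {
        "plants": sorted(n for n in net.plants if not adj[n]),
        "chemicals": sorted(n for n in net.chemicals if not adj[n]),
        "targets": sorted(n for n in net.targets if not adj[n]),
    }
    drop = set(removed["plants"]) | set(removed["chemicals"]) | set(removed["targets"])
    if not drop:
        return net, removed
    pruned = MultipartiteNetwork(
        plants=net.plants - drop,
        chemicals=net.chemicals - drop,
        targets=net.targets - drop,
        pc_edges=net.pc_edges,
        ct_edges=net.ct_edges,
        node_attrs={n: a for n, a in net.node_attrs.items() if n not in drop},
    )
    logger.info(
        "pruned %d isolated nodes (%d plants, %d chemicals, %d targets)",
        len(drop), len(removed["plants"]), len(removed["chemicals"]),
        len(removed["targets"]),
    )
    return pruned, removed


def stage_report(net: MultipartiteNetwork, stage_name: str) -> StageReport:
    return StageReport(
        stage_name=stage_name,
        n_plants=net.n_plants,
        n_chemicals=net.n_chemicals,
        n_targets=net.n_targets,
        n_pc_edges=len(net.pc_edges),
        n_ct_edges=len(net.ct_edges),
        density=multipartite_density(
            net.n_plants, net.n_chemicals, net.n_targets, net.n_edges
        ),
    )


def run_preprocess(
    records: Sequence[PlantRecord],
    pc_edges: Sequence[tuple[str, str]],
    predictions: Sequence[TargetPrediction],
    p_min: float = 0.9,
) -> tuple[MultipartiteNetwork, list[StageReport]]:
    """Run the full cascade and return the final network plus 5 stage reports.

    The chemical and target registries of the raw network are carried
    through the intermediate stages, so chemicals left without edges by the
    earlier filters remain counted until the explicit pruning stage.
    """
    raw_ct = [(p.chemical_id, p.target_id) for p in predictions]
    raw_net = build_network(records, pc_edges, raw_ct)
    reports = [stage_report(raw_net, STAGE_NAMES[0])]
    all_chems = raw_net.chemicals
    all_targets = raw_net.targets

    # stage 2: drop non-plant records and their edges
    kept = filter_non_plants(records)
    kept_ids = {r.record_id for r in kept}
    pc2 = [(p, c) for p, c in pc_edges if p in kept_ids]
    net2 = build_network(kept, pc2, raw_ct, chemicals=all_chems, targets=all_targets)
    reports.append(stage_report(net2, STAGE_NAMES[1]))

    # stage 3: dedup, merging removed duplicates' edges into the survivor
    deduped, remap = deduplicate_plants(kept)
    pc3 = [(remap.get(p, p), c) for p, c in pc2]
    net3 = build_network(deduped, pc3, raw_ct, chemicals=all_chems, targets=all_targets)
    reports.append(stage_report(net3, STAGE_NAMES[2]))

    # stage 4: strict probability threshold; targets with no surviving
    # prediction leave the registry here
    ct4 = threshold_predictions(predictions, p_min)
    net4 = build_network(deduped, pc3, ct4, chemicals=all_chems)
    reports.append(stage_report(net4, STAGE_NAMES[3]))

    # stage 5: prune degree-zero nodes
    net5, _removed = prune_isolated(net4)
    reports.append(stage_report(net5, STAGE_NAMES[4]))
    return net5, reports
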