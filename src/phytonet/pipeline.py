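"""One-command orchestration: preprocess → co-cluster → dendrogram → TPS.

``run_pipeline`` executes the full analysis from either real input tables
or a synthetic specification, writes every artifact to the output
directory, and finishes with a manifest listing each file with its SHA-256
content hash. All randomness flows from the single ``seed`` in the config,
so identical configs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import io as pio
from .cocluster import select_k, structural_stats
from .hcluster import (
    DEFAULT_CUT_HEIGHT,
    complete_linkage_tree,
    cut_clusters,
    distance_matrix,
    tally_classes,
)
from .preprocess import run_preprocess
from .synth import SyntheticSpec, generate
from .tps import DEFAULT_MIN_TARGET_CHEMICALS, rank_targets_for_cluster

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    Either the three input paths or ``synthetic`` must be set. Thresholds:
    ``p_min`` — strict activity-probability cut-off; ``k_min``/``k_max`` —
    modularity scan range; ``h_max`` — dendrogram cut height; ``tps_min`` —
    minimum reported TPS; ``min_target_chemicals`` — reliability filter on
    |C_T|.
    """

    out_dir: str = "phytonet_out"
    seed: int = 0
    plants_path: Optional[str] = None
    pc_edges_path: Optional[str] = None
    predictions_path: Optional[str] = None
    annotations_path: Optional[str] = None
    synthetic: Optional[dict] = None  # kwargs for SyntheticSpec
    p_min: float = 0.9
    k_min: int = 2
    k_max: int = 20
    h_max: float = DEFAULT_CUT_HEIGHT
    tps_min: float = 0.1
    min_target_chemicals: int = DEFAULT_MIN_TARGET_CHEMICALS

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not (0.0 <= self.p_min <= 1.0):
            raise ValueError(f"p_min must lie in [0, 1], got {self.p_min}")
        if not (0.0 <= self.tps_min <= 1.0):
            raise ValueError(f"tps_min must lie in [0, 1], got {self.tps_min}")
        if self.h_max < 0:
            raise ValueError(f"h_max must be >= 0, got {self.h_max}")
        if self.k_min > self.k_max or self.k_min < 1:
            raise ValueError(
                f"empty or invalid k range [{self.k_min}, {self.k_max}]"
            )
        have_paths = all(
            (self.plants_path, self.pc_edges_path, self.predictions_path)
        )
        if not have_paths and self.synthetic is None:
            raise ValueError(
                "config needs either input table paths or a synthetic spec"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline start: seed=%d p_min=%g k=[%d,%d] h_max=%g tps_min=%g "
        "min_target_chemicals=%d",
        config.seed, config.p_min, config.k_min, config.k_max, config.h_max,
        config.tps_min, config.min_target_chemicals,
    )
    written: list[Path] = []
    stage = "inputs"
    try:
        if config.synthetic is not None:
            spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
            dataset = generate(spec)
            paths = dataset.write(out / "inputs")
            written.extend(paths.values())
            records = pio.read_plants(paths["plants"])
            pc_edges = pio.read_pc_edges(paths["pc_edges"])
            predictions = pio.read_predictions(paths["predictions"])
            annotations = pio.read_annotations(paths["annotations"])
        else:
            records, pc_edges, predictions, annotations = pio.read_tables(
                config.plants_path,
                config.pc_edges_path,
                config.predictions_path,
                config.annotations_path,
            )

        stage = "preprocess"
        net, reports = run_preprocess(records, pc_edges, predictions, config.p_min)
        reports_df = pd.DataFrame([r.to_dict() for r in reports])
        p = out / "stage_reports.tsv"
        reports_df.to_csv(p, sep="\t", index=False)
        written.append(p)
        written.extend(pio.write_network_tsv(net, out / "network"))
        written.append(pio.write_network_graphml(net, out / "network" / "network.graphml"))

        stage = "cocluster"
        upper = min(config.k_max, net.n_plants + net.n_targets, net.n_chemicals)
        curve, partitions = select_k(
            net, range(config.k_min, upper + 1), seed=config.seed
        )
        best = partitions[curve.k_best]
        part_df = pd.DataFrame(
            {
                "node": sorted(best.assignment),
                "layer": [net.layer_of(n) for n in sorted(best.assignment)],
                "cluster": [best.assignment[n] for n in sorted(best.assignment)],
            }
        )
        p = out / "partition.tsv"
        part_df.to_csv(p, sep="\t", index=False)
        written.append(p)
        curve_df = pd.DataFrame(curve.entries, columns=["k", "modularity"])
        p = out / "modularity_curve.tsv"
        curve_df.to_csv(p, sep="\t", index=False)
        written.append(p)

        stage = "structural_stats"
        stats = {"whole": structural_stats(net).to_dict()}
        for cid, members in sorted(best.clusters().items()):
            stats[f"subnetwork_{cid}"] = structural_stats(
                net.subnetwork(members)
            ).to_dict()
        p = out / "stats.json"
        p.write_text(json.dumps(stats, indent=1, sort_keys=True) + "\n")
        written.append(p)

        stage = "hcluster"
        plants, D = distance_matrix(net)
        tree = complete_linkage_tree(plants, D)
        p = out / "dendrogram.nwk"
        p.write_text(tree.to_newick() + "\n")
        written.append(p)
        clusters = cut_clusters(tree, config.h_max, net)
        clus_df = pd.DataFrame(
            [
                {"plant_id": m, "cluster_id": c.cluster_id}
                for c in clusters
                for m in sorted(c.members)
            ]
        )
        p = out / "clusters.tsv"
        clus_df.to_csv(p, sep="\t", index=False)
        written.append(p)
        if annotations is not None:
            tally_rows = []
            for c in clusters:
                tallies = tally_classes(c, annotations)
                for level, counts in tallies.items():
                    for label, count in sorted(counts.items()):
                        tally_rows.append(
                            {
                                "cluster_id": c.cluster_id,
                                "level": level,
                                "label": label,
                                "n_chemicals": count,
                            }
                        )
            p = out / "class_tallies.tsv"
            pd.DataFrame(tally_rows).to_csv(p, sep="\t", index=False)
            written.append(p)

        stage = "tps"
        tps_rows = []
        for c in clusters:
            for res in rank_targets_for_cluster(
                c, net, config.tps_min, config.min_target_chemicals
            ):
                d = res.to_dict()
                d["overlap_chemicals"] = ",".join(d["overlap_chemicals"])
                tps_rows.append(d)
        p = out / "tps_results.tsv"
        pd.DataFrame(
            tps_rows,
            columns=[
                "cluster_id", "target_id", "tps", "n_target_chemicals",
                "n_overlap", "overlap_chemicals",
            ],
        ).to_csv(p, sep="\t", index=False)
        written.append(p)
    except Exception:
        logger.error("pipeline failed at stage %r; earlier outputs kept", stage)
        raise

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "k_best": curve.k_best,
        "n_plant_clusters": len(clusters),
        "files": {
            str(f.relative_to(out)): _sha256(f) for f in sorted(set(written))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline done: %d files in %s", len(manifest["files"]), out)
    return manifest
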