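"""Seeded generator of raw input tables with planted structure.

The generator emulates the statistical shape of a medicinal-plant inventory
joined to chemical–target activity predictions, so that every stage of the
pipeline is testable without any external database:

* planted plant blocks — disjoint groups of plants sharing a designed
  chemical profile, each with a designated protein target predicted active
  (probability above the 0.9 threshold) on that profile;
* decoy targets whose predictions all fall below the threshold, so they
  vanish at the thresholding stage;
* heavy-tailed background chemistry — background chemicals whose
  plant-degrees follow a discrete power law (default exponent 2.5),
  echoing the scale-free degree spread of real plant–chemical networks,
  plus one ubiquitous chemical shared across blocks (a β-sitosterol-like
  compound), which blurs family-level clustering exactly as widely shared
  phytosterols do in real data;
* preprocessing fodder — non-plant decoy records (minerals/animals),
  duplicated records (same species and used part under a new record id),
  and isolated records with no edges.

Activity probabilities are drawn from two Beta-shaped laws with disjoint
supports: designated edges on [0.95, 1], decoy edges on [0, 0.8]. Every
designated edge therefore survives a strict >0.9 cut and every decoy edge
is removed — the threshold property is exact by construction, and the
ground truth records which is which.

A fixed seed makes the emitted tables byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticDataset", "generate", "evaluate_recovery"]

_USE_PARTS = ("root", "leaf", "seed", "flower", "bark", "whole plant")
_SUBCLASSES = [f"subclass_{i:02d}" for i in range(10)]
_PARENTS = [f"parent_{i:02d}" for i in range(20)]
_SUPERCLASSES = ["Lipids and lipid-like molecules", "Phenylpropanoids and polyketides",
                 "Organoheterocyclic compounds", "Benzenoids"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic dataset.

    Defaults describe the study conditions the pipeline is exercised
    under: five planted blocks of 20 plants, 40 profile chemicals per
    block, 50 heavy-tailed background chemicals plus one ubiquitous
    chemical, five designated targets and ten decoys, block membership
    probability 0.5 with 0.02 cross-block background, and Beta probability
    laws concentrated above 0.95 (designated) / below 0.8 (decoy).
    """

    seed: int = 0
    n_plants: int = 100
    n_chemicals: int = 251  # 5 blocks x 40 profile + 50 background + 1 ubiquitous
    n_targets: int = 15
    n_nonplants: int = 5
    dup_rate: float = 0.05
    n_isolates: int = 2
    n_blocks: int = 5
    block_profile_size: int = 40
    within_block_connect_prob: float = 0.5
    background_edge_prob: float = 0.02
    ubiquitous_connect_prob: float = 0.6
    # (alpha, beta, low, high): probability = low + (high-low) * Beta(alpha, beta)
    prob_high_params: tuple[float, float, float, float] = (2.0, 2.0, 0.95, 1.0)
    prob_low_params: tuple[float, float, float, float] = (2.0, 2.0, 0.0, 0.8)
    decoy_target_degree: int = 30
    degree_tail_exponent: float = 2.5

    def validate(self) -> None:
        if self.n_blocks < 1 or self.n_plants < self.n_blocks:
            raise ValueError(
                f"{self.n_blocks} blocks cannot partition {self.n_plants} plants"
            )
        if self.n_blocks * self.block_profile_size > self.n_chemicals:
            raise ValueError(
                "block profiles exceed the chemical universe: "
                f"{self.n_blocks} x {self.block_profile_size} > {self.n_chemicals}"
            )
        if self.n_targets < self.n_blocks:
            raise ValueError("need at least one target per block")
        for name in ("dup_rate", "within_block_connect_prob",
                     "background_edge_prob", "ubiquitous_connect_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for pname in ("prob_high_params", "prob_low_params"):
            a, b, lo, hi = getattr(self, pname)
            if not (0.0 <= lo <= hi <= 1.0) or a <= 0 or b <= 0:
                raise ValueError(f"invalid {pname}: {(a, b, lo, hi)}")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    block_of_plant: dict[str, int]  # plant record_id -> block index (1-based)
    designated_targets: dict[int, str]  # block index -> target id
    duplicates: list[str]  # record ids of injected duplicate records
    nonplants: list[str]  # record ids of mineral/animal decoys
    isolates: list[str]  # record ids of edgeless plant records
    decoy_targets: list[str]
    designated_edges: list[tuple[str, str]]  # (chemical, target) above threshold
    decoy_edges: list[tuple[str, str]]  # below threshold

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["designated_edges"] = [list(e) for e in self.designated_edges]
        d["decoy_edges"] = [list(e) for e in self.decoy_edges]
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    """Generated tables (as DataFrames) plus the ground truth."""

    plants: pd.DataFrame
    pc_edges: pd.DataFrame
    predictions: pd.DataFrame
    annotations: pd.DataFrame
    truth: GroundTruth

    def to_inputs(self):
        """In-memory inputs for :func:`phytonet.preprocess.run_preprocess`:
        (records, pc_edges, predictions, annotations)."""
        from .network import Category, PlantRecord, TargetPrediction

        records = [
            PlantRecord(
                record_id=r.record_id,
                scientific_name=r.scientific_name,
                latin_name=r.latin_name,
                use_target=r.use_target,
                category=Category.coerce(r.category),
            )
            for r in self.plants.itertuples(index=False)
        ]
        pc = list(zip(self.pc_edges["plant_id"], self.pc_edges["chemical_id"]))
        preds = [
            TargetPrediction(r.chemical_id, r.target_id, float(r.probability))
            for r in self.predictions.itertuples(index=False)
        ]
        return records, pc, preds, self.annotations.set_index("chemical_id")

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "plants": outdir / "plants.tsv",
            "pc_edges": outdir / "plant_chemical.tsv",
            "predictions": outdir / "predictions.tsv",
            "annotations": outdir / "annotations.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        self.plants.to_csv(paths["plants"], sep="\t", index=False)
        self.pc_edges.to_csv(paths["pc_edges"], sep="\t", index=False)
        self.predictions.to_csv(
            paths["predictions"], sep="\t", index=False, float_format="%.6f"
        )
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        paths["ground_truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _scaled_beta(rng: np.random.Generator, params, size: int) -> np.ndarray:
    a, b, lo, hi = params
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def _powerlaw_degrees(
    rng: np.random.Generator, n: int, exponent: float, d_max: int
) -> np.ndarray:
    """Discrete power-law degrees P(d) ∝ d^-exponent on 1..d_max."""
    support = np.arange(1, max(d_max, 1) + 1)
    weights = support.astype(float) ** (-exponent)
    weights /= weights.sum()
    return rng.choice(support, size=n, p=weights)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one dataset; fully determined by ``spec`` (including seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    chem_ids = [f"C{j:04d}" for j in range(spec.n_chemicals)]
    profile_chems: dict[int, list[str]] = {}
    cursor = 0
    for b in range(1, spec.n_blocks + 1):
        profile_chems[b] = chem_ids[cursor : cursor + spec.block_profile_size]
        cursor += spec.block_profile_size
    ubiquitous = chem_ids[cursor] if cursor < spec.n_chemicals else None
    background = chem_ids[cursor + 1 :] if ubiquitous is not None else []

    # --- plant records, block labels ------------------------------------
    block_sizes = np.full(spec.n_blocks, spec.n_plants // spec.n_blocks)
    block_sizes[: spec.n_plants % spec.n_blocks] += 1
    plant_rows = []
    block_of_plant: dict[str, int] = {}
    idx = 0
    for b in range(1, spec.n_blocks + 1):
        for _ in range(block_sizes[b - 1]):
            rid = f"P{idx:04d}"
            species = f"Plantus block{b}sp{idx:03d}"
            plant_rows.append(
                {
                    "record_id": rid,
                    "scientific_name": species,
                    "latin_name": species.lower().replace(" ", "_"),
                    "use_target": _USE_PARTS[idx % len(_USE_PARTS)],
                    "category": "fungus" if idx % 25 == 24 else "plant",
                }
            )
            block_of_plant[rid] = b
            idx += 1

    # --- plant-chemical edges -------------------------------------------
    pc: set[tuple[str, str]] = set()
    for row in plant_rows:
        rid = row["record_id"]
        b = block_of_plant[rid]
        mask = rng.random(spec.block_profile_size) < spec.within_block_connect_prob
        own = [c for c, m in zip(profile_chems[b], mask) if m]
        if not own:  # every block plant carries at least one profile chemical
            own = [profile_chems[b][int(rng.integers(spec.block_profile_size))]]
        pc.update((rid, c) for c in own)
        for other_b, chems in profile_chems.items():
            if other_b == b:
                continue
            mask = rng.random(len(chems)) < spec.background_edge_prob
            pc.update((rid, c) for c, m in zip(chems, mask) if m)
        if ubiquitous is not None and rng.random() < spec.ubiquitous_connect_prob:
            pc.add((rid, ubiquitous))
    plant_ids = [r["record_id"] for r in plant_rows]
    if background:
        degs = _powerlaw_degrees(
            rng, len(background), spec.degree_tail_exponent,
            d_max=max(1, spec.n_plants // 2),
        )
        for chem, d in zip(background, degs):
            carriers = rng.choice(plant_ids, size=int(d), replace=False)
            pc.update((p, chem) for p in carriers)

    # --- duplicates, non-plants, isolates -------------------------------
    n_dups = int(round(spec.dup_rate * spec.n_plants))
    dup_sources = list(rng.choice(plant_ids, size=n_dups, replace=False)) if n_dups else []
    duplicates = []
    dup_rows = []
    for i, src in enumerate(sorted(dup_sources)):
        src_row = next(r for r in plant_rows if r["record_id"] == src)
        rid = f"D{i:04d}"
        dup_rows.append({**src_row, "record_id": rid})
        duplicates.append(rid)
        # the duplicate carries a random subset of the source's edges, so
        # dedup must union them back into the survivor
        src_edges = sorted(c for p, c in pc if p == src)
        take = max(1, len(src_edges) // 2)
        pc.update((rid, c) for c in src_edges[:take])

    nonplants = []
    nonplant_rows = []
    for i in range(spec.n_nonplants):
        rid = f"N{i:04d}"
        cat = "mineral" if i % 2 == 0 else "animal"
        name = f"{'Mineralis' if cat == 'mineral' else 'Animalia'} decoy{i:03d}"
        nonplant_rows.append(
            {
                "record_id": rid,
                "scientific_name": name,
                "latin_name": name.lower().replace(" ", "_"),
                "use_target": "whole",
                "category": cat,
            }
        )
        nonplants.append(rid)
        # non-plants carry edges too, exercising edge removal at the filter
        carriers = rng.choice(chem_ids[: cursor], size=3, replace=False)
        pc.update((rid, c) for c in carriers)

    isolates = []
    isolate_rows = []
    for i in range(spec.n_isolates):
        rid = f"I{i:04d}"
        name = f"Plantus isolatus{i:03d}"
        isolate_rows.append(
            {
                "record_id": rid,
                "scientific_name": name,
                "latin_name": name.lower().replace(" ", "_"),
                "use_target": "root",
                "category": "plant",
            }
        )
        isolates.append(rid)

    all_rows = plant_rows + dup_rows + nonplant_rows + isolate_rows

    # --- predictions -----------------------------------------------------
    target_ids = [f"T{j:03d}" for j in range(spec.n_targets)]
    designated = {b: target_ids[b - 1] for b in range(1, spec.n_blocks + 1)}
    decoy_targets = target_ids[spec.n_blocks :]
    pred_rows = []
    designated_edges = []
    decoy_edges = []
    for b, tgt in designated.items():
        chems = profile_chems[b]
        probs = _scaled_beta(rng, spec.prob_high_params, len(chems))
        for c, p in zip(chems, probs):
            pred_rows.append({"chemical_id": c, "target_id": tgt, "probability": p})
            designated_edges.append((c, tgt))
        # sub-threshold noise predictions on chemicals outside the profile
        others = [c for c in chem_ids if c not in chems]
        noise = rng.choice(others, size=min(10, len(others)), replace=False)
        nprobs = _scaled_beta(rng, spec.prob_low_params, len(noise))
        for c, p in zip(noise, nprobs):
            pred_rows.append({"chemical_id": c, "target_id": tgt, "probability": p})
            decoy_edges.append((c, tgt))
    for tgt in decoy_targets:
        chems = rng.choice(chem_ids, size=min(spec.decoy_target_degree, spec.n_chemicals),
                           replace=False)
        probs = _scaled_beta(rng, spec.prob_low_params, len(chems))
        for c, p in zip(chems, probs):
            pred_rows.append({"chemical_id": c, "target_id": tgt, "probability": p})
            decoy_edges.append((c, tgt))

    # --- annotations -----------------------------------------------------
    ann_rows = []
    for j, chem in enumerate(chem_ids):
        block = next(
            (b for b, chems in profile_chems.items() if chem in chems), None
        )
        if block is not None:
            # profile chemicals lean toward block-specific chemistry
            subclass = _SUBCLASSES[(block * 2 + j % 2) % len(_SUBCLASSES)]
            parent = _PARENTS[(block * 4 + j % 4) % len(_PARENTS)]
        else:
            subclass = _SUBCLASSES[j % len(_SUBCLASSES)]
            parent = _PARENTS[j % len(_PARENTS)]
        ann_rows.append(
            {
                "chemical_id": chem,
                "kingdom": "Organic compounds",
                "superclass": _SUPERCLASSES[j % len(_SUPERCLASSES)],
                "class": f"class_{j % 6:02d}",
                "subclass": subclass,
                "direct_parent": parent,
            }
        )

    plants_df = pd.DataFrame(all_rows)
    pc_df = pd.DataFrame(sorted(pc), columns=["plant_id", "chemical_id"])
    pred_df = pd.DataFrame(pred_rows).sort_values(
        ["chemical_id", "target_id"], kind="mergesort", ignore_index=True
    )
    ann_df = pd.DataFrame(ann_rows)
    truth = GroundTruth(
        block_of_plant=block_of_plant,
        designated_targets=designated,
        duplicates=duplicates,
        nonplants=nonplants,
        isolates=isolates,
        decoy_targets=list(decoy_targets),
        designated_edges=designated_edges,
        decoy_edges=decoy_edges,
    )
    return SyntheticDataset(
        plants=plants_df,
        pc_edges=pc_df,
        predictions=pred_df,
        annotations=ann_df,
        truth=truth,
    )


def evaluate_recovery(
    labels: dict[str, int], truth: GroundTruth
) -> dict[str, object]:
    """Adjusted Rand index and per-block purity of recovered plant labels.

    ``labels`` must cover every planted plant (extra nodes such as
    chemicals or targets are ignored).
    """
    plants = sorted(truth.block_of_plant)
    missing = [p for p in plants if p not in labels]
    if missing:
        raise ValueError(f"labels missing for planted plants: {missing[:5]}")
    y_true = [truth.block_of_plant[p] for p in plants]
    y_pred = [labels[p] for p in plants]
    ari = float(adjusted_rand_score(y_true, y_pred))
    purity: dict[int, float] = {}
    for b in sorted(set(y_true)):
        members = [p for p in plants if truth.block_of_plant[p] == b]
        pred_in_block = [labels[p] for p in members]
        top = max(pred_in_block.count(v) for v in set(pred_in_block))
        purity[b] = top / len(members)
    return {"ari": ari, "purity": purity}
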