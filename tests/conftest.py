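import numpy as np
import pytest

from phytonet import (
    Category,
    MultipartiteNetwork,
    PlantRecord,
    TargetPrediction,
    build_network,
)
from phytonet.synth import SyntheticSpec, generate


@pytest.fixture
def toy_network() -> MultipartiteNetwork:
    """2 plants, 3 chemicals, 1 target; 6 nodes, 3 edges."""
    records = [
        PlantRecord("p1", "Plantus unus", "plantus_unus", "root", Category.PLANT),
        PlantRecord("p2", "Plantus duo", "plantus_duo", "leaf", Category.PLANT),
    ]
    return build_network(
        records,
        pc_edges=[("p1", "c1"), ("p2", "c2")],
        ct_edges=[("c1", "t1")],
        chemicals=["c1", "c2", "c3"],
    )


@pytest.fixture
def profile_network() -> MultipartiteNetwork:
    """3 plants with chemical profiles {c1,c2}, {c2,c3}, {c4}; one target."""
    return build_network(
        ["p1", "p2", "p3"],
        pc_edges=[("p1", "c1"), ("p1", "c2"), ("p2", "c2"), ("p2", "c3"), ("p3", "c4")],
        ct_edges=[("c1", "t1"), ("c2", "t1")],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default-spec synthetic dataset shared across the session."""
    return generate(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def preprocessed(default_dataset):
    from phytonet import run_preprocess

    records, pc, preds, ann = default_dataset.to_inputs()
    net, reports = run_preprocess(records, pc, preds)
    return net, reports, default_dataset.truth, ann


def random_profile_network(rng: np.random.Generator, n_plants=8, n_chems=10, p=0.35):
    """Small random plant-chemical network where every plant has >= 1 chemical."""
    plants = [f"p{i}" for i in range(n_plants)]
    chems = [f"c{j}" for j in range(n_chems)]
    pc = []
    for pl in plants:
        mask = rng.random(n_chems) < p
        if not mask.any():
            mask[rng.integers(n_chems)] = True
        pc.extend((pl, c) for c, m in zip(chems, mask) if m)
    return build_network(plants, pc, ct_edges=[])
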