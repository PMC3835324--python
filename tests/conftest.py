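"""Shared fixtures: small rendered scenes and reusable ground-truth cohorts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ycquant.morphology import DendriteTrace
from ycquant.synthetic import CohortConfig, GroundTruthScene


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """A 2+2-animal rendered-cohort configuration used across tests."""
    return dataclasses.replace(
        CohortConfig(seed=20230),
        n_control_animals=2,
        n_tau_animals=2,
        volumes_per_animal=2,
        rendered_dendrites_per_volume=2,
    )


def straight_dendrite_scene(
    n_spines: int,
    calcium_nM: float = 125.0,
    z_plane: int = 8,
    seed: int = 5,
    config: CohortConfig | None = None,
) -> tuple[GroundTruthScene, np.ndarray]:
    """A single straight dendrite along x with ``n_spines`` alternating-side
    spines at known positions.  Returns (scene, true spine positions)."""
    cfg = config or CohortConfig(seed=0)
    z0 = (z_plane + 0.5) * cfg.voxel_size[0]
    trace = DendriteTrace(
        "d0",
        np.array([[z0, 16.0, 3.0], [z0, 16.0, 29.0]]),
        radius=cfg.shaft_radius,
        animal_id="a1",
        genotype="control",
    )
    rng = np.random.default_rng(seed)
    positions = []
    arc = np.linspace(2.0, 24.0, n_spines) if n_spines else np.empty(0)
    for i, s in enumerate(arc):
        side = 1.0 if i % 2 == 0 else -1.0
        offset = trace.radius + rng.uniform(*cfg.spine_protrusion_range)
        positions.append([z0, 16.0 + side * offset, 3.0 + s])
    positions = np.asarray(positions) if len(positions) else np.empty((0, 3))
    calcium = {"d0": calcium_nM}
    calcium.update({f"d0_s{j:03d}": calcium_nM for j in range(n_spines)})
    scene = GroundTruthScene(
        scene_id="s0",
        animal_id="a1",
        genotype="control",
        traces=[trace],
        spines={"d0": positions},
        true_calcium=calcium,
        spine_arc={"d0": arc},
    )
    return scene, positions


@pytest.fixture()
def twelve_spine_scene():
    return straight_dendrite_scene(12)
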