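from __future__ import annotations

import numpy as np
import pytest

from nanosite.core import AtomRole, LabeledTopology, Trajectory
from nanosite.synthetic import SyntheticConfig, build_nanoparticle


def make_topology(roles, masses=None, names=None, ligand_ids=None,
                  substrate_ids=None, resids=None) -> LabeledTopology:
    """Hand-built topology for geometric unit tests."""
    n = len(roles)
    return LabeledTopology(
        names=list(names) if names else [r.value for r in roles],
        resids=np.asarray(resids) if resids is not None else np.arange(1, n + 1),
        roles=list(roles),
        masses=np.asarray(masses, dtype=float) if masses is not None else np.ones(n),
        ligand_ids=np.asarray(ligand_ids) if ligand_ids is not None else np.full(n, -1),
        substrate_ids=(
            np.asarray(substrate_ids) if substrate_ids is not None else np.full(n, -1)
        ),
    )


def make_trajectory(frames, box_edge=10.0, dt=5.0) -> Trajectory:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = len(frames)
    return Trajectory(
        times=np.arange(n) * dt,
        boxes=np.broadcast_to(np.eye(3) * box_edge, (n, 3, 3)).copy(),
        coords=frames,
    )


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_gold=40, n_ligands=12, n_substrates=3, n_waters=50, n_cl=10,
        n_frames=30, box_edge=10.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_system(small_config):
    topo, frame0 = build_nanoparticle(small_config)
    return small_config, topo, frame0


@pytest.fixture()
def binding_playground():
    """2 Zn + 1 labeled substrate + 1 water for classifier tests.

    Zn at (0,0,0) and (0.4,0,0); substrate/water positions are set by each
    test.  Box is large enough that periodicity never matters.
    """
    roles = [
        AtomRole.ZN, AtomRole.ZN,
        AtomRole.SUB_P, AtomRole.SUB_O3, AtomRole.SUB_O4, AtomRole.SUB_O5,
        AtomRole.WATER_O,
    ]
    topo = make_topology(
        roles,
        names=["ZN", "ZN", "P", "O3", "O4", "O5", "OW"],
        substrate_ids=[-1, -1, 0, 0, 0, 0, -1],
        resids=[1, 2, 3, 3, 3, 3, 4],
    )
    frame = np.array(
        [[0.0, 0.0, 0.0], [0.4, 0.0, 0.0],
         [3.0, 3.0, 3.0], [3.0, 3.0, 3.3], [3.1, 3.0, 2.9], [2.9, 3.0, 2.9],
         [6.0, 6.0, 6.0]]
    ) + 2.0
    return topo, frame, np.eye(3) * 20.0
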