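"""Thiol bundle detection.

A bundle is more than two coating ligands simultaneously interconnected by
interligand C=O8...H-N9 hydrogen bonds.  Bundles are the connected components
(size >= 3) of the per-frame graph whose nodes are ligand ids and whose edges
join ligands sharing at least one qualifying hydrogen bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import AtomRole, LabeledTopology, LabelingError, Trajectory
from .structure import HydrogenBond, hydrogen_bonds, nh_donor_triples

__all__ = ["BundleRecord", "interligand_hb_graph", "detect_bundles"]

_MIN_BUNDLE = 3
_MAX_TRACKED = 6  # sizes 3..6 reported individually, larger under ">6"


@dataclass(frozen=True)
class BundleRecord:
    frame: int
    members: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.members)


def interligand_hb_graph(
    hb_list: list[HydrogenBond], topology: LabeledTopology
) -> nx.Graph:
    """Graph over ligand ids from one frame's N9-H...O8 hydrogen bonds.

    Only bonds whose donor is a ligand N9 and whose acceptor is a ligand O8
    qualify; duplicate bonds between the same ligand pair collapse to a
    single edge and self-loops (intraligand bonds) are excluded.
    """
    g = nx.Graph()
    for hb in hb_list:
        if topology.roles[hb.donor] is not AtomRole.N9:
            continue
        if topology.roles[hb.acceptor] is not AtomRole.O8:
            continue
        ld = int(topology.ligand_ids[hb.donor])
        la = int(topology.ligand_ids[hb.acceptor])
        if ld < 0 or la < 0:
            raise LabelingError(
                f"hydrogen-bond atoms {hb.donor}/{hb.acceptor} lack ligand ids"
            )
        if ld != la:
            g.add_edge(ld, la)
    return g


def detect_bundles(
    traj: Trajectory,
    topology: LabeledTopology,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
) -> tuple[list[BundleRecord], dict]:
    """Bundles per frame plus the size-frequency table.

    The summary maps each size bucket ('3'..'6', '>6') to the fraction of
    frames containing at least one bundle of exactly that size; raw bundle
    counts per bucket are reported alongside so either normalisation of the
    distribution can be read off.
    """
    donors = nh_donor_triples(topology, (AtomRole.N9,))
    acceptors = topology.select(AtomRole.O8)
    per_frame, _ = hydrogen_bonds(traj, topology, donors, acceptors, d_cut, angle_cut)

    records: list[BundleRecord] = []
    buckets = [str(s) for s in range(_MIN_BUNDLE, _MAX_TRACKED + 1)] + [">6"]
    frames_with = {b: 0 for b in buckets}
    raw_counts = {b: 0 for b in buckets}
    for f, hbs in enumerate(per_frame):
        g = interligand_hb_graph(hbs, topology)
        present: set[str] = set()
        for comp in nx.connected_components(g):
            if len(comp) < _MIN_BUNDLE:
                continue
            records.append(BundleRecord(frame=f, members=frozenset(comp)))
            b = str(len(comp)) if len(comp) <= _MAX_TRACKED else ">6"
            raw_counts[b] += 1
            present.add(b)
        for b in present:
            frames_with[b] += 1

    n = max(traj.n_frames, 1)
    summary = {
        "frequency": {b: frames_with[b] / n for b in buckets},
        "raw_counts": dict(raw_counts),
        "n_frames": traj.n_frames,
    }
    return records, summary
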