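"""Ground-truth synthetic fixtures.

Generates nanoparticle topologies and trajectories that *plant* contact and
complex events with known identities, start frames and durations, so every
detector downstream can be verified exactly without running molecular
dynamics.  The fixtures are statistical stand-ins, not physics: baseline
motion is Gaussian jitter about a built geometry (substrates perform a
reflected random walk), and scheduled events place the participating atoms so
the defining distances hold exactly.

The built particle emulates a ~1.6 nm gold core carrying 60 surface-anchored
flexible ligands (segments S, C1-C7, O8, N9, linker 12/15, N18, O19, and a
TACN crown chelating one Zn each), ~10 diffusing phosphodiester substrates
(P, O3, O4, O5), water oxygens and chloride counterions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    AtomRole,
    GeometryError,
    LabeledTopology,
    Trajectory,
    center_of_mass,
    distance_matrix,
)
from .sites import SiteKind, Thresholds

__all__ = [
    "SyntheticConfig",
    "EventEntry",
    "EventSchedule",
    "PackingError",
    "ScheduleError",
    "build_nanoparticle",
    "generate_trajectory",
    "sample_event_durations",
    "generate_tumbling_vectors",
    "generate_uniform_gas",
    "plant_hb_chain",
    "write_gro",
    "write_xtc",
    "default_label_map",
]

_BOND = 0.15          # chain bead spacing, nm
_ZN_N_BOND = 0.21     # Zn to each chelating TACN nitrogen, nm
_TACN_RING = 0.12     # TACN nitrogen ring radius, nm
_MIN_SEPARATION = 0.2  # packing overlap floor, nm
# clearance between the Zn shell and diffusing species: substrate arms extend
# ~0.25 nm from their centre, so 0.7 keeps every substrate/water oxygen well
# beyond 1.5x the 0.25 nm coordination cutoff unless an event plants it
_MONOLAYER_CLEARANCE = 0.7


class PackingError(RuntimeError):
    """Solvent/substrate placement failed within the retry budget."""


class ScheduleError(ValueError):
    """An event schedule is inconsistent or geometrically infeasible."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic system.

    Defaults emulate the studied particles: a 0.8 nm-radius (~1.6 nm
    diameter) core of 144 gold beads, 60 ligands each chelating one Zn, 10
    substrates, explicit water oxygens and chloride, frames every 5 ps.
    """

    core_radius: float = 0.8          # nm
    n_gold: int = 144
    n_ligands: int = 60
    alkyl_carbons: int = 7            # C1..C7
    linker: str = "alkyl"             # "alkyl" (C12/C15) or "peg" (O12/O15)
    n_substrates: int = 10
    n_waters: int = 500
    n_cl: int = 60
    box_edge: float = 10.0            # nm
    jitter_sigma: float = 0.02        # nm, baseline Gaussian jitter
    walk_step: float = 0.05           # nm, substrate random-walk step
    dt: float = 5.0                   # ps
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_gold", "n_ligands", "alkyl_carbons", "n_substrates",
                     "n_waters", "n_cl", "n_frames"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("core_radius", "box_edge", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.linker not in ("alkyl", "peg"):
            raise ValueError("linker must be 'alkyl' or 'peg'")

    @property
    def box(self) -> np.ndarray:
        return np.eye(3) * self.box_edge


@dataclass(frozen=True)
class EventEntry:
    """One scheduled event: who, when, and the planted geometry.

    ``zn`` holds Zn *atom indices*; ``substrate`` a substrate id;
    ``geometry`` planted distances in nm (keys among d1, d2, d3, d4, d5,
    zn_zn) and optionally ``water`` (a water-O atom index for d4/d5).
    """

    kind: SiteKind
    start: int
    duration: int
    zn: tuple[int, ...] = ()
    substrate: int | None = None
    geometry: dict = field(default_factory=dict)

    @property
    def frames(self) -> range:
        return range(self.start, self.start + self.duration)

    def participants(self) -> tuple:
        return (self.kind, self.zn, self.substrate)


@dataclass
class EventSchedule:
    entries: list[EventEntry] = field(default_factory=list)

    def validate(self, n_frames: int) -> None:
        seen: dict[tuple, list[range]] = {}
        for e in self.entries:
            if e.duration < 1 or e.start < 0 or e.start + e.duration > n_frames:
                raise ScheduleError(
                    f"event {e.kind.value} [{e.start}, {e.start + e.duration}) "
                    f"outside trajectory of {n_frames} frames"
                )
            key = (e.kind, tuple(sorted(e.zn)), e.substrate)
            for prev in seen.setdefault(key, []):
                if e.start < prev.stop and prev.start < e.frames.stop:
                    raise ScheduleError(
                        f"overlapping intervals for the same participants: {key}"
                    )
            seen[key].append(e.frames)


# ---------------------------------------------------------------------------
# geometry helpers

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic lattice)."""
    if n == 0:
        return np.zeros((0, 3))
    i = np.arange(n) + 0.5
    phi = np.pi * (np.sqrt(5.0) - 1.0) * (np.arange(n))
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u, v, w) right-handed with v, w perpendicular to u."""
    u = u / np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return u, v, w


# ---------------------------------------------------------------------------
# topology construction

def build_nanoparticle(config: SyntheticConfig) -> tuple[LabeledTopology, np.ndarray]:
    """Build the labeled topology and initial frame of a synthetic particle.

    Gold beads sit on/in a sphere of ``core_radius`` at the box centre;
    ligand anchors occupy a deterministic Fibonacci lattice on that sphere;
    each ligand is a radial bead chain S, C1..C7 (+1 H each), O8, N9 (+H),
    linker 12/15, N18, O19, then a TACN crown of 3 N + 3 C with one Zn at
    0.21 nm from each chelating nitrogen.  Substrates, waters and Cl are
    placed uniformly outside the monolayer with a 0.2 nm overlap floor.
    """
    rng = np.random.default_rng(config.seed)
    center = np.full(3, config.box_edge / 2.0)

    names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    roles: list[AtomRole] = []
    masses: list[float] = []
    lig_ids: list[int] = []
    sub_ids: list[int] = []
    coords: list[np.ndarray] = []

    def add(name, resid, resname, role, mass, lig, sub, pos):
        names.append(name)
        resids.append(resid)
        resnames.append(resname)
        roles.append(role)
        masses.append(mass)
        lig_ids.append(lig)
        sub_ids.append(sub)
        coords.append(np.asarray(pos, dtype=float))

    resid = 1
    # --- gold core: one centre bead, an inner and an outer shell
    if config.n_gold:
        n_in = max(0, (config.n_gold - 1) // 3)
        n_out = config.n_gold - 1 - n_in
        gold = [np.zeros(3)]
        gold += [0.55 * config.core_radius * u for u in fibonacci_sphere(n_in)]
        gold += [config.core_radius * u for u in fibonacci_sphere(n_out)]
        gold = np.array(gold)
        gold -= gold.mean(axis=0)  # plant the core c.o.m. exactly at centre
        for pos in gold:
            add("AU", resid, "AUC", AtomRole.GOLD, 196.967, -1, -1, center + pos)
        resid += 1

    # --- ligands
    peg = config.linker == "peg"
    linker_mass = 15.999 if peg else 12.011
    linker_names = ("O12", "O15") if peg else ("C12", "C15")
    anchors = fibonacci_sphere(config.n_ligands)
    zn_radius = 0.0
    for lig in range(config.n_ligands):
        u, v, w = _orthonormal_frame(anchors[lig])
        r = config.core_radius + 0.18
        add("S", resid, "LIG", AtomRole.SULFUR, 32.06, lig, -1, center + r * u)
        for k in range(1, config.alkyl_carbons + 1):
            r += _BOND
            role = AtomRole[f"ALKYL_C{k}"] if k <= 7 else AtomRole.OTHER
            add(f"C{k}", resid, "LIG", role, 12.011, lig, -1, center + r * u)
            add(f"HC{k}", resid, "LIG", AtomRole.OTHER, 1.008, lig, -1,
                center + r * u + 0.105 * v)
        r += 0.12
        add("O8", resid, "LIG", AtomRole.O8, 15.999, lig, -1, center + r * u)
        r += 0.14
        n9_pos = center + r * u
        add("N9", resid, "LIG", AtomRole.N9, 14.007, lig, -1, n9_pos)
        add("HN9", resid, "LIG", AtomRole.OTHER, 1.008, lig, -1, n9_pos + 0.10 * w)
        for nm, role in zip(linker_names, (AtomRole.LINKER_12, AtomRole.LINKER_15)):
            r += _BOND
            add(nm, resid, "LIG", role, linker_mass, lig, -1, center + r * u)
        r += 0.14
        add("N18", resid, "LIG", AtomRole.N18, 14.007, lig, -1, center + r * u)
        r += 0.12
        add("O19", resid, "LIG", AtomRole.O19, 15.999, lig, -1, center + r * u)
        # TACN crown: 3 N (chelating) + 3 C on a ring perpendicular to u
        r += _BOND
        ring_center = center + r * u
        for k in range(3):
            ang = 2.0 * np.pi * k / 3.0
            add(f"NT{k + 1}", resid, "LIG", AtomRole.TACN_N, 14.007, lig, -1,
                ring_center + _TACN_RING * (np.cos(ang) * v + np.sin(ang) * w))
            ang_c = ang + np.pi / 3.0
            add(f"CT{k + 1}", resid, "LIG", AtomRole.TACN_C, 12.011, lig, -1,
                ring_center + 0.145 * (np.cos(ang_c) * v + np.sin(ang_c) * w))
        # Zn on the crown axis, 0.21 nm from each chelating N
        h = np.sqrt(_ZN_N_BOND**2 - _TACN_RING**2)
        zn_pos = ring_center + h * u
        add("ZN", resid, "LIG", AtomRole.ZN, 65.38, lig, -1, zn_pos)
        zn_radius = max(zn_radius, float(np.linalg.norm(zn_pos - center)))
        resid += 1

    monolayer_r = (
        zn_radius if config.n_ligands else config.core_radius
    ) + _MONOLAYER_CLEARANCE
    placed = np.array(coords) if coords else np.zeros((0, 3))
    hetero: list[np.ndarray] = []

    def place_outside(n_points: int, label: str) -> np.ndarray:
        """Uniform positions in the box, outside the monolayer, no overlap."""
        out = []
        for _ in range(n_points):
            for _attempt in range(2000):
                p = rng.uniform(0.0, config.box_edge, size=3)
                if np.linalg.norm(p - center) < monolayer_r:
                    continue
                if hetero and np.min(
                    np.linalg.norm(np.array(hetero) - p, axis=1)
                ) < _MIN_SEPARATION:
                    continue
                out.append(p)
                hetero.append(p)
                break
            else:
                raise PackingError(
                    f"could not place {label} #{len(out)} without overlap; "
                    "box too small"
                )
        return np.array(out)

    # --- substrates: P with O3/O4/O5 in a fixed template, randomly oriented
    template = np.array(
        [[0.0, 0.0, 0.0],       # P
         [0.0, 0.0, 0.25],      # O3 (hydroxyl arm)
         [0.15, 0.0, -0.05],    # O4 (phosphoryl)
         [-0.15, 0.0, -0.05]]   # O5 (phosphoryl)
    )
    sub_centers = place_outside(config.n_substrates, "substrate")
    for s in range(config.n_substrates):
        axis = rng.normal(size=3)
        u, v, w = _orthonormal_frame(axis)
        rot = np.column_stack([v, w, u])
        pts = sub_centers[s] + template @ rot.T
        for nm, role, pos in zip(
            ("P", "O3", "O4", "O5"),
            (AtomRole.SUB_P, AtomRole.SUB_O3, AtomRole.SUB_O4, AtomRole.SUB_O5),
            pts,
        ):
            add(nm, resid, "HPN", role,
                30.974 if role is AtomRole.SUB_P else 15.999, -1, s, pos)
        resid += 1

    for p in place_outside(config.n_waters, "water"):
        add("OW", resid, "SOL", AtomRole.WATER_O, 15.999, -1, -1, p)
        resid += 1
    for p in place_outside(config.n_cl, "chloride"):
        add("CL", resid, "CLA", AtomRole.CL, 35.45, -1, -1, p)
        resid += 1

    topo = LabeledTopology(
        names=names,
        resids=np.array(resids),
        roles=roles,
        masses=np.array(masses),
        ligand_ids=np.array(lig_ids),
        substrate_ids=np.array(sub_ids),
    )
    topo.resnames = resnames  # carried for the writers
    return topo, np.array(coords)


# ---------------------------------------------------------------------------
# trajectory generation

def _event_placement(frame: np.ndarray, topo: LabeledTopology, entry: EventEntry,
                     center: np.ndarray, rng: np.random.Generator) -> None:
    """Overwrite participant coordinates so the event geometry holds exactly."""
    g = entry.geometry
    zn = list(entry.zn)
    zn1 = frame[zn[0]]
    u, v, w = _orthonormal_frame(zn1 - center)

    if entry.kind is SiteKind.ZN_PAIR:
        d = g.get("zn_zn", 0.45)
        frame[zn[1]] = zn1 + d * v
        return

    ox = topo.substrate_oxygens(entry.substrate)
    iP, iO3, iO4, iO5 = ox["P"], ox["O3"], ox["O4"], ox["O5"]
    d1 = g.get("d1", 0.22)

    if entry.kind is SiteKind.MONO_BINDING:
        frame[iO4] = zn1 + d1 * u
        frame[iP] = frame[iO4] + 0.16 * u
        frame[iO5] = frame[iP] + 0.20 * u + 0.10 * w
        frame[iO3] = frame[iP] + 0.20 * u - 0.10 * w
    elif entry.kind is SiteKind.PRECAT_1:
        d2, d3 = g.get("d2", 0.23), g.get("d3", 0.24)
        e1 = (2 * u + v) / np.linalg.norm(2 * u + v)
        e2 = (2 * u - v) / np.linalg.norm(2 * u - v)
        e3 = (2 * u + w) / np.linalg.norm(2 * u + w)
        frame[iO4] = zn1 + d1 * e1
        frame[iO5] = zn1 + d2 * e2
        frame[iO3] = zn1 + d3 * e3
        frame[iP] = zn1 + 0.32 * u
    else:  # bimetallic / pseudo-bimetallic: second Zn moved next to the first
        d_zz = g.get("zn_zn", 0.48)
        frame[zn[1]] = zn1 + d_zz * v
        zn2 = frame[zn[1]]
        if entry.kind is SiteKind.BI_BINDING:
            d2 = g.get("d2", 0.23)
            frame[iO4] = zn1 + d1 * u
            frame[iO5] = zn2 + d2 * u
            frame[iP] = 0.5 * (frame[iO4] + frame[iO5]) + 0.12 * u
            frame[iO3] = frame[iP] + 0.30 * u
        elif entry.kind is SiteKind.PRECAT_2:
            d2, d3 = g.get("d2", 0.23), g.get("d3", 0.24)
            frame[iO4] = zn1 + d1 * u
            frame[iO5] = zn2 + d2 * u
            frame[iO3] = zn1 - d3 * v
            frame[iP] = 0.5 * (frame[iO4] + frame[iO5]) + 0.12 * u
        elif entry.kind is SiteKind.PRECAT_3:
            d3 = g.get("d3", 0.24)
            frame[iO4] = zn1 + d1 * u
            frame[iO5] = frame[iO4] + 0.25 * u + 0.10 * w
            frame[iO3] = zn2 + d3 * v
            frame[iP] = 0.5 * (frame[iO4] + frame[iO3])
        else:
            raise ScheduleError(f"unknown event kind {entry.kind}")

    # optional planted solvation geometry: water at d4 from Zn1, d5 from O3
    if "d4" in g:
        water = g.get("water")
        if water is None:
            raise ScheduleError("solvation geometry needs a 'water' atom index")
        d4 = g["d4"]
        d5 = g.get("d5")
        if d5 is None:
            frame[water] = zn1 + d4 * w
        else:
            big_d = float(np.linalg.norm(frame[iO3] - zn1))
            if not abs(big_d - d4) <= d5 <= big_d + d4:
                raise ScheduleError(
                    f"infeasible solvation triangle: |O3-Zn|={big_d:.3f}, "
                    f"d4={d4}, d5={d5}"
                )
            e1 = (frame[iO3] - zn1) / big_d
            e2 = w - np.dot(w, e1) * e1
            e2 /= np.linalg.norm(e2)
            cos_a = (d4**2 + big_d**2 - d5**2) / (2.0 * d4 * big_d)
            sin_a = np.sqrt(max(0.0, 1.0 - cos_a**2))
            frame[water] = zn1 + d4 * (cos_a * e1 + sin_a * e2)


def _threshold_for(kind: SiteKind, thresholds: Thresholds) -> float:
    return thresholds.zn_zn if kind is SiteKind.ZN_PAIR else thresholds.o_zn


def generate_trajectory(
    topology: LabeledTopology,
    initial_frame: np.ndarray,
    schedule: EventSchedule,
    config: SyntheticConfig,
    gro_path: str | Path | None = None,
    xtc_path: str | Path | None = None,
) -> Trajectory:
    """Jittered trajectory with the scheduled events planted exactly.

    Baseline: independent Gaussian jitter (``jitter_sigma``) about the
    initial positions; substrates perform a reflected random walk (reflected
    at the box walls and off the monolayer sphere).  During each scheduled
    event the participating atoms are overwritten so the planted distances
    hold exactly; outside its interval the baseline keeps the same atoms
    farther than 1.5x the relevant cutoff (validated).  Fully reproducible
    from ``config.seed``.
    """
    schedule.validate(config.n_frames)
    rng = np.random.default_rng((config.seed, 1))
    X0 = np.asarray(initial_frame, dtype=float)
    if X0.shape != (topology.n_atoms, 3):
        raise GeometryError("initial frame does not match topology")
    gold = topology.select(AtomRole.GOLD)
    center = (
        center_of_mass(topology, X0, AtomRole.GOLD)
        if gold.size
        else np.full(3, config.box_edge / 2.0)
    )

    _validate_baseline_separation(topology, X0, schedule, config)

    # substrate rigid-walk bookkeeping
    sub_atoms = [
        np.nonzero(topology.substrate_ids == s)[0]
        for s in range(topology.n_substrates)
    ]
    sub_centers = [X0[idx].mean(axis=0) for idx in sub_atoms]
    sub_offsets = [X0[idx] - c for idx, c in zip(sub_atoms, sub_centers)]
    monolayer_r = _monolayer_radius(topology, X0, center)

    frames = np.empty((config.n_frames, topology.n_atoms, 3))
    centers = [np.array(c) for c in sub_centers]
    for f in range(config.n_frames):
        frame = X0 + rng.normal(scale=config.jitter_sigma, size=X0.shape)
        for s, idx in enumerate(sub_atoms):
            if config.walk_step > 0:
                step = rng.normal(scale=config.walk_step, size=3)
                centers[s] = _reflect(
                    centers[s] + step, config.box_edge, center, monolayer_r
                )
            frame[idx] = (
                centers[s]
                + sub_offsets[s]
                + rng.normal(scale=config.jitter_sigma, size=(idx.size, 3))
            )
        for entry in schedule.entries:
            if f in entry.frames:
                _event_placement(frame, topology, entry, center, rng)
        frames[f] = frame

    traj = Trajectory(
        times=np.arange(config.n_frames) * config.dt,
        boxes=np.broadcast_to(config.box, (config.n_frames, 3, 3)).copy(),
        coords=frames,
    )
    if gro_path is not None:
        write_gro(topology, X0, config.box, gro_path)
    if xtc_path is not None:
        write_xtc(topology, traj, xtc_path)
    return traj


def _monolayer_radius(topo: LabeledTopology, X0: np.ndarray, center: np.ndarray) -> float:
    zn = topo.select(AtomRole.ZN)
    if zn.size == 0:
        return 0.0
    return float(np.max(np.linalg.norm(X0[zn] - center, axis=1))) + _MONOLAYER_CLEARANCE


def _reflect(p: np.ndarray, edge: float, center: np.ndarray, r_min: float) -> np.ndarray:
    p = np.where(p < 0, -p, p)
    p = np.where(p > edge, 2 * edge - p, p)
    d = np.linalg.norm(p - center)
    if r_min > 0 and d < r_min:
        p = center + (p - center) / max(d, 1e-12) * (2 * r_min - d)
    return p


def _validate_baseline_separation(
    topo: LabeledTopology,
    X0: np.ndarray,
    schedule: EventSchedule,
    config: SyntheticConfig,
    thresholds: Thresholds = Thresholds(),
) -> None:
    """Participants must rest farther than 1.5x their cutoff at baseline."""
    box = config.box
    for e in schedule.entries:
        cut = 1.5 * _threshold_for(e.kind, thresholds)
        pts: list[np.ndarray] = [X0[i] for i in e.zn]
        if e.substrate is not None:
            ox = topo.substrate_oxygens(e.substrate)
            pts_sub = [X0[ox[k]] for k in ("O3", "O4", "O5")]
            dm = distance_matrix(np.array(pts), np.array(pts_sub), box)
            if dm.min() <= cut:
                raise ScheduleError(
                    f"baseline too close for event {e.kind.value}: "
                    f"min distance {dm.min():.3f} nm <= {cut:.3f} nm"
                )
        if len(e.zn) == 2:
            dzz = distance_matrix(pts[0], pts[1], box)[0, 0]
            if dzz <= 1.5 * thresholds.zn_zn:
                raise ScheduleError(
                    f"baseline Zn-Zn distance {dzz:.3f} nm too small for "
                    f"event {e.kind.value}"
                )


# ---------------------------------------------------------------------------
# statistical generators

def sample_event_durations(
    n: int, lambda_true: float, dt: float, seed: int | tuple = 0
) -> np.ndarray:
    """Exponential existence times, discretised to whole frames (>= 1).

    ``lambda_true`` in ns^-1, ``dt`` in ps; returns durations in frames.
    With ceiling discretisation the survival counts at the frame grid remain
    exactly exponential, so decay-rate recovery tests see no discretisation
    bias.
    """
    if lambda_true <= 0:
        raise ValueError("lambda_true must be > 0")
    if n == 0:
        return np.zeros(0, dtype=int)
    rng = np.random.default_rng(seed)
    durations_ns = rng.exponential(1.0 / lambda_true, size=n)
    frames = np.ceil(durations_ns * 1000.0 / dt).astype(int)
    return np.maximum(frames, 1)


def generate_tumbling_vectors(
    d_rot: float,
    s2: float,
    tau_e: float,
    dt: float,
    n_frames: int,
    seed: int | tuple = 0,
    n_vectors: int = 1,
) -> np.ndarray:
    """Unit vectors undergoing overall rotational diffusion plus an internal
    wobble with plateau order parameter ``s2`` and correlation time ``tau_e``.

    The internal process keeps the vector at a fixed cone angle from a
    body-frame axis and resamples its azimuth at Poisson rate 1/tau_e; the
    cone angle is chosen so that P2(cos theta) = sqrt(s2), which makes the
    internal P2 autocorrelation exactly s2 + (1-s2) e^(-t/tau_e).  The body
    frame itself diffuses isotropically with rotational diffusion constant
    ``d_rot`` (s^-1), so the composite P2 autocorrelation approaches
    e^(-6 d_rot t) [s2 + (1-s2) e^(-t/tau_e)] for small steps.

    Returns an array of shape (n_frames, n_vectors, 3).
    """
    if not 0.0 <= s2 <= 1.0:
        raise ValueError("s2 must lie in [0, 1]")
    if d_rot < 0 or tau_e <= 0 or dt <= 0:
        raise ValueError("d_rot must be >= 0; tau_e, dt > 0")
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    # cone angle: P2(cos theta) = sqrt(s2)  =>  cos^2 theta = (2 sqrt(s2)+1)/3
    cos_t = np.sqrt((2.0 * np.sqrt(s2) + 1.0) / 3.0)
    sin_t = np.sqrt(1.0 - cos_t**2)
    p_jump = 1.0 - np.exp(-dt / tau_e)
    sigma = np.sqrt(2.0 * d_rot * dt * 1e-12)  # rad, per axis per step

    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_vectors)
    rot = Rotation.random(n_vectors, random_state=np.random.RandomState(
        rng.integers(0, 2**31)))
    out = np.empty((n_frames, n_vectors, 3))
    for f in range(n_frames):
        if f > 0:
            if sigma > 0:
                rot = Rotation.from_rotvec(
                    rng.normal(scale=sigma, size=(n_vectors, 3))
                ) * rot
            jumps = rng.random(n_vectors) < p_jump
            if jumps.any():
                phi[jumps] = rng.uniform(0.0, 2.0 * np.pi, size=int(jumps.sum()))
        u_int = np.column_stack(
            [sin_t * np.cos(phi), sin_t * np.sin(phi), np.full(n_vectors, cos_t)]
        )
        out[f] = rot.apply(u_int)
    return out


def generate_uniform_gas(n: int, box_edge: float, seed: int | tuple = 0) -> np.ndarray:
    """i.i.d. uniform positions in a cubic box (ideal-gas RDF control)."""
    if n < 2:
        raise ValueError("need at least 2 particles")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, box_edge, size=(n, 3))


def plant_hb_chain(
    topology: LabeledTopology, frame: np.ndarray, ligand_ids: Sequence[int]
) -> np.ndarray:
    """Place O8 of each next ligand on the N9-H axis of the previous one so
    the chain is connected by ideal interligand hydrogen bonds (N...O =
    0.29 nm, H on the axis).  Returns a modified copy of the frame."""
    frame = np.array(frame, dtype=float)
    roles = topology.roles
    lig = topology.ligand_ids
    names = topology.names

    def _find(ligand: int, name: str) -> int:
        for i in range(topology.n_atoms):
            if lig[i] == ligand and names[i] == name:
                return i
        raise ValueError(f"ligand {ligand} has no atom {name}")

    for a, b in zip(ligand_ids[:-1], ligand_ids[1:]):
        n9, h = _find(a, "N9"), _find(a, "HN9")
        o8 = _find(b, "O8")
        axis = frame[h] - frame[n9]
        axis /= np.linalg.norm(axis)
        frame[o8] = frame[n9] + 0.29 * axis
    return frame


# ---------------------------------------------------------------------------
# file output

def _as_universe(topology: LabeledTopology, coords_nm: np.ndarray, box: np.ndarray,
                 dt: float = 5.0):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    coords_nm = np.asarray(coords_nm, dtype=float)
    if coords_nm.ndim == 2:
        coords_nm = coords_nm[None]
    resids = topology.resids
    unique_res, res_index = np.unique(resids, return_inverse=True)
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=len(unique_res),
        atom_resindex=res_index,
        trajectory=False,
    )
    u.add_TopologyAttr("names", topology.names)
    resnames = getattr(topology, "resnames", None)
    if resnames is None:
        resnames = ["MOL"] * topology.n_atoms
    first_of_res = [np.nonzero(res_index == k)[0][0] for k in range(len(unique_res))]
    u.add_TopologyAttr("resnames", [resnames[i] for i in first_of_res])
    u.add_TopologyAttr("resids", unique_res)
    dims = np.array([box[0, 0], box[1, 1], box[2, 2], 90.0, 90.0, 90.0]) * np.array(
        [10.0, 10.0, 10.0, 1.0, 1.0, 1.0]
    )
    u.load_new(coords_nm * 10.0, format=MemoryReader, dimensions=dims, dt=dt)
    return u


def write_gro(topology: LabeledTopology, frame: np.ndarray, box: np.ndarray,
              path: str | Path) -> None:
    """Write one frame as GRO (exercises the reader end-to-end)."""
    u = _as_universe(topology, frame, box)
    u.atoms.write(str(path))


def write_xtc(topology: LabeledTopology, traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as XTC with the trajectory's frame spacing."""
    import MDAnalysis as mda

    u = _as_universe(topology, traj.coords, traj.boxes[0], dt=traj.dt)
    with mda.Writer(str(path), topology.n_atoms) as writer:
        for _ in u.trajectory:
            writer.write(u.atoms)


def write_manifest(path: str | Path, config: SyntheticConfig,
                   schedule: EventSchedule) -> None:
    """JSON ground-truth manifest (config + schedule) for a generated fixture."""
    payload = {
        "config": asdict(config),
        "schedule": [
            {
                "kind": e.kind.value,
                "start": e.start,
                "duration": e.duration,
                "zn": list(e.zn),
                "substrate": e.substrate,
                "geometry": {k: v for k, v in e.geometry.items()},
            }
            for e in schedule.entries
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def default_label_map(linker: str = "alkyl") -> dict:
    """Label map matching the synthetic naming (AuNP-2 alkyl / AuNP-3 PEG)."""
    by_name = {
        "AU": "GOLD", "S": "SULFUR", "O8": "O8", "N9": "N9",
        "N18": "N18", "O19": "O19", "ZN": "ZN",
        "P": "SUB_P", "O3": "SUB_O3", "O4": "SUB_O4", "O5": "SUB_O5",
        "OW": "WATER_O", "HW1": "WATER_H", "HW2": "WATER_H", "CL": "CL",
        "HN9": "OTHER",
    }
    for k in range(1, 8):
        by_name[f"C{k}"] = f"ALKYL_C{k}"
        by_name[f"HC{k}"] = "OTHER"
    for k in range(1, 4):
        by_name[f"NT{k}"] = "TACN_N"
        by_name[f"CT{k}"] = "TACN_C"
    masses = {}
    if linker == "peg":
        by_name["O12"] = "LINKER_12"
        by_name["O15"] = "LINKER_15"
        masses = {"LINKER_12": 15.999, "LINKER_15": 15.999}
    else:
        by_name["C12"] = "LINKER_12"
        by_name["C15"] = "LINKER_15"
    return {
        "by_name": by_name,
        "ligand_resnames": ["LIG"],
        "substrate_resnames": ["HPN"],
        "default": "OTHER",
        "masses": masses,
    }
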