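"""Domain types, file readers and periodic-geometry primitives.

Semantic layer over standard coordinate/trajectory formats: every atom of a
monolayer-protected gold nanoparticle system is mapped to a role (gold core,
ligand segment C1..C7/O8/N9/linker/N18/O19/TACN, chelated Zn, substrate
P/O3/O4/O5, water, chloride) so that all downstream analyses can select atoms
by what they *are* rather than by file-specific naming.

Units: coordinates and boxes in nm, times in ps, masses in amu.  PDB files
(Angstrom) are converted to nm on load.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "AtomRole",
    "LabeledTopology",
    "Trajectory",
    "LabelingError",
    "GeometryError",
    "SelectionError",
    "ShapeError",
    "SpacingError",
    "load_label_map",
    "load_topology",
    "load_trajectory",
    "periodic_distance",
    "minimum_image",
    "distance_matrix",
    "center_of_mass",
    "stable_exp",
]


def stable_exp(x) -> np.ndarray:
    """Element-wise exp evaluated scalar-by-scalar.

    NumPy's SIMD exp can differ by 1 ulp depending on array alignment, which
    is enough to push an ill-conditioned nonlinear fit into a different
    basin between two otherwise identical runs.  The fits use this scalar
    path so seeded runs are byte-reproducible; the arrays involved are tiny.
    """
    import math

    arr = np.asarray(x, dtype=float)
    flat = np.array([math.exp(v) if v < 709.0 else np.inf for v in arr.ravel()])
    return flat.reshape(arr.shape)


class AtomRole(Enum):
    """Semantic role of an atom in the nanozyme system."""

    GOLD = "GOLD"
    SULFUR = "SULFUR"
    ALKYL_C1 = "ALKYL_C1"
    ALKYL_C2 = "ALKYL_C2"
    ALKYL_C3 = "ALKYL_C3"
    ALKYL_C4 = "ALKYL_C4"
    ALKYL_C5 = "ALKYL_C5"
    ALKYL_C6 = "ALKYL_C6"
    ALKYL_C7 = "ALKYL_C7"
    O8 = "O8"
    N9 = "N9"
    LINKER_12 = "LINKER_12"
    LINKER_15 = "LINKER_15"
    N18 = "N18"
    O19 = "O19"
    TACN_N = "TACN_N"
    TACN_C = "TACN_C"
    ZN = "ZN"
    SUB_P = "SUB_P"
    SUB_O3 = "SUB_O3"
    SUB_O4 = "SUB_O4"
    SUB_O5 = "SUB_O5"
    SUB_OTHER = "SUB_OTHER"
    WATER_O = "WATER_O"
    WATER_H = "WATER_H"
    CL = "CL"
    OTHER = "OTHER"


#: roles that mark an atom as belonging to a coating ligand
LIGAND_ROLES = frozenset(
    {
        AtomRole.SULFUR,
        AtomRole.ALKYL_C1,
        AtomRole.ALKYL_C2,
        AtomRole.ALKYL_C3,
        AtomRole.ALKYL_C4,
        AtomRole.ALKYL_C5,
        AtomRole.ALKYL_C6,
        AtomRole.ALKYL_C7,
        AtomRole.O8,
        AtomRole.N9,
        AtomRole.LINKER_12,
        AtomRole.LINKER_15,
        AtomRole.N18,
        AtomRole.O19,
        AtomRole.TACN_N,
        AtomRole.TACN_C,
    }
)

SUBSTRATE_ROLES = frozenset(
    {AtomRole.SUB_P, AtomRole.SUB_O3, AtomRole.SUB_O4, AtomRole.SUB_O5, AtomRole.SUB_OTHER}
)

#: default per-role masses (amu); overridable through the label map
DEFAULT_MASSES = {
    AtomRole.GOLD: 196.967,
    AtomRole.SULFUR: 32.06,
    AtomRole.O8: 15.999,
    AtomRole.N9: 14.007,
    AtomRole.LINKER_12: 12.011,
    AtomRole.LINKER_15: 12.011,
    AtomRole.N18: 14.007,
    AtomRole.O19: 15.999,
    AtomRole.TACN_N: 14.007,
    AtomRole.TACN_C: 12.011,
    AtomRole.ZN: 65.38,
    AtomRole.SUB_P: 30.974,
    AtomRole.SUB_O3: 15.999,
    AtomRole.SUB_O4: 15.999,
    AtomRole.SUB_O5: 15.999,
    AtomRole.SUB_OTHER: 12.011,
    AtomRole.WATER_O: 15.999,
    AtomRole.WATER_H: 1.008,
    AtomRole.CL: 35.45,
    AtomRole.OTHER: 1.008,
}
for _i in range(1, 8):
    DEFAULT_MASSES[AtomRole[f"ALKYL_C{_i}"]] = 12.011


class LabelingError(ValueError):
    """Atom cannot be mapped to a role, or a role assignment is inconsistent."""


class GeometryError(ValueError):
    """Degenerate box or otherwise invalid geometry."""


class SelectionError(ValueError):
    """An atom selection required by an operation is empty."""


class ShapeError(ValueError):
    """Trajectory/topology atom counts disagree."""


class SpacingError(ValueError):
    """Frame times are not uniformly spaced."""


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    resid: int
    ligand_id: int | None
    substrate_id: int | None
    role: AtomRole
    mass: float


@dataclass
class LabeledTopology:
    """Atoms with semantic roles.

    ``roles`` / ``masses`` / ``ligand_ids`` / ``substrate_ids`` are dense
    per-atom arrays (``-1`` in the id arrays means "not part of one").
    """

    names: list[str]
    resids: np.ndarray
    roles: list[AtomRole]
    masses: np.ndarray
    ligand_ids: np.ndarray
    substrate_ids: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        self.resids = np.asarray(self.resids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.ligand_ids = np.asarray(self.ligand_ids, dtype=int)
        self.substrate_ids = np.asarray(self.substrate_ids, dtype=int)
        if not (len(self.roles) == len(self.resids) == len(self.masses) == n):
            raise ShapeError("per-atom arrays have inconsistent lengths")
        if np.any(self.masses <= 0):
            raise LabelingError("all atom masses must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_ligands(self) -> int:
        return int(np.unique(self.ligand_ids[self.ligand_ids >= 0]).size)

    @property
    def n_zn(self) -> int:
        return sum(r is AtomRole.ZN for r in self.roles)

    @property
    def n_substrates(self) -> int:
        return int(np.unique(self.substrate_ids[self.substrate_ids >= 0]).size)

    def select(self, roles: AtomRole | Iterable[AtomRole]) -> np.ndarray:
        """Indices of atoms whose role is in ``roles``."""
        if isinstance(roles, AtomRole):
            roles = {roles}
        roles = set(roles)
        return np.array([i for i, r in enumerate(self.roles) if r in roles], dtype=int)

    def atoms(self) -> list[Atom]:
        return [
            Atom(
                i,
                self.names[i],
                int(self.resids[i]),
                int(self.ligand_ids[i]) if self.ligand_ids[i] >= 0 else None,
                int(self.substrate_ids[i]) if self.substrate_ids[i] >= 0 else None,
                self.roles[i],
                float(self.masses[i]),
            )
            for i in range(self.n_atoms)
        ]

    def substrate_oxygens(self, substrate_id: int) -> dict[str, int]:
        """Indices of the labeled O3/O4/O5 (and P) of one substrate."""
        out: dict[str, int] = {}
        for i, r in enumerate(self.roles):
            if self.substrate_ids[i] == substrate_id and r in (
                AtomRole.SUB_O3,
                AtomRole.SUB_O4,
                AtomRole.SUB_O5,
                AtomRole.SUB_P,
            ):
                out[r.value.replace("SUB_", "")] = i
        for key in ("O3", "O4", "O5"):
            if key not in out:
                raise LabelingError(
                    f"substrate {substrate_id} lacks a labeled {key} atom"
                )
        return out

    def zn_ligand(self, zn_index: int) -> int:
        """Ligand id a Zn belongs to, via the chelating TACN_N residue."""
        if self.roles[zn_index] is not AtomRole.ZN:
            raise LabelingError(f"atom {zn_index} is not ZN")
        lig = int(self.ligand_ids[zn_index])
        if lig < 0:
            raise LabelingError(f"ZN atom {zn_index} is not associated with a ligand")
        return lig


@dataclass
class Trajectory:
    """Time-ordered frames: coordinates (n_frames, n_atoms, 3) nm, triclinic
    boxes (n_frames, 3, 3) nm (rows are lattice vectors), times in ps."""

    times: np.ndarray
    boxes: np.ndarray
    coords: np.ndarray
    dt: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError("coords must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords):
            raise ShapeError("times and coords disagree on frame count")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise SpacingError("frame times must be strictly increasing")
            dt = steps[0]
            bad = np.nonzero(np.abs(steps - dt) > 1e-6)[0]
            if bad.size:
                raise SpacingError(
                    f"non-uniform frame spacing at frame(s) {', '.join(str(b + 1) for b in bad[:5])}"
                    f" (expected dt={dt:g} ps)"
                )
            self.dt = float(dt)
        elif self.dt == 0.0:
            self.dt = 1.0  # single frame: spacing undefined; harmless default

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


# ---------------------------------------------------------------------------
# label maps

def load_label_map(source: str | Path | Mapping) -> dict:
    """Load a role-assignment map.

    Schema (YAML or dict)::

        by_name:             # atom name -> role
          AU: GOLD
          ZN: ZN
        by_resname_name:     # "RESNAME:ATOMNAME" -> role (takes precedence)
          SOL:OW: WATER_O
        ligand_resnames: [LIG]      # residues that constitute one ligand each
        substrate_resnames: [HPN]   # residues that constitute one substrate each
        default: OTHER       # optional fallback role
        masses:              # optional per-role mass overrides (amu)
          OTHER: 1.008
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    out = {
        "by_name": {str(k): AtomRole[v] for k, v in (raw.get("by_name") or {}).items()},
        "by_resname_name": {
            str(k): AtomRole[v] for k, v in (raw.get("by_resname_name") or {}).items()
        },
        "ligand_resnames": set(raw.get("ligand_resnames") or []),
        "substrate_resnames": set(raw.get("substrate_resnames") or []),
        "default": AtomRole[raw["default"]] if raw.get("default") else None,
        "masses": {AtomRole[k]: float(v) for k, v in (raw.get("masses") or {}).items()},
    }
    return out


def _mda_universe(coordinate_file: str | Path):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(coordinate_file), to_guess=())
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read coordinate file {coordinate_file}: {exc}") from exc


def load_topology(coordinate_file: str | Path, label_map: str | Path | Mapping) -> LabeledTopology:
    """Read a PDB/GRO coordinate file and attach semantic roles.

    Atoms not covered by the map get the map's ``default`` role if one is
    declared; otherwise a :class:`LabelingError` lists the orphans.
    """
    lm = load_label_map(label_map)
    u = _mda_universe(coordinate_file)

    names = [str(a.name) for a in u.atoms]
    resids = np.array([int(a.resid) for a in u.atoms])
    resnames = [str(a.resname).strip() for a in u.atoms]

    roles: list[AtomRole] = []
    orphans: list[str] = []
    n_defaulted = 0
    for nm, rn in zip(names, resnames):
        key = f"{rn}:{nm}"
        if key in lm["by_resname_name"]:
            roles.append(lm["by_resname_name"][key])
        elif nm in lm["by_name"]:
            roles.append(lm["by_name"][nm])
        elif lm["default"] is not None:
            roles.append(lm["default"])
            n_defaulted += 1
        else:
            roles.append(AtomRole.OTHER)
            orphans.append(f"{rn}:{nm}")
    if orphans:
        raise LabelingError(
            "label map covers neither these atoms nor declares a default: "
            + ", ".join(sorted(set(orphans))[:10])
        )
    if n_defaulted:
        warnings.warn(
            f"{n_defaulted} atoms fell through to the default role "
            f"{lm['default'].value}", stacklevel=2,
        )

    masses = np.array(
        [lm["masses"].get(r, DEFAULT_MASSES[r]) for r in roles], dtype=float
    )

    # ligand / substrate ids from residue membership
    ligand_ids = np.full(len(names), -1, dtype=int)
    substrate_ids = np.full(len(names), -1, dtype=int)
    lig_key_to_id: dict[int, int] = {}
    sub_key_to_id: dict[int, int] = {}
    for i, (rid, rn, role) in enumerate(zip(resids, resnames, roles)):
        if rn in lm["ligand_resnames"] or (
            not lm["ligand_resnames"] and role in LIGAND_ROLES
        ):
            if role in LIGAND_ROLES or role in (AtomRole.ZN, AtomRole.OTHER):
                ligand_ids[i] = lig_key_to_id.setdefault(rid, len(lig_key_to_id))
        if rn in lm["substrate_resnames"] or (
            not lm["substrate_resnames"] and role in SUBSTRATE_ROLES
        ):
            if role in SUBSTRATE_ROLES:
                substrate_ids[i] = sub_key_to_id.setdefault(rid, len(sub_key_to_id))

    topo = LabeledTopology(
        names=names,
        resids=resids,
        roles=roles,
        masses=masses,
        ligand_ids=ligand_ids,
        substrate_ids=substrate_ids,
    )

    # each Zn must have chelating TACN_N atoms in its residue
    for i, role in enumerate(roles):
        if role is AtomRole.ZN:
            in_res = resids == resids[i]
            has_tacn = any(
                roles[j] is AtomRole.TACN_N for j in np.nonzero(in_res)[0]
            )
            if not has_tacn:
                raise LabelingError(
                    f"ZN atom {i} (resid {resids[i]}) has no TACN_N in its residue"
                )
            if ligand_ids[i] < 0:
                raise LabelingError(f"ZN atom {i} could not be assigned to a ligand")
    return topo


def load_trajectory(trajectory_file: str | Path, topology: LabeledTopology,
                    coordinate_file: str | Path | None = None) -> Trajectory:
    """Read an XTC/TRR/DCD trajectory (coordinates converted A -> nm).

    DCD carries no absolute time; frame times then come from the reader's
    dt.  ``coordinate_file`` may supply the topology MDAnalysis needs when
    the trajectory format stores no atom metadata (it never overrides the
    semantic topology).
    """
    import MDAnalysis as mda

    path = Path(trajectory_file)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if coordinate_file is not None:
                u = mda.Universe(str(coordinate_file), str(path), to_guess=())
            else:
                u = mda.Universe(str(path), str(path), to_guess=())
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read trajectory {path}: {exc}") from exc

    if u.atoms.n_atoms != topology.n_atoms:
        raise ShapeError(
            f"trajectory has {u.atoms.n_atoms} atoms, topology has {topology.n_atoms}"
        )

    times, boxes, coords = [], [], []
    for ts in u.trajectory:
        times.append(float(ts.time))
        boxes.append(np.asarray(ts.triclinic_dimensions, dtype=float) / 10.0)
        coords.append(np.asarray(ts.positions, dtype=float) / 10.0)
    return Trajectory(times=np.array(times), boxes=np.array(boxes), coords=np.array(coords))


# ---------------------------------------------------------------------------
# periodic geometry

_NEIGHBOR_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3, 3):
        raise GeometryError("box must be three 3-vectors (lattice rows)")
    if abs(np.linalg.det(box)) < 1e-12:
        raise GeometryError("degenerate (zero-volume) box")
    return box


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors for a (..., 3) array.

    Rounds in fractional space, then refines over the 27 neighbour images so
    the result is exact for triclinic cells too.
    """
    box = _check_box(box)
    disp = np.asarray(disp, dtype=float)
    frac = disp @ np.linalg.inv(box)
    d0 = (frac - np.round(frac)) @ box
    shifts = _NEIGHBOR_SHIFTS @ box  # (27, 3)
    cand = d0[..., None, :] + shifts  # (..., 27, 3)
    norms = np.einsum("...ki,...ki->...k", cand, cand)
    best = np.argmin(norms, axis=-1)
    return np.take_along_axis(cand, best[..., None, None], axis=-2).squeeze(-2)


def periodic_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum-image Euclidean distance between two points (nm)."""
    d = minimum_image(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), box)
    return float(np.linalg.norm(d))


def distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances, shape (len(a), len(b))."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    disp = b[None, :, :] - a[:, None, :]
    return np.linalg.norm(minimum_image(disp, box), axis=-1)


def center_of_mass(
    topology: LabeledTopology,
    frame: np.ndarray,
    role_filter: AtomRole | Iterable[AtomRole] | None = None,
    box: np.ndarray | None = None,
    indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Mass-weighted centre of the selected atoms.

    With a box, coordinates are first unwrapped by minimum image relative to
    the first selected atom so a cluster split across the boundary still gets
    a sensible centre.
    """
    if indices is None:
        if role_filter is None:
            idx = np.arange(topology.n_atoms)
        else:
            idx = topology.select(role_filter)
    else:
        idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise SelectionError("center_of_mass: empty selection")
    pos = np.asarray(frame, dtype=float)[idx]
    if box is not None:
        ref = pos[0]
        pos = ref + minimum_image(pos - ref, box)
    m = topology.masses[idx]
    return (pos * m[:, None]).sum(axis=0) / m.sum()
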