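"""Monolayer structural descriptors.

RDFs and cumulative coordination numbers (atom- or core-centre-referenced),
RMSF after rigid-body superposition on the gold core, P2 rotational
autocorrelation functions, radius of gyration, inertia eccentricity,
geometric hydrogen bonds, close contacts, and solvent-shell counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    AtomRole,
    GeometryError,
    LabeledTopology,
    SelectionError,
    Trajectory,
    center_of_mass,
    distance_matrix,
    minimum_image,
)

__all__ = [
    "RDFProfile",
    "ContactSummary",
    "HydrogenBond",
    "radial_distribution",
    "rmsf",
    "rotational_acf",
    "p2_autocorrelation",
    "radius_of_gyration",
    "eccentricity",
    "hydrogen_bonds",
    "close_contacts",
    "shell_counts",
    "superpose",
]


@dataclass
class RDFProfile:
    r: np.ndarray            # bin centres, nm
    g: np.ndarray            # unitless
    cumulative: np.ndarray   # mean target count within r of a reference
    bin_width: float
    reference: str
    target: str


@dataclass
class ContactSummary:
    mean: float
    std: float
    kind: str


@dataclass(frozen=True)
class HydrogenBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor-acceptor, nm
    angle: float     # H-D...A angle, degrees
    tag: str         # interligand | intraligand | ligand-water | other


def _resolve(topology: LabeledTopology, sel) -> np.ndarray:
    if sel is None:
        raise SelectionError("selection is required")
    if isinstance(sel, AtomRole) or (
        isinstance(sel, (set, frozenset, list, tuple))
        and sel
        and all(isinstance(s, AtomRole) for s in sel)
    ):
        idx = topology.select(sel)
    else:
        idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty atom selection")
    return idx


# ---------------------------------------------------------------------------
# radial distribution

def radial_distribution(
    traj: Trajectory,
    topology: LabeledTopology,
    reference,
    target,
    bin_width: float = 0.02,
    r_max: float | None = None,
    center_reference: bool = False,
) -> RDFProfile:
    """g(r) and cumulative number N(r) of target atoms around a reference.

    With ``center_reference`` the single reference point is the gold-core
    centre of mass of each frame (the convention used for locating monolayer
    segments radially); otherwise every reference atom contributes.
    g(r) is normalised by the ideal-gas density of the target selection,
    N(r) is the running mean count of targets within r of a reference.
    """
    tgt = _resolve(topology, target)
    half_box = float(np.min(np.linalg.norm(traj.boxes[0], axis=1))) / 2.0
    if r_max is None:
        r_max = half_box
    if r_max > half_box + 1e-9:
        raise GeometryError(f"r_max={r_max} exceeds half the box height {half_box:.3f}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))

    if center_reference:
        n_ref = 1
        overlap = 0
    else:
        ref = _resolve(topology, reference)
        n_ref = ref.size
        overlap = int(np.intersect1d(ref, tgt).size)

    for f in range(traj.n_frames):
        box = traj.boxes[f]
        if center_reference:
            ref_pos = center_of_mass(topology, traj.coords[f], AtomRole.GOLD, box=box)[None, :]
        else:
            ref_pos = traj.coords[f][ref]
        d = distance_matrix(ref_pos, traj.coords[f][tgt], box)
        if not center_reference and overlap:
            # mask self pairs (same atom in both selections)
            for i, a in enumerate(ref):
                j = np.nonzero(tgt == a)[0]
                if j.size:
                    d[i, j[0]] = np.inf
        counts += np.histogram(d[np.isfinite(d)], bins=edges)[0]

    counts /= traj.n_frames * n_ref
    volume = float(abs(np.linalg.det(traj.boxes[0])))
    n_tgt_eff = tgt.size - (overlap / n_ref if n_ref else 0.0)
    rho = n_tgt_eff / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (rho * shell) if rho > 0 else np.zeros_like(counts)
    return RDFProfile(
        r=centers,
        g=g,
        cumulative=np.cumsum(counts),
        bin_width=bin_width,
        reference="core_com" if center_reference else "atoms",
        target="atoms",
    )


# ---------------------------------------------------------------------------
# superposition (Kabsch) and RMSF

def _kabsch(mobile: np.ndarray, ref: np.ndarray, weights: np.ndarray):
    """Optimal rotation + translation of mobile onto ref (weighted)."""
    w = weights / weights.sum()
    mc = (mobile * w[:, None]).sum(axis=0)
    rc = (ref * w[:, None]).sum(axis=0)
    h = (mobile - mc).T @ ((ref - rc) * w[:, None])
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    return rot, rc - rot @ mc


def superpose(
    traj: Trajectory, topology: LabeledTopology, fit_selection=AtomRole.GOLD
) -> np.ndarray:
    """Coordinates after rigid-body superposition of every frame onto the
    first frame, fitting on ``fit_selection`` (gold core by default)."""
    fit = _resolve(topology, fit_selection)
    ref = traj.coords[0][fit]
    w = topology.masses[fit]
    out = np.empty_like(traj.coords)
    out[0] = traj.coords[0]
    for f in range(1, traj.n_frames):
        rot, trans = _kabsch(traj.coords[f][fit], ref, w)
        out[f] = traj.coords[f] @ rot.T + trans
    return out


def rmsf(
    traj: Trajectory,
    topology: LabeledTopology,
    fit_selection=AtomRole.GOLD,
    target=None,
) -> np.ndarray:
    """Per-atom RMS fluctuation (nm) about the mean position after core
    superposition; ``target`` selects which atoms are reported (all by
    default)."""
    if traj.n_frames < 2:
        raise ValueError("rmsf needs at least 2 frames")
    coords = superpose(traj, topology, fit_selection)
    if target is not None:
        coords = coords[:, _resolve(topology, target), :]
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# rotational ACF

def p2_autocorrelation(vectors: np.ndarray) -> np.ndarray:
    """ACF of the second Legendre polynomial of unit-vector series.

    ``vectors``: (n_frames, 3) or (n_frames, n_series, 3); series are
    averaged.  Uses the identity P2(u.v) = 3/2 (u x v)^2-ish quadratic form:
    C(tau) = 3/2 <(u(t).u(t+tau))^2> - 1/2, evaluated with FFT-based
    correlation of the 9 dyadic components.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim == 2:
        v = v[:, None, :]
    n = v.shape[0]
    v = v / np.linalg.norm(v, axis=2, keepdims=True)
    # dyadic components q_ab(t) = u_a u_b, ACF summed over ab
    q = np.einsum("tsa,tsb->tsab", v, v).reshape(n, v.shape[1], 9)
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    fq = np.fft.rfft(q, n=nfft, axis=0)
    corr = np.fft.irfft(fq * np.conj(fq), n=nfft, axis=0)[:n]
    corr = corr.sum(axis=2).mean(axis=1)  # sum dyadic, average series
    norm = n - np.arange(n)
    return 1.5 * corr / norm - 0.5


def rotational_acf(
    traj: Trajectory,
    topology: LabeledTopology,
    vector_pairs: Sequence[tuple[int, int]],
    fit_selection=AtomRole.GOLD,
    do_superpose: bool = True,
) -> np.ndarray:
    """P2 orientational ACF of bond vectors (atom index pairs), averaged over
    pairs, computed after core superposition."""
    if traj.n_frames < 2:
        raise ValueError("rotational_acf needs at least 2 frames")
    if not vector_pairs:
        raise SelectionError("no vector pairs given")
    coords = superpose(traj, topology, fit_selection) if do_superpose else traj.coords
    a = np.array([p[0] for p in vector_pairs])
    b = np.array([p[1] for p in vector_pairs])
    vec = coords[:, b, :] - coords[:, a, :]
    norms = np.linalg.norm(vec, axis=2)
    bad = np.argwhere(norms < 1e-12)
    if bad.size:
        f, p = bad[0]
        raise GeometryError(f"zero-length vector for pair {p} in frame {f}")
    return p2_autocorrelation(vec)


# ---------------------------------------------------------------------------
# size and shape

def radius_of_gyration(
    traj: Trajectory, topology: LabeledTopology, selection
) -> tuple[np.ndarray, float, float]:
    """Mass-weighted Rg per frame; returns (per-frame, mean, std)."""
    idx = _resolve(topology, selection)
    m = topology.masses[idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pos = traj.coords[f][idx]
        com = (pos * m[:, None]).sum(axis=0) / m.sum()
        out[f] = np.sqrt((m * ((pos - com) ** 2).sum(axis=1)).sum() / m.sum())
    return out, float(out.mean()), float(out.std())


def eccentricity(
    traj: Trajectory, topology: LabeledTopology, selection
) -> tuple[np.ndarray, float, float]:
    """e = 1 - I_min / I_avg from the principal moments of inertia.

    0 for a spherically symmetric body, -> 1 for a thin rod.
    """
    idx = _resolve(topology, selection)
    if idx.size < 3:
        raise GeometryError("eccentricity needs at least 3 atoms")
    m = topology.masses[idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pos = traj.coords[f][idx]
        com = (pos * m[:, None]).sum(axis=0) / m.sum()
        x = pos - com
        r2 = (x**2).sum(axis=1)
        inertia = np.einsum("i,ab->ab", m * r2, np.eye(3)) - np.einsum(
            "i,ia,ib->ab", m, x, x
        )
        moments = np.linalg.eigvalsh(inertia)
        if moments[-1] < 1e-15:
            raise GeometryError(f"collinear/degenerate selection in frame {f}")
        out[f] = 1.0 - moments[0] / moments.mean()
    return out, float(out.mean()), float(out.std())


# ---------------------------------------------------------------------------
# hydrogen bonds and contacts

def nh_donor_triples(topology: LabeledTopology,
                     donor_roles=(AtomRole.N9,)) -> list[tuple[int, int]]:
    """(donor, hydrogen) pairs: an H named 'H'+donor-name in the same residue."""
    pairs = []
    for d in topology.select(set(donor_roles)):
        h_name = "H" + topology.names[d]
        found = None
        for j in np.nonzero(topology.resids == topology.resids[d])[0]:
            if topology.names[j] == h_name:
                found = int(j)
                break
        if found is None:
            raise ValueError(
                f"donor atom {d} ({topology.names[d]}) has no bonded hydrogen "
                f"'{h_name}' in its residue"
            )
        pairs.append((int(d), found))
    return pairs


def _hb_tag(topology: LabeledTopology, donor: int, acceptor: int) -> str:
    ld, la = topology.ligand_ids[donor], topology.ligand_ids[acceptor]
    water = (AtomRole.WATER_O, AtomRole.WATER_H)
    d_water = topology.roles[donor] in water
    a_water = topology.roles[acceptor] in water
    if (ld >= 0 and a_water) or (la >= 0 and d_water):
        return "ligand-water"
    if ld >= 0 and la >= 0:
        return "interligand" if ld != la else "intraligand"
    return "other"


def hydrogen_bonds(
    traj: Trajectory,
    topology: LabeledTopology,
    donor_hydrogen_pairs: Sequence[tuple[int, int]],
    acceptors,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
) -> tuple[list[list[HydrogenBond]], ContactSummary]:
    """Geometric hydrogen bonds per frame.

    Criterion: donor-acceptor distance <= d_cut and H-D...A angle (at the
    donor, between D->H and D->A) <= angle_cut.  Returned bonds are tagged
    interligand / intraligand / ligand-water.
    """
    acc = _resolve(topology, acceptors)
    if not donor_hydrogen_pairs:
        raise SelectionError("no donor-hydrogen pairs")
    donors = np.array([p[0] for p in donor_hydrogen_pairs])
    hydros = np.array([p[1] for p in donor_hydrogen_pairs])

    per_frame: list[list[HydrogenBond]] = []
    counts = []
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        pos = traj.coords[f]
        dda = distance_matrix(pos[donors], pos[acc], box)
        bonds: list[HydrogenBond] = []
        cand = np.argwhere(dda <= d_cut)
        for i, j in cand:
            d_idx, a_idx = int(donors[i]), int(acc[j])
            if d_idx == a_idx:
                continue
            dh = minimum_image(pos[hydros[i]] - pos[d_idx], box)
            da = minimum_image(pos[a_idx] - pos[d_idx], box)
            cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang <= angle_cut:
                bonds.append(
                    HydrogenBond(
                        d_idx, int(hydros[i]), a_idx, float(dda[i, j]), ang,
                        _hb_tag(topology, d_idx, a_idx),
                    )
                )
        per_frame.append(bonds)
        counts.append(len(bonds))
    counts = np.array(counts, dtype=float)
    return per_frame, ContactSummary(float(counts.mean()), float(counts.std()), "hbond")


def close_contacts(
    traj: Trajectory,
    topology: LabeledTopology,
    group_a,
    group_b,
    cutoff: float,
    kind: str = "contact",
) -> tuple[list[list[tuple[int, int]]], ContactSummary]:
    """Unordered atom pairs within ``cutoff`` (inclusive), per frame, plus the
    mean +/- std count per frame.  Used for Zn...O8, Zn...water and Zn...Cl
    tallies (0.25 nm convention)."""
    a = _resolve(topology, group_a)
    b = _resolve(topology, group_b)
    per_frame: list[list[tuple[int, int]]] = []
    counts = []
    for f in range(traj.n_frames):
        d = distance_matrix(traj.coords[f][a], traj.coords[f][b], traj.boxes[f])
        pairs = set()
        for i, j in np.argwhere(d <= cutoff):
            ai, bj = int(a[i]), int(b[j])
            if ai == bj:
                continue
            pairs.add((min(ai, bj), max(ai, bj)))
        pair_list = sorted(pairs)
        per_frame.append(pair_list)
        counts.append(len(pair_list))
    counts = np.array(counts, dtype=float)
    return per_frame, ContactSummary(float(counts.mean()), float(counts.std()), kind)


def shell_counts(
    traj: Trajectory,
    topology: LabeledTopology,
    target,
    shells: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Mean number of target atoms whose distance to the gold-core centre of
    mass lies in [r_lo, r_hi), per shell."""
    for (lo, hi), (lo2, _hi2) in zip(shells, list(shells)[1:]):
        if hi > lo2 + 1e-12:
            raise ValueError("shells must be non-overlapping and ordered")
    for lo, hi in shells:
        if hi <= lo:
            raise ValueError("each shell needs r_hi > r_lo")
    tgt = _resolve(topology, target)
    acc = np.zeros(len(shells))
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        com = center_of_mass(topology, traj.coords[f], AtomRole.GOLD, box=box)
        d = distance_matrix(com, traj.coords[f][tgt], box)[0]
        for k, (lo, hi) in enumerate(shells):
            acc[k] += np.count_nonzero((d >= lo) & (d < hi))
    return acc / traj.n_frames
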