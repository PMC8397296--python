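"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive enumeration, O(n^2) scans,
literal transcriptions of the geometric definitions) and shares no code with
the package's vectorised implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

_SHIFTS = np.array(list(itertools.product(range(-4, 5), repeat=3)), dtype=float)


def brute_min_image_distance(a, b, box):
    """Minimum distance over all 27 periodic images."""
    best = np.inf
    for s in _SHIFTS:
        d = np.linalg.norm(np.asarray(b) + s @ np.asarray(box) - np.asarray(a))
        best = min(best, d)
    return best


def brute_pair_counts(ref_pos, tgt_pos, box, edges, exclude_same_index=False):
    """Histogram of reference-target minimum-image distances."""
    counts = np.zeros(len(edges) - 1)
    for i, a in enumerate(ref_pos):
        for j, b in enumerate(tgt_pos):
            if exclude_same_index and i == j:
                continue
            d = brute_min_image_distance(a, b, box)
            k = np.searchsorted(edges, d, side="right") - 1
            if 0 <= k < len(counts) and d < edges[-1]:
                counts[k] += 1
    return counts


def brute_hydrogen_bonds(pos, donor_h_pairs, acceptors, box, d_cut, angle_cut):
    """All (donor, hydrogen, acceptor) triples passing the geometric test."""
    out = set()
    for d_idx, h_idx in donor_h_pairs:
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            # distances/angles via explicit image search
            best = (np.inf, None)
            for s in _SHIFTS:
                img = pos[a_idx] + s @ np.asarray(box)
                dist = np.linalg.norm(img - pos[d_idx])
                if dist < best[0]:
                    best = (dist, img)
            dda, img = best
            if dda > d_cut:
                continue
            dh = pos[h_idx] - pos[d_idx]
            da = img - pos[d_idx]
            cosang = dh @ da / (np.linalg.norm(dh) * np.linalg.norm(da))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang <= angle_cut:
                out.add((int(d_idx), int(h_idx), int(a_idx)))
    return out


def brute_contacts(pos_a, idx_a, pos_b, idx_b, box, cutoff):
    out = set()
    for i, a in zip(idx_a, pos_a):
        for j, b in zip(idx_b, pos_b):
            if i == j:
                continue
            if brute_min_image_distance(a, b, box) <= cutoff:
                out.add((min(int(i), int(j)), max(int(i), int(j))))
    return out


def brute_components(edges, nodes):
    """Connected components via union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return {frozenset(c) for c in comps.values()}


# ---------------------------------------------------------------------------
# literal transcriptions of the binding / precatalytic definitions.
# contacts[o][z] is True when oxygen o of the substrate is within the cutoff
# of Zn number z.

def binding_oracle(contacts: dict[str, list[bool]]) -> str:
    n_zn = len(contacts["O3"])
    # bimetallic: both phosphoryl oxygens bound to two different Zn
    for a in range(n_zn):
        for b in range(n_zn):
            if a != b and contacts["O4"][a] and contacts["O5"][b]:
                return "BI_BINDING"
    # monometallic: >=1 phosphoryl oxygen bound to exactly one Zn and no
    # second Zn touching any substrate oxygen
    involved = {
        z for z in range(n_zn)
        if contacts["O3"][z] or contacts["O4"][z] or contacts["O5"][z]
    }
    phosphoryl = {z for z in range(n_zn) if contacts["O4"][z] or contacts["O5"][z]}
    if phosphoryl and len(involved) == 1:
        return "MONO_BINDING"
    return "NONE"


def precat_oracle(contacts: dict[str, list[bool]]) -> str:
    n_zn = len(contacts["O3"])
    # type 2: O4 and O5 on two distinct Zn, O3 on one of those two
    for a in range(n_zn):
        for b in range(n_zn):
            if a != b and contacts["O4"][a] and contacts["O5"][b]:
                if contacts["O3"][a] or contacts["O3"][b]:
                    return "PRECAT_2"
    # type 3: exactly one Zn holds O4 and/or O5; a second Zn touches only O3
    phosphoryl = {z for z in range(n_zn) if contacts["O4"][z] or contacts["O5"][z]}
    if len(phosphoryl) == 1:
        (a,) = phosphoryl
        for b in range(n_zn):
            if (
                b != a
                and contacts["O3"][b]
                and not contacts["O4"][b]
                and not contacts["O5"][b]
            ):
                return "PRECAT_3"
    # type 1: one single Zn holds O3, O4 and O5; no other Zn touches any
    involved = {
        z for z in range(n_zn)
        if contacts["O3"][z] or contacts["O4"][z] or contacts["O5"][z]
    }
    if len(involved) == 1:
        (a,) = involved
        if contacts["O3"][a] and contacts["O4"][a] and contacts["O5"][a]:
            return "PRECAT_1"
    return "NONE"


def place_for_contacts(da: float, db: float, zn1, zn2, z_offset: float = 0.0):
    """A point at distance da from zn1 and db from zn2 (zn1/zn2 on x axis)."""
    zn1, zn2 = np.asarray(zn1, dtype=float), np.asarray(zn2, dtype=float)
    sep = np.linalg.norm(zn2 - zn1)
    x = (da**2 - db**2 + sep**2) / (2 * sep)
    y2 = da**2 - x**2
    if y2 < -1e-12:
        raise ValueError("infeasible distance pair")
    y = np.sqrt(max(y2, 0.0))
    ex = (zn2 - zn1) / sep
    ey = np.array([-ex[1], ex[0], 0.0])
    if np.linalg.norm(ey) < 1e-9:
        ey = np.array([0.0, 1.0, 0.0])
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    return zn1 + x * ex + y * ey + z_offset * ez
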