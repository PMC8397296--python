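"""Bimetallic-site and precatalytic-complex analysis.

Per-frame geometric classifiers (Zn pairs within a cutoff; mono/bimetallic
substrate binding; precatalytic types 1-3), segmentation of boolean series
into maximal contiguous events, existence-time population curves with
single-exponential decay fits N(t) = N0 exp(-lambda t), distance-to-core
location statistics, and state-transition counting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    AtomRole,
    LabeledTopology,
    SelectionError,
    Trajectory,
    center_of_mass,
    distance_matrix,
    stable_exp,
)
from .sites import (
    PrecatalyticGeometry,
    SiteIdentity,
    SiteKind,
    Thresholds,
)

__all__ = [
    "Event",
    "DecayFit",
    "LocationStats",
    "detect_zn_pair_series",
    "segment_events",
    "classify_binding",
    "classify_precatalytic",
    "solvation_flags",
    "build_events",
    "population_curve",
    "fit_decay",
    "location_stats",
    "transition_counts",
    "InsufficientDataError",
    "FitError",
]


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


@dataclass
class Event:
    identity: SiteIdentity
    start_time: float          # ps
    existence_time: float      # ps
    median_core_distance: float | None = None  # nm
    solvated: bool = False
    nucleophile_ready: bool = False
    start_frame: int = 0
    n_frames: int = 0


@dataclass
class DecayFit:
    n0: float
    lam: float                 # ns^-1
    residual_norm: float
    fit_range_ns: tuple[float, float]


@dataclass
class LocationStats:
    median: float
    q25: float
    q75: float
    w05: float
    w95: float
    n: int


# ---------------------------------------------------------------------------
# per-frame detectors

def detect_zn_pair_series(
    traj: Trajectory, topology: LabeledTopology, cutoff: float = 0.50
) -> dict[tuple[int, int], np.ndarray]:
    """Boolean time series for every unordered Zn pair: periodic distance
    <= cutoff.  Keys are (zn_atom_i, zn_atom_j) with i < j."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    zn = topology.select(AtomRole.ZN)
    if zn.size < 2:
        raise SelectionError("need at least 2 Zn atoms")
    n = zn.size
    iu = np.triu_indices(n, k=1)
    series = np.zeros((traj.n_frames, iu[0].size), dtype=bool)
    for f in range(traj.n_frames):
        d = distance_matrix(traj.coords[f][zn], traj.coords[f][zn], traj.boxes[f])
        series[f] = d[iu] <= cutoff
    return {
        (int(zn[i]), int(zn[j])): series[:, k]
        for k, (i, j) in enumerate(zip(*iu))
    }


def segment_events(series: np.ndarray, dt: float,
                   gap_tolerance: int = 0) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True frames -> (start_frame, n_frames).

    ``gap_tolerance`` > 0 merges runs separated by at most that many False
    frames (off by default: a single false frame ends an event)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s = np.asarray(series, dtype=bool)
    if s.size == 0:
        return []
    padded = np.concatenate([[False], s, [False]]).astype(int)
    starts = np.nonzero(np.diff(padded) == 1)[0]
    ends = np.nonzero(np.diff(padded) == -1)[0]
    runs = list(zip(starts, ends - starts))
    if gap_tolerance > 0 and len(runs) > 1:
        merged = [runs[0]]
        for start, length in runs[1:]:
            p_start, p_len = merged[-1]
            if start - (p_start + p_len) <= gap_tolerance:
                merged[-1] = (p_start, start + length - p_start)
            else:
                merged.append((start, length))
        runs = merged
    return runs


def _substrate_distances(
    frame: np.ndarray, box: np.ndarray, topology: LabeledTopology, substrate_id: int,
    zn: np.ndarray,
) -> dict[str, np.ndarray]:
    ox = topology.substrate_oxygens(substrate_id)
    pts = np.array([frame[ox["O3"]], frame[ox["O4"]], frame[ox["O5"]]])
    d = distance_matrix(pts, frame[zn], box)
    return {"O3": d[0], "O4": d[1], "O5": d[2]}


def classify_binding(
    frame: np.ndarray,
    box: np.ndarray,
    topology: LabeledTopology,
    substrate_id: int,
    o_cut: float = 0.25,
) -> tuple[SiteKind, tuple[int, ...]]:
    """Mono/bimetallic substrate binding of one substrate in one frame.

    BI_BINDING: the two phosphoryl oxygens (O4, O5) contact two *different*
    Zn ions (each within ``o_cut``).  MONO_BINDING: at least one phosphoryl
    oxygen contacts exactly one Zn and no second Zn contacts any substrate
    oxygen (O3/O4/O5).  NONE otherwise.  Returns the kind and the Zn atom
    indices involved.
    """
    zn = topology.select(AtomRole.ZN)
    if zn.size == 0:
        return SiteKind.NONE, ()
    d = _substrate_distances(frame, box, topology, substrate_id, zn)
    c4 = d["O4"] <= o_cut
    c5 = d["O5"] <= o_cut
    c3 = d["O3"] <= o_cut

    # bimetallic: O4 -> zn_a, O5 -> zn_b with zn_a != zn_b
    for a in np.nonzero(c4)[0]:
        for b in np.nonzero(c5)[0]:
            if a != b:
                return SiteKind.BI_BINDING, (int(zn[a]), int(zn[b]))

    z_phos = set(np.nonzero(c4 | c5)[0])
    z_all = set(np.nonzero(c4 | c5 | c3)[0])
    if len(z_phos) >= 1 and len(z_all) == 1:
        return SiteKind.MONO_BINDING, (int(zn[next(iter(z_all))]),)
    return SiteKind.NONE, ()


def classify_precatalytic(
    frame: np.ndarray,
    box: np.ndarray,
    topology: LabeledTopology,
    substrate_id: int,
    thresholds: Thresholds = Thresholds(),
    precedence: tuple[SiteKind, ...] = (
        SiteKind.PRECAT_2, SiteKind.PRECAT_3, SiteKind.PRECAT_1,
    ),
) -> tuple[SiteKind, tuple[int, ...], PrecatalyticGeometry]:
    """Precatalytic-complex type of one substrate in one frame.

    Type 2 (bimetallic): O4 and O5 coordinate two distinct Zn (d1, d2 <=
    threshold) while O3 coordinates one of those two (d3).  Type 3
    (pseudo-bimetallic): exactly one Zn holds O4 and/or O5 while a second Zn
    interacts only with O3.  Type 1 (monometallic): a single Zn holds O3, O4
    and O5 and no other Zn contacts any of them.  Evaluation precedence
    2 -> 3 -> 1 (bimetallic evidence outranks pseudo-bimetallic outranks
    monometallic); all cutoffs inclusive.
    """
    zn = topology.select(AtomRole.ZN)
    if zn.size == 0:
        return SiteKind.NONE, (), PrecatalyticGeometry()
    t = thresholds.o_zn
    d = _substrate_distances(frame, box, topology, substrate_id, zn)
    c3, c4, c5 = d["O3"] <= t, d["O4"] <= t, d["O5"] <= t

    def geom(zn1: int, zn2: int | None) -> PrecatalyticGeometry:
        d2 = float(d["O5"][zn2]) if zn2 is not None else float(d["O5"][zn1])
        d3_zn = zn1 if d["O3"][zn1] <= d["O3"][zn2 if zn2 is not None else zn1] else zn2
        return PrecatalyticGeometry(
            d1=float(d["O4"][zn1]), d2=d2,
            d3=float(d["O3"][d3_zn if d3_zn is not None else zn1]),
        )

    for kind in precedence:
        if kind is SiteKind.PRECAT_2:
            for a in np.nonzero(c4)[0]:
                for b in np.nonzero(c5)[0]:
                    if a != b and (c3[a] or c3[b]):
                        return (
                            SiteKind.PRECAT_2,
                            (int(zn[a]), int(zn[b])),
                            geom(a, b),
                        )
        elif kind is SiteKind.PRECAT_3:
            z_phos = set(np.nonzero(c4 | c5)[0])
            if len(z_phos) == 1:
                a = next(iter(z_phos))
                for b in np.nonzero(c3)[0]:
                    if b != a and not (c4[b] or c5[b]):
                        return (
                            SiteKind.PRECAT_3,
                            (int(zn[a]), int(zn[b])),
                            PrecatalyticGeometry(
                                d1=float(d["O4"][a]), d2=float(d["O5"][a]),
                                d3=float(d["O3"][b]),
                            ),
                        )
        elif kind is SiteKind.PRECAT_1:
            z_all = set(np.nonzero(c3 | c4 | c5)[0])
            if len(z_all) == 1:
                a = next(iter(z_all))
                if c3[a] and c4[a] and c5[a]:
                    return (
                        SiteKind.PRECAT_1,
                        (int(zn[a]),),
                        PrecatalyticGeometry(
                            d1=float(d["O4"][a]), d2=float(d["O5"][a]),
                            d3=float(d["O3"][a]),
                        ),
                    )
    return SiteKind.NONE, (), PrecatalyticGeometry()


def solvation_flags(
    frame: np.ndarray,
    box: np.ndarray,
    topology: LabeledTopology,
    complex_zn: tuple[int, ...],
    substrate_id: int,
    thresholds: Thresholds = Thresholds(),
) -> tuple[bool, bool]:
    """(solvated, nucleophile_ready) of a complex in one frame.

    Solvated: some water oxygen lies strictly within ``zn_water`` (0.20 nm)
    of a complex Zn.  Nucleophile-ready: such a Zn-bound water oxygen lies
    within ``water_o3`` (0.25 nm) of the substrate's O3.
    """
    if not complex_zn:
        raise SelectionError("complex has no Zn ids")
    waters = topology.select(AtomRole.WATER_O)
    if waters.size == 0:
        return False, False
    d_zw = distance_matrix(frame[list(complex_zn)], frame[waters], box)
    bound = np.nonzero((d_zw < thresholds.zn_water).any(axis=0))[0]
    if bound.size == 0:
        return False, False
    ox = topology.substrate_oxygens(substrate_id)
    d_wo3 = distance_matrix(frame[waters[bound]], frame[ox["O3"]], box)[:, 0]
    return True, bool((d_wo3 <= thresholds.water_o3).any())


# ---------------------------------------------------------------------------
# event construction

def _core_center(topology: LabeledTopology, frame: np.ndarray, box: np.ndarray):
    gold = topology.select(AtomRole.GOLD)
    if gold.size == 0:
        return None
    return center_of_mass(topology, frame, AtomRole.GOLD, box=box)


def _frame_states(
    traj: Trajectory,
    topology: LabeledTopology,
    kind_group: str,
    thresholds: Thresholds,
) -> list[list[tuple[SiteKind, tuple[int, ...]]]]:
    """Per-substrate, per-frame classified state."""
    out = []
    for s in range(topology.n_substrates):
        states = []
        for f in range(traj.n_frames):
            frame, box = traj.coords[f], traj.boxes[f]
            if kind_group == "binding":
                kind, ids = classify_binding(frame, box, topology, s, thresholds.o_zn)
            else:
                kind, ids, _ = classify_precatalytic(frame, box, topology, s, thresholds)
            states.append((kind, ids))
        out.append(states)
    return out


def build_events(
    traj: Trajectory,
    topology: LabeledTopology,
    kind: str,
    thresholds: Thresholds = Thresholds(),
    gap_tolerance: int = 0,
    with_flags: bool = True,
) -> list[Event]:
    """Segment per-frame classifications into events for one analysis kind.

    ``kind`` is ``"znpair"``, ``"binding"`` or ``"precat"``.  Each event is a
    maximal run of frames over which the same identity (kind + Zn ids +
    substrate) holds; it carries existence time (frames x dt), the median
    distance of its Zn ions to the gold-core centre of mass pooled over both
    ions and all event frames, and (for precatalytic kinds) solvation flags
    with any-frame semantics.
    """
    if kind not in ("znpair", "binding", "precat"):
        raise ValueError(f"unknown event kind {kind!r}")
    dt = traj.dt
    centers = [
        _core_center(topology, traj.coords[f], traj.boxes[f])
        for f in range(traj.n_frames)
    ]

    def med_dist(zn_ids: tuple[int, ...], f0: int, n: int) -> float | None:
        if centers[0] is None:
            return None
        pool = []
        for f in range(f0, f0 + n):
            d = distance_matrix(
                traj.coords[f][list(zn_ids)], centers[f], traj.boxes[f]
            )[:, 0]
            pool.extend(d)
        return float(np.median(pool))

    events: list[Event] = []
    if kind == "znpair":
        for (zi, zj), series in detect_zn_pair_series(
            traj, topology, thresholds.zn_zn
        ).items():
            ident = SiteIdentity(SiteKind.ZN_PAIR, frozenset((zi, zj)))
            for f0, n in segment_events(series, dt, gap_tolerance):
                events.append(
                    Event(
                        identity=ident,
                        start_time=f0 * dt,
                        existence_time=n * dt,
                        median_core_distance=med_dist((zi, zj), f0, n),
                        start_frame=f0,
                        n_frames=n,
                    )
                )
        events.sort(key=lambda e: (e.start_frame, sorted(e.identity.zn_ids)))
        return events

    group = "binding" if kind == "binding" else "precat"
    per_sub = _frame_states(traj, topology, group, thresholds)
    for s, states in enumerate(per_sub):
        identities = {
            (k, frozenset(ids)) for k, ids in states if k is not SiteKind.NONE
        }
        for k, ids in sorted(identities, key=lambda x: (x[0].value, sorted(x[1]))):
            series = np.array(
                [st[0] is k and frozenset(st[1]) == ids for st in states],
                dtype=bool,
            )
            for f0, n in segment_events(series, dt, gap_tolerance):
                ev = Event(
                    identity=SiteIdentity(k, ids, substrate_id=s),
                    start_time=f0 * dt,
                    existence_time=n * dt,
                    median_core_distance=med_dist(tuple(sorted(ids)), f0, n),
                    start_frame=f0,
                    n_frames=n,
                )
                if with_flags and kind == "precat":
                    for f in range(f0, f0 + n):
                        solv, nuc = solvation_flags(
                            traj.coords[f], traj.boxes[f], topology,
                            tuple(sorted(ids)), s, thresholds,
                        )
                        ev.solvated = ev.solvated or solv
                        ev.nucleophile_ready = ev.nucleophile_ready or nuc
                        if ev.solvated and ev.nucleophile_ready:
                            break
                events.append(ev)
    events.sort(key=lambda e: (e.start_frame, e.identity.kind.value))
    return events


# ---------------------------------------------------------------------------
# existence-time statistics

def population_curve(events_or_durations) -> tuple[np.ndarray, np.ndarray]:
    """Cumulated population N(t): number of events with existence time > t.

    Accepts a list of :class:`Event` or an array of durations in ps; t is
    returned in ns, evaluated at 0 and at each distinct observed existence
    time.  N is non-increasing with N(0) = total events.
    """
    if len(events_or_durations) == 0:
        return np.zeros(0), np.zeros(0)
    if isinstance(events_or_durations[0], Event):
        dur_ps = np.array([e.existence_time for e in events_or_durations])
    else:
        dur_ps = np.asarray(events_or_durations, dtype=float)
    dur_ns = dur_ps / 1000.0
    grid = np.concatenate([[0.0], np.unique(dur_ns)])
    n_t = np.array([(dur_ns > t).sum() for t in grid], dtype=float)
    return grid, n_t


def fit_decay(curve: tuple[np.ndarray, np.ndarray],
              fit_range_ns: tuple[float, float] | None = None) -> DecayFit:
    """Nonlinear least-squares fit of N(t) = N0 exp(-lambda t).

    Initial guess from log-linear regression on the strictly positive part
    of the curve; lambda reported in ns^-1.  ``fit_range_ns`` restricts the
    fitted window (the full curve by default).
    """
    t, n = np.asarray(curve[0], dtype=float), np.asarray(curve[1], dtype=float)
    if fit_range_ns is not None:
        keep = (t >= fit_range_ns[0]) & (t <= fit_range_ns[1])
        t, n = t[keep], n[keep]
    if np.unique(t).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct existence times, got {np.unique(t).size}"
        )
    pos = n > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(n[pos]), 1)
        lam0 = max(-slope, 1e-9)
        n0_0 = float(np.exp(intercept))
    else:
        lam0, n0_0 = 1.0, float(n.max() or 1.0)
    try:
        popt, _ = curve_fit(
            lambda tt, n0, lam: n0 * stable_exp(-lam * tt),
            t, n, p0=(n0_0, lam0), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge: {exc}") from exc
    n0, lam = float(popt[0]), float(popt[1])
    if n0 <= 0 or lam <= 0:
        raise FitError(f"unphysical fit: N0={n0:.3g}, lambda={lam:.3g}")
    resid = float(np.linalg.norm(n0 * stable_exp(-lam * t) - n))
    return DecayFit(
        n0=n0, lam=lam, residual_norm=resid,
        fit_range_ns=(float(t.min()), float(t.max())),
    )


def location_stats(events: list[Event]) -> LocationStats:
    """Boxplot statistics (5/25/50/75/95 percentiles) of per-event median
    distances to the gold-core centre."""
    dist = [e.median_core_distance for e in events if e.median_core_distance is not None]
    if not dist:
        raise InsufficientDataError("no events with a core distance")
    q = np.percentile(dist, [5, 25, 50, 75, 95])
    return LocationStats(
        median=float(q[2]), q25=float(q[1]), q75=float(q[3]),
        w05=float(q[0]), w95=float(q[4]), n=len(dist),
    )


def transition_counts(
    state_series: list[list[SiteKind]] | list[SiteKind],
) -> dict[tuple[SiteKind, SiteKind], int]:
    """Counts of consecutive-frame transitions between *distinct* states,
    aggregated over substrates; self-transitions excluded."""
    if state_series and isinstance(state_series[0], SiteKind):
        state_series = [state_series]
    counts: dict[tuple[SiteKind, SiteKind], int] = {}
    for series in state_series:
        for a, b in zip(series[:-1], series[1:]):
            if a is not b:
                counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def state_series(
    traj: Trajectory,
    topology: LabeledTopology,
    thresholds: Thresholds = Thresholds(),
) -> list[list[SiteKind]]:
    """Per-substrate frame-state series combining binding and precatalytic
    classification (precatalytic label wins where both apply)."""
    out = []
    for s in range(topology.n_substrates):
        states = []
        for f in range(traj.n_frames):
            frame, box = traj.coords[f], traj.boxes[f]
            kind, _, _ = classify_precatalytic(frame, box, topology, s, thresholds)
            if kind is SiteKind.NONE:
                kind, _ = classify_binding(frame, box, topology, s, thresholds.o_zn)
            states.append(kind)
        out.append(states)
    return out
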