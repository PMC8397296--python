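"""Site detection, complex classification, event segmentation and decay fits."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanosite.core import AtomRole, SelectionError
from nanosite.events import (
    InsufficientDataError,
    build_events,
    classify_binding,
    classify_precatalytic,
    detect_zn_pair_series,
    fit_decay,
    location_stats,
    population_curve,
    segment_events,
    solvation_flags,
    transition_counts,
)
from nanosite.sites import SiteKind, Thresholds
from nanosite.synthetic import (
    EventEntry,
    EventSchedule,
    build_nanoparticle,
    generate_trajectory,
    sample_event_durations,
    SyntheticConfig,
)

from conftest import make_topology, make_trajectory
from oracles import binding_oracle, place_for_contacts, precat_oracle

F, T = False, True


class TestSegmentEvents:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([F, T, T, T, F, T, F], [(1, 3), (5, 1)]),
            ([F, F, F], []),
            ([T, T, T, T], [(0, 4)]),
            ([T, F, T], [(0, 1), (2, 1)]),
            ([], []),
        ],
    )
    def test_maximal_runs(self, series, expected):
        assert segment_events(np.array(series, dtype=bool), dt=5.0) == expected

    def test_existence_time_is_run_length_times_dt(self):
        runs = segment_events(np.array([F, T, T, T, F, T, F]), dt=5.0)
        assert [n * 5.0 for _, n in runs] == [15.0, 5.0]

    def test_gap_tolerance_merges_runs(self):
        series = np.array([T, T, F, T, T])
        assert segment_events(series, 5.0, gap_tolerance=1) == [(0, 5)]
        assert segment_events(series, 5.0, gap_tolerance=0) == [(0, 2), (3, 2)]


class TestZnPairSeries:
    def test_three_mutually_close_zn_give_three_pairs(self):
        topo = make_topology([AtomRole.ZN] * 3,
                             resids=[1, 2, 3])
        frame = np.array([[1.0, 1, 1], [1.3, 1, 1], [1.15, 1.25, 1]])
        traj = make_trajectory(frame, box_edge=6.0)
        series = detect_zn_pair_series(traj, topo, cutoff=0.50)
        active = [k for k, v in series.items() if v.any()]
        assert len(active) == 3

    def test_far_zn_no_sites(self):
        topo = make_topology([AtomRole.ZN] * 3)
        frame = np.array([[0.5, 0.5, 0.5], [2.5, 2.5, 2.5], [4.5, 4.5, 0.5]])
        traj = make_trajectory(frame, box_edge=10.0)
        series = detect_zn_pair_series(traj, topo, cutoff=0.50)
        assert not any(v.any() for v in series.values())

    def test_fewer_than_two_zn_rejected(self):
        topo = make_topology([AtomRole.ZN])
        traj = make_trajectory(np.zeros((1, 3)))
        with pytest.raises(SelectionError):
            detect_zn_pair_series(traj, topo, 0.5)

    def test_planted_schedule_recovered_exactly(self, small_system):
        cfg, topo, frame0 = small_system
        zn = topo.select(AtomRole.ZN)
        entries = []
        expected = {}
        specs = [(0, 1, 2, 5), (2, 3, 10, 3), (4, 5, 1, 8), (6, 7, 20, 4),
                 (8, 9, 12, 6)]
        for a, b, start, dur in specs:
            pair = (int(zn[a]), int(zn[b]))
            entries.append(EventEntry(SiteKind.ZN_PAIR, start, dur, zn=pair,
                                      geometry={"zn_zn": 0.44}))
            expected[pair] = (start, dur)
        traj = generate_trajectory(topo, frame0, EventSchedule(entries), cfg)
        series = detect_zn_pair_series(traj, topo, 0.50)
        active = {k: v for k, v in series.items() if v.any()}
        assert set(active) == set(expected)
        for pair, (start, dur) in expected.items():
            assert segment_events(active[pair], cfg.dt) == [(start, dur)]


class TestClassifyBinding:
    def test_single_phosphoryl_contact_is_mono(self, binding_playground):
        topo, frame, box = binding_playground
        zn = topo.select(AtomRole.ZN)
        frame[4] = frame[zn[0]] - [0.24, 0, 0]  # O4 near Zn1, away from Zn2
        kind, ids = classify_binding(frame, box, topo, 0)
        assert kind is SiteKind.MONO_BINDING
        assert ids == (int(zn[0]),)

    def test_two_phosphoryl_on_two_zn_is_bi(self, binding_playground):
        topo, frame, box = binding_playground
        zn = topo.select(AtomRole.ZN)
        frame[4] = frame[zn[0]] + [0.0, 0.24, 0]   # O4-Zn1
        frame[5] = frame[zn[1]] + [0.0, 0.23, 0]   # O5-Zn2
        kind, ids = classify_binding(frame, box, topo, 0)
        assert kind is SiteKind.BI_BINDING
        assert set(ids) == {int(zn[0]), int(zn[1])}

    def test_all_far_is_none(self, binding_playground):
        topo, frame, box = binding_playground
        kind, ids = classify_binding(frame, box, topo, 0)
        assert kind is SiteKind.NONE


class TestClassifyPrecatalytic:
    def test_type2_forced_geometry(self, binding_playground):
        topo, frame, box = binding_playground
        zn = topo.select(AtomRole.ZN)
        frame[4] = frame[zn[0]] + [0.0, 0.22, 0]      # d1 O4-Zn1
        frame[5] = frame[zn[1]] + [0.0, 0.23, 0]      # d2 O5-Zn2
        frame[3] = frame[zn[0]] + [0.0, 0.0, 0.24]    # d3 O3-Zn1
        kind, ids, geom = classify_precatalytic(frame, box, topo, 0)
        assert kind is SiteKind.PRECAT_2
        assert set(ids) == {int(zn[0]), int(zn[1])}
        assert geom.d1 == pytest.approx(0.22)

    def test_type3_second_zn_only_on_hydroxyl(self, binding_playground):
        topo, frame, box = binding_playground
        zn = topo.select(AtomRole.ZN)
        frame[4] = frame[zn[0]] + [0.0, 0.22, 0]      # O4-Zn1
        frame[3] = frame[zn[1]] + [0.0, 0.0, 0.24]    # O3-Zn2
        kind, ids, _ = classify_precatalytic(frame, box, topo, 0)
        assert kind is SiteKind.PRECAT_3
        assert ids == (int(zn[0]), int(zn[1]))

    def test_type1_single_zn_holds_all_three(self, binding_playground):
        topo, frame, box = binding_playground
        zn = topo.select(AtomRole.ZN)
        frame[3] = frame[zn[0]] + [0.0, 0.0, 0.24]
        frame[4] = frame[zn[0]] + [0.0, 0.24, 0.0]
        frame[5] = frame[zn[0]] + [0.0, -0.24, 0.0]
        kind, ids, _ = classify_precatalytic(frame, box, topo, 0)
        assert kind is SiteKind.PRECAT_1
        assert ids == (int(zn[0]),)

    def test_truth_table_matches_oracle(self, binding_playground):
        """Exhaustive check over every qualitative distance configuration:
        each of O3/O4/O5 at 0.20 (contact) or 0.30 nm (no contact) from each
        of 2 Zn, labels compared against literal transcriptions of the
        definitions, including the subset relations type1 within mono and
        type2 within bimetallic binding."""
        topo, frame, box = binding_playground
        zn = topo.select(AtomRole.ZN)
        zn1, zn2 = frame[zn[0]], frame[zn[1]]
        choices = (0.20, 0.30)
        for combo in itertools.product(choices, repeat=6):
            d = {"O3": combo[0:2], "O4": combo[2:4], "O5": combo[4:6]}
            f = frame.copy()
            for k, (o_name, idx) in enumerate((("O3", 3), ("O4", 4), ("O5", 5))):
                f[idx] = place_for_contacts(d[o_name][0], d[o_name][1], zn1, zn2,
                                            z_offset=0.0)
            contacts = {o: [d[o][0] <= 0.25, d[o][1] <= 0.25] for o in d}
            b_kind, _ = classify_binding(f, box, topo, 0)
            p_kind, _, _ = classify_precatalytic(f, box, topo, 0)
            assert b_kind.value == binding_oracle(contacts), contacts
            assert p_kind.value == precat_oracle(contacts), contacts
            if p_kind is SiteKind.PRECAT_1:
                assert b_kind is SiteKind.MONO_BINDING
            if p_kind is SiteKind.PRECAT_2:
                assert b_kind is SiteKind.BI_BINDING


class TestSolvationFlags:
    def _prep(self, binding_playground, water_from_zn, water_from_o3=None):
        topo, frame, box = binding_playground
        zn = topo.select(AtomRole.ZN)
        frame[3] = frame[zn[0]] + [0.0, 0.0, 0.24]  # O3 bound to Zn1
        if water_from_o3 is None:
            frame[6] = frame[zn[0]] + [0.0, water_from_zn, 0.0]
        else:
            frame[6] = place_for_contacts(
                water_from_zn, water_from_o3, frame[zn[0]], frame[3]
            )
        return topo, frame, box, (int(zn[0]),)

    def test_bound_water_near_nucleophile(self, binding_playground):
        topo, frame, box, zn_ids = self._prep(binding_playground, 0.19, 0.24)
        assert solvation_flags(frame, box, topo, zn_ids, 0) == (True, True)

    def test_no_water_nearby(self, binding_playground):
        topo, frame, box, zn_ids = self._prep(binding_playground, 0.30)
        assert solvation_flags(frame, box, topo, zn_ids, 0) == (False, False)

    def test_bound_water_far_from_nucleophile(self, binding_playground):
        topo, frame, box, zn_ids = self._prep(binding_playground, 0.19, 0.40)
        assert solvation_flags(frame, box, topo, zn_ids, 0) == (True, False)

    def test_d4_boundary_is_strict(self, binding_playground):
        topo, frame, box, zn_ids = self._prep(binding_playground, 0.20)
        assert solvation_flags(frame, box, topo, zn_ids, 0) == (False, False)


class TestBuildEvents:
    def test_planted_precat2_event(self, small_system):
        cfg, topo, frame0 = small_system
        zn = topo.select(AtomRole.ZN)
        w = topo.select(AtomRole.WATER_O)
        sched = EventSchedule([
            EventEntry(SiteKind.PRECAT_2, start=4, duration=6,
                       zn=(int(zn[0]), int(zn[1])), substrate=0,
                       geometry={"d1": 0.22, "d2": 0.23, "d3": 0.24,
                                 "d4": 0.19, "d5": 0.24, "water": int(w[0])}),
        ])
        traj = generate_trajectory(topo, frame0, sched, cfg)
        events = build_events(traj, topo, "precat")
        assert len(events) == 1
        e = events[0]
        assert e.identity.kind is SiteKind.PRECAT_2
        assert e.identity.zn_ids == frozenset({int(zn[0]), int(zn[1])})
        assert e.existence_time == pytest.approx(30.0)
        assert e.solvated and e.nucleophile_ready
        assert e.median_core_distance is not None

    def test_same_identity_two_intervals_two_events(self, small_system):
        cfg, topo, frame0 = small_system
        zn = topo.select(AtomRole.ZN)
        pair = (int(zn[2]), int(zn[7]))
        sched = EventSchedule([
            EventEntry(SiteKind.ZN_PAIR, 2, 3, zn=pair, geometry={"zn_zn": 0.44}),
            EventEntry(SiteKind.ZN_PAIR, 10, 2, zn=pair, geometry={"zn_zn": 0.44}),
        ])
        traj = generate_trajectory(topo, frame0, sched, cfg)
        events = build_events(traj, topo, "znpair")
        assert len(events) == 2
        assert events[0].identity == events[1].identity

    def test_unique_vs_total_tallies(self, small_system):
        cfg, topo, frame0 = small_system
        zn = topo.select(AtomRole.ZN)
        sched = EventSchedule([
            EventEntry(SiteKind.ZN_PAIR, 0, 2, zn=(int(zn[0]), int(zn[1]))),
            EventEntry(SiteKind.ZN_PAIR, 5, 2, zn=(int(zn[0]), int(zn[1]))),
            EventEntry(SiteKind.ZN_PAIR, 9, 2, zn=(int(zn[2]), int(zn[3]))),
        ])
        traj = generate_trajectory(topo, frame0, sched, cfg)
        events = build_events(traj, topo, "znpair")
        assert len(events) == 3                       # "formed X times"
        assert len({e.identity for e in events}) == 2  # unique sites


class TestPopulationCurve:
    def test_counting_example(self):
        t, n = population_curve(np.array([5.0, 5.0, 20.0]))  # ps
        assert t[0] == 0.0 and n[0] == 3
        lookup = dict(zip(t, n))
        assert lookup[0.005] == 1
        assert lookup[0.020] == 0

    def test_single_event_step(self):
        t, n = population_curve(np.array([10.0]))
        np.testing.assert_array_equal(n, [1, 0])

    def test_non_increasing_and_matches_brute_force(self):
        rng = np.random.default_rng(5)
        dur = rng.integers(1, 50, size=200) * 5.0
        t, n = population_curve(dur)
        assert np.all(np.diff(n) <= 0)
        for tt, nn in zip(t, n):
            assert nn == np.sum(dur / 1000.0 > tt)
        assert n[-1] == 0


class TestFitDecay:
    def test_noiseless_exact_recovery(self):
        t = np.linspace(0, 3.0, 60)
        curve = (t, 1000.0 * np.exp(-2.0 * t))
        fit = fit_decay(curve)
        assert fit.n0 == pytest.approx(1000.0, rel=1e-6)
        assert fit.lam == pytest.approx(2.0, rel=1e-6)

    def test_sampled_at_paper_regime(self):
        lam = 131.0
        dur = sample_event_durations(5000, lam, dt=5.0, seed=77)
        fit = fit_decay(population_curve(dur * 5.0))
        assert abs(fit.lam - lam) / lam < 0.10

    def test_constant_curve_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_decay(population_curve(np.full(10, 25.0)))

    @settings(deadline=None, max_examples=10)
    @given(st.floats(0.2, 5.0))
    def test_scale_consistency(self, c):
        rng = np.random.default_rng(11)
        dur = rng.exponential(50.0, size=400) + 5.0  # ps
        base = fit_decay(population_curve(dur))
        scaled = fit_decay(population_curve(dur * c))
        assert scaled.lam == pytest.approx(base.lam / c, rel=1e-3)


class TestLocationStats:
    def _events(self, distances):
        from nanosite.events import Event
        from nanosite.sites import SiteIdentity

        ident = SiteIdentity(SiteKind.ZN_PAIR, frozenset({0, 1}))
        return [Event(ident, 0.0, 5.0, median_core_distance=d) for d in distances]

    def test_median_of_three(self):
        s = location_stats(self._events([1.0, 2.0, 3.0]))
        assert s.median == 2.0

    def test_single_event_collapses(self):
        s = location_stats(self._events([2.5]))
        assert s.w05 == s.q25 == s.median == s.q75 == s.w95 == 2.5

    def test_quantiles_match_numpy_sort(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(1.5, 3.5, size=87)
        s = location_stats(self._events(d))
        ref = np.percentile(np.sort(d), [5, 25, 50, 75, 95])
        np.testing.assert_allclose([s.w05, s.q25, s.median, s.q75, s.w95], ref)
        assert s.w05 <= s.q25 <= s.median <= s.q75 <= s.w95

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            location_stats([])


class TestTransitionCounts:
    def test_round_trip_example(self):
        M, P1 = SiteKind.MONO_BINDING, SiteKind.PRECAT_1
        counts = transition_counts([M, P1, P1, M])
        assert counts == {(M, P1): 1, (P1, M): 1}

    def test_constant_series_empty(self):
        assert transition_counts([SiteKind.NONE] * 10) == {}

    def test_planted_path_counted_once(self, small_system):
        cfg, topo, frame0 = small_system
        zn = topo.select(AtomRole.ZN)
        sched = EventSchedule([
            EventEntry(SiteKind.MONO_BINDING, 2, 3, zn=(int(zn[0]),), substrate=0),
            EventEntry(SiteKind.PRECAT_2, 5, 3, zn=(int(zn[0]), int(zn[1])),
                       substrate=0),
        ])
        traj = generate_trajectory(topo, frame0, sched, cfg)
        from nanosite.events import state_series

        counts = transition_counts(state_series(traj, topo))
        assert counts[(SiteKind.MONO_BINDING, SiteKind.PRECAT_2)] == 1
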