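"""Distances, coverage, contact maps, surface maps, and binding events."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycocover as gc
from glycocover.contacts import (
    _frame_pair_count,
    contact_fraction,
    events_from_series,
    min_distance_per_residue,
    pair_contact_counts,
    surface_distance_map,
)
from glycocover.errors import AnalysisError, ParameterError

from conftest import brute_min_distances, make_random_system, simple_system


class TestMinDistance:
    def test_single_pair_no_box(self):
        sysm = simple_system(
            [[0.0, 0.0, 0.0], [0.3, 0.0, 0.0]], residue_split=1
        )
        series = min_distance_per_residue(sysm, "entity a", "entity b")
        np.testing.assert_allclose(series.distances, [[0.3]])

    def test_minimum_image_in_cubic_box(self):
        sysm = simple_system(
            [[0.0, 0.0, 0.0], [0.9, 0.0, 0.0]], residue_split=1,
            box=np.array([1.0, 1.0, 1.0]),
        )
        series = min_distance_per_residue(sysm, "entity a", "entity b")
        np.testing.assert_allclose(series.distances, [[0.1]], atol=1e-12)

    @pytest.mark.parametrize("periodic", [True, False])
    @pytest.mark.parametrize("seed", range(4))
    def test_backends_match_brute_force_oracle(self, seed, periodic):
        rng = np.random.default_rng(seed)
        sysm = make_random_system(rng, n_group_atoms=50, n_target_atoms=50,
                                  n_frames=4, periodic=periodic)
        ga = gc.resolve("entity groupA", sysm)
        ta = gc.resolve("entity groupB", sysm)
        for method in ("brute", "kdtree"):
            series = min_distance_per_residue(sysm, "entity groupA",
                                              "entity groupB", method=method)
            for f in range(sysm.n_frames):
                ref = brute_min_distances(sysm, ga, ta, f)
                for j, rid in enumerate(series.residue_ids):
                    assert abs(series.distances[f, j] - ref[int(rid)]) < 1e-9

    def test_overlapping_selections_rejected(self):
        sysm = simple_system(np.zeros((4, 3)), residue_split=2)
        with pytest.raises(AnalysisError, match="overlap"):
            min_distance_per_residue(sysm, "entity a", "entity a or entity b")

    def test_rigid_motion_invariance_without_box(self):
        rng = np.random.default_rng(3)
        sysm = make_random_system(rng, n_frames=2, periodic=False)
        series0 = min_distance_per_residue(sysm, "entity groupA", "entity groupB")
        # random rotation + translation applied to every frame
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_quat([0.3, -0.5, 0.2, 0.79]).as_matrix()
        moved = sysm.with_frames(sysm.frames @ rot.T + [1.0, -2.0, 0.5], None)
        series1 = min_distance_per_residue(moved, "entity groupA", "entity groupB")
        np.testing.assert_allclose(series0.distances, series1.distances, atol=1e-9)


class TestContactFraction:
    def test_counting_examples(self):
        series = gc.ResidueDistanceSeries([1], np.array([[0.2], [0.4], [0.2], [0.4]]), 0.1)
        cov = contact_fraction(series, 0.3)
        assert cov.coverage[0] == 0.5
        assert contact_fraction(series, 0.15).coverage[0] == 0.0
        assert contact_fraction(series, 5.0).coverage[0] == 1.0

    def test_strict_inequality_at_cutoff(self):
        series = gc.ResidueDistanceSeries([1], np.array([[0.3], [0.3]]), 0.1)
        assert contact_fraction(series, 0.3).coverage[0] == 0.0

    def test_matches_direct_count(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1, (200, 7))
        series = gc.ResidueDistanceSeries(np.arange(7), d, 0.1)
        cov = contact_fraction(series, 0.3)
        np.testing.assert_array_equal(cov.coverage, (d < 0.3).sum(axis=0) / 200)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(st.floats(0, 2, allow_nan=False), min_size=1, max_size=50),
        c1=st.floats(0.01, 1.0),
        c2=st.floats(0.01, 1.0),
    )
    def test_monotone_in_cutoff(self, data, c1, c2):
        lo, hi = sorted([c1, c2])
        series = gc.ResidueDistanceSeries([1], np.array(data)[:, None], 0.1)
        assert contact_fraction(series, lo).coverage[0] <= contact_fraction(series, hi).coverage[0]

    def test_zero_frames_error(self):
        with pytest.raises(AnalysisError):
            contact_fraction(gc.ResidueDistanceSeries([1], np.empty((0, 1)), 0.1))


class TestPairContactCounts:
    def test_two_atoms_within_cutoff(self):
        sysm = simple_system([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]], residue_split=1)
        cm = pair_contact_counts(sysm, ["a", "b"], cutoff=0.6)
        np.testing.assert_array_equal(cm.counts, [[0.0, 1.0], [1.0, 0.0]])

    def test_far_apart_is_zero(self):
        sysm = simple_system([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]], residue_split=1)
        cm = pair_contact_counts(sysm, ["a", "b"], cutoff=0.6)
        assert cm.counts.sum() == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sysm = make_random_system(rng, n_group_atoms=20, n_target_atoms=15, n_frames=3)
        cm = pair_contact_counts(sysm, ["groupA", "groupB"], cutoff=0.8)
        ga = gc.resolve("entity groupA", sysm)
        ta = gc.resolve("entity groupB", sysm)
        total = 0
        for f in range(3):
            box = sysm.boxes[f]
            for i in ga:
                for j in ta:
                    d = sysm.frames[f, i] - sysm.frames[f, j]
                    d = d - box * np.round(d / box)
                    if np.sqrt((d * d).sum()) < 0.8:
                        total += 1
        assert cm.counts[0, 1] == pytest.approx(total / 3)
        assert cm.counts[0, 1] == cm.counts[1, 0]  # symmetry

    def test_replica_aggregation_is_mean_of_means(self):
        near = simple_system([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]], residue_split=1)
        far = simple_system([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]], residue_split=1)
        cm = pair_contact_counts([near, far], ["a", "b"], cutoff=0.6)
        assert cm.counts[0, 1] == 0.5

    def test_atom_count_mode(self):
        # 2 atoms of "a" each touching the single "b" atom: 2 pairs, 3 atoms
        sysm = simple_system(
            [[0.0, 0.0, 0.0], [0.2, 0.0, 0.0], [0.1, 0.1, 0.0]], residue_split=2
        )
        pairs = pair_contact_counts(sysm, ["a", "b"], cutoff=0.6, count_mode="pairs")
        atoms = pair_contact_counts(sysm, ["a", "b"], cutoff=0.6, count_mode="atoms")
        assert pairs.counts[0, 1] == 2.0
        assert atoms.counts[0, 1] == 3.0


class TestSurfaceDistanceMap:
    def test_constant_distance_and_clamp(self):
        sysm = simple_system([[0.0, 0.0, 0.0], [0.7, 0.0, 0.0]], residue_split=1)
        df = surface_distance_map([sysm], "entity a", "entity b")
        assert df["mean_min_distance_nm"].iloc[0] == pytest.approx(0.7)
        assert df["clamped_nm"].iloc[0] == pytest.approx(0.7)
        far = simple_system([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]], residue_split=1)
        df2 = surface_distance_map([far], "entity a", "entity b")
        assert df2["mean_min_distance_nm"].iloc[0] == pytest.approx(2.0)
        assert df2["clamped_nm"].iloc[0] == pytest.approx(1.5)

    def test_replica_mean_is_arithmetic(self):
        reps = [
            simple_system([[0.0, 0.0, 0.0], [d, 0.0, 0.0]], residue_split=1)
            for d in (0.4, 0.6, 1.1)
        ]
        df = surface_distance_map(reps, "entity a", "entity b")
        assert df["mean_min_distance_nm"].iloc[0] == pytest.approx((0.4 + 0.6 + 1.1) / 3)

    def test_unequal_replica_lengths_warn(self):
        r1 = simple_system(np.tile([[0, 0, 0], [0.5, 0, 0]], (3, 1, 1)), residue_split=1)
        r2 = simple_system([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]], residue_split=1)
        with pytest.warns(UserWarning, match="unequal"):
            surface_distance_map([r1, r2], "entity a", "entity b")


def oracle_events(distances, dt, on, off, min_dwell):
    """Independent reference state machine operating on a per-frame state array."""
    n = len(distances)
    state = np.zeros(n, dtype=bool)
    bound = distances[0] < on
    for i, d in enumerate(distances):
        if bound and d > off:
            bound = False
        elif not bound and d < on:
            bound = True
        state[i] = bound
    min_frames = int(np.ceil(min_dwell / dt)) if min_dwell > 0 else 0
    # repeatedly rewrite the shortest too-short run in the state array itself
    while True:
        runs = []
        s = 0
        for i in range(1, n + 1):
            if i == n or state[i] != state[s]:
                runs.append((s, i))
                s = i
        if len(runs) <= 1:
            break
        short = [(e - s, k) for k, (s, e) in enumerate(runs) if e - s < min_frames]
        if not short:
            break
        _, k = min(short)
        s, e = runs[k]
        if k == 0:
            state[s:e] = state[runs[1][0]]
        else:
            state[s:e] = state[runs[k - 1][0]]
    events = []
    s = None
    for i in range(n):
        if state[i] and s is None:
            s = i
        if s is not None and (i == n - 1 or not state[i + 1]):
            if state[i]:
                events.append((s, i, (i - s + 1) * dt))
                s = None
    return events


class TestBindingEvents:
    def test_scripted_single_episode(self):
        dt = 0.1
        d = np.concatenate([np.full(50, 2.0), np.full(100, 0.2), np.full(50, 2.0)])
        evs = events_from_series(d, dt)
        assert len(evs) == 1
        assert evs[0].start_frame == 50 and evs[0].end_frame == 149
        assert evs[0].duration_ns == pytest.approx(10.0)

    def test_single_frame_dip_filtered_by_dwell(self):
        d = np.full(200, 2.0)
        d[100] = 0.1
        evs = events_from_series(d, 0.1, min_dwell=1.0)
        assert evs == []

    def test_hysteresis_zone_keeps_state(self):
        # distance rises into (on, off) gap: still bound
        d = np.concatenate([np.full(30, 0.2), np.full(30, 0.4), np.full(30, 0.2)])
        evs = events_from_series(d, 0.1, min_dwell=0.0)
        assert len(evs) == 1 and evs[0].duration_ns == pytest.approx(9.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_telegraph_signals_match_reference_machine(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.choice([0.1, 0.4, 2.0], size=300, p=[0.3, 0.2, 0.5])
        evs = events_from_series(d, 0.1, on_cutoff=0.3, off_cutoff=0.5, min_dwell=0.7)
        ref = oracle_events(d, 0.1, 0.3, 0.5, 0.7)
        assert [(e.start_frame, e.end_frame) for e in evs] == [(s, e) for s, e, _ in ref]
        np.testing.assert_allclose([e.duration_ns for e in evs], [t for *_, t in ref])

    def test_equal_cutoffs_zero_dwell_is_simple_threshold(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 1, 500)
        evs = events_from_series(d, 0.1, on_cutoff=0.3, off_cutoff=0.3, min_dwell=0.0)
        below = d < 0.3
        n_runs = int(below[0]) + int((~below[:-1] & below[1:]).sum())
        assert len(evs) == n_runs
        covered = np.zeros(500, dtype=bool)
        for e in evs:
            covered[e.start_frame:e.end_frame + 1] = True
        np.testing.assert_array_equal(covered, below)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            events_from_series(np.full(100, 1.0), 0.1, on_cutoff=0.5, off_cutoff=0.3)
        with pytest.raises(AnalysisError, match="shorter than min_dwell"):
            events_from_series(np.full(5, 1.0), 0.1, min_dwell=10.0)

    def test_system_level_detection(self):
        scn = gc.ShieldScenario(seed=4, n_frames=300,
                                binding_schedule=[(3.0, 9.0), (15.0, 22.0)])
        sysm, truth = gc.gen_shielded_trajectory(scn)
        evs = gc.binding_events(sysm, "entity ligand_HA6_1", "entity receptor")
        assert len(evs) == 2
        np.testing.assert_allclose(
            [e.duration_ns for e in evs], truth.schedule["duration_ns"], atol=1e-9
        )
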