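import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memglyco.contacts import (ContactSeries, SwitchingParams, classify_bound,
                               contact_value, per_side_series, switch)
from memglyco.errors import SelectionError
from memglyco.model_io import AtomSelection, Frame, Topology, Trajectory

PARAMS = SwitchingParams()  # r0=5, n=8, m=16


def _frame_topology(coords):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    top = Topology(
        names=np.array(["C"] * n), elements=np.array(["C"] * n),
        res_ids=np.arange(1, n + 1), res_names=np.array(["ALA"] * n),
        chain_ids=np.array(["P"] * n), hetero=np.zeros(n, dtype=bool))
    return top, Frame(coordinates=coords)


def brute_force_contact(coords_a, coords_b, params, box=None):
    """Independent O(N^2) double loop with explicit per-pair switch calls."""
    total = 0.0
    for a in coords_a:
        for b in coords_b:
            d = np.asarray(a) - np.asarray(b)
            if box is not None:
                d = d - box * np.round(d / box)
            r = float(np.sqrt((d ** 2).sum()))
            x = r / params.r0
            if abs(x - 1.0) < 1e-12:
                total += params.n / params.m
            else:
                total += (1 - x ** params.n) / (1 - x ** params.m)
    return total


class TestSwitch:
    def test_contact_limit(self):
        assert switch(0.0, PARAMS) == 1.0

    def test_removable_singularity_at_r0(self):
        # both-sided limit: values straddling r0 converge to n/m
        assert switch(5.0, PARAMS) == pytest.approx(0.5)
        assert switch(5.0 - 1e-7, PARAMS) == pytest.approx(0.5, abs=1e-6)
        assert switch(5.0 + 1e-7, PARAMS) == pytest.approx(0.5, abs=1e-6)

    def test_closed_form_at_two_r0(self):
        expected = (1 - 2 ** 8) / (1 - 2 ** 16)
        assert switch(10.0, PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            switch(-0.1, PARAMS)

    @given(st.floats(0, 40), st.floats(0, 40))
    @settings(max_examples=200, deadline=None)
    def test_monotone_decreasing(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert switch(lo, PARAMS) >= switch(hi, PARAMS)
        # strict decrease wherever (r/r0)^n is resolvable in float
        if lo > 0.5 and hi - lo > 1e-9:
            assert switch(lo, PARAMS) > switch(hi, PARAMS)

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            SwitchingParams(r0=-1)
        with pytest.raises(ValueError):
            SwitchingParams(n=16, m=8)
        with pytest.raises(ValueError):
            SwitchingParams(n=7, m=16)


class TestContactValue:
    def test_single_pair_at_r0(self):
        top, frame = _frame_topology([[0, 0, 0], [5.0, 0, 0]])
        s = contact_value(frame, AtomSelection("a", [0]),
                          AtomSelection("b", [1]), PARAMS)
        assert s == pytest.approx(0.5)

    def test_far_field_decay(self, rng):
        coords_a = rng.uniform(0, 5, (5, 3))
        coords_b = coords_a + np.array([200.0, 0, 0]) + rng.uniform(0, 5, (5, 3))
        top, frame = _frame_topology(np.vstack([coords_a, coords_b]))
        s = contact_value(frame, AtomSelection("a", range(5)),
                          AtomSelection("b", range(5, 10)), PARAMS)
        assert s < 1e-9

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(100):
            coords = rng.uniform(0, 40, (70, 3))
            top, frame = _frame_topology(coords)
            sel_a = AtomSelection("a", range(20))
            sel_b = AtomSelection("b", range(20, 70))
            s = contact_value(frame, sel_a, sel_b, PARAMS,
                              normalization="raw-sum")
            ref = brute_force_contact(coords[:20], coords[20:], PARAMS)
            assert s == pytest.approx(ref, rel=1e-10, abs=1e-12)

    def test_minimum_image_with_box(self):
        box = np.array([20.0, 20.0, 20.0])
        coords = np.array([[1.0, 0, 0], [19.0, 0, 0]])  # 2 A apart via image
        top, _ = _frame_topology(coords)
        frame = Frame(coordinates=coords, box=box)
        s = contact_value(frame, AtomSelection("a", [0]),
                          AtomSelection("b", [1]), PARAMS, "raw-sum")
        assert s == pytest.approx(switch(2.0, PARAMS))

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        coords = rng.uniform(0, 20, (30, 3))
        top, frame = _frame_topology(coords)
        a, b = AtomSelection("a", range(10)), AtomSelection("b", range(10, 30))
        s0 = contact_value(frame, a, b, PARAMS)
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 11.0])
        s1 = contact_value(Frame(coordinates=moved), a, b, PARAMS)
        assert s1 == pytest.approx(s0, rel=1e-10)

    def test_additivity_over_disjoint_targets(self, rng):
        coords = rng.uniform(0, 15, (30, 3))
        top, frame = _frame_topology(coords)
        a = AtomSelection("a", range(10))
        b1 = AtomSelection("b1", range(10, 20))
        b2 = AtomSelection("b2", range(20, 30))
        b = AtomSelection("b", range(10, 30))
        total = contact_value(frame, a, b, PARAMS, "raw-sum")
        parts = (contact_value(frame, a, b1, PARAMS, "raw-sum")
                 + contact_value(frame, a, b2, PARAMS, "raw-sum"))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_overlapping_or_empty_selections_rejected(self):
        top, frame = _frame_topology([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(SelectionError):
            contact_value(frame, AtomSelection("a", [0]),
                          AtomSelection("b", [0, 1]), PARAMS)
        with pytest.raises(SelectionError):
            contact_value(frame, AtomSelection("a", []),
                          AtomSelection("b", [1]), PARAMS)


class TestPerSideSeries:
    def _fixture(self):
        # Side1 atoms within r0 of the phosphates, Side2 >= 4 r0 away
        coords = np.array([
            [0.0, 0, 3.0], [4.0, 0, 3.0],       # side1
            [0.0, 0, 25.0], [4.0, 0, 25.0],     # side2
            [0.0, 0, 0.0], [4.0, 0, 0.0],       # phosphates
        ])
        top, frame = _frame_topology(coords)
        traj = Trajectory(topology=top, frames=[frame] * 6)
        side1 = AtomSelection("Side1", [0, 1])
        side2 = AtomSelection("Side2", [2, 3])
        phos = AtomSelection("P", [4, 5])
        return traj, side1, side2, phos

    def test_side1_bound_fixture_dominates(self):
        traj, side1, side2, phos = self._fixture()
        s1, s2 = per_side_series(traj, side1, side2, phos, PARAMS)
        assert s1.mean() > 10 * s2.mean()

    def test_fully_unbound_fixture(self):
        traj, side1, side2, phos = self._fixture()
        far = [Frame(coordinates=f.coordinates + np.array([0, 0, 200.0]))
               for f in traj.frames]
        # move the peptide away but keep the phosphates
        for f, orig in zip(far, traj.frames):
            f.coordinates[4:] = orig.coordinates[4:]
        traj2 = Trajectory(topology=traj.topology, frames=far)
        s1, s2 = per_side_series(traj2, side1, side2, phos, PARAMS)
        assert (s1.values < 1e-6).all() and (s2.values < 1e-6).all()

    def test_mask_bookkeeping(self):
        traj, side1, side2, phos = self._fixture()
        mask = np.array([True, False, True, False, True, False])
        s1, _ = per_side_series(traj, side1, side2, phos, PARAMS, excluded=mask)
        assert len(s1.retained) == 3
        assert s1.n_frames == 6

    def test_overlapping_sides_rejected(self):
        traj, side1, _, phos = self._fixture()
        with pytest.raises(SelectionError):
            per_side_series(traj, side1, side1, phos, PARAMS)


class TestClassifyBound:
    def test_strict_threshold(self):
        series = ContactSeries("Side1", [0.2, 0.6, 0.5, 0.9], PARAMS,
                               "per-group-atom", np.zeros(4, dtype=bool))
        mask, frac = classify_bound(series)
        assert mask.tolist() == [False, True, False, True]
        assert frac == pytest.approx(0.5)

    def test_all_zero_series(self):
        series = ContactSeries("Side1", np.zeros(10), PARAMS,
                               "per-group-atom", np.zeros(10, dtype=bool))
        _, frac = classify_bound(series)
        assert frac == 0.0

    def test_excluded_frames_never_bound(self):
        excl = np.array([False, True, False])
        series = ContactSeries("Side1", [0.9, 0.9, 0.9], PARAMS,
                               "per-group-atom", excl)
        mask, frac = classify_bound(series)
        assert mask.tolist() == [True, False, True]
        assert frac == pytest.approx(1.0)  # over the 2 retained frames

    def test_two_state_recovery(self, rng):
        # well-separated s distributions with margin >= 0.3 around 0.5
        truth = rng.random(400) < 0.4
        values = np.where(truth, rng.uniform(0.85, 2.0, 400),
                          rng.uniform(0.0, 0.15, 400))
        series = ContactSeries("Side1", values, PARAMS, "per-group-atom",
                               np.zeros(400, dtype=bool))
        mask, _ = classify_bound(series)
        assert (mask == truth).mean() >= 0.99
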