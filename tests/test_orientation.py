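import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtilt.io import AtomSelection, Frame, Topology, Trajectory
from memtilt.orientation import (DegenerateGeometryError, TiltVectors,
                                 angle_distribution, compute_tilt_vectors,
                                 tilt_angles, tilt_series)
from memtilt.synthetic import (DimerFixtureSpec, TiltSegment,
                               gen_dimer_trajectory)


def _marker_frame(coords, box=(10.0, 10.0, 10.0)):
    """Frame with 4 marker atoms: proximal, distal, monomer A, monomer B."""
    n = len(coords)
    topo = Topology(names=np.array(["M"] * n), resnames=np.array(["X"] * n),
                    resids=np.arange(1, n + 1), segids=np.array([""] * n))
    frame = Frame(coords=np.asarray(coords, dtype=float),
                  box=np.asarray(box, dtype=float))
    sels = [AtomSelection(str(i), np.array([i])) for i in range(n)]
    return frame, sels


UPRIGHT = [[0, 0, 0], [0, 0, 5], [-1, 0, 2.5], [1, 0, 2.5]]


class TestTiltVectors:
    def test_upright_geometry(self):
        frame, (p, d, a, b) = _marker_frame(UPRIGHT)
        v = compute_tilt_vectors(frame, p, d, a, b)
        np.testing.assert_allclose(v.v1, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(v.v2, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(v.v3, [0, 1, 0], atol=1e-12)

    def test_rotated_geometry_matches_independent_rotation(self):
        # oracle: the same rotation applied to the expected vectors directly
        th = np.radians(30.0)
        rot = np.array([[np.cos(th), 0, np.sin(th)],
                        [0, 1, 0],
                        [-np.sin(th), 0, np.cos(th)]])
        coords = np.asarray(UPRIGHT, dtype=float) @ rot.T
        frame, (p, d, a, b) = _marker_frame(coords)
        v = compute_tilt_vectors(frame, p, d, a, b)
        np.testing.assert_allclose(v.v1, rot @ [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(v.v2, rot @ [1, 0, 0], atol=1e-9)

    def test_orthonormality_invariants(self):
        frame, (p, d, a, b) = _marker_frame(
            [[0.3, -0.2, 0.1], [1.1, 0.9, 4.2], [-1, 0.5, 2], [1.4, 0.1, 2.2]])
        v = compute_tilt_vectors(frame, p, d, a, b)
        for vec in (v.v1, v.v2, v.v3):
            assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-9)
        assert abs(np.dot(v.v1, v.v2)) < 1e-9
        np.testing.assert_allclose(v.v3, np.cross(v.v1, v.v2), atol=1e-9)

    def test_coincident_centroids_raise(self):
        frame, (p, d, a, b) = _marker_frame(
            [[0, 0, 0], [0, 0, 0], [-1, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            compute_tilt_vectors(frame, p, d, a, b)


class TestTiltAngles:
    def _angles(self, u, ref=(1.0, 0.0, 0.0)):
        u = np.asarray(u, dtype=float)
        u = u / np.linalg.norm(u)
        v2 = np.asarray(ref, dtype=float)
        vecs = TiltVectors(v1=u, v2=v2, v3=np.cross(u, v2))
        return tilt_angles(vecs, lateral_ref=ref)

    def test_upright_is_zero(self):
        a = self._angles([0, 0, 1])
        assert (a.overall, a.lateral, a.forward) == (0.0, 0.0, 0.0)

    def test_pure_lateral_30(self):
        a = self._angles([np.sin(np.radians(30)), 0, np.cos(np.radians(30))])
        assert a.overall == pytest.approx(30.0, abs=1e-9)
        assert a.lateral == pytest.approx(30.0, abs=1e-9)
        assert a.forward == pytest.approx(0.0, abs=1e-9)

    def test_mixed_closed_form(self):
        # independent closed form: u = (0.5, 0.5, 1)/|.|
        a = self._angles([0.5, 0.5, 1.0])
        assert a.overall == pytest.approx(np.degrees(np.arccos(1 / np.sqrt(1.5))),
                                          abs=1e-6)
        assert a.overall == pytest.approx(35.264, abs=1e-3)
        assert a.lateral == pytest.approx(26.565, abs=1e-3)
        assert a.forward == pytest.approx(26.565, abs=1e-3)
        t2 = np.tan(np.radians(a.overall)) ** 2
        assert t2 == pytest.approx(np.tan(np.radians(a.lateral)) ** 2
                                   + np.tan(np.radians(a.forward)) ** 2,
                                   rel=1e-9)

    def test_in_plane_saturation(self):
        a = self._angles([1, 0, 0])
        assert a.overall == 90.0
        assert a.saturated
        assert abs(a.lateral) == 90.0

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(
        st.floats(-1, 1), st.floats(-1, 1), st.floats(0.05, 1)))
    def test_tan_squared_identity(self, u):
        a = self._angles(np.asarray(u))
        t_o = np.tan(np.radians(a.overall)) ** 2
        t_lf = (np.tan(np.radians(a.lateral)) ** 2
                + np.tan(np.radians(a.forward)) ** 2)
        assert t_o == pytest.approx(t_lf, rel=1e-6, abs=1e-12)


class TestTiltSeries:
    def test_noise_free_upright_is_zero(self):
        spec = DimerFixtureSpec(n_frames=10,
                                schedule=[TiltSegment(0, 10, 0.0)],
                                noise_deg=0.0, seed=0)
        traj, _, sels = gen_dimer_trajectory(spec)
        ts = tilt_series(traj, sels["proximal"], sels["distal"],
                         sels["monomer_a"], sels["monomer_b"])
        np.testing.assert_allclose(ts.overall, 0.0, atol=1e-6)

    def test_constant_schedule_recovery(self, tilted_dimer):
        traj, truth, sels = tilted_dimer
        ts = tilt_series(traj, sels["proximal"], sels["distal"],
                         sels["monomer_a"], sels["monomer_b"])
        # 33 deg schedule, sigma = 2 deg, 100 frames -> 3 sigma/sqrt(n) = 0.6
        assert abs(ts.overall.mean() - 33.0) < 0.6
        np.testing.assert_allclose(ts.overall, truth["overall_deg"], atol=1e-8)
        np.testing.assert_allclose(ts.forward, truth["forward_deg"], atol=1e-8)

    def test_two_segment_schedule(self):
        spec = DimerFixtureSpec(
            n_frames=100,
            schedule=[TiltSegment(0, 50, 15.0), TiltSegment(50, 100, 57.0)],
            noise_deg=2.0, seed=3)
        traj, _, sels = gen_dimer_trajectory(spec)
        ts = tilt_series(traj, sels["proximal"], sels["distal"],
                         sels["monomer_a"], sels["monomer_b"])
        assert abs(ts.overall[:50].mean() - 15.0) < 3 * 2.0 / np.sqrt(50)
        assert abs(ts.overall[50:].mean() - 57.0) < 3 * 2.0 / np.sqrt(50)

    def test_rotation_about_normal_leaves_overall_unchanged(self, tilted_dimer):
        traj, _, sels = tilted_dimer
        base = tilt_series(traj, sels["proximal"], sels["distal"],
                           sels["monomer_a"], sels["monomer_b"])
        ang = np.radians(73.0)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0],
                        [0, 0, 1]])
        frames = [Frame(coords=f.coords @ rot.T, box=f.box, time=f.time)
                  for f in traj]
        rotated = Trajectory(topology=traj.topology, frames=frames)
        ts = tilt_series(rotated, sels["proximal"], sels["distal"],
                         sels["monomer_a"], sels["monomer_b"])
        np.testing.assert_allclose(ts.overall, base.overall, atol=1e-9)


class TestAngleDistribution:
    def _const_series(self, value, n=40, label=""):
        from memtilt.orientation import TiltSeries
        arr = np.full(n, float(value))
        return TiltSeries(times=np.arange(n, dtype=float), overall=arr,
                          lateral=arr, forward=arr, label=label)

    def test_constant_series_single_unit_bin(self):
        h = angle_distribution([self._const_series(30.0)], bin_width=1.0)
        assert h.density.sum() * 1.0 == pytest.approx(1.0, abs=1e-9)
        assert h.density.max() == pytest.approx(1.0, abs=1e-9)

    def test_normalization(self, tilted_dimer):
        traj, _, sels = tilted_dimer
        ts = tilt_series(traj, sels["proximal"], sels["distal"],
                         sels["monomer_a"], sels["monomer_b"])
        h = angle_distribution([ts], window=0.5, bin_width=1.0)
        widths = np.diff(h.edges)
        assert (h.density * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_delta_runs_average_to_half(self):
        h = angle_distribution(
            [self._const_series(20.0), self._const_series(40.0)],
            bin_width=1.0)
        nonzero = h.density[h.density > 0]
        assert len(nonzero) == 2
        np.testing.assert_allclose(nonzero, 0.5, atol=1e-9)

    def test_run_permutation_invariance(self):
        runs = [self._const_series(v, n=30 + 5 * i)
                for i, v in enumerate((18.0, 25.0, 33.0))]
        h1 = angle_distribution(runs, bin_width=1.0)
        h2 = angle_distribution(runs[::-1], bin_width=1.0)
        np.testing.assert_allclose(h1.density, h2.density, atol=1e-12)
        np.testing.assert_allclose(h1.edges, h2.edges)
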