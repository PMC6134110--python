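import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtilt.contacts import (ContactConfig, brute_force_count, contact_series,
                              count_contacts, membrane_contact_series)
from memtilt.io import AtomSelection, Frame
from memtilt.synthetic import (DimerFixtureSpec, TiltSegment,
                               gen_dimer_trajectory)


class TestSinglePairs:
    def test_below_cutoff(self, single_atom_frame_factory):
        frame, a, b = single_atom_frame_factory([0, 0, 0], [0, 0, 0.5])
        assert count_contacts(frame, a, b) == 1

    def test_above_cutoff(self, single_atom_frame_factory):
        frame, a, b = single_atom_frame_factory([0, 0, 0], [0, 0, 0.7])
        assert count_contacts(frame, a, b) == 0

    def test_exact_cutoff_tie_counts(self, single_atom_frame_factory):
        frame, a, b = single_atom_frame_factory([0, 0, 0], [0, 0, 0.6])
        assert count_contacts(frame, a, b) == 1  # closed interval

    def test_minimum_image(self, single_atom_frame_factory):
        frame, a, b = single_atom_frame_factory([0.05, 0, 0], [4.95, 0, 0])
        assert count_contacts(frame, a, b) == 1
        assert count_contacts(
            frame, a, b, ContactConfig(periodic=False)) == 0

    def test_overlapping_selections_rejected(self, single_atom_frame_factory):
        frame, a, _ = single_atom_frame_factory([0, 0, 0], [1, 1, 1])
        with pytest.raises(ValueError, match="overlap"):
            count_contacts(frame, a, a)

    def test_cutoff_violating_minimum_image_rejected(self,
                                                     single_atom_frame_factory):
        frame, a, b = single_atom_frame_factory([0, 0, 0], [1, 1, 1],
                                                box=(1.0, 5.0, 5.0))
        with pytest.raises(ValueError, match="minimum-image"):
            count_contacts(frame, a, b)


class TestOracleEquivalence:
    def _random_frame(self, rng, box=(6.0, 6.0, 6.0), n=200, spread=1.5):
        # spread > box exercises wrapping of out-of-box coordinates
        coords = rng.uniform(-spread, spread, (2 * n, 3)) + np.asarray(box) / 2
        frame = Frame(coords=coords, box=np.asarray(box))
        return (frame, AtomSelection("a", np.arange(n)),
                AtomSelection("b", np.arange(n, 2 * n)))

    def test_cell_list_equals_brute_force_on_100_configs(self):
        rng = np.random.default_rng(1234)
        for trial in range(100):
            frame, a, b = self._random_frame(rng, spread=rng.uniform(1.0, 4.0))
            assert count_contacts(frame, a, b) == brute_force_count(frame, a, b)

    def test_against_kdtree_oracle(self):
        """Second independent route: periodic cKDTree pair counting."""
        from scipy.spatial import cKDTree
        rng = np.random.default_rng(7)
        box = np.array([6.0, 6.0, 6.0])
        for _ in range(10):
            frame, a, b = self._random_frame(rng)
            pa = np.mod(frame.coords[a.indices], box)
            pb = np.mod(frame.coords[b.indices], box)
            t_a = cKDTree(pa, boxsize=box)
            t_b = cKDTree(pb, boxsize=box)
            expected = t_a.count_neighbors(t_b, r=0.6)
            assert count_contacts(frame, a, b) == expected

    def test_aperiodic_cell_list_equals_brute_force(self):
        rng = np.random.default_rng(55)
        cfg = ContactConfig(periodic=False)
        for _ in range(20):
            frame, a, b = self._random_frame(rng)
            assert (count_contacts(frame, a, b, cfg)
                    == brute_force_count(frame, a, b, cfg))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.2, 1.4))
    def test_property_equivalence_any_seed_and_cutoff(self, seed, cutoff):
        rng = np.random.default_rng(seed)
        frame, a, b = self._random_frame(rng, n=60)
        cfg = ContactConfig(cutoff=cutoff)
        assert (count_contacts(frame, a, b, cfg)
                == brute_force_count(frame, a, b, cfg))


class TestInvariances:
    def _frame(self, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 6, (300, 3))
        frame = Frame(coords=coords, box=np.array([6.0, 6.0, 6.0]))
        return (frame, AtomSelection("a", np.arange(150)),
                AtomSelection("b", np.arange(150, 300)))

    def test_symmetry(self):
        frame, a, b = self._frame()
        assert count_contacts(frame, a, b) == count_contacts(frame, b, a)

    def test_translation_invariance(self):
        frame, a, b = self._frame(3)
        base = count_contacts(frame, a, b)
        shifted = Frame(coords=frame.coords + np.array([1.7, -2.3, 4.1]),
                        box=frame.box)
        assert count_contacts(shifted, a, b) == base

    def test_cutoff_monotonicity(self):
        frame, a, b = self._frame(5)
        counts = [count_contacts(frame, a, b, ContactConfig(cutoff=c))
                  for c in (0.2, 0.4, 0.6, 0.9, 1.2)]
        assert counts == sorted(counts)


class TestEngineeredFixtures:
    @pytest.mark.parametrize("k", [0, 5, 337])
    def test_engineered_pair_counts(self, k):
        spec = DimerFixtureSpec(n_frames=5,
                                schedule=[TiltSegment(0, 5, 33.0)],
                                noise_deg=2.0, contact_pairs=k, seed=k)
        traj, truth, sels = gen_dimer_trajectory(spec)
        series = contact_series(traj, sels["ecd_a"], sels["ecd_b"])
        assert np.all(series.counts == k)
        np.testing.assert_array_equal(series.counts,
                                      truth["n_dimer_contacts"])

    def test_separating_monomers_non_increasing(self, single_atom_frame_factory):
        from memtilt.io import Topology, Trajectory
        rng = np.random.default_rng(2)
        n = 20
        base = rng.uniform(0, 1, (n, 3))
        frames = []
        topo = Topology(names=np.array(["X"] * (2 * n)),
                        resnames=np.array(["R"] * (2 * n)),
                        resids=np.arange(1, 2 * n + 1),
                        segids=np.array(["A"] * n + ["B"] * n))
        for t in range(8):
            sep = np.array([0.15 * t, 0.0, 0.0])
            coords = np.vstack([base, base + 0.3 + sep])
            frames.append(Frame(coords=coords, box=np.array([40.0, 40.0, 40.0]),
                                time=float(t)))
        traj = Trajectory(topology=topo, frames=frames)
        series = contact_series(traj, AtomSelection("a", np.arange(n)),
                                AtomSelection("b", np.arange(n, 2 * n)),
                                ContactConfig(periodic=False))
        assert np.all(np.diff(series.counts) <= 0)
        assert series.counts[0] > series.counts[-1]

    def test_empty_selection_gives_zero_series_with_warning(self):
        spec = DimerFixtureSpec(n_frames=3, schedule=[TiltSegment(0, 3, 0.0)],
                                noise_deg=0.0, seed=0)
        traj, _, sels = gen_dimer_trajectory(spec)
        empty = AtomSelection("empty", np.array([], dtype=int))
        with pytest.warns(UserWarning, match="empty"):
            series = contact_series(traj, sels["ecd_a"], empty)
        assert np.all(series.counts == 0)


class TestMembraneContacts:
    def test_upright_dimer_clear_of_membrane(self):
        spec = DimerFixtureSpec(n_frames=5, schedule=[TiltSegment(0, 5, 0.0)],
                                noise_deg=0.0, clearance=2.0, seed=0)
        traj, _, sels = gen_dimer_trajectory(spec)
        series = membrane_contact_series(traj, sels["protein"], sels["lipids"])
        assert np.all(series.counts == 0)

    def test_engineered_membrane_pairs_recovered(self):
        spec = DimerFixtureSpec(n_frames=4, schedule=[TiltSegment(0, 4, 0.0)],
                                noise_deg=0.0, membrane_contact_pairs=7, seed=0)
        traj, truth, sels = gen_dimer_trajectory(spec)
        series = membrane_contact_series(traj, sels["protein"], sels["lipids"])
        assert np.all(series.counts == 7)
        np.testing.assert_array_equal(series.counts,
                                      truth["n_membrane_contacts"])

    def test_tilting_toward_membrane_increases_contacts(self):
        spec = DimerFixtureSpec(
            n_frames=60,
            schedule=[TiltSegment(0, 30, 0.0), TiltSegment(30, 60, 57.0)],
            noise_deg=1.0, clearance=1.2, lower_with_tilt=True, seed=9)
        traj, _, sels = gen_dimer_trajectory(spec)
        series = membrane_contact_series(traj, sels["protein"], sels["lipids"])
        assert series.counts[30:].mean() > series.counts[:30].mean()
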