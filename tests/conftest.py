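import numpy as np
import pytest

from memtilt.io import AtomSelection, Frame, Topology, Trajectory
from memtilt.synthetic import DimerFixtureSpec, TiltSegment, gen_dimer_trajectory


@pytest.fixture(scope="session")
def tilted_dimer():
    """A 100-frame rigid-dimer fixture at a 33 deg scheduled tilt, 2 deg noise."""
    spec = DimerFixtureSpec(
        n_frames=100,
        schedule=[TiltSegment(0, 100, 33.0)],
        noise_deg=2.0,
        contact_pairs=5,
        seed=11,
    )
    return gen_dimer_trajectory(spec)


@pytest.fixture()
def single_atom_frame_factory():
    """Build a frame + two single/multi-atom selections from raw coordinates."""

    def build(coords_a, coords_b, box=(5.0, 5.0, 5.0)):
        coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
        coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
        n_a, n_b = len(coords_a), len(coords_b)
        n = n_a + n_b
        topo = Topology(
            names=np.array(["X"] * n),
            resnames=np.array(["RES"] * n),
            resids=np.arange(1, n + 1),
            segids=np.array(["A"] * n_a + ["B"] * n_b),
        )
        frame = Frame(coords=np.vstack([coords_a, coords_b]),
                      box=np.asarray(box, dtype=float))
        sel_a = AtomSelection("a", np.arange(n_a))
        sel_b = AtomSelection("b", np.arange(n_a, n))
        return frame, sel_a, sel_b

    return build
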