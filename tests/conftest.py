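import numpy as np
import pytest

from k2pflex import SelectionSpec
from k2pflex.core import Frame, Trajectory
from k2pflex import synthetic as syn


@pytest.fixture(scope="session")
def reference_pair():
    """Idealised (down, up) channel conformations with default distances."""
    return syn.make_reference_pair()


@pytest.fixture(scope="session")
def transition_spec():
    return syn.TransitionSpec(noise_sd=0.0, n_frames=100, dt=1.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_transition(transition_spec):
    return syn.make_transition_trajectory(transition_spec)


@pytest.fixture
def ca_spec():
    return SelectionSpec(atom_names=["CA"])


@pytest.fixture
def simple_frame():
    """Four labelled atoms in a 20 Å box, for selection/distance tests."""
    return Frame(
        names=["CA", "CB", "CA", "P"],
        resnames=["ALA", "ALA", "GLY", "LIP"],
        resids=[1, 1, 2, 3],
        chains=["A", "A", "B", "M"],
        elements=["C", "C", "C", "P"],
        positions=np.array(
            [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 0.0, 19.0]]
        ),
        box=np.array([20.0, 20.0, 20.0]),
    )


def single_atom_frame(radius=2.0, z=0.0):
    f = Frame(
        names=["X"],
        resnames=["UNK"],
        resids=[1],
        chains=["A"],
        elements=["C"],
        positions=np.array([[0.0, 0.0, z]]),
        box=np.array([50.0, 50.0, 50.0]),
    )
    f.radii[:] = radius
    return f


def cloud_frame(rng, n, box=50.0, radius=1.7):
    """Random atom cloud used by area/contact oracle tests."""
    f = Frame(
        names=[f"A{i}" for i in range(n)],
        resnames=["UNK"] * n,
        resids=list(range(1, n + 1)),
        chains=["A"] * n,
        elements=["C"] * n,
        positions=rng.uniform(5, box - 5, size=(n, 3)),
        box=np.full(3, box),
    )
    f.radii[:] = radius
    return f


@pytest.fixture
def make_cloud():
    return cloud_frame
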