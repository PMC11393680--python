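import numpy as np
import pytest

from forcegrad.io import FixtureSpec, generate_fixture
from forcegrad.nerf import build_all_atom


@pytest.fixture
def helix8():
    """Ideal poly-alanine alpha helix, 8 residues."""
    return generate_fixture(FixtureSpec(kind="helix", n_residues=8))


@pytest.fixture
def clashed_helix8():
    """Helix with a central leucine chi1 rotated into steric conflict."""
    return generate_fixture(FixtureSpec(kind="clashed-helix", n_residues=8))


@pytest.fixture
def all20_structure():
    """Built all-atom structure containing every standard residue."""
    sample = generate_fixture(FixtureSpec(
        kind="helix", n_residues=20, sequence="ARNDCQEGHILKMFPSTWYV",
    ))
    return build_all_atom(sample, include_hydrogens=True)


def random_rigid_transform(rng: np.random.Generator):
    """A seeded proper rotation + translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-20.0, 20.0, size=3)
    return rot, shift
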