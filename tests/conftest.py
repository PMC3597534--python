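import numpy as np
import pytest

from helixpack import enm, structio, synthetic


@pytest.fixture(scope="session")
def dumbbell():
    """Default two-domain fixture with ground-truth labels (seed 0)."""
    return synthetic.make_dumbbell(seed=0)


@pytest.fixture(scope="session")
def dumbbell_modes(dumbbell):
    s, _ = dumbbell
    return enm.compute_modes(s)


@pytest.fixture(scope="session")
def helix10():
    return synthetic.make_helix(10, seed=0)


@pytest.fixture
def dimer():
    """Two Cα nodes 5 Å apart: the analytically solvable elastic network."""
    return structio.MolecularStructure(
        names=["CA", "CA"], resnames=["ALA", "ALA"], resids=[1, 2],
        chains=["A", "A"], coords=[[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])


@pytest.fixture(scope="session")
def membrane_contrast():
    """Patch with a 20% lipid-density contrast between the monomers."""
    return synthetic.make_membrane_patch(contrast_factor=0.2, seed=0)


def random_structure(rng: np.random.Generator, n: int) -> structio.MolecularStructure:
    """Connected random Cα cloud: a jittered chain with ~5 Å steps."""
    steps = rng.normal(0.0, 1.0, (n, 3))
    steps = 5.0 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.cumsum(steps, axis=0)
    return structio.MolecularStructure(
        names=["CA"] * n, resnames=["ALA"] * n, resids=np.arange(1, n + 1),
        chains=["A"] * n, coords=coords)
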