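import warnings

import numpy as np
import pytest
import biotite.structure as bst

from peldock.structures import StructureModel
from peldock.synthetic import (
    SyntheticDimerSpec,
    make_benchmark_case,
    make_helical_dimer,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def dimer_and_truth():
    """Default planted C2 helical dimer with its ground-truth record."""
    return make_helical_dimer(SyntheticDimerSpec())


@pytest.fixture(scope="session")
def benchmark():
    """End-to-end benchmark bundle (deterministic, seed 1)."""
    return make_benchmark_case(seed=1)


def _bare_residue(coords=None):
    """A single backbone residue floating in free space."""
    arr = bst.AtomArray(3)
    arr.coord = np.asarray(
        coords
        if coords is not None
        else [[-1.458, 0.0, 0.0], [0.0, 0.0, 0.0], [0.55, 1.42, 0.0]]
    )
    arr.chain_id = np.array(["A"] * 3)
    arr.res_id = np.array([1] * 3)
    arr.res_name = np.array(["ALA"] * 3)
    arr.atom_name = np.array(["N", "CA", "C"])
    arr.element = np.array(["N", "C", "C"])
    return StructureModel(arr)


@pytest.fixture
def free_residue():
    return _bare_residue()


@pytest.fixture
def caged_residue():
    """The same residue enclosed in a dense 4 A cage of heavy atoms."""
    base = _bare_residue()
    n_cage = 400
    idx = np.arange(n_cage)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * idx
    z = 1.0 - 2.0 * (idx + 0.5) / n_cage
    rad = np.sqrt(1.0 - z**2)
    sphere = 4.0 * np.column_stack([rad * np.cos(phi), rad * np.sin(phi), z])
    arr = bst.AtomArray(3 + n_cage)
    arr.coord = np.vstack([base.array.coord, sphere])
    arr.chain_id = np.array(["A"] * 3 + ["X"] * n_cage)
    arr.res_id = np.array([1] * 3 + list(range(100, 100 + n_cage)))
    arr.res_name = np.array(["ALA"] * 3 + ["CAG"] * n_cage)
    arr.atom_name = np.array(["N", "CA", "C"] + ["C"] * n_cage)
    arr.element = np.array(["N", "C", "C"] + ["C"] * n_cage)
    return StructureModel(arr)
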