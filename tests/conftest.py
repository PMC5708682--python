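import numpy as np
import pytest

from pbptraj.model_io import Atom, DomainPartition, Structure
from pbptraj.synthetic import SyntheticConfig, make_toy_protein


def make_atom(res, name="CA", pos=(0.0, 0.0, 0.0), element="C", mass=0.0, resname="ALA"):
    return Atom(residue_index=res, residue_name=resname, atom_name=name,
                element=element, position=np.asarray(pos, float), mass=mass)


def ca_chain(positions, start_res=1):
    """Structure with one CA per residue at the given positions."""
    atoms = [make_atom(start_res + i, "CA", p) for i, p in enumerate(positions)]
    return Structure(atoms, label="chain")


@pytest.fixture(scope="session")
def small_cfg():
    """A cheap 60-residue synthetic config used across tests."""
    return SyntheticConfig(n_residues=60, n_runs=1, run_length_ns=2.0,
                           noise_sigma=0.2, seed=11, label="small")


@pytest.fixture(scope="session")
def small_refs(small_cfg):
    return make_toy_protein(small_cfg)


@pytest.fixture(scope="session")
def quad_partition():
    """Four single-residue groups: domain1=1, linker1=2, linker2=3, domain2=4."""
    return DomainPartition(domain1={1}, linker1={2}, linker2={3}, domain2={4})


def quad_structure(p1, p2, p3, p4):
    return Structure([make_atom(1, "CA", p1), make_atom(2, "CA", p2),
                      make_atom(3, "CA", p3), make_atom(4, "CA", p4)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng):
    """A random proper rotation and translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


def transform_structure(structure, R, t):
    return structure.with_coords(structure.coords @ R.T + t)
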