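"""Shared fixtures: toy molecules, hidden truth potentials, datasets.

The expensive objects (reference datasets, fitted force fields, the
planted-truth search) are session-scoped so the suite pays for them
once.
"""

import numpy as np
import pytest

from aiffcsp.fitting import FitConfig, fit_extended, fit_lj1261
from aiffcsp.forcefield import ForceField, PairParameters, RigidMonomer
from aiffcsp.crystal import (CrystalStructure, Lattice, MoleculePose,
                             SpaceGroup)
from aiffcsp.oracle import (GroundTruth, evaluate_reference,
                            sample_dimer_configurations)
from aiffcsp.pipeline import default_ground_truth, fixture_monomers


@pytest.fixture(scope="session")
def diatomic():
    """Polar heteronuclear diatomic with a single shared atom type."""
    return fixture_monomers()["diatomic"]


@pytest.fixture(scope="session")
def truth_ff(diatomic):
    return default_ground_truth(diatomic).truth_ff


@pytest.fixture(scope="session")
def ground_truth(diatomic):
    return default_ground_truth(diatomic, seed=5)


@pytest.fixture(scope="session")
def dataset(diatomic, ground_truth):
    """Noiseless 500-point reference dataset for the diatomic."""
    cfgs = sample_dimer_configurations(diatomic, diatomic, 500, seed=5,
                                       R_range=(2.6, 9.0), min_contact=1.6)
    return evaluate_reference(ground_truth, cfgs)


@pytest.fixture(scope="session")
def extended_fit(dataset):
    return fit_extended(dataset, FitConfig(remediate=False))


@pytest.fixture(scope="session")
def rough_fit(dataset):
    return fit_lj1261(dataset, FitConfig(remediate=False))


@pytest.fixture(scope="session")
def p1bar_crystal(diatomic):
    """A hand-built triclinic crystal of the diatomic, Z = 2."""
    lat = Lattice.from_parameters(3.5, 4.2, 4.8, 80, 95, 100)
    pose = MoleculePose(diatomic, np.array([0.13, 0.22, 0.31]),
                        np.array([0.9, 0.2, 0.3, 0.1]))
    return CrystalStructure(lat, SpaceGroup.from_symbol("P-1"), [pose],
                            name="p1bar_toy")


@pytest.fixture(scope="session")
def planted_study():
    """Reduced-scale planted-truth CSP (shared by several deep tests)."""
    from aiffcsp.pipeline import planted_truth_study
    return planted_truth_study(seed=1, quota=20, n_points=500)


def make_ionic_crystal(symbolA, symbolB, positionsA, positionsB, a0,
                       qA=1.0, qB=-1.0):
    monA = RigidMonomer([symbolA], [[0, 0, 0]], charges=[qA], name=symbolA)
    monB = RigidMonomer([symbolB], [[0, 0, 0]], charges=[qB], name=symbolB)
    lat = Lattice.from_parameters(a0, a0, a0, 90, 90, 90)
    poses = [MoleculePose(monA, np.array(p, dtype=float)) for p in positionsA]
    poses += [MoleculePose(monB, np.array(p, dtype=float)) for p in positionsB]
    return CrystalStructure(lat, SpaceGroup.from_symbol("P1"), poses)


def zero_coulomb_ff(types):
    """12-6-1 force field with no repulsion/dispersion: bare charges."""
    ff = ForceField("lj1261")
    for t1 in types:
        for t2 in types:
            ff.set(t1, t2, PairParameters(A12=0.0, C6=0.0))
    return ff
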