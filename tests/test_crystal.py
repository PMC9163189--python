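"""Crystal model: symmetry, Ewald electrostatics, reduction, CIF."""

import numpy as np
import pytest

from aiffcsp.crystal import (CrystalStructure, Lattice, MoleculePose,
                             SpaceGroup, density, expand_symmetry,
                             lattice_energy, min_contact, niggli_parameters,
                             read_cif, reduce_cell, write_cif)
from aiffcsp.forcefield import ForceField, PairParameters, RigidMonomer
from aiffcsp.units import KC, N_AVOGADRO

from conftest import make_ionic_crystal, zero_coulomb_ff


def evjen_energy(lattice_matrix, frac_positions, charges, n_shells):
    """Independent Ewald oracle: direct neutral-shell (Evjen) summation.

    Whole unit cells are summed over an expanding cube with half weights
    on the boundary layer; the basis representatives must be chosen so
    the cell dipole vanishes (fractional coordinates may be negative),
    which makes the conditionally convergent sum converge to the
    physical (tinfoil) limit.  Returns kJ/mol per ion.
    """
    M = np.asarray(lattice_matrix, float)
    coords = np.asarray(frac_positions, float) @ M
    q = np.asarray(charges, float)
    e = 0.0
    n = n_shells
    for ia in range(-n, n + 1):
        for ib in range(-n, n + 1):
            for ic in range(-n, n + 1):
                w = 1.0
                for t in (ia, ib, ic):
                    if abs(t) == n:
                        w *= 0.5
                shift = np.array([ia, ib, ic]) @ M
                d = np.linalg.norm(coords[:, None] - coords[None] + shift,
                                   axis=-1)
                if ia == ib == ic == 0:
                    np.fill_diagonal(d, np.inf)
                e += 0.5 * w * float(np.sum(q[:, None] * q[None] / d))
    return KC * e / len(q)


class TestSymmetryExpansion:
    def test_p1_single_image(self, diatomic):
        s = CrystalStructure(Lattice.from_parameters(5, 5, 5, 90, 90, 90),
                             SpaceGroup.from_symbol("P1"),
                             [MoleculePose(diatomic, np.array([0.1, 0.2, 0.3]))])
        assert len(expand_symmetry(s)) == 1

    def test_p212121_four_images(self, diatomic):
        s = CrystalStructure(Lattice.from_parameters(6, 7, 8, 90, 90, 90),
                             SpaceGroup.from_symbol("P212121"),
                             [MoleculePose(diatomic, np.array([0.1, 0.2, 0.3]))])
        placed = expand_symmetry(s)
        assert len(placed) == 4
        assert s.Z == 4

    def test_p21c_matches_textbook_operators(self, diatomic):
        """General position orbit of P2_1/c: (x,y,z), (-x,y+1/2,-z+1/2),
        (-x,-y,-z), (x,-y+1/2,z+1/2)."""
        lat = Lattice.from_parameters(6, 7, 8, 90, 102, 90)
        x = np.array([0.11, 0.23, 0.37])
        s = CrystalStructure(lat, SpaceGroup.from_symbol("P21/c"),
                             [MoleculePose(diatomic, x)])
        placed = expand_symmetry(s)
        got = sorted(tuple(np.round(lat.frac(p.com) % 1, 6)) for p in placed)
        expected = sorted(tuple(np.round(np.array(v) % 1, 6)) for v in [
            x,
            (-x[0], x[1] + 0.5, -x[2] + 0.5),
            (-x[0], -x[1], -x[2]),
            (x[0], -x[1] + 0.5, x[2] + 0.5)])
        assert got == expected

    def test_special_position_detected(self):
        # a centrosymmetric molecule on an inversion center maps onto
        # itself under -x,-y,-z
        n2 = RigidMonomer(["N", "N"], [[0, 0, -0.55], [0, 0, 0.55]])
        s = CrystalStructure(Lattice.from_parameters(6, 7, 8, 90, 90, 90),
                             SpaceGroup.from_symbol("P-1"),
                             [MoleculePose(n2, np.zeros(3))])
        with pytest.raises(ValueError, match="special"):
            expand_symmetry(s)


class TestEwald:
    # dipole-free basis representatives (negative fractions allowed for
    # the direct sum; the Ewald side wraps them with no effect)
    _FCC0 = [(0, 0, 0), (-.5, .5, 0), (.5, 0, -.5), (0, -.5, .5)]
    _CASES = [
        ("rock-salt", 5.64,
         [(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)],
         [(.5, 0, 0), (0, .5, 0), (0, 0, .5), (.5, .5, .5)], 1.0, -1.0),
        ("zinc-blende", 5.41, _FCC0,
         [(.25, .25, .25), (.25, -.25, -.25), (-.25, .25, -.25),
          (-.25, -.25, .25)], 1.0, -1.0),
        ("fluorite", 5.46, _FCC0,
         [(sx * .25, sy * .25, sz * .25)
          for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], 2.0, -1.0),
    ]

    @pytest.mark.parametrize("name,a0,posA,posB,qA,qB", _CASES)
    def test_matches_direct_neutral_shell_sum(self, name, a0, posA, posB,
                                              qA, qB):
        s = make_ionic_crystal("Na", "Cl", posA, posB, a0, qA=qA, qB=qB)
        ff = zero_coulomb_ff(["Na", "Cl"])
        e_ewald = lattice_energy(ff, s, cutoff=15.0)
        frac = list(posA) + list(posB)
        charges = [qA] * len(posA) + [qB] * len(posB)
        # the cube-summed partial sums converge as 1/n^2; Richardson
        # extrapolation over two shell counts removes the leading term
        n1, n2 = 7, 10
        e1 = evjen_energy(s.lattice.matrix, frac, charges, n_shells=n1)
        e2 = evjen_energy(s.lattice.matrix, frac, charges, n_shells=n2)
        e_direct = (n2 ** 2 * e2 - n1 ** 2 * e1) / (n2 ** 2 - n1 ** 2)
        assert e_ewald == pytest.approx(e_direct, rel=1e-4)

    def test_rock_salt_madelung_constant(self):
        a0 = 5.6402
        s = make_ionic_crystal(
            "Na", "Cl",
            [(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)],
            [(.5, 0, 0), (0, .5, 0), (0, 0, .5), (.5, .5, .5)], a0)
        e = lattice_energy(zero_coulomb_ff(["Na", "Cl"]), s, cutoff=15.0)
        madelung = -1.747564594633
        assert e == pytest.approx(madelung * KC / (a0 / 2) / 2, rel=1e-6)

    def test_non_neutral_cell_rejected(self):
        s = make_ionic_crystal("Na", "Cl", [(0, 0, 0)], [(.5, .5, .5)],
                               5.0, qA=1.0, qB=-0.5)
        with pytest.raises(ValueError, match="neutral"):
            lattice_energy(zero_coulomb_ff(["Na", "Cl"]), s)


class TestLatticeEnergyInvariances:
    def test_isolated_molecule_zero(self, diatomic, truth_ff):
        s = CrystalStructure(Lattice.from_parameters(80, 80, 80, 90, 90, 90),
                             SpaceGroup.from_symbol("P1"),
                             [MoleculePose(diatomic, np.array([0.5, 0.5, 0.5]))])
        # the residual is the real dipole-lattice Coulomb energy at 80 A
        assert abs(lattice_energy(truth_ff, s, cutoff=15.0)) < 2e-3
        neutral = RigidMonomer(list(diatomic.elements), diatomic.coords,
                               types=list(diatomic.types))
        s0 = CrystalStructure(s.lattice, s.space_group,
                              [MoleculePose(neutral, np.array([0.5, 0.5, 0.5]))])
        assert abs(lattice_energy(truth_ff, s0, cutoff=15.0)) < 1e-12

    def test_supercell_invariance(self, p1bar_crystal, truth_ff):
        e1 = lattice_energy(truth_ff, p1bar_crystal, cutoff=15.0)
        placed = expand_symmetry(p1bar_crystal)
        lat = p1bar_crystal.lattice
        lat2 = Lattice(np.vstack([2 * lat.matrix[0], lat.matrix[1],
                                  lat.matrix[2]]))
        poses = []
        for shift in (0.0, 0.5):
            for p in placed:
                com_f = lat2.frac(p.com)
                com_f[0] += shift
                R = _placed_rotation(p, p1bar_crystal)
                from aiffcsp.crystal import matrix_to_quat
                improper = np.linalg.det(R) < 0
                poses.append(MoleculePose(
                    p.monomer, com_f,
                    matrix_to_quat(-R if improper else R), improper))
        s2 = CrystalStructure(lat2, SpaceGroup.from_symbol("P1"), poses)
        e2 = lattice_energy(truth_ff, s2, cutoff=15.0)
        assert e2 == pytest.approx(e1, abs=1e-6)

    def test_rigid_rotation_invariance(self, p1bar_crystal, truth_ff):
        from aiffcsp.crystal import matrix_to_quat, quat_to_matrix
        from aiffcsp.oracle import _random_rotation
        e1 = lattice_energy(truth_ff, p1bar_crystal, cutoff=15.0)
        Q = _random_rotation(np.random.default_rng(3))
        lat2 = Lattice(p1bar_crystal.lattice.matrix @ Q.T)
        poses = []
        for pose in p1bar_crystal.asymmetric_unit:
            R2 = Q @ pose.rotation
            improper = np.linalg.det(R2) < 0
            poses.append(MoleculePose(pose.monomer, pose.frac_com.copy(),
                                      matrix_to_quat(-R2 if improper else R2),
                                      improper))
        s2 = CrystalStructure(lat2, p1bar_crystal.space_group, poses)
        assert lattice_energy(truth_ff, s2, cutoff=15.0) == \
            pytest.approx(e1, abs=1e-6)

    def test_origin_shift_invariance(self, p1bar_crystal, truth_ff):
        e1 = lattice_energy(truth_ff, p1bar_crystal, cutoff=15.0)
        s2 = p1bar_crystal.copy()
        # P-1 allows any origin among the inversion centers; a lattice
        # translation of the asymmetric unit must leave the energy alone
        s2.asymmetric_unit[0].frac_com = \
            s2.asymmetric_unit[0].frac_com + np.array([1.0, -1.0, 1.0])
        assert lattice_energy(truth_ff, s2, cutoff=15.0) == \
            pytest.approx(e1, abs=1e-6)

    def test_cutoff_convergence(self, diatomic, truth_ff, p1bar_crystal):
        """Dispersion truncation: modest cutoff growth changes little."""
        e15 = lattice_energy(truth_ff, p1bar_crystal, cutoff=15.0)
        e25 = lattice_energy(truth_ff, p1bar_crystal, cutoff=25.0)
        assert abs(e25 - e15) < 0.15


def _placed_rotation(p, s):
    pose = s.asymmetric_unit[p.asym_index]
    M = s.lattice.matrix
    R = s.space_group.rotations[p.op_index]
    Rc = M.T @ R @ s.lattice.inverse.T
    return Rc @ pose.rotation


class TestGeometryHelpers:
    def test_density_hand_arithmetic(self):
        water_like = RigidMonomer(["O", "H", "H"],
                                  [[0, 0, 0], [0.96, 0, 0],
                                   [-0.24, 0.93, 0]])
        s = CrystalStructure(Lattice.from_parameters(10, 10, 10, 90, 90, 90),
                             SpaceGroup.from_symbol("P1"),
                             [MoleculePose(water_like, np.array([0.5, 0.5, 0.5]))])
        expected = 18.015 / (N_AVOGADRO * 1e-21)
        assert density(s) == pytest.approx(expected, rel=1e-3)

    def test_density_scalings(self, p1bar_crystal):
        rho = density(p1bar_crystal)
        s2 = p1bar_crystal.copy()
        s2.lattice = Lattice(2.0 * p1bar_crystal.lattice.matrix)
        assert density(s2) == pytest.approx(rho / 8, rel=1e-12)

    def test_min_contact_brute_force(self, p1bar_crystal):
        mc = min_contact(p1bar_crystal)
        placed = expand_symmetry(p1bar_crystal)
        coords = np.concatenate([p.coords for p in placed])
        molid = np.concatenate([np.full(p.monomer.n_atoms, i)
                                for i, p in enumerate(placed)])
        best = np.inf
        M = p1bar_crystal.lattice.matrix
        for ia in range(-3, 4):
            for ib in range(-3, 4):
                for ic in range(-3, 4):
                    shift = np.array([ia, ib, ic]) @ M
                    for i in range(len(coords)):
                        for j in range(len(coords)):
                            if ia == ib == ic == 0 and molid[i] == molid[j]:
                                continue
                            best = min(best, float(np.linalg.norm(
                                coords[i] - coords[j] + shift)))
        assert mc == pytest.approx(best, abs=1e-10)

    def test_reduce_cell(self, p1bar_crystal):
        red = reduce_cell(p1bar_crystal)
        assert red.lattice.volume == pytest.approx(
            p1bar_crystal.lattice.volume, rel=1e-9)
        # a cell already reduced keeps its parameters
        p1 = niggli_parameters(red)
        assert np.allclose(sorted(p1[:3]), sorted(red.lattice.parameters[:3]),
                           atol=1e-6)
        # a sheared description reduces to the same canonical parameters
        M = p1bar_crystal.lattice.matrix
        sheared = p1bar_crystal.copy()
        sheared.lattice = Lattice(np.vstack([M[0] + M[1], M[1], M[2]]))
        assert np.allclose(niggli_parameters(sheared),
                           niggli_parameters(p1bar_crystal), atol=1e-6)


class TestCifIO:
    def test_round_trip(self, p1bar_crystal, diatomic, tmp_path):
        path = tmp_path / "s.cif"
        write_cif(p1bar_crystal, path)
        back = read_cif(path, monomer=diatomic)
        assert back.Z == p1bar_crystal.Z
        assert np.allclose(back.lattice.parameters,
                           p1bar_crystal.lattice.parameters, atol=1e-6)
        orig = {tuple(np.round(c, 5)) for p in expand_symmetry(p1bar_crystal)
                for c in p.coords}
        new = {tuple(np.round(c, 5)) for p in expand_symmetry(back)
               for c in p.coords}
        for c in orig:
            assert any(np.allclose(c, n, atol=1e-4) for n in new)

    def test_non_standard_setting_via_operator_list(self, diatomic, tmp_path):
        """P2_1/n operators are honored without a standard-setting pass."""
        ops = ["x,y,z", "-x+1/2,y+1/2,-z+1/2", "-x,-y,-z",
               "x+1/2,-y+1/2,z+1/2"]
        sg = SpaceGroup.from_operations("P21/n", ops,
                                        crystal_system="monoclinic")
        lat = Lattice.from_parameters(7, 8, 9, 90, 98, 90)
        s = CrystalStructure(lat, sg,
                             [MoleculePose(diatomic,
                                           np.array([0.12, 0.21, 0.33]))],
                             name="p21n")
        assert len(expand_symmetry(s)) == 4
        path = tmp_path / "p21n.cif"
        write_cif(s, path)
        back = read_cif(path, monomer=diatomic)
        assert back.Z == 4
        assert back.space_group.symbol == "P21/n"

    def test_malformed_cif_raises(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("data_x\n_cell_length_a 5.0\n")
        with pytest.raises(ValueError, match="_cell"):
            read_cif(path)
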