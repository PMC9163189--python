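"""Pair potentials: damping, analytic forms, dimer sums, I/O."""

import math

import numpy as np
import pytest

from aiffcsp.forcefield import (DimerConfiguration, ForceField,
                                PairParameters, RigidMonomer,
                                dimer_component_energies,
                                dimer_interaction_energy,
                                electrostatic_energy, load_forcefield,
                                pair_energy_exp61, pair_energy_extended,
                                pair_energy_lj1261, read_xyz, save_forcefield,
                                tang_toennies, write_xyz)
from aiffcsp.units import KC


def tt_series(n, delta, r):
    """Independent brute-force Tang-Toennies: the truncated sum itself."""
    x = delta * r
    s = sum(x ** m / math.factorial(m) for m in range(n + 1))
    return 1.0 - math.exp(-x) * s


class TestTangToennies:
    def test_limits(self):
        assert tang_toennies(6, 2.0, 0.0) == 0.0
        assert tang_toennies(6, 2.0, 1e6) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_n1(self):
        # f_1(1, 1) = 1 - 2/e
        assert tang_toennies(1, 1.0, 1.0) == pytest.approx(1 - 2 / math.e,
                                                           abs=1e-12)

    def test_against_series_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.choice([1, 6, 8]))
            delta = float(rng.uniform(0.1, 5.0))
            r = float(rng.uniform(0.0, 20.0))
            assert tang_toennies(n, delta, r) == pytest.approx(
                tt_series(n, delta, r), abs=1e-12)

    def test_bounds_and_monotonicity(self):
        r = np.linspace(0, 30, 400)
        for n in (1, 6, 8):
            f = tang_toennies(n, 1.7, r)
            assert np.all(f >= 0) and np.all(f <= 1)
            assert np.all(np.diff(f) >= -1e-14)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tang_toennies(6, -1.0, 1.0)
        with pytest.raises(ValueError):
            tang_toennies(6, 1.0, -0.5)


class TestPairEnergies:
    def test_extended_pure_exponential(self):
        p = PairParameters(alpha=0.0, beta=1.0)
        assert pair_energy_extended(p, 0.0, 0.0, 2.0) == pytest.approx(
            math.exp(-2.0), rel=1e-12)

    def test_extended_vanishes_at_infinity(self):
        p = PairParameters(alpha=9.0, beta=3.0, a1=-0.2, a2=0.02, A12=4e3,
                           C6=1e3, C8=7e3)
        assert abs(pair_energy_extended(p, 0.0, 0.0, 1e4)) < 1e-10
        # the Coulomb tail decays as 1/r
        assert abs(pair_energy_extended(p, 0.3, -0.3, 1e6)) < 1e-3

    def test_extended_term_by_term(self):
        # independent evaluation: each term summed separately with the
        # series form of the damping function
        p = PairParameters(alpha=8.5, beta=3.1, a1=-0.15, a2=0.018,
                           A12=3200.0, C6=950.0, C8=6900.0,
                           delta1=1.9, delta6=2.1, delta8=2.3)
        qa, qb, r = 0.25, -0.4, 3.5
        expected = ((1 + p.a1 * r + p.a2 * r ** 2) * math.exp(p.alpha - p.beta * r)
                    + p.A12 / r ** 12
                    - tt_series(6, p.delta6, r) * p.C6 / r ** 6
                    - tt_series(8, p.delta8, r) * p.C8 / r ** 8
                    + tt_series(1, p.delta1, r) * KC * qa * qb / r)
        assert pair_energy_extended(p, qa, qb, r) == pytest.approx(
            expected, rel=1e-12)

    def test_exp61_bare_coulomb(self):
        assert pair_energy_exp61(0.0, 1.0, 0.0, 1.0, 1.0, 1.0) == \
            pytest.approx(KC, rel=1e-12)

    def test_exp61_finite_at_tiny_r(self):
        assert pair_energy_exp61(1000.0, 3.0, 0.0, 0.0, 0.0, 1e-4) == \
            pytest.approx(1000.0, rel=1e-3)

    def test_lj_cancellation_and_minimum(self):
        assert pair_energy_lj1261(4.0, 4.0, 0.0, 0.0, 1.0) == pytest.approx(0.0)
        # minimum location by dense scan vs closed form
        A12, C6 = 3.7e5, 1100.0
        r = np.linspace(2.0, 8.0, 200001)
        e = pair_energy_lj1261(A12, C6, 0.0, 0.0, r)
        r_min_scan = r[np.argmin(e)]
        assert r_min_scan == pytest.approx((2 * A12 / C6) ** (1 / 6),
                                           abs=1e-4)

    def test_lj_approaches_zero_from_below(self):
        assert pair_energy_lj1261(4.0, 4.0, 0.0, 0.0, 50.0) < 0

    def test_domain_errors(self):
        p = PairParameters()
        for fn in (lambda: pair_energy_extended(p, 0, 0, -1.0),
                   lambda: pair_energy_exp61(1, 1, 1, 0, 0, 0.0),
                   lambda: pair_energy_lj1261(1, 1, 0, 0, -2.0)):
            with pytest.raises(ValueError):
                fn()


class TestDimerSums:
    def _brute_force(self, ff, d):
        """Second, independent double-loop evaluation."""
        total = 0.0
        A, B = d.coordsA, d.coordsB
        for i in range(d.monomerA.n_atoms):
            for j in range(d.monomerB.n_atoms):
                r = float(np.linalg.norm(A[i] - B[j]))
                p = ff.get(d.monomerA.types[i], d.monomerB.types[j])
                qa, qb = d.monomerA.charges[i], d.monomerB.charges[j]
                if ff.form == "extended":
                    total += ((1 + p.a1 * r + p.a2 * r * r)
                              * math.exp(p.alpha - p.beta * r)
                              + p.A12 / r ** 12
                              - tt_series(6, p.delta6, r) * p.C6 / r ** 6
                              - tt_series(8, p.delta8, r) * p.C8 / r ** 8
                              + tt_series(1, p.delta1, r) * KC * qa * qb / r)
                elif ff.form == "lj1261":
                    total += (p.A12 / r ** 12 - p.C6 / r ** 6
                              + KC * qa * qb / r)
        return total

    def test_single_atom_pair(self, truth_ff):
        a = RigidMonomer(["N"], [[0, 0, 0]], charges=[0.3], types=["X"])
        b = RigidMonomer(["O"], [[0, 0, 0]], charges=[-0.3], types=["X"])
        d = DimerConfiguration(a, b, tranB=np.array([0, 0, 4.0]))
        p = truth_ff.get("X", "X")
        assert dimer_interaction_energy(truth_ff, d) == pytest.approx(
            pair_energy_extended(p, 0.3, -0.3, 4.0), rel=1e-12)

    def test_rigid_motion_invariance(self, diatomic, truth_ff):
        d = DimerConfiguration(diatomic, diatomic,
                               tranB=np.array([1.0, 2.0, 3.5]))
        e1 = dimer_interaction_energy(truth_ff, d)
        shift = np.array([5.0, 5.0, 5.0])
        d2 = DimerConfiguration(diatomic, diatomic, tranA=shift,
                                tranB=d.tranB + shift)
        assert dimer_interaction_energy(truth_ff, d2) == pytest.approx(
            e1, abs=1e-10)

    def test_against_brute_force_random_dimers(self, diatomic, truth_ff):
        from aiffcsp.oracle import sample_dimer_configurations
        cfgs = sample_dimer_configurations(diatomic, diatomic, 100, seed=9,
                                           R_range=(2.5, 10.0),
                                           min_contact=1.5)
        for d in cfgs:
            e = dimer_interaction_energy(truth_ff, d)
            assert e == pytest.approx(self._brute_force(truth_ff, d),
                                      rel=1e-9, abs=1e-12)

    def test_multi_type_brute_force(self):
        """3-atom x 2-atom mixed-type dimer equals the explicit 6-term sum."""
        a = RigidMonomer(["C", "O", "H"],
                         [[0, 0, 0], [1.2, 0, 0], [-0.6, 0.9, 0]],
                         charges=[0.1, -0.3, 0.2], types=["C", "O", "H"])
        b = RigidMonomer(["O", "H"], [[0, 0, 0], [0.97, 0, 0]],
                         charges=[-0.2, 0.2], types=["O", "H"])
        ff = ForceField("lj1261")
        rng = np.random.default_rng(4)
        for t1 in ("C", "O", "H"):
            for t2 in ("C", "O", "H"):
                ff.set(t1, t2, PairParameters(A12=float(rng.uniform(1e4, 1e5)),
                                              C6=float(rng.uniform(100, 900))))
        d = DimerConfiguration(a, b, tranB=np.array([0.5, 3.4, 1.0]))
        assert dimer_interaction_energy(ff, d) == pytest.approx(
            self._brute_force(ff, d), rel=1e-12)

    def test_missing_pair_raises_with_pair_name(self, diatomic):
        ff = ForceField("extended")
        d = DimerConfiguration(diatomic, diatomic,
                               tranB=np.array([0, 0, 4.0]))
        with pytest.raises(KeyError, match="X"):
            dimer_interaction_energy(ff, d)

    def test_electrostatic_component(self, diatomic, truth_ff):
        d = DimerConfiguration(diatomic, diatomic,
                               tranB=np.array([0.8, 2.9, 1.4]))
        comp = dimer_component_energies(truth_ff, d)
        assert electrostatic_energy(truth_ff, d) == pytest.approx(
            comp["elst"], rel=1e-12)
        assert comp["total"] == pytest.approx(
            dimer_interaction_energy(truth_ff, d), rel=1e-12)
        # with zero charges the electrostatic part vanishes
        neutral = RigidMonomer(list(diatomic.elements), diatomic.coords,
                               types=list(diatomic.types))
        dn = DimerConfiguration(neutral, neutral, tranB=d.tranB)
        assert electrostatic_energy(truth_ff, dn) == 0.0

    def test_large_R_asymptotics(self, diatomic, truth_ff):
        """V(R) * R^6 approaches -sum(C6) for a neutral-neutral dimer."""
        neutral = RigidMonomer(list(diatomic.elements), diatomic.coords,
                               types=list(diatomic.types))
        R = 40.0
        # approach perpendicular to the bond so the finite molecular
        # extent perturbs the pair distances only at second order
        d = DimerConfiguration(neutral, neutral, tranB=np.array([R, 0, 0]))
        V = dimer_interaction_energy(truth_ff, d)
        C6_sum = sum(truth_ff.get(t1, t2).C6
                     for t1 in neutral.types for t2 in neutral.types)
        assert abs(V * R ** 6 + C6_sum) / C6_sum < 0.01

    def test_gradient_continuity(self, diatomic, truth_ff):
        """Finite-difference derivative is consistent across r > 0."""
        p = truth_ff.get("X", "X")
        for r in (1.0, 2.5, 3.5, 6.0):
            h = 1e-6
            g1 = (pair_energy_extended(p, 0.3, -0.3, r + h)
                  - pair_energy_extended(p, 0.3, -0.3, r - h)) / (2 * h)
            h2 = h / 4
            g2 = (pair_energy_extended(p, 0.3, -0.3, r + h2)
                  - pair_energy_extended(p, 0.3, -0.3, r - h2)) / (2 * h2)
            assert g1 == pytest.approx(g2, rel=1e-5, abs=1e-8)


class TestMonomerAndIO:
    def test_monomer_invariants(self):
        with pytest.raises(ValueError):
            RigidMonomer([], np.zeros((0, 3)))
        with pytest.raises(ValueError):
            RigidMonomer(["H", "H"], [[0, 0, 0], [0.2, 0, 0]])
        m = RigidMonomer(["N", "O"], [[0, 0, 0], [0, 0, 1.15]])
        com = m.masses @ m.coords / m.masses.sum()
        assert np.allclose(com, 0.0, atol=1e-12)

    def test_xyz_round_trip(self, diatomic, tmp_path):
        path = tmp_path / "m.xyz"
        write_xyz(diatomic, path)
        m2 = read_xyz(path)
        assert m2.elements == diatomic.elements
        assert m2.types == diatomic.types
        assert np.allclose(m2.coords, diatomic.coords)
        assert np.allclose(m2.charges, diatomic.charges)

    def test_forcefield_round_trip_exact(self, truth_ff, tmp_path):
        path = tmp_path / "ff.txt"
        save_forcefield(truth_ff, path)
        ff2 = load_forcefield(path)
        assert ff2.form == truth_ff.form
        for key, p in truth_ff.pair_table.items():
            p2 = ff2.pair_table[key]
            for nm in ("alpha", "beta", "a1", "a2", "A12", "C6", "C8",
                       "delta1", "delta6", "delta8", "A"):
                assert getattr(p, nm) == getattr(p2, nm)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PairParameters(beta=-1.0)
        with pytest.raises(ValueError):
            PairParameters(C6=-5.0)
        with pytest.raises(ValueError):
            ForceField("morse")
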