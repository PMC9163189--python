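"""Crystal data model, symmetry expansion and periodic lattice energies.

Conventions: lattice matrix rows are the lattice vectors (Angstrom);
molecular centers of mass are fractional, atom coordinates Cartesian;
orientations are scalar-first quaternions with an ``improper`` flag for
symmetry images of opposite handedness.  Lattice energies are reported
per molecule.  Charge-charge sums use Ewald summation (automatic
splitting parameter); all other terms are direct sums within a real-space
cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.special import erf, erfc, gammainc

from .forcefield import ForceField, RigidMonomer
from .units import COVALENT_RADII, KC, N_AVOGADRO

__all__ = [
    "Lattice", "SpaceGroup", "MoleculePose", "CrystalStructure",
    "RANDOM_SEARCH_GROUPS", "GRID_SEARCH_GROUPS",
    "expand_symmetry", "lattice_energy", "density", "reduce_cell",
    "min_contact", "read_cif", "write_cif", "quat_to_matrix", "matrix_to_quat",
]

# default space-group sets of the grid (27 groups) and random (13
# groups) generation strategies
RANDOM_SEARCH_GROUPS = ["C2", "C2/c", "Cc", "P1", "P-1", "P21", "P21/c",
                        "P212121", "Pbca", "Pc", "Pbcn", "Pca21", "Pna21"]
GRID_SEARCH_GROUPS = ["P1", "P-1", "P2", "Pm", "Pc", "P21", "P2/c", "P21/m",
                      "P2/m", "P21/c", "Cc", "C2", "C2/c", "Pnn2", "Pba2",
                      "Pnc2", "P2221", "Pmn21", "Pma2", "P21212", "P212121",
                      "Pca21", "Pna21", "Pnma", "Fdd2", "Pbcn", "Pbca"]


# --------------------------------------------------------------------------
# lattice

@dataclass
class Lattice:
    """Unit cell, stored as a 3x3 matrix whose rows are lattice vectors."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("lattice matrix must be 3x3")
        if self.volume <= 0:
            raise ValueError("lattice must be right-handed with positive volume")

    @classmethod
    def from_parameters(cls, a, b, c, alpha, beta, gamma) -> "Lattice":
        for x, nm in ((a, "a"), (b, "b"), (c, "c")):
            if x <= 0:
                raise ValueError(f"cell length {nm} must be > 0")
        for x, nm in ((alpha, "alpha"), (beta, "beta"), (gamma, "gamma")):
            if not 0 < x < 180:
                raise ValueError(f"cell angle {nm} must be in (0, 180) degrees")
        al, be, ga = np.radians([alpha, beta, gamma])
        cx = math.cos(be)
        cy = (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz2 = 1.0 - cx * cx - cy * cy
        if cz2 <= 0:
            raise ValueError("cell angles do not define a valid lattice")
        m = np.array([
            [a, 0.0, 0.0],
            [b * math.cos(ga), b * math.sin(ga), 0.0],
            [c * cx, c * cy, c * math.sqrt(cz2)],
        ])
        return cls(m)

    @property
    def parameters(self):
        m = self.matrix
        a, b, c = np.linalg.norm(m, axis=1)
        al = math.degrees(math.acos(np.dot(m[1], m[2]) / (b * c)))
        be = math.degrees(math.acos(np.dot(m[0], m[2]) / (a * c)))
        ga = math.degrees(math.acos(np.dot(m[0], m[1]) / (a * b)))
        return a, b, c, al, be, ga

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def heights(self) -> np.ndarray:
        """Perpendicular inter-plane distances along the three axes."""
        return 1.0 / np.linalg.norm(self.inverse, axis=0)

    def cart(self, frac) -> np.ndarray:
        return np.asarray(frac, float) @ self.matrix

    def frac(self, cart) -> np.ndarray:
        return np.asarray(cart, float) @ self.inverse


# --------------------------------------------------------------------------
# space group

@dataclass
class SpaceGroup:
    """Hermann-Mauguin symbol plus explicit (rotation, translation) operators.

    Rotations act on fractional coordinates (integer matrices); they are
    taken from the crystallographic tables via gemmi, or supplied
    explicitly for arbitrary settings.
    """

    symbol: str
    rotations: np.ndarray   # (n_ops, 3, 3)
    translations: np.ndarray  # (n_ops, 3)
    crystal_system: str = "triclinic"

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroup":
        sg = gemmi.SpaceGroup(symbol)
        ops = list(sg.operations())
        rots = np.array([np.array(op.rot) / op.DEN for op in ops])
        trans = np.array([np.array(op.tran) / op.DEN for op in ops])
        return cls(symbol=sg.hm, rotations=rots, translations=trans,
                   crystal_system=sg.crystal_system_str())

    @classmethod
    def from_operations(cls, symbol: str, triplets, crystal_system="triclinic"):
        ops = [gemmi.Op(t) for t in triplets]
        rots = np.array([np.array(op.rot) / op.DEN for op in ops])
        trans = np.array([np.array(op.tran) / op.DEN for op in ops])
        return cls(symbol=symbol, rotations=rots, translations=trans,
                   crystal_system=crystal_system)

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, float)
        self.translations = np.asarray(self.translations, float)
        # identity must be present; closure is inherited from the tables
        has_id = any(np.allclose(R, np.eye(3)) and np.allclose(t % 1, 0)
                     for R, t in zip(self.rotations, self.translations))
        if not has_id:
            raise ValueError("space-group operator list lacks the identity")


def quat_to_matrix(q) -> np.ndarray:
    """Scalar-first unit quaternion to a proper rotation matrix."""
    w, x, y, z = np.asarray(q, float) / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def matrix_to_quat(R) -> np.ndarray:
    """Proper rotation matrix to a scalar-first unit quaternion (w >= 0)."""
    R = np.asarray(R, float)
    tr = np.trace(R)
    if tr > 0:
        s = math.sqrt(tr + 1.0) * 2
        q = np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                      (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1.0 + R[i, i] - R[j, j] - R[k, k], 0.0)) * 2
        q = np.zeros(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    q = q / np.linalg.norm(q)
    return q if q[0] >= 0 else -q


@dataclass
class MoleculePose:
    """One asymmetric-unit molecule: body frame -> crystal placement.

    The Cartesian rotation is quat_to_matrix(quaternion), negated when
    ``improper`` is set (an inversion image of the body frame).
    """

    monomer: RigidMonomer
    frac_com: np.ndarray
    quaternion: np.ndarray = None
    improper: bool = False

    def __post_init__(self):
        self.frac_com = np.asarray(self.frac_com, float)
        if self.quaternion is None:
            self.quaternion = np.array([1.0, 0.0, 0.0, 0.0])
        self.quaternion = np.asarray(self.quaternion, float)
        self.quaternion = self.quaternion / np.linalg.norm(self.quaternion)

    @property
    def rotation(self) -> np.ndarray:
        R = quat_to_matrix(self.quaternion)
        return -R if self.improper else R


@dataclass
class CrystalStructure:
    lattice: Lattice
    space_group: SpaceGroup
    asymmetric_unit: list  # of MoleculePose
    name: str = "crystal"
    meta: dict = field(default_factory=dict)

    @property
    def Z(self) -> int:
        return len(self.asymmetric_unit) * self.space_group.n_ops

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            lattice=Lattice(self.lattice.matrix.copy()),
            space_group=self.space_group,
            asymmetric_unit=[replace(p, frac_com=p.frac_com.copy(),
                                     quaternion=p.quaternion.copy())
                             for p in self.asymmetric_unit],
            name=self.name, meta=dict(self.meta))


@dataclass
class PlacedMolecule:
    monomer: RigidMonomer
    coords: np.ndarray      # (n_atoms, 3) Cartesian
    com: np.ndarray         # Cartesian
    asym_index: int
    op_index: int


# --------------------------------------------------------------------------
# symmetry expansion

def expand_symmetry(s: CrystalStructure, check_special: bool = True) -> list:
    """Expand the asymmetric unit into the Z molecules of one unit cell.

    Each image is wrapped so its center of mass lies in [0, 1) fractional.
    An operator mapping a molecule onto itself (special position) raises,
    since rigid-molecule packing assumes general positions.
    """
    M = s.lattice.matrix
    Minv = s.lattice.inverse
    placed = []
    for ai, pose in enumerate(s.asymmetric_unit):
        body = pose.monomer.coords
        R0 = pose.rotation
        com_f0 = pose.frac_com
        for oi, (R, t) in enumerate(zip(s.space_group.rotations,
                                        s.space_group.translations)):
            com_f = com_f0 @ R.T + t
            shift = np.floor(com_f)
            com_f = com_f - shift
            # Cartesian action of the fractional operator
            Rc = M.T @ R @ Minv.T
            atoms = (body @ R0.T + s.lattice.cart(com_f0)) @ Rc.T \
                + s.lattice.cart(t) - s.lattice.cart(shift)
            com = s.lattice.cart(com_f)
            placed.append(PlacedMolecule(monomer=pose.monomer, coords=atoms,
                                         com=com, asym_index=ai, op_index=oi))
    if check_special:
        for i in range(len(placed)):
            for j in range(i + 1, len(placed)):
                if placed[i].asym_index != placed[j].asym_index:
                    continue
                if not np.allclose(placed[i].com, placed[j].com, atol=1e-6):
                    continue
                # compare atom sets; an operator may permute equivalent atoms
                a = np.array(sorted(map(tuple, np.round(placed[i].coords, 5))))
                b = np.array(sorted(map(tuple, np.round(placed[j].coords, 5))))
                if np.allclose(a, b, atol=1e-4):
                    raise ValueError(
                        f"molecule {placed[i].asym_index} sits on a special "
                        f"position (operators {placed[i].op_index} and "
                        f"{placed[j].op_index} coincide)")
    return placed


def _cell_arrays(s: CrystalStructure, placed=None):
    """Concatenate the expanded cell into flat atom arrays."""
    placed = placed if placed is not None else expand_symmetry(s)
    coords = np.concatenate([p.coords for p in placed])
    charges = np.concatenate([p.monomer.charges for p in placed])
    types = sum(([t for t in p.monomer.types] for p in placed), [])
    molid = np.concatenate([np.full(p.monomer.n_atoms, i)
                            for i, p in enumerate(placed)])
    return coords, charges, types, molid, placed


def _translations(lattice: Lattice, reach: float,
                  max_count: int = 30000) -> np.ndarray:
    """All lattice translations with |n_i| within the given reach.

    Degenerate sliver cells would need an unbounded image list; they are
    rejected (they always correspond to collapsed structures here).
    """
    nmax = np.ceil(reach / lattice.heights()).astype(int)
    count = np.prod(2 * nmax + 1)
    if count > max_count:
        raise ValueError(
            f"cell too thin for the requested reach ({count} images)")
    grid = np.mgrid[-nmax[0]:nmax[0] + 1, -nmax[1]:nmax[1] + 1,
                    -nmax[2]:nmax[2] + 1].reshape(3, -1).T
    return grid @ lattice.matrix


# --------------------------------------------------------------------------
# lattice energy

_GRID_FIELDS = ("alpha", "beta", "a1", "a2", "A12", "C6", "C8",
                "delta1", "delta6", "delta8", "A")


def _pair_param_grids(ff: ForceField, types):
    """(N, N) per-parameter arrays for direct vectorized evaluation."""
    unique = sorted(set(types))
    t_idx = np.array([unique.index(t) for t in types])
    nt = len(unique)
    small = {nm: np.empty((nt, nt)) for nm in _GRID_FIELDS}
    for i, ti in enumerate(unique):
        for j, tj in enumerate(unique):
            p = ff.get(ti, tj)
            for nm in _GRID_FIELDS:
                small[nm][i, j] = getattr(p, nm)
    return {nm: g[np.ix_(t_idx, t_idx)] for nm, g in small.items()}


# beyond this distance the Tang-Toennies factors are 1 (and the f1 - 1
# Ewald correction 0) to double precision for delta >= ~1.5/Angstrom
_DAMP_RANGE = 9.0


def _nc_energy_1d(form: str, P: dict, ii, jj, r) -> float:
    """Total non-Coulomb energy over gathered atom pairs at distances r."""
    C6 = P["C6"][ii, jj]
    if form == "lj1261":
        return float(np.sum(P["A12"][ii, jj] / r ** 12 - C6 / r ** 6))
    if form == "exp61":
        return float(np.sum(P["A"][ii, jj] * np.exp(-P["beta"][ii, jj] * r)
                            - C6 / r ** 6))
    C8 = P["C8"][ii, jj]
    e = -np.sum(C6 / r ** 6) - np.sum(C8 / r ** 8)
    near = r < _DAMP_RANGE
    rn, iin, jjn = r[near], ii[near], jj[near]
    rep = (1.0 + P["a1"][iin, jjn] * rn + P["a2"][iin, jjn] * rn * rn) \
        * np.exp(P["alpha"][iin, jjn] - P["beta"][iin, jjn] * rn)
    e += np.sum(rep) + np.sum(P["A12"][iin, jjn] / rn ** 12)
    # restore the damped short range: subtracting the (1 - f_n) tails
    e += np.sum((1.0 - gammainc(7, P["delta6"][iin, jjn] * rn))
                * P["C6"][iin, jjn] / rn ** 6)
    e += np.sum((1.0 - gammainc(9, P["delta8"][iin, jjn] * rn))
                * P["C8"][iin, jjn] / rn ** 8)
    return float(e)


def lattice_energy(ff: ForceField, s: CrystalStructure, cutoff: float = 15.0,
                   ewald_accuracy: float = 1e-8,
                   return_contact: bool = False):
    """Lattice energy per molecule (kJ/mol).

    Half-sum of two-body atom-atom interactions between the unit cell and
    all periodic images: repulsion and dispersion terms are summed
    directly within the cutoff; charge-charge terms use Ewald summation,
    with the short-range Tang-Toennies correction (f1 - 1) folded into the
    real-space part for the extended form.  Intramolecular pairs are
    excluded.
    """
    coords, charges, types, molid, placed = _cell_arrays(s)
    Z = len(placed)
    N = len(coords)
    dmax = 2.0 * max(p.monomer.radius() for p in placed)
    L = _translations(s.lattice, cutoff + dmax)
    home = np.all(np.abs(L) < 1e-12, axis=1)

    P = _pair_param_grids(ff, types)
    dX = coords[:, None, :] - coords[None, :, :]   # x_i - x_j
    same_mol = molid[:, None] == molid[None, :]
    qq = charges[:, None] * charges[None, :]
    has_charge = np.abs(charges).max() > 1e-12
    if has_charge and abs(charges.sum()) > 1e-8:
        raise ValueError(f"unit cell is not charge-neutral: Q = {charges.sum():.3g} e")

    alpha = 4.0 / cutoff
    e_nc = 0.0
    e_real = 0.0
    min_inter = np.inf
    # chunk over lattice translations to bound memory
    chunk = max(1, int(2e6 / (N * N)))
    with np.errstate(over="ignore", under="ignore"):
        for start in range(0, len(L), chunk):
            Lc = L[start:start + chunk]
            hc = home[start:start + chunk]
            d = np.linalg.norm(dX[None, :, :, :] + Lc[:, None, None, :], axis=-1)
            exclude = hc[:, None, None] & same_mol[None, :, :]
            within = ~exclude & (d < cutoff)
            dv = np.where(exclude, np.inf, d)
            m = float(dv.min())
            if m < min_inter:
                min_inter = m
            if not within.any():
                continue
            _, ii, jj = np.nonzero(within)
            r = d[within]
            e_nc += _nc_energy_1d(ff.form, P, ii, jj, r)
            if has_charge:
                qr = qq[ii, jj]
                e_real += float(np.sum(qr * erfc(alpha * r) / r))
                if ff.form == "extended":
                    near = r < _DAMP_RANGE
                    rn = r[near]
                    e_real += float(np.sum(
                        qr[near] * (gammainc(2, P["delta1"][ii[near], jj[near]]
                                             * rn) - 1.0) / rn))
    if min_inter < 0.3:
        raise ValueError(
            f"structure collapse: intermolecular contact {min_inter:.3f} A < 0.3 A")

    energy = 0.5 * e_nc
    if has_charge:
        e_coul = 0.5 * e_real
        # reciprocal sum
        V = s.lattice.volume
        Brows = 2 * np.pi * np.linalg.inv(s.lattice.matrix).T
        kmax = 2.0 * alpha * math.sqrt(-math.log(ewald_accuracy))
        nmax = np.ceil(kmax / (2 * np.pi / s.lattice.heights())).astype(int)
        if np.prod(2 * nmax + 1) > 2e6:
            raise ValueError(
                "cell too large for the reciprocal-space grid "
                f"({np.prod(2 * nmax + 1)} vectors)")
        grid = np.mgrid[-nmax[0]:nmax[0] + 1, -nmax[1]:nmax[1] + 1,
                        -nmax[2]:nmax[2] + 1].reshape(3, -1).T
        grid = grid[np.any(grid != 0, axis=1)]
        k = grid @ Brows
        k2 = np.einsum("ij,ij->i", k, k)
        keep = k2 <= kmax * kmax
        k, k2 = k[keep], k2[keep]
        phase = coords @ k.T  # (N, nk)
        S = (charges @ np.exp(1j * phase))
        e_recip = (2 * np.pi / V) * float(
            np.sum(np.exp(-k2 / (4 * alpha ** 2)) / k2 * np.abs(S) ** 2))
        e_self = -alpha / math.sqrt(math.pi) * float(np.sum(charges ** 2))
        # remove the smeared intramolecular contribution
        e_intra = 0.0
        for p in placed:
            if p.monomer.n_atoms < 2:
                continue
            dmat = np.linalg.norm(p.coords[:, None] - p.coords[None, :], axis=-1)
            iu = np.triu_indices(p.monomer.n_atoms, 1)
            qm = p.monomer.charges
            e_intra += float(np.sum(qm[iu[0]] * qm[iu[1]]
                                    * erf(alpha * dmat[iu]) / dmat[iu]))
        energy += KC * (e_coul + e_recip + e_self - e_intra)
    if return_contact:
        return energy / Z, min_inter
    return energy / Z


def density(s: CrystalStructure) -> float:
    """Mass density in g/cm^3."""
    mass = sum(p.monomer.molecular_mass for p in s.asymmetric_unit) \
        * s.space_group.n_ops
    return mass / (N_AVOGADRO * s.lattice.volume * 1e-24)


def min_contact(s: CrystalStructure, search_reach: float = None) -> float:
    """Shortest intermolecular atom-atom distance (Angstrom).

    Searches the home cell against all images within a reach that covers
    nearest neighbors even for elongated cells.
    """
    coords, charges, types, molid, placed = _cell_arrays(s)
    dmax = 2.0 * max(p.monomer.radius() for p in placed)
    reach = search_reach if search_reach is not None \
        else float(s.lattice.heights().max()) + dmax
    L = _translations(s.lattice, reach)
    home = np.all(np.abs(L) < 1e-12, axis=1)
    dX = coords[:, None, :] - coords[None, :, :]
    same_mol = molid[:, None] == molid[None, :]
    best = np.inf
    N = len(coords)
    chunk = max(1, int(2e6 / (N * N)))
    for start in range(0, len(L), chunk):
        Lc = L[start:start + chunk]
        hc = home[start:start + chunk]
        d = np.linalg.norm(dX[None] + Lc[:, None, None, :], axis=-1)
        d = np.where(hc[:, None, None] & same_mol[None], np.inf, d)
        best = min(best, float(d.min()))
    return best


def reduce_cell(s: CrystalStructure) -> CrystalStructure:
    """Re-express the crystal in its Niggli-reduced cell.

    The atom positions are untouched (same crystal, new basis); the
    space-group operator list does not transform with the basis, so the
    result is described in P1 with all Z molecules as the asymmetric
    unit.  Volume is preserved exactly up to round-off.
    """
    a, b, c, al, be, ga = s.lattice.parameters
    gv = gemmi.GruberVector(gemmi.UnitCell(a, b, c, al, be, ga), None, True)
    if s.lattice.volume < 1e-9:
        raise ValueError("degenerate lattice")
    gv.niggli_reduce()
    op = gv.change_of_basis
    C = np.array(op.rot, dtype=float) / op.DEN  # basis-change matrix
    new_matrix = C.T @ s.lattice.matrix
    if np.linalg.det(new_matrix) < 0:
        new_matrix = -new_matrix
    new_lat = Lattice(new_matrix)
    placed = expand_symmetry(s)
    poses = []
    for p in placed:
        com_f = new_lat.frac(p.com) % 1.0
        R0 = s.asymmetric_unit[p.asym_index].rotation
        M = s.lattice.matrix
        R = s.space_group.rotations[p.op_index]
        Rc = M.T @ R @ s.lattice.inverse.T
        Rtot = Rc @ R0
        improper = np.linalg.det(Rtot) < 0
        q = matrix_to_quat(-Rtot if improper else Rtot)
        poses.append(MoleculePose(monomer=p.monomer, frac_com=com_f,
                                  quaternion=q, improper=improper))
    return CrystalStructure(lattice=new_lat,
                            space_group=SpaceGroup.from_symbol("P1"),
                            asymmetric_unit=poses, name=s.name,
                            meta=dict(s.meta))


def niggli_parameters(s: CrystalStructure):
    """Niggli-reduced cell parameters (a, b, c, alpha, beta, gamma)."""
    a, b, c, al, be, ga = s.lattice.parameters
    gv = gemmi.GruberVector(gemmi.UnitCell(a, b, c, al, be, ga), None, True)
    gv.niggli_reduce()
    return tuple(gv.cell_parameters())


# --------------------------------------------------------------------------
# CIF I/O

def write_cif(s: CrystalStructure, path) -> None:
    """Write core CIF 1.1: cell, explicit symmetry operators, atom sites.

    Fractional coordinates of the asymmetric unit are written unwrapped
    so molecules stay contiguous for bond-based reassembly on read.
    """
    a, b, c, al, be, ga = s.lattice.parameters
    lines = [f"data_{s.name.replace(' ', '_')}",
             f"_cell_length_a {a:.8f}",
             f"_cell_length_b {b:.8f}",
             f"_cell_length_c {c:.8f}",
             f"_cell_angle_alpha {al:.8f}",
             f"_cell_angle_beta {be:.8f}",
             f"_cell_angle_gamma {ga:.8f}",
             f"_symmetry_space_group_name_H-M '{s.space_group.symbol}'",
             "loop_",
             "_symmetry_equiv_pos_as_xyz"]
    for R, t in zip(s.space_group.rotations, s.space_group.translations):
        op = gemmi.Op()
        op.rot = [[int(round(x * op.DEN)) for x in row] for row in R]
        op.tran = [int(round(x * op.DEN)) for x in t]
        lines.append(f"'{op.triplet()}'")
    lines += ["loop_", "_atom_site_label", "_atom_site_type_symbol",
              "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z",
              "_atom_site_occupancy"]
    counter = {}
    for pose in s.asymmetric_unit:
        atoms = pose.monomer.coords @ pose.rotation.T \
            + s.lattice.cart(pose.frac_com)
        fr = s.lattice.frac(atoms)
        for e, f in zip(pose.monomer.elements, fr):
            counter[e] = counter.get(e, 0) + 1
            lines.append(f"{e}{counter[e]} {e} {f[0]:.8f} {f[1]:.8f} {f[2]:.8f} 1.0")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _assemble_molecules(elements, cart):
    """Union-find bond perception by covalent radii (factor 1.3)."""
    n = len(elements)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            rij = np.linalg.norm(cart[i] - cart[j])
            rmax = 1.3 * (COVALENT_RADII.get(elements[i], 1.5)
                          + COVALENT_RADII.get(elements[j], 1.5))
            if rij < rmax:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _fit_pose(monomer: RigidMonomer, coords, masses):
    """Best rigid transform body -> coords; allows improper images."""
    com = masses @ coords / masses.sum()
    X = monomer.coords  # body frame, COM at origin
    Y = coords - com
    H = X.T @ (Y * masses[:, None])
    U, S, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    # try the improper branch too; keep whichever matches better
    D = np.diag([1.0, 1.0, -1.0])
    R2 = Vt.T @ D @ U.T
    err1 = np.linalg.norm(X @ R.T - Y)
    err2 = np.linalg.norm(X @ R2.T - Y)
    return (R, com, err1) if err1 <= err2 else (R2, com, err2)


def read_cif(path, monomer: RigidMonomer = None) -> CrystalStructure:
    """Read a CIF into a crystal of rigid molecules.

    Symmetry is taken from the listed equivalent positions when present
    (so non-standard settings work without transformation), else from the
    Hermann-Mauguin symbol.  Atom sites are reassembled into molecules by
    covalent-radius bonding; if a reference ``monomer`` is given, each
    molecule's pose is fitted to its body frame (restoring charges and
    atom types), otherwise a neutral monomer is built from the first
    molecule found.
    """
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    def need(tag):
        v = block.find_value(tag)
        if v is None:
            raise ValueError(f"CIF {path} lacks {tag}")
        return float(v)

    lat = Lattice.from_parameters(
        need("_cell_length_a"), need("_cell_length_b"), need("_cell_length_c"),
        need("_cell_angle_alpha"), need("_cell_angle_beta"),
        need("_cell_angle_gamma"))
    triplets = [row.str(0) for row in block.find(
        ["_symmetry_equiv_pos_as_xyz"])]
    if not triplets:
        triplets = [row.str(0) for row in block.find(
            ["_space_group_symop_operation_xyz"])]
    symbol = block.find_value("_symmetry_space_group_name_H-M")
    symbol = symbol.strip("'\"") if symbol else "P1"
    if triplets:
        try:
            cs = gemmi.SpaceGroup(symbol).crystal_system_str()
        except Exception:
            cs = "triclinic"
        sg = SpaceGroup.from_operations(symbol, triplets, crystal_system=cs)
    else:
        sg = SpaceGroup.from_symbol(symbol)
    tab = block.find(["_atom_site_type_symbol", "_atom_site_fract_x",
                      "_atom_site_fract_y", "_atom_site_fract_z"])
    if len(tab) == 0:
        raise ValueError(f"CIF {path} has no _atom_site loop")
    elements = [row.str(0) for row in tab]
    frac = np.array([[float(row.str(1)), float(row.str(2)), float(row.str(3))]
                     for row in tab])
    cart = lat.cart(frac)
    groups = _assemble_molecules(elements, cart)
    poses = []
    ref = monomer
    for g in groups:
        els = [elements[i] for i in g]
        xyz = cart[g]
        if ref is None:
            ref = RigidMonomer(elements=els, coords=xyz, name="from_cif")
        if sorted(els) != sorted(ref.elements):
            raise ValueError(
                f"molecule with formula {sorted(els)} does not match the "
                f"reference monomer {sorted(ref.elements)}")
        # order atoms to the reference by element-wise nearest matching
        order = _match_atoms(ref, els, xyz)
        xyz = xyz[order]
        R, com, err = _fit_pose(ref, xyz, ref.masses)
        if err > 1e-3 * len(els):
            raise ValueError(
                f"atom sites deviate from a rigid image of the monomer "
                f"(fit residual {err:.2e})")
        improper = np.linalg.det(R) < 0
        q = matrix_to_quat(-R if improper else R)
        poses.append(MoleculePose(monomer=ref, frac_com=lat.frac(com),
                                  quaternion=q, improper=improper))
    return CrystalStructure(lattice=lat, space_group=sg,
                            asymmetric_unit=poses, name=block.name)


def _match_atoms(ref: RigidMonomer, elements, coords):
    """Map site order onto the reference monomer's atom order.

    Superposes centroids, then solves an element-restricted assignment on
    squared distances (exact via the Hungarian algorithm).
    """
    from scipy.optimize import linear_sum_assignment
    Y = coords - coords.mean(axis=0)
    X = ref.coords - ref.coords.mean(axis=0)
    # initial orientation via the pose fit with identity order when
    # elements already line up; otherwise match on distance profiles
    cost = np.full((ref.n_atoms, len(elements)), 1e9)
    profX = np.sort(np.linalg.norm(X[:, None] - X[None], axis=-1), axis=1)
    profY = np.sort(np.linalg.norm(Y[:, None] - Y[None], axis=-1), axis=1)
    for i in range(ref.n_atoms):
        for j in range(len(elements)):
            if ref.elements[i] == elements[j]:
                cost[i, j] = np.linalg.norm(profX[i] - profY[j])
    ri, cj = linear_sum_assignment(cost)
    order = np.empty(ref.n_atoms, dtype=int)
    order[ri] = cj
    return order
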