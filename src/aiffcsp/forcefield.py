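"""Analytic two-body intermolecular potentials for rigid molecules.

Three functional forms are supported for an atom-atom pair at distance r
(Angstrom, energies kJ/mol):

``extended``
    [1 + a1*r + a2*r^2] * exp(alpha - beta*r) + A12/r^12
    - sum_{n=6,8} f_n(delta_n, r) * C_n/r^n
    + f_1(delta_1, r) * k_C * q_a*q_b / r

``exp61`` (Buckingham)
    A * exp(-beta*r) - C6/r^6 + k_C * q_a*q_b / r

``lj1261`` (Lennard-Jones)
    A12/r^12 - C6/r^6 + k_C * q_a*q_b / r

where f_n is the Tang-Toennies incomplete-gamma damping function.  Charges
live on the molecules (one charge set serves all forms); the pair table
holds everything else, keyed by unordered atom-type pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc

from .units import KC, mass_of

__all__ = [
    "RigidMonomer",
    "PairParameters",
    "ForceField",
    "DimerConfiguration",
    "tang_toennies",
    "pair_energy_extended",
    "pair_energy_exp61",
    "pair_energy_lj1261",
    "dimer_interaction_energy",
    "dimer_component_energies",
    "electrostatic_energy",
    "pair_key",
    "read_xyz",
    "write_xyz",
    "load_forcefield",
    "save_forcefield",
]


# --------------------------------------------------------------------------
# damping

def tang_toennies(n: int, delta: float, r):
    """Tang-Toennies damping factor f_n(delta, r).

    f_n(delta, r) = 1 - exp(-delta*r) * sum_{m=0}^{n} (delta*r)^m / m!

    which equals the regularized lower incomplete gamma function
    P(n+1, delta*r); that identity is used for numerical stability at
    large delta*r.  Returns a value in [0, 1], monotone in r.
    """
    if n < 0:
        raise ValueError(f"damping order must be non-negative, got {n}")
    delta = float(delta)
    if delta < 0:
        raise ValueError(f"damping parameter must be >= 0, got {delta}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    out = gammainc(n + 1, delta * r)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# data model

@dataclass
class RigidMonomer:
    """A rigid molecule in its body frame (center of mass at origin).

    elements : element symbols, one per atom
    types    : atom-type labels used to key the force-field pair table
               (defaults to the element symbol)
    coords   : (N, 3) Cartesian coordinates, Angstrom
    charges  : per-atom partial charges, elementary charge units
    masses   : per-atom masses, amu (tabulated by element if omitted)
    """

    elements: list
    coords: np.ndarray
    charges: np.ndarray = None
    types: list = None
    masses: np.ndarray = None
    name: str = "monomer"

    def __post_init__(self):
        self.coords = np.array(self.coords, dtype=float)
        n = len(self.elements)
        if n < 1:
            raise ValueError("monomer needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.types is None:
            self.types = list(self.elements)
        if self.masses is None:
            self.masses = np.array([mass_of(e) for e in self.elements])
        self.masses = np.asarray(self.masses, dtype=float)
        if n > 1:
            d = np.linalg.norm(
                self.coords[:, None, :] - self.coords[None, :, :], axis=-1)
            iu = np.triu_indices(n, 1)
            if d[iu].min() < 0.5:
                raise ValueError(
                    f"intramolecular distance {d[iu].min():.3f} A < 0.5 A")
        # re-center on the center of mass (body-frame convention)
        com = self.masses @ self.coords / self.masses.sum()
        self.coords = self.coords - com

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def molecular_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def radius(self) -> float:
        """Largest atom distance from the center of mass."""
        return float(np.linalg.norm(self.coords, axis=1).max()) if self.n_atoms else 0.0


def pair_key(t1: str, t2: str) -> tuple:
    """Canonical unordered atom-type pair key."""
    return (t1, t2) if t1 <= t2 else (t2, t1)


@dataclass
class PairParameters:
    """Parameters of one atom-type pair.

    Units: alpha dimensionless; beta, a1, delta* in 1/Angstrom;
    a2 in 1/Angstrom^2; A12 in kJ/mol*A^12; C6 kJ/mol*A^6; C8 kJ/mol*A^8;
    A (Buckingham prefactor, = exp(alpha) when converted) in kJ/mol.
    """

    alpha: float = 0.0
    beta: float = 1.0
    a1: float = 0.0
    a2: float = 0.0
    A12: float = 0.0
    C6: float = 0.0
    C8: float = 0.0
    delta1: float = 2.0
    delta6: float = 2.0
    delta8: float = 2.0
    A: float = 0.0  # exp-6-1 prefactor, stored directly for conditioning

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        for nm in ("delta1", "delta6", "delta8"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        for nm in ("C6", "C8", "A12"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")

    def copy(self, **kw) -> "PairParameters":
        return replace(self, **kw)


_FORMS = ("extended", "exp61", "lj1261")


@dataclass
class ForceField:
    """Functional-form tag plus the per-atom-type-pair parameter table."""

    form: str
    pair_table: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {_FORMS}")

    def get(self, t1: str, t2: str) -> PairParameters:
        key = pair_key(t1, t2)
        try:
            return self.pair_table[key]
        except KeyError:
            raise KeyError(
                f"force field has no parameters for atom-type pair {key}")

    def set(self, t1: str, t2: str, params: PairParameters) -> None:
        self.pair_table[pair_key(t1, t2)] = params

    def covers(self, mA: RigidMonomer, mB: RigidMonomer) -> bool:
        keys = {pair_key(a, b) for a in mA.types for b in mB.types}
        return keys <= set(self.pair_table)

    def copy(self) -> "ForceField":
        return ForceField(self.form,
                          {k: replace(v) for k, v in self.pair_table.items()})


@dataclass
class DimerConfiguration:
    """Two rigid molecules: A in an optional pose, B in a rigid pose.

    Poses are (rotation matrix, translation) pairs acting on body-frame
    coordinates.  Rotation matrices with determinant -1 are allowed so
    that symmetry images (inversions, glides) of a monomer can be
    represented; pair energies only depend on atom positions.
    """

    monomerA: RigidMonomer
    monomerB: RigidMonomer
    rotB: np.ndarray = None
    tranB: np.ndarray = None
    rotA: np.ndarray = None
    tranA: np.ndarray = None

    def __post_init__(self):
        self.rotB = np.eye(3) if self.rotB is None else np.asarray(self.rotB, float)
        self.tranB = np.zeros(3) if self.tranB is None else np.asarray(self.tranB, float)
        self.rotA = np.eye(3) if self.rotA is None else np.asarray(self.rotA, float)
        self.tranA = np.zeros(3) if self.tranA is None else np.asarray(self.tranA, float)

    @property
    def coordsA(self) -> np.ndarray:
        return self.monomerA.coords @ self.rotA.T + self.tranA

    @property
    def coordsB(self) -> np.ndarray:
        return self.monomerB.coords @ self.rotB.T + self.tranB

    @property
    def R(self) -> float:
        """Center-of-mass separation, Angstrom."""
        mA, mB = self.monomerA, self.monomerB
        comA = mA.masses @ self.coordsA / mA.molecular_mass
        comB = mB.masses @ self.coordsB / mB.molecular_mass
        return float(np.linalg.norm(comB - comA))

    def distances(self) -> np.ndarray:
        """(nA, nB) intermolecular atom-atom distance matrix."""
        diff = self.coordsA[:, None, :] - self.coordsB[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def min_distance(self) -> float:
        return float(self.distances().min())


# --------------------------------------------------------------------------
# pair energies

def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be > 0")
    return r


def pair_energy_extended(p: PairParameters, qa: float, qb: float, r):
    """Extended-form pair energy at distance r (kJ/mol)."""
    r = _check_r(r)
    rep = (1.0 + p.a1 * r + p.a2 * r * r) * np.exp(p.alpha - p.beta * r)
    rep = rep + p.A12 / r ** 12
    disp = (tang_toennies(6, p.delta6, r) * p.C6 / r ** 6
            + tang_toennies(8, p.delta8, r) * p.C8 / r ** 8)
    coul = tang_toennies(1, p.delta1, r) * KC * qa * qb / r
    out = rep - disp + coul
    return out if np.ndim(out) else float(out)


def pair_energy_exp61(A: float, beta: float, C6: float, qa: float, qb: float, r):
    """Buckingham exp-6-1 pair energy (kJ/mol)."""
    r = _check_r(r)
    out = A * np.exp(-beta * r) - C6 / r ** 6 + KC * qa * qb / r
    return out if np.ndim(out) else float(out)


def pair_energy_lj1261(A12: float, C6: float, qa: float, qb: float, r):
    """Lennard-Jones 12-6-1 pair energy (kJ/mol)."""
    r = _check_r(r)
    out = A12 / r ** 12 - C6 / r ** 6 + KC * qa * qb / r
    return out if np.ndim(out) else float(out)


def pair_energy(ff_form: str, p: PairParameters, qq, r):
    """Pair energy for charge product(s) qq at distance(s) r, any form.

    Vectorized over r (and qq of the same shape).
    """
    r = _check_r(r)
    qq = np.asarray(qq, dtype=float)
    if ff_form == "extended":
        rep = (1.0 + p.a1 * r + p.a2 * r * r) * np.exp(p.alpha - p.beta * r)
        rep = rep + p.A12 / r ** 12
        disp = (tang_toennies(6, p.delta6, r) * p.C6 / r ** 6
                + tang_toennies(8, p.delta8, r) * p.C8 / r ** 8)
        coul = tang_toennies(1, p.delta1, r) * KC * qq / r
        return rep - disp + coul
    if ff_form == "exp61":
        return p.A * np.exp(-p.beta * r) - p.C6 / r ** 6 + KC * qq / r
    if ff_form == "lj1261":
        return p.A12 / r ** 12 - p.C6 / r ** 6 + KC * qq / r
    raise ValueError(f"unknown form {ff_form!r}")


def pair_energy_noncoulomb(ff_form: str, p: PairParameters, r):
    """Repulsion + dispersion part (everything except the charge term)."""
    r = _check_r(r)
    if ff_form == "extended":
        rep = (1.0 + p.a1 * r + p.a2 * r * r) * np.exp(p.alpha - p.beta * r)
        rep = rep + p.A12 / r ** 12
        disp = (tang_toennies(6, p.delta6, r) * p.C6 / r ** 6
                + tang_toennies(8, p.delta8, r) * p.C8 / r ** 8)
        return rep - disp
    if ff_form == "exp61":
        return p.A * np.exp(-p.beta * r) - p.C6 / r ** 6
    if ff_form == "lj1261":
        return p.A12 / r ** 12 - p.C6 / r ** 6
    raise ValueError(f"unknown form {ff_form!r}")


# --------------------------------------------------------------------------
# dimer sums

def _pair_groups(mA: RigidMonomer, mB: RigidMonomer):
    """Group the intermolecular atom-pair index grid by atom-type pair.

    Returns {pair_key: (ia, ib)} with ia, ib integer index arrays.
    """
    groups = {}
    for i, ta in enumerate(mA.types):
        for j, tb in enumerate(mB.types):
            groups.setdefault(pair_key(ta, tb), ([], []))
            ia, ib = groups[pair_key(ta, tb)]
            ia.append(i)
            ib.append(j)
    return {k: (np.array(ia), np.array(ib)) for k, (ia, ib) in groups.items()}


def dimer_interaction_energy(ff: ForceField, d: DimerConfiguration) -> float:
    """Total two-body interaction energy of a dimer (kJ/mol).

    Sums the pair potential over all intermolecular atom pairs; invariant
    under any common rigid motion of both molecules.
    """
    dist = d.distances()
    qA, qB = d.monomerA.charges, d.monomerB.charges
    total = 0.0
    for key, (ia, ib) in _pair_groups(d.monomerA, d.monomerB).items():
        p = ff.pair_table.get(key)
        if p is None:
            raise KeyError(f"force field has no parameters for atom-type pair {key}")
        total += float(np.sum(pair_energy(ff.form, p, qA[ia] * qB[ib], dist[ia, ib])))
    return total


def electrostatic_energy(ff: ForceField, d: DimerConfiguration) -> float:
    """Damped charge-charge part of the dimer energy (kJ/mol)."""
    dist = d.distances()
    qA, qB = d.monomerA.charges, d.monomerB.charges
    total = 0.0
    for key, (ia, ib) in _pair_groups(d.monomerA, d.monomerB).items():
        p = ff.pair_table.get(key)
        if p is None:
            raise KeyError(f"force field has no parameters for atom-type pair {key}")
        r = dist[ia, ib]
        if ff.form == "extended":
            f1 = tang_toennies(1, p.delta1, r)
        else:
            f1 = 1.0
        total += float(np.sum(f1 * KC * qA[ia] * qB[ib] / r))
    return total


def dimer_component_energies(ff: ForceField, d: DimerConfiguration) -> dict:
    """Decompose an extended-form dimer energy into physical components.

    elst  : damped charge-charge sum
    exch  : polynomial-prefactored exponential + A12/r^12 (>= 0 for
            non-negative repulsion parameters)
    dispx : damped -C6/r^6 sum
    indx  : damped -C8/r^8 sum
    """
    if ff.form != "extended":
        raise ValueError("component decomposition requires the extended form")
    dist = d.distances()
    qA, qB = d.monomerA.charges, d.monomerB.charges
    elst = exch = dispx = indx = 0.0
    for key, (ia, ib) in _pair_groups(d.monomerA, d.monomerB).items():
        p = ff.pair_table.get(key)
        if p is None:
            raise KeyError(f"force field has no parameters for atom-type pair {key}")
        r = dist[ia, ib]
        elst += float(np.sum(tang_toennies(1, p.delta1, r) * KC * qA[ia] * qB[ib] / r))
        exch += float(np.sum((1.0 + p.a1 * r + p.a2 * r * r)
                             * np.exp(p.alpha - p.beta * r) + p.A12 / r ** 12))
        dispx += float(np.sum(-tang_toennies(6, p.delta6, r) * p.C6 / r ** 6))
        indx += float(np.sum(-tang_toennies(8, p.delta8, r) * p.C8 / r ** 8))
    return {"elst": elst, "exch": exch, "indx": indx, "dispx": dispx,
            "total": elst + exch + indx + dispx}


# --------------------------------------------------------------------------
# I/O

def write_xyz(monomer: RigidMonomer, path) -> None:
    """Write a monomer as extended XYZ: element x y z charge type."""
    lines = [str(monomer.n_atoms),
             f"{monomer.name} fields=element:x:y:z:charge:type"]
    for e, xyz, q, t in zip(monomer.elements, monomer.coords,
                            monomer.charges, monomer.types):
        lines.append(f"{e} {float(xyz[0])!r} {float(xyz[1])!r} "
                     f"{float(xyz[2])!r} {float(q)!r} {t}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> RigidMonomer:
    """Read a monomer from (extended) XYZ.

    Columns beyond x, y, z are interpreted as charge and atom type when
    present; otherwise charges default to zero and types to elements.
    """
    with open(path) as fh:
        raw = [ln for ln in fh.read().splitlines()]
    if not raw:
        raise ValueError(f"empty XYZ file: {path}")
    try:
        n = int(raw[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"bad XYZ header in {path}: {raw[0]!r}")
    comment = raw[1] if len(raw) > 1 else ""
    elements, coords, charges, types = [], [], [], []
    for ln in raw[2:2 + n]:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"bad XYZ atom line: {ln!r}")
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
        charges.append(float(parts[4]) if len(parts) > 4 else 0.0)
        types.append(parts[5] if len(parts) > 5 else parts[0])
    if len(elements) != n:
        raise ValueError(f"XYZ header promises {n} atoms, found {len(elements)}")
    name = comment.split()[0] if comment.split() else "monomer"
    return RigidMonomer(elements=elements, coords=np.array(coords),
                        charges=np.array(charges), types=types, name=name)


_PARAM_FIELDS = ("alpha", "beta", "a1", "a2", "A12", "C6", "C8",
                 "delta1", "delta6", "delta8", "A")


def save_forcefield(ff: ForceField, path) -> None:
    """Serialize a force field as a human-readable key-value table.

    Floats are written with repr so the round trip is bit-exact.
    """
    lines = [f"form {ff.form}"]
    for key in sorted(ff.pair_table):
        p = ff.pair_table[key]
        lines.append(f"pair {key[0]} {key[1]}")
        for nm in _PARAM_FIELDS:
            lines.append(f"  {nm} {float(getattr(p, nm))!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_forcefield(path) -> ForceField:
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("form "):
        raise ValueError(f"force-field file {path} must start with a 'form' line")
    ff = ForceField(form=lines[0].split()[1])
    key, fields = None, {}

    def flush():
        if key is not None:
            ff.pair_table[key] = PairParameters(**fields)

    for ln in lines[1:]:
        if ln.startswith("pair "):
            flush()
            _, t1, t2 = ln.split()
            key, fields = pair_key(t1, t2), {}
        else:
            nm, val = ln.split()
            if nm not in _PARAM_FIELDS:
                raise ValueError(f"unknown parameter {nm!r} in {path}")
            fields[nm] = float(val)
    flush()
    return ff


def exp61_A_from_alpha(alpha: float) -> float:
    """Convert the extended-form log-prefactor alpha to a Buckingham A."""
    return math.exp(alpha)
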