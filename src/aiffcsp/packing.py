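"""Candidate crystal packing generation.

Two strategies:

* grid mode -- deterministic orientation-grid packing: the central
  molecule is rotated over an inclusive Euler-angle grid (0..180 degrees,
  19 values per angle at the default 10-degree step) in each coordination
  geometry, and the cell is contracted axis by axis until a purely
  repulsive 1/r^12 contact energy reaches a threshold.  The densest
  candidates per geometry are kept.

* random mode -- two-step random generation per space group: step 1
  samples unrestricted cells to estimate cell-length ranges from the
  accepted structures; step 2 samples within the estimated ranges and
  applies a short rough 12-6-1 lattice-energy minimization.  Structures
  with any atom-atom 12-6-1 pair energy above 2000 kJ/mol are rejected
  immediately in both steps.

The coordination geometries are a parametrized library of axis
contraction schemes constructed systematically from the 26 grid-search
space groups (two axis-order variants per group, 51 entries), a stand-in
that preserves the combinatorics of the original geometry catalogue.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .crystal import (CrystalStructure, Lattice, GRID_SEARCH_GROUPS, MoleculePose,
                      SpaceGroup, RANDOM_SEARCH_GROUPS, _translations, density,
                      expand_symmetry, matrix_to_quat)
from .forcefield import ForceField, RigidMonomer
from .minimize import minimize_structure
from .units import KC, VDW_RADII

__all__ = ["GenerationConfig", "CandidateSet", "coordination_geometries",
           "grid_generate", "grid_candidate_count", "select_densest",
           "random_generate_step1", "random_generate_step2",
           "molecular_volume"]


@dataclass
class GenerationConfig:
    mode: str = "random"
    space_groups: list = field(default_factory=lambda: list(RANDOM_SEARCH_GROUPS))
    angle_step: float = 10.0
    n_geometries: int = 51
    per_geometry_keep: int = 500
    per_group_quota_step1: int = 500
    per_group_quota_step2: int = 5000
    pair_energy_reject: float = 2000.0   # kJ/mol, per atom-atom pair
    contraction_threshold: float = 50.0  # kJ/mol per cell, grid mode
    rough_maxiter: int = 25
    rough_gtol: float = 1.0              # kJ/mol per DOF, loose
    cutoff: float = 12.0                 # rough-stage real-space cutoff
    seed: int = 0

    def __post_init__(self):
        if 180.0 % self.angle_step != 0:
            raise ValueError("angle_step must divide 180")
        for nm in ("n_geometries", "per_geometry_keep",
                   "per_group_quota_step1", "per_group_quota_step2"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be >= 1")


@dataclass
class CandidateSet:
    structures: list
    provenance: list          # one dict per structure
    rough_energy: np.ndarray
    density: np.ndarray

    def __len__(self):
        return len(self.structures)

    @classmethod
    def empty(cls):
        return cls([], [], np.zeros(0), np.zeros(0))

    def extend(self, other: "CandidateSet"):
        self.structures += other.structures
        self.provenance += other.provenance
        self.rough_energy = np.concatenate([self.rough_energy,
                                            other.rough_energy])
        self.density = np.concatenate([self.density, other.density])


def molecular_volume(m: RigidMonomer) -> float:
    """Crude molecular volume from van der Waals spheres (cubic Angstrom)."""
    return sum(4.0 / 3.0 * math.pi * VDW_RADII.get(e, 1.7) ** 3
               for e in m.elements)


# --------------------------------------------------------------------------
# grid mode

def coordination_geometries(n: int = 51):
    """The default library of n axis-contraction packing schemes."""
    axis_orders = [(0, 1, 2), (2, 0, 1), (1, 2, 0)]
    geoms = []
    i = 0
    while len(geoms) < n:
        group = GRID_SEARCH_GROUPS[i % len(GRID_SEARCH_GROUPS)]
        order = axis_orders[i // len(GRID_SEARCH_GROUPS) % 3]
        geoms.append({"id": i, "space_group": group, "axis_order": order})
        i += 1
    return geoms


def grid_candidate_count(cfg: GenerationConfig) -> int:
    """Size of the full orientation grid: (180/step + 1)^3 x geometries."""
    per_axis = int(180.0 / cfg.angle_step) + 1
    return per_axis ** 3 * cfg.n_geometries


def _euler_matrix(a, b, g):
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cg, sg = math.cos(g), math.sin(g)
    Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return Rz1 @ Ry @ Rz2


def _repulsion_energy(s: CrystalStructure, r0: float = 3.3,
                      cutoff: float = 8.0) -> float:
    """Packing control energy: sum of (r0/r)^12 over intermolecular pairs."""
    placed = expand_symmetry(s, check_special=False)
    coords = np.concatenate([p.coords for p in placed])
    molid = np.concatenate([np.full(p.monomer.n_atoms, i)
                            for i, p in enumerate(placed)])
    dmax = 2.0 * max(p.monomer.radius() for p in placed)
    L = _translations(s.lattice, cutoff + dmax)
    home = np.all(np.abs(L) < 1e-12, axis=1)
    dX = coords[:, None, :] - coords[None, :, :]
    same = molid[:, None] == molid[None, :]
    e = 0.0
    for Lc, h in zip(L, home):
        d = np.linalg.norm(dX + Lc, axis=-1)
        mask = ~(same & h) & (d < cutoff) & (d > 1e-9)
        if mask.any():
            e += float(np.sum((r0 / d[mask]) ** 12))
    return 0.5 * e


def grid_generate(monomer: RigidMonomer, cfg: GenerationConfig) -> CandidateSet:
    """Deterministic orientation-grid packing over coordination geometries.

    For each geometry and Euler-angle triple the cell axes are contracted
    in the geometry's order by bisection until the cumulative repulsive
    1/r^12 energy reaches the contraction threshold.  Candidates whose
    contraction fails to bracket the threshold are skipped and logged in
    the provenance of the returned set (meta key "skipped").
    """
    if cfg.mode != "grid":
        raise ValueError("grid_generate requires mode='grid'")
    geoms = coordination_geometries(cfg.n_geometries)
    per_axis = int(180.0 / cfg.angle_step) + 1
    angles = np.radians(np.linspace(0.0, 180.0, per_axis))
    out = CandidateSet.empty()
    skipped = 0
    diameter = 2.0 * monomer.radius() + 2.0 * max(
        VDW_RADII.get(e, 1.7) for e in monomer.elements)
    frac0 = np.array([0.13, 0.27, 0.41])
    for geom in geoms:
        sg = SpaceGroup.from_symbol(geom["space_group"])
        L0 = 2.5 * diameter * max(1.0, sg.n_ops ** (1.0 / 3.0))
        for ia, ib, ig in itertools.product(range(per_axis), repeat=3):
            R = _euler_matrix(angles[ia], angles[ib], angles[ig])
            q = matrix_to_quat(R)
            lengths = [L0, L0, L0]
            ok = True
            for step_i, axis in enumerate(geom["axis_order"]):
                target = cfg.contraction_threshold * (step_i + 1)

                def energy_at(val):
                    lt = list(lengths)
                    lt[axis] = val
                    lat = Lattice.from_parameters(*lt, 90, 90, 90)
                    s = CrystalStructure(lat, sg, [MoleculePose(
                        monomer, frac0, q)])
                    return _repulsion_energy(s)

                lo, hi = max(1.6, 0.3 * diameter), L0
                if energy_at(lo) < target:
                    ok = False
                    break
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if energy_at(mid) > target:
                        lo = mid
                    else:
                        hi = mid
                    if hi - lo < 1e-3:
                        break
                lengths[axis] = hi
            if not ok:
                skipped += 1
                continue
            lat = Lattice.from_parameters(*lengths, 90, 90, 90)
            s = CrystalStructure(lat, sg, [MoleculePose(monomer, frac0, q)],
                                 name=f"g{geom['id']}_{ia}_{ib}_{ig}")
            out.structures.append(s)
            out.provenance.append({"geometry": geom["id"],
                                   "space_group": geom["space_group"],
                                   "angles": (float(np.degrees(angles[ia])),
                                              float(np.degrees(angles[ib])),
                                              float(np.degrees(angles[ig])))})
            out.rough_energy = np.append(out.rough_energy,
                                         _repulsion_energy(s))
            out.density = np.append(out.density, density(s))
    if skipped:
        out.provenance.append({"skipped": skipped})
    return out


def select_densest(cands: CandidateSet, per_geometry_keep: int) -> CandidateSet:
    """Keep the densest candidates within each coordination geometry.

    Ties break by rough energy (lower first), then provenance order.  A
    geometry with fewer candidates than the quota keeps them all.
    """
    entries = [(p, s, e, d, i) for i, (p, s, e, d) in enumerate(
        zip(cands.provenance, cands.structures, cands.rough_energy,
            cands.density)) if "geometry" in p]
    by_geom = {}
    for p, s, e, d, i in entries:
        by_geom.setdefault(p["geometry"], []).append((p, s, e, d, i))
    out = CandidateSet.empty()
    for g in sorted(by_geom):
        rows = sorted(by_geom[g], key=lambda r: (-r[3], r[2], r[4]))
        for p, s, e, d, i in rows[:per_geometry_keep]:
            out.structures.append(s)
            out.provenance.append(p)
            out.rough_energy = np.append(out.rough_energy, e)
            out.density = np.append(out.density, d)
    return out


# --------------------------------------------------------------------------
# random mode

_ANGLE_RANGES = {
    "triclinic": ((60, 120), (60, 120), (60, 120)),
    "monoclinic": ((90, 90), (90, 130), (90, 90)),
    "orthorhombic": ((90, 90), (90, 90), (90, 90)),
    "tetragonal": ((90, 90), (90, 90), (90, 90)),
    "trigonal": ((90, 90), (90, 90), (120, 120)),
    "hexagonal": ((90, 90), (90, 90), (120, 120)),
    "cubic": ((90, 90), (90, 90), (90, 90)),
}


def _sample_cell(rng, sg: SpaceGroup, scale, length_ranges=None):
    cs = sg.crystal_system
    if length_ranges is None:
        lengths = rng.uniform(0.7 * scale, 2.0 * scale, size=3)
    else:
        lengths = np.array([rng.uniform(lo, hi) for lo, hi in length_ranges])
    if cs in ("tetragonal", "trigonal", "hexagonal"):
        lengths[1] = lengths[0]
    elif cs == "cubic":
        lengths[1] = lengths[2] = lengths[0]
    angs = [rng.uniform(lo, hi) if hi > lo else float(lo)
            for lo, hi in _ANGLE_RANGES[cs]]
    return Lattice.from_parameters(*lengths, *angs)


def _random_quat(rng):
    u1, u2, u3 = rng.random(3)
    return np.array([math.sqrt(u1) * math.cos(2 * math.pi * u3),
                     math.sqrt(1 - u1) * math.sin(2 * math.pi * u2),
                     math.sqrt(1 - u1) * math.cos(2 * math.pi * u2),
                     math.sqrt(u1) * math.sin(2 * math.pi * u3)])


def _max_pair_energy(rough_ff: ForceField, s: CrystalStructure,
                     cutoff: float = 6.0) -> float:
    """Largest single atom-atom 12-6-1 energy between different molecules."""
    placed = expand_symmetry(s, check_special=False)
    coords = np.concatenate([p.coords for p in placed])
    charges = np.concatenate([p.monomer.charges for p in placed])
    types = sum(([t for t in p.monomer.types] for p in placed), [])
    molid = np.concatenate([np.full(p.monomer.n_atoms, i)
                            for i, p in enumerate(placed)])
    dmax = 2.0 * max(p.monomer.radius() for p in placed)
    L = _translations(s.lattice, cutoff + dmax)
    home = np.all(np.abs(L) < 1e-12, axis=1)
    unique = sorted(set(types))
    tid = np.array([unique.index(t) for t in types])
    A12 = np.empty((len(unique), len(unique)))
    C6 = np.empty_like(A12)
    for i, ti in enumerate(unique):
        for j, tj in enumerate(unique):
            p = rough_ff.get(ti, tj)
            A12[i, j], C6[i, j] = p.A12, p.C6
    dX = coords[:, None, :] - coords[None, :, :]
    same = molid[:, None] == molid[None, :]
    qq = charges[:, None] * charges[None, :]
    worst = -np.inf
    for Lc, h in zip(L, home):
        d = np.linalg.norm(dX + Lc, axis=-1)
        mask = ~(same & h) & (d < cutoff)
        if not mask.any():
            continue
        i, j = np.nonzero(mask)
        r = d[mask]
        e = A12[tid[i], tid[j]] / r ** 12 - C6[tid[i], tid[j]] / r ** 6 \
            + KC * qq[mask] / r
        worst = max(worst, float(e.max()))
    return worst


def _sample_structure(rng, monomer, sg, scale, cfg, rough_ff,
                      length_ranges=None):
    """One rejection-sampling attempt; returns the structure or None."""
    lat = _sample_cell(rng, sg, scale, length_ranges)
    pose = MoleculePose(monomer, rng.random(3), _random_quat(rng))
    s = CrystalStructure(lat, sg, [pose])
    vol = lat.volume
    pack = sg.n_ops * molecular_volume(monomer) / vol
    if not 0.35 <= pack <= 1.0:
        return None
    try:
        if _max_pair_energy(rough_ff, s) > cfg.pair_energy_reject:
            return None
    except ValueError:
        return None
    return s


def random_generate_step1(monomer: RigidMonomer, group: str, quota: int,
                          rough_ff: ForceField, cfg: GenerationConfig,
                          seed: int = None):
    """Unrestricted random generation; returns a cell-dimension estimate.

    The estimate is the 5th-95th percentile range of each accepted cell
    length.  Aborts with diagnostics if the acceptance rate falls below
    1e-4.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sg = SpaceGroup.from_symbol(group)
    scale = (sg.n_ops * molecular_volume(monomer)) ** (1.0 / 3.0)
    accepted = []
    attempts = 0
    while len(accepted) < quota:
        attempts += 1
        if attempts > 1e4 and len(accepted) / attempts < 1e-4:
            raise RuntimeError(
                f"step-1 acceptance rate {len(accepted)}/{attempts} below "
                f"1e-4 for group {group}")
        s = _sample_structure(rng, monomer, sg, scale, cfg, rough_ff)
        if s is not None:
            accepted.append(s.lattice.parameters[:3])
    arr = np.array(accepted)
    lo = np.percentile(arr, 5, axis=0)
    hi = np.percentile(arr, 95, axis=0)
    return [(float(a), float(b)) for a, b in zip(lo, hi)]


def random_generate_step2(monomer: RigidMonomer, group: str, cell_estimate,
                          quota: int, rough_ff: ForceField,
                          cfg: GenerationConfig, seed: int = None) -> CandidateSet:
    """Restricted random generation plus rough 12-6-1 mini-optimization.

    Cell lengths are sampled within the step-1 percentile ranges widened
    by 20%; every accepted structure gets a short loose-tolerance
    lattice-energy minimization with the rough force field.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    sg = SpaceGroup.from_symbol(group)
    scale = (sg.n_ops * molecular_volume(monomer)) ** (1.0 / 3.0)
    ranges = [(0.8 * lo, 1.2 * hi) for lo, hi in cell_estimate]
    out = CandidateSet.empty()
    attempts = 0
    while len(out.structures) < quota:
        attempts += 1
        if attempts > 1e4 and len(out.structures) / attempts < 1e-4:
            raise RuntimeError(
                f"step-2 acceptance rate {len(out.structures)}/{attempts} "
                f"below 1e-4 for group {group}")
        s = _sample_structure(rng, monomer, sg, scale, cfg, rough_ff, ranges)
        if s is None:
            continue
        res = minimize_structure(rough_ff, s, cutoff=cfg.cutoff,
                                 gtol=cfg.rough_gtol, ftol=1e-7,
                                 maxiter=cfg.rough_maxiter)
        if res.collapse_flag or not np.isfinite(res.energy):
            continue
        st = res.structure
        # drop structures that drifted apart during the rough optimization
        pack = sg.n_ops * molecular_volume(monomer) / st.lattice.volume
        if pack < 0.3:
            continue
        st.name = f"{group.replace('/', '_')}_{len(out.structures)}"
        out.structures.append(st)
        out.provenance.append({"space_group": group, "seed_attempt": attempts,
                               "mode": "random"})
        out.rough_energy = np.append(out.rough_energy, res.energy)
        out.density = np.append(out.density, density(st))
    return out
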