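"""Polymorph deduplication, energy ranking, and packing-similarity scoring.

Duplicate detection combines three descriptors: lattice energy, the
Niggli-reduced cell parameters, and a fingerprint of the shortest
intermolecular heavy-atom distances.  Structural agreement with a
reference crystal is scored as the RMSD of an optimally superposed
n-molecule cluster (default 20 molecules, heavy atoms only), with the
conventional 0.8 Angstrom match threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .crystal import CrystalStructure, expand_symmetry, niggli_parameters

__all__ = ["PolymorphSet", "OverlapResult", "ClusterTolerances",
           "cluster_structures", "rank_polymorphs", "rmsd_n",
           "landscape_table", "distance_fingerprint"]


@dataclass
class ClusterTolerances:
    dE: float = 0.5            # kJ/mol
    dlength: float = 0.01      # relative, Niggli-reduced lengths
    dangle: float = 1.0        # degrees, Niggli-reduced angles
    dfingerprint: float = 0.05  # Angstrom RMS over the distance fingerprint
    n_fingerprint: int = 200


@dataclass
class PolymorphSet:
    """Clustered, ranked polymorph collection.

    entries: list of dicts with keys id, structure, energy, density,
    cluster, rank (rank only on cluster representatives; ranks are
    consecutive 1..K).
    """

    entries: list = field(default_factory=list)

    def representatives(self):
        return [e for e in self.entries if e.get("rank") is not None]

    def __len__(self):
        return len(self.entries)


@dataclass
class OverlapResult:
    rmsd: float
    n_molecules: int
    threshold: float = 0.8
    rotation: np.ndarray = None
    translation: np.ndarray = None

    @property
    def matched(self) -> bool:
        return self.rmsd < self.threshold


# --------------------------------------------------------------------------
# fingerprints and clustering

def distance_fingerprint(s: CrystalStructure, n: int = 200,
                         reach: float = 8.0) -> np.ndarray:
    """Sorted shortest intermolecular heavy-atom distances (Angstrom)."""
    placed = expand_symmetry(s, check_special=False)
    coords, heavy, molid = [], [], []
    for i, p in enumerate(placed):
        keep = [k for k, e in enumerate(p.monomer.elements) if e != "H"]
        coords.append(p.coords[keep])
        molid.append(np.full(len(keep), i))
    coords = np.concatenate(coords)
    molid = np.concatenate(molid)
    dmax = 2.0 * max(p.monomer.radius() for p in placed)
    nmax = np.ceil((reach + dmax) / s.lattice.heights()).astype(int)
    grid = np.mgrid[-nmax[0]:nmax[0] + 1, -nmax[1]:nmax[1] + 1,
                    -nmax[2]:nmax[2] + 1].reshape(3, -1).T
    L = grid @ s.lattice.matrix
    home = np.all(grid == 0, axis=1)
    dX = coords[:, None, :] - coords[None, :, :]
    same = molid[:, None] == molid[None, :]
    dists = []
    for Lc, h in zip(L, home):
        d = np.linalg.norm(dX + Lc, axis=-1)
        m = ~(same & h) & (d < reach)
        if m.any():
            dists.append(d[m])
    alld = np.sort(np.concatenate(dists)) if dists else np.zeros(0)
    return alld[:n]


def _same_structure(e1, e2, tol: ClusterTolerances) -> bool:
    if abs(e1["energy"] - e2["energy"]) > tol.dE:
        return False
    c1, c2 = e1["_niggli"], e2["_niggli"]
    for a, b in zip(c1[:3], c2[:3]):
        if abs(a - b) > tol.dlength * max(a, b):
            return False
    for a, b in zip(c1[3:], c2[3:]):
        if abs(a - b) > tol.dangle:
            return False
    f1, f2 = e1["_fp"], e2["_fp"]
    n = min(len(f1), len(f2))
    if n == 0:
        return True
    rms = float(np.sqrt(np.mean((f1[:n] - f2[:n]) ** 2)))
    return rms < tol.dfingerprint


def cluster_structures(entries, tol: ClusterTolerances = None) -> PolymorphSet:
    """Group duplicate polymorphs; the representative is the lowest-energy
    member of each cluster.

    ``entries`` is a list of (structure, energy) pairs or dicts with keys
    structure/energy (extra keys are carried through).  Clustering is the
    transitive closure of pairwise matches, hence independent of input
    order up to cluster labels.
    """
    tol = tol or ClusterTolerances()
    from .crystal import density as _density
    norm = []
    for i, e in enumerate(entries):
        if not isinstance(e, dict):
            e = {"structure": e[0], "energy": e[1]}
        e = dict(e)
        e.setdefault("id", i)
        e.setdefault("density", _density(e["structure"]))
        e["_niggli"] = niggli_parameters(e["structure"])
        e["_fp"] = distance_fingerprint(e["structure"],
                                        n=tol.n_fingerprint)
        norm.append(e)
    n = len(norm)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _same_structure(norm[i], norm[j], tol):
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[max(pi, pj)] = min(pi, pj)
    roots = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    out = PolymorphSet()
    for ci, (root, members) in enumerate(sorted(roots.items())):
        rep = min(members, key=lambda k: (norm[k]["energy"], norm[k]["id"]))
        for k in members:
            e = {kk: v for kk, v in norm[k].items()
                 if not kk.startswith("_")}
            e["cluster"] = ci
            e["rank"] = None
            e["is_representative"] = (k == rep)
            out.entries.append(e)
    return out


def rank_polymorphs(pset: PolymorphSet) -> PolymorphSet:
    """Assign ranks 1..K to cluster representatives by ascending energy.

    Near-degenerate energies (within 1e-6 kJ/mol) break ties by density
    (descending) then id.
    """
    reps = [e for e in pset.entries if e.get("is_representative")]
    reps.sort(key=lambda e: (round(e["energy"] / 1e-6) * 1e-6,
                             -e["density"], e["id"]))
    for r, e in enumerate(reps, start=1):
        e["rank"] = r
    return pset


def landscape_table(pset: PolymorphSet) -> pd.DataFrame:
    """Rank / energy / relative energy / density / space group table."""
    reps = sorted([e for e in pset.entries if e.get("rank") is not None],
                  key=lambda e: e["rank"])
    if not reps:
        return pd.DataFrame(columns=["rank", "energy", "relative_energy",
                                     "density", "space_group"])
    e0 = min(e["energy"] for e in reps)
    rows = [{"rank": e["rank"], "energy": e["energy"],
             "relative_energy": e["energy"] - e0, "density": e["density"],
             "space_group": e["structure"].space_group.symbol}
            for e in reps]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# n-molecule overlap RMSD

def _molecule_cluster(s: CrystalStructure, n: int, heavy_only: bool):
    """n molecules around a central one, as (coords, elements) lists."""
    placed = expand_symmetry(s, check_special=False)
    Z = len(placed)
    # enough images to surround the central molecule with n neighbors
    need = int(np.ceil((n / Z) ** (1 / 3))) + 1
    mols = []
    for na in range(-need, need + 1):
        for nb in range(-need, need + 1):
            for nc in range(-need, need + 1):
                shift = np.array([na, nb, nc]) @ s.lattice.matrix
                for p in placed:
                    mols.append((p.coords + shift, p.monomer))
    return mols


def _central_cluster(s: CrystalStructure, n: int, heavy_only: bool = True,
                     central_index: int = 0):
    mols = _molecule_cluster(s, n, heavy_only)
    placed = expand_symmetry(s, check_special=False)
    center = placed[central_index].coords.mean(axis=0)
    coms = np.array([m[0].mean(axis=0) for m in mols])
    order = np.argsort(np.linalg.norm(coms - center, axis=1))
    cluster = []
    for k in order[:n]:
        coords, monomer = mols[k]
        if heavy_only:
            keep = [i for i, e in enumerate(monomer.elements) if e != "H"]
        else:
            keep = list(range(monomer.n_atoms))
        cluster.append((coords[keep], [monomer.elements[i] for i in keep]))
    return cluster


def _kabsch(P, Q, proper: bool = True):
    """Least-squares rotation mapping P onto Q (both centered)."""
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if proper else 1.0])
    return Vt.T @ D @ U.T


def _match_molecule_atoms(elsA, A, elsB, B):
    """Element-restricted assignment of atoms of A onto B (both placed)."""
    cost = np.full((len(A), len(B)), 1e6)
    for i in range(len(A)):
        for j in range(len(B)):
            if elsA[i] == elsB[j]:
                cost[i, j] = np.linalg.norm(A[i] - B[j])
    ri, cj = linear_sum_assignment(cost)
    return ri, cj


def rmsd_n(candidate: CrystalStructure, reference: CrystalStructure,
           n: int = 20, heavy_only: bool = True,
           threshold: float = 0.8) -> OverlapResult:
    """Optimal n-molecule cluster overlay RMSD (Angstrom).

    Builds an n-molecule cluster around a central molecule in each
    crystal, tries every symmetry-distinct central-molecule pairing,
    aligns the central molecules (proper rotations only), matches the
    remaining molecules greedily by center of mass, and refines with a
    full least-squares superposition over all matched heavy atoms.
    Returns the smallest RMSD found.
    """
    Zr = len(expand_symmetry(reference, check_special=False))
    candC = _central_cluster(candidate, n, heavy_only, 0)
    # the reference pool carries extra boundary molecules so that shell
    # ties at the cluster surface cannot force bad pairings
    n_ref = n + max(8, n // 2)
    best = None
    for ci in range(Zr):
        refC = _central_cluster(reference, n_ref, heavy_only, ci)
        res = _overlay_clusters(candC, refC)
        if res is not None and (best is None or res[0] < best[0]):
            best = res
    if best is None:
        raise ValueError("could not overlay clusters (molecule mismatch?)")
    rmsd, R, t = best
    return OverlapResult(rmsd=float(rmsd), n_molecules=n, threshold=threshold,
                         rotation=R, translation=t)


def _axis_rotation(axis, theta):
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _overlay_clusters(candC, refC, n_axial: int = 12):
    """Best cluster overlay over trial central-molecule alignments.

    The central-molecule Kabsch fit is degenerate for linear molecules
    (free rotation about the bond axis) and ambiguous for symmetric
    ones, so additional trial rotations about the reference molecule's
    principal axes seed the molecule-matching refinement.
    """
    if sorted(candC[0][1]) != sorted(refC[0][1]):
        raise ValueError(
            f"molecular formulas differ: {sorted(candC[0][1])} vs "
            f"{sorted(refC[0][1])}")
    # central-molecule alignment; initial atom correspondence from
    # orientation-invariant intramolecular distance profiles
    A0, elsA = candC[0]
    B0, elsB = refC[0]
    cA0, cB0 = A0.mean(axis=0), B0.mean(axis=0)
    profA = np.sort(np.linalg.norm(A0[:, None] - A0[None], axis=-1), axis=1)
    profB = np.sort(np.linalg.norm(B0[:, None] - B0[None], axis=-1), axis=1)
    cost = np.full((len(A0), len(B0)), 1e6)
    for i in range(len(A0)):
        for j in range(len(B0)):
            if elsA[i] == elsB[j]:
                cost[i, j] = np.linalg.norm(profA[i] - profB[j])
    ri, cj = linear_sum_assignment(cost)
    R0 = _kabsch((A0 - cA0)[ri], (B0 - cB0)[cj])
    # trial rotations about the reference molecule's principal axes
    _, sv, Vt = np.linalg.svd(B0 - cB0)
    trials = [np.eye(3)]
    for axis in (Vt[0], Vt[-1]):
        for k in range(1, n_axial):
            trials.append(_axis_rotation(axis, 2 * np.pi * k / n_axial))
    comsR = np.array([c.mean(axis=0) for c, _ in refC])
    best = None
    for T in trials:
        R, cA, cB = T @ R0, cA0, cB0
        local = None
        for _ in range(4):
            candT = [((c - cA) @ R.T + cB, els) for c, els in candC]
            comsC = np.array([c.mean(axis=0) for c, _ in candT])
            dist = np.linalg.norm(comsC[:, None] - comsR[None], axis=-1)
            mi, mj = linear_sum_assignment(dist)
            P_all, Q_all = [], []
            for i, j in zip(mi, mj):
                ci_, elsC = candT[i]
                rj_, elsR = refC[j]
                # absolute positions: clusters already roughly superposed
                ai, aj = _match_molecule_atoms(elsC, ci_, elsR, rj_)
                P_all.append(candC[i][0][ai])
                Q_all.append(rj_[aj])
            P = np.concatenate(P_all)
            Q = np.concatenate(Q_all)
            cP, cQ = P.mean(axis=0), Q.mean(axis=0)
            R_full = _kabsch(P - cP, Q - cQ)
            rmsd = float(np.sqrt(np.mean(
                np.sum(((P - cP) @ R_full.T - (Q - cQ)) ** 2, axis=1))))
            if local is None or rmsd < local[0] - 1e-12:
                local = (rmsd, R_full, cQ - cP)
                cA, cB, R = cP, cQ, R_full
            else:
                break
        if best is None or local[0] < best[0]:
            best = local
        if best[0] < 1e-8:
            break
    return best
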