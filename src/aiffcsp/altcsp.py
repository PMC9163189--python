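"""Iterative force-field refinement from predicted polymorphs.

After an initial search, the top-ranked polymorphs are mined for their
nearest-neighbor dimers; the reference oracle is queried at exactly those
geometries, the force field is refitted on the enlarged dataset, and the
top polymorphs are re-minimized and re-ranked.  Convergence is declared
when, for every top polymorph, the energy of a finite block of unit
cells (default 5x5x5) computed purely from the force field agrees with a
hybrid energy -- in which every dimer whose geometry matches a stored
reference is substituted by the reference energy -- to within a
threshold (default 1 kJ/mol, the scale of typical fit residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import CrystalStructure, expand_symmetry
from .fitting import FitConfig, fit_extended
from .forcefield import (DimerConfiguration, ForceField, pair_energy,
                         _pair_groups)
from .minimize import staged_minimize
from .oracle import GroundTruth, evaluate_reference
from .rank_cluster import cluster_structures, rank_polymorphs

__all__ = ["AltCspState", "extract_nn_dimers", "cluster_energy",
           "alt_csp_loop", "dimer_descriptor", "dedupe_dimers"]


@dataclass
class AltCspState:
    iteration: int
    force_field: ForceField
    charges: np.ndarray
    top_structures: list
    reference_pool: list
    gaps: list                      # per-structure |pure - hybrid|, kJ/mol
    threshold: float
    converged: bool
    history: list = field(default_factory=list)


# --------------------------------------------------------------------------
# dimer extraction

def dimer_descriptor(cfg: DimerConfiguration) -> np.ndarray:
    """Rigid-motion-invariant descriptor: sorted atom-pair distances."""
    return np.sort(cfg.distances().ravel())


def dedupe_dimers(configs, tol: float = 0.05) -> list:
    """Drop dimers whose distance multisets agree within tol (Angstrom).

    The descriptor test is a cheap sufficient proxy for superposed-RMSD
    deduplication: two rigid dimers of the same molecules with equal
    atom-pair distance multisets are congruent up to reflection.
    """
    kept, descs = [], []
    for cfg in configs:
        desc = dimer_descriptor(cfg)
        dup = any(len(d) == len(desc) and np.max(np.abs(d - desc)) < tol
                  for d in descs)
        if not dup:
            kept.append(cfg)
            descs.append(desc)
    return kept


def extract_nn_dimers(s: CrystalStructure, k_shells: int = 1,
                      shell_tol: float = 1e-3) -> list:
    """Nearest-neighbor dimers of the central molecule, one per geometry.

    Neighbors are grouped into distance shells (center-of-mass distances
    equal within shell_tol); the dimers of the first k_shells shells are
    returned, deduplicated by congruence.
    """
    placed = expand_symmetry(s, check_special=False)
    central = placed[0]
    neighbors = []
    reach = 2  # cells in each direction; ample for nearest shells
    for na in range(-reach, reach + 1):
        for nb in range(-reach, reach + 1):
            for nc in range(-reach, reach + 1):
                shift = np.array([na, nb, nc]) @ s.lattice.matrix
                for i, p in enumerate(placed):
                    if i == 0 and na == nb == nc == 0:
                        continue
                    neighbors.append((p, p.com + shift))
    dists = np.array([np.linalg.norm(c - central.com) for _, c in neighbors])
    order = np.argsort(dists)
    shells = []
    for idx in order:
        d = dists[idx]
        if not shells or d > shells[-1][0] + shell_tol:
            shells.append((d, [idx]))
        else:
            shells[-1][1].append(idx)
    take = [i for _, members in shells[:k_shells] for i in members]
    mon = central.monomer
    configs = []
    for idx in take:
        p, com = neighbors[idx]
        shift = com - p.com
        # pose of the central molecule and the neighbor, both explicit
        RA, tA = _placed_transform(central)
        RB, tB = _placed_transform(p)
        configs.append(DimerConfiguration(mon, p.monomer, rotA=RA, tranA=tA,
                                          rotB=RB, tranB=tB + shift))
    return dedupe_dimers(configs)


def _placed_transform(p):
    """Rigid transform (R, t) with coords = body @ R.T + t."""
    body = p.monomer.coords
    X = p.coords
    cb = body.mean(axis=0)
    cX = X.mean(axis=0)
    H = (body - cb).T @ (X - cX)
    U, S, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if np.linalg.norm(body @ R.T - (X - cX + cb @ R.T)) > \
       np.linalg.norm(body @ (Vt.T @ np.diag([1, 1, -1]) @ U.T).T
                      - (X - cX + cb @ R.T)):
        R = Vt.T @ np.diag([1, 1, -1]) @ U.T
    t = cX - cb @ R.T
    return R, t


# --------------------------------------------------------------------------
# finite-cluster energies

def _block_molecules(s: CrystalStructure, dims):
    placed = expand_symmetry(s, check_special=False)
    mols = []
    for na in range(dims[0]):
        for nb in range(dims[1]):
            for nc in range(dims[2]):
                shift = np.array([na, nb, nc]) @ s.lattice.matrix
                for p in placed:
                    mols.append((p.monomer, p.coords + shift))
    return mols


def cluster_energy(ff: ForceField, s: CrystalStructure, dims=(5, 5, 5),
                   mode: str = "pure", known_refs=None,
                   match_tol: float = 0.05) -> float:
    """Total two-body energy of a finite dims block of unit cells (kJ/mol).

    No periodic images: the block is an isolated cluster.  In hybrid
    mode, every molecule pair whose dimer geometry matches a stored
    reference (distance-multiset agreement within match_tol Angstrom) has
    its model energy replaced by the reference total.
    """
    mols = _block_molecules(s, dims)
    nm = len(mols)
    if nm < 2:
        return 0.0
    if mode not in ("pure", "hybrid"):
        raise ValueError(f"unknown mode {mode!r}")
    refs = known_refs or []
    if mode == "hybrid" and not refs:
        import warnings
        warnings.warn("hybrid cluster energy without references equals pure mode")
    # group reference descriptors by length for vectorized matching;
    # each reference carries its substitution correction
    # (reference total minus the model evaluated at the reference's own
    # geometry), so a matched dimer contributes the model's error there
    ref_groups = {}
    max_ref_R = 0.0
    for ref in refs:
        rdists = ref.config.distances()
        desc = np.sort(rdists.ravel())
        model_at_ref = _dimer_energy_from_dists(
            ff, ref.config.monomerA, ref.config.monomerB, rdists)
        ref_groups.setdefault(len(desc), ([], []))
        ref_groups[len(desc)][0].append(desc)
        ref_groups[len(desc)][1].append(ref.energies.total - model_at_ref)
        max_ref_R = max(max_ref_R, ref.config.R)
    ref_groups = {k: (np.array(d), np.array(t))
                  for k, (d, t) in ref_groups.items()}

    coords = np.concatenate([c for _, c in mols])
    charges = np.concatenate([m.charges for m, _ in mols])
    types = sum(([t for t in m.types] for m, _ in mols), [])
    molid = np.concatenate([np.full(m.n_atoms, i)
                            for i, (m, _) in enumerate(mols)])
    from .crystal import _pair_param_grids, _nc_energy_1d
    from scipy.special import gammainc
    from .units import KC
    P = _pair_param_grids(ff, types)
    d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
    inter = molid[:, None] < molid[None, :]   # each pair once
    ii, jj = np.nonzero(inter)
    r = d[inter]
    with np.errstate(over="ignore", under="ignore"):
        e = _nc_energy_1d(ff.form, P, ii, jj, r)
        qq = charges[ii] * charges[jj]
        if ff.form == "extended":
            f1 = gammainc(2, P["delta1"][ii, jj] * r)
        else:
            f1 = 1.0
        e += float(np.sum(f1 * KC * qq / r))
    if mode == "pure" or not ref_groups:
        return float(e)

    # hybrid substitution over geometry-matched dimers
    coms = np.array([c.mean(axis=0) for _, c in mols])
    dcom = np.linalg.norm(coms[:, None] - coms[None], axis=-1)
    cand = np.argwhere((dcom < max_ref_R + 2.0)
                       & (np.arange(nm)[:, None] < np.arange(nm)[None]))
    for i, j in cand:
        # distances straight from explicit coordinates
        diff = mols[i][1][:, None, :] - mols[j][1][None, :, :]
        dists = np.linalg.norm(diff, axis=-1)
        desc = np.sort(dists.ravel())
        group = ref_groups.get(desc.size)
        if group is None:
            continue
        D, corr = group
        err = np.max(np.abs(D - desc[None, :]), axis=1)
        k = int(np.argmin(err))
        if err[k] < match_tol:
            e += float(corr[k])
    return float(e)


def _dimer_energy_from_dists(ff, mA, mB, dists) -> float:
    total = 0.0
    for key, (ia, ib) in _pair_groups(mA, mB).items():
        p = ff.get(*key)
        qq = mA.charges[ia] * mB.charges[ib]
        total += float(np.sum(pair_energy(ff.form, p, qq, dists[ia, ib])))
    return total


# --------------------------------------------------------------------------
# the loop

def alt_csp_loop(initial_report, oracle: GroundTruth, minimized_entries,
                 rough_ff: ForceField = None, threshold: float = 1.0,
                 max_iter: int = 5, top_n: int = 20, k_shells: int = 3,
                 dims=(5, 5, 5), fit_cfg: FitConfig = None,
                 initial_refs=None, cutoff: float = 15.0,
                 minimize_kw=None):
    """Iterate {rank -> extract dimers -> oracle -> refit -> re-minimize}.

    initial_report : FitReport of the starting force field (carries the
        fitted charges; its monomers are reused for dimer extraction).
    minimized_entries : list of dicts with structure/energy from the
        initial search (already minimized with the starting force field).
    initial_refs : the training references backing the starting fit; the
        pool grows from here and never shrinks.

    Returns (ranked PolymorphSet, AltCspState).
    """
    fit_cfg = fit_cfg or FitConfig()
    minimize_kw = minimize_kw or {}
    ff = initial_report.fitted_ff
    charges = initial_report.charges
    pool = list(initial_refs or [])   # everything the fit may use
    mined = []                        # references at polymorph geometries
    pset = rank_polymorphs(cluster_structures(minimized_entries))
    state = AltCspState(iteration=0, force_field=ff, charges=charges,
                        top_structures=[], reference_pool=pool, gaps=[],
                        threshold=threshold, converged=False)

    def top_entries(ps):
        reps = sorted([e for e in ps.entries if e.get("rank") is not None],
                      key=lambda e: e["rank"])
        return reps[:top_n]

    def gaps_for(entries):
        # only references computed at the polymorphs' own dimer
        # geometries enter the hybrid substitution; loose matches against
        # unrelated training configurations would fake a disagreement
        out = []
        for e in entries:
            pure = cluster_energy(ff, e["structure"], dims=dims, mode="pure")
            hyb = cluster_energy(ff, e["structure"], dims=dims, mode="hybrid",
                                 known_refs=mined, match_tol=0.02)
            out.append(abs(pure - hyb))
        return out

    def mine(entries):
        new_cfgs = []
        for e in entries:
            new_cfgs.extend(extract_nn_dimers(e["structure"],
                                              k_shells=k_shells))
        fresh = []
        known = [dimer_descriptor(r.config) for r in mined]
        for cfg in dedupe_dimers(new_cfgs):
            desc = dimer_descriptor(cfg)
            dup = any(len(dp) == len(desc)
                      and np.max(np.abs(dp - desc)) < 0.02 for dp in known)
            if not dup:
                fresh.append(cfg)
                known.append(desc)
        if fresh:
            refs = evaluate_reference(oracle, fresh)
            mined.extend(refs)
            pool.extend(refs)

    for it in range(max_iter):
        top = top_entries(pset)
        state.iteration = it + 1
        mine(top)
        gaps = gaps_for(top)
        state.history.append({"iteration": it, "max_gap": max(gaps) if gaps
                              else 0.0, "n_refs": len(pool)})
        if gaps and max(gaps) < threshold:
            state.converged = True
            state.gaps = gaps
            break
        # refit on the pooled data and re-minimize the top structures
        report = fit_extended(pool, fit_cfg)
        ff = report.fitted_ff
        charges = report.charges
        state.force_field, state.charges = ff, charges
        new_entries = []
        for e in top:
            res = staged_minimize(rough_ff, ff, e["structure"],
                                  cutoff=cutoff, **minimize_kw)
            new_entries.append({"structure": res.structure,
                                "energy": res.energy, "id": e["id"]})
        pset = rank_polymorphs(cluster_structures(new_entries))
    else:
        if max_iter > 0:
            top = top_entries(pset)
            mine(top)
            state.gaps = gaps_for(top)
            state.converged = bool(state.gaps) and max(state.gaps) < threshold
    state.top_structures = top_entries(pset)
    state.reference_pool = pool
    return pset, state
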