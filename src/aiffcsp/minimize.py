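"""Symmetry-preserving rigid-body + cell lattice-energy minimization.

The crystal is parametrized by the free cell parameters of its space
group's crystal system plus 7 pose degrees of freedom per asymmetric-unit
molecule (fractional center of mass and a quaternion, renormalized on
evaluation), so every step satisfies the space-group symmetry exactly.
Optimization is bounded quasi-Newton (L-BFGS-B) with finite-difference
gradients.

The staged protocol minimizes first with a hole-free 12-6-1 force field
and only then with the target (extended) form, which keeps structures
out of the unphysical short-range minima the richer form can have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .crystal import (CrystalStructure, Lattice, MoleculePose,
                      lattice_energy, min_contact)
from .forcefield import ForceField

__all__ = ["MinimizationResult", "minimize_structure", "staged_minimize",
           "minimize_set", "free_cell_parameters"]


_SYSTEM_FREE = {
    "triclinic": (0, 1, 2, 3, 4, 5),
    "monoclinic": (0, 1, 2, 4),
    "orthorhombic": (0, 1, 2),
    "tetragonal": (0, 2),
    "trigonal": (0, 2),
    "hexagonal": (0, 2),
    "cubic": (0,),
}


def free_cell_parameters(crystal_system: str):
    """Indices of the free entries of (a, b, c, alpha, beta, gamma)."""
    try:
        return _SYSTEM_FREE[crystal_system]
    except KeyError:
        raise ValueError(f"unknown crystal system {crystal_system!r}")


def _complete_cell(free_vals, free_idx, template):
    params = list(template)
    for i, v in zip(free_idx, free_vals):
        params[i] = v
    a, b, c = params[:3]
    if tuple(free_idx) == (0, 2):   # tetragonal / trigonal / hexagonal
        b = a
    elif tuple(free_idx) == (0,):   # cubic
        b = c = a
    return [a, b, c] + params[3:]


@dataclass
class MinimizationResult:
    structure: CrystalStructure
    energy: float
    converged: bool
    n_iterations: int
    collapse_flag: bool
    initial_energy: float
    max_gradient: float
    message: str = ""


# per-DOF scales that bring lengths (Angstrom), angles (degrees),
# fractional coordinates and quaternion components to comparable
# magnitudes for the quasi-Newton optimizer
_LEN_SCALE, _ANG_SCALE, _FRAC_SCALE, _QUAT_SCALE = 2.0, 20.0, 0.2, 0.2


def _dof_scales(s: CrystalStructure, free_idx) -> np.ndarray:
    sc = [_LEN_SCALE if i < 3 else _ANG_SCALE for i in free_idx]
    for _ in s.asymmetric_unit:
        sc += [_FRAC_SCALE] * 3 + [_QUAT_SCALE] * 4
    return np.array(sc)


def _pack(s: CrystalStructure, free_idx):
    x = [s.lattice.parameters[i] for i in free_idx]
    for pose in s.asymmetric_unit:
        x += list(pose.frac_com)
        x += list(pose.quaternion)
    return np.array(x, float) / _dof_scales(s, free_idx)


def _unpack(x, s: CrystalStructure, free_idx):
    x = np.asarray(x, float) * _dof_scales(s, free_idx)
    template = s.lattice.parameters
    cell = _complete_cell(x[: len(free_idx)], free_idx, template)
    lat = Lattice.from_parameters(*cell)
    poses = []
    off = len(free_idx)
    for pose in s.asymmetric_unit:
        com = x[off: off + 3]
        q = x[off + 3: off + 7]
        poses.append(MoleculePose(monomer=pose.monomer,
                                  frac_com=np.array(com),
                                  quaternion=np.array(q) / np.linalg.norm(q),
                                  improper=pose.improper))
        off += 7
    return CrystalStructure(lattice=lat, space_group=s.space_group,
                            asymmetric_unit=poses, name=s.name,
                            meta=dict(s.meta))


def minimize_structure(ff: ForceField, s: CrystalStructure,
                       cutoff: float = 15.0, gtol: float = 1e-3,
                       ftol: float = 1e-9, maxiter: int = 300,
                       contact_floor: float = 0.7,
                       energy_floor: float = -500.0,
                       finite_diff_step: float = 1e-5,
                       dof=("cell", "position", "orientation"),
                       prerelax: bool = True) -> MinimizationResult:
    """Locally minimize the lattice energy over cell and pose DOF.

    ``dof`` selects which degrees of freedom vary: any subset of
    {"cell", "position", "orientation"}; cell angles are restricted to
    the space group's crystal system regardless.  Space-group symmetry
    is preserved exactly through the parametrization.  Collapses
    (intermolecular contact below ``contact_floor`` Angstrom or
    per-molecule energy below ``energy_floor`` kJ/mol) set collapse_flag
    and the structure is returned at the last safe point visited.
    """
    bad = set(dof) - {"cell", "position", "orientation"}
    if bad:
        raise ValueError(f"unknown degrees of freedom: {sorted(bad)}")
    free_idx = free_cell_parameters(s.space_group.crystal_system)
    x0 = _pack(s, free_idx)
    frozen = np.zeros(len(x0), dtype=bool)
    if "cell" not in dof:
        frozen[: len(free_idx)] = True
    for k in range(len(s.asymmetric_unit)):
        off = len(free_idx) + 7 * k
        if "position" not in dof:
            frozen[off: off + 3] = True
        if "orientation" not in dof:
            frozen[off + 3: off + 7] = True
    state = {"best_safe": None, "best_safe_E": np.inf, "collapsed": False}
    from .packing import molecular_volume
    vmol = sum(molecular_volume(p.monomer) for p in s.asymmetric_unit) \
        * s.space_group.n_ops

    def objective(x):
        try:
            x = np.where(frozen, x0, x)
            cand = _unpack(x, s, free_idx)
            # over-packed cells imply overlap; steer back before paying
            # for an energy evaluation
            pack = vmol / cand.lattice.volume
            if pack > 2.0:
                state["collapsed"] = True
                return 1e4 * pack
            E, mc = lattice_energy(ff, cand, cutoff=cutoff,
                                   return_contact=True)
        except (ValueError, FloatingPointError):
            state["collapsed"] = True
            return 1e8
        if mc < contact_floor or E < energy_floor:
            state["collapsed"] = True
            # steer away from the collapse region without discarding info
            return max(E, energy_floor) + 1e4 * max(0.0, contact_floor - mc)
        if E < state["best_safe_E"]:
            state["best_safe_E"] = E
            state["best_safe"] = x.copy()
        return E

    lo, hi = [], []
    for i in free_idx:
        if i < 3:
            lo.append(1.5)
            hi.append(60.0)
        else:
            lo.append(50.0)
            hi.append(130.0)
    for _ in s.asymmetric_unit:
        lo += [-2.0] * 3 + [-1.5] * 4
        hi += [3.0] * 3 + [1.5] * 4
    scales = _dof_scales(s, free_idx)
    lo = np.where(frozen, x0, np.array(lo) / scales)
    hi = np.where(frozen, x0, np.array(hi) / scales)
    E0 = objective(x0)
    # walk violently repulsive starts down the wall by inflating the
    # cell; otherwise the first quasi-Newton step can overshoot the
    # physical minimum into the non-interacting plateau
    if prerelax and "cell" in dof and E0 > 0:
        n_len = sum(1 for i in free_idx if i < 3)
        x_cur, E_cur = x0, E0
        for _ in range(200):
            if E_cur <= 0.0:
                break
            x_try = x_cur.copy()
            x_try[:n_len] *= 1.04
            if np.any(x_try[:n_len] > hi[:n_len]):
                break
            E_try = objective(x_try)
            if not np.isfinite(E_try) or E_try >= E_cur - 1e-10:
                break
            x_cur, E_cur = x_try, E_try
        x0, E0 = x_cur, min(E0, E_cur)
    res = _scipy_minimize(objective, x0, method="L-BFGS-B",
                          bounds=list(zip(lo, hi)),
                          options={"maxiter": maxiter, "ftol": ftol,
                                   "gtol": gtol, "eps": finite_diff_step})
    x_final = np.where(frozen, x0, res.x)
    final = _unpack(x_final, s, free_idx)
    collapsed = False
    try:
        E_final, mc = lattice_energy(ff, final, cutoff=cutoff,
                                     return_contact=True)
    except (ValueError, FloatingPointError):
        E_final, mc = np.inf, 0.0
    # a minimizer pinned at the contact-floor boundary is a collapse:
    # the true minimum lies inside the excluded region
    if mc <= contact_floor + 1e-4 or E_final < energy_floor \
            or not np.isfinite(E_final):
        collapsed = True
        if state["best_safe"] is not None:
            x_final = state["best_safe"]
            final = _unpack(x_final, s, free_idx)
            E_final = state["best_safe_E"]
        else:
            final, E_final = s.copy(), E0
    grad = np.max(np.abs(res.jac)) if res.jac is not None else np.nan
    return MinimizationResult(structure=final, energy=float(E_final),
                              converged=bool(res.success) and not collapsed,
                              n_iterations=int(res.nit),
                              collapse_flag=collapsed,
                              initial_energy=float(E0),
                              max_gradient=float(grad),
                              message=str(res.message))


def staged_minimize(rough_ff: ForceField, target_ff: ForceField,
                    s: CrystalStructure, cutoff: float = 15.0,
                    rough_maxiter: int = 150, maxiter: int = 300,
                    gtol: float = 1e-3, **kw) -> MinimizationResult:
    """Minimize with the rough 12-6-1 form first, then the target form.

    When the two force fields are the same object this reduces to a
    single minimization.
    """
    if rough_ff is not None and rough_ff is not target_ff:
        pre = minimize_structure(rough_ff, s, cutoff=cutoff, gtol=10 * gtol,
                                 ftol=1e-7, maxiter=rough_maxiter, **kw)
        start = pre.structure
    else:
        start = s
    out = minimize_structure(target_ff, start, cutoff=cutoff, gtol=gtol,
                             maxiter=maxiter, **kw)
    return out


def minimize_set(rough_ff, target_ff, structures, cutoff: float = 15.0,
                 **kw) -> list:
    """Staged minimization of a batch; result order equals input order.

    Individual failures are recorded in the result (converged=False,
    message) and never abort the batch.
    """
    results = []
    for s in structures:
        try:
            results.append(staged_minimize(rough_ff, target_ff, s,
                                           cutoff=cutoff, **kw))
        except Exception as exc:  # noqa: BLE001 - batch robustness
            results.append(MinimizationResult(
                structure=s, energy=float("nan"), converged=False,
                n_iterations=0, collapse_flag=True,
                initial_energy=float("nan"), max_gradient=float("nan"),
                message=f"failed: {exc}"))
    return results
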