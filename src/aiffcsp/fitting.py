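"""Force-field fitting to component-resolved dimer reference data.

The extended form is fitted in stages, each stage freezing the previous
one's parameters:

1. long range   -- atomic charges from the electrostatic tail, C6/C8 from
                   the induction+dispersion tail (linear, non-negative);
2. delta_1      -- charge-charge damping, fitted to the electrostatic
                   component over all separations (charges refined here);
3. delta_6/8    -- dispersion damping, fitted to the induction+dispersion
                   sum (C6/C8 refined here);
4. repulsion    -- alpha, beta, a1, a2, A12 from the total energies with
                   everything else frozen.

Charges are fitted per atom under a total-charge constraint per monomer;
atoms made equivalent by symmetry should share an atom-type label, which
ties their pair-table entries (their charges remain free and are resolved
by the data to the extent the geometry allows).

The exp-6-1 and 12-6-1 baselines are fitted jointly (few parameters) to
the total energies.  Weighting emphasises the attractive well:
w = 1 for E <= 0 and w = (E0/(E+E0))^2 for E > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .forcefield import (DimerConfiguration, ForceField, PairParameters,
                         RigidMonomer, pair_energy, tang_toennies,
                         _pair_groups)
from .units import KC, VDW_RADII

__all__ = [
    "FitConfig", "FitReport", "DimerTable",
    "fit_long_range", "fit_electrostatic_damping", "fit_dispersion_damping",
    "fit_repulsion", "fit_extended", "fit_exp61", "fit_lj1261",
    "rmse_negative", "rmse_all", "detect_holes", "remediate_holes",
    "apply_charges", "default_weights", "count_parameters", "contact_distance",
]


@dataclass
class FitConfig:
    """Knobs of the fitting protocol."""

    E0: float = 20.0                  # kJ/mol, positive-energy down-weighting scale
    asymptotic_R_threshold: float = None  # Angstrom; default 2.5 x contact distance
    barrier_min: float = 100.0        # kJ/mol, minimum acceptable hole barrier
    ridge: float = 1e-8               # regularization on linear solves
    ftol: float = 1e-14
    xtol: float = 1e-14
    gtol: float = 1e-14
    max_nfev: int = 20000
    n_starts: int = 4                 # multi-start count for nonlinear stages
    seed: int = 0
    remediate: bool = True            # enforce the hole-barrier constraint
    joint_polish: bool = False        # final all-parameter refinement pass

    def __post_init__(self):
        if self.barrier_min <= 0:
            raise ValueError("barrier_min must be > 0")


@dataclass
class FitReport:
    fitted_ff: ForceField
    charges: np.ndarray               # per charge site (atoms of A [+ B])
    rmse_negative: float
    rmse_all: float
    per_component_rmse: dict
    n_parameters: int
    hole_report: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def default_weights(totals, E0: float = 20.0) -> np.ndarray:
    """Fit weights: 1 on the attractive side, decaying on the repulsive wall."""
    totals = np.asarray(totals, float)
    w = np.ones_like(totals)
    pos = totals > 0
    w[pos] = (E0 / (totals[pos] + E0)) ** 2
    return w


def count_parameters(form: str, n_types: int, include_charges: bool = False) -> int:
    """Pair-table parameter count for n_types atom types (homodimer).

    Per unordered pair: extended 10 (alpha, beta, a1, a2, A12, C6, C8,
    delta1, delta6, delta8), exp-6-1 3 (A, beta, C6), 12-6-1 2 (A12, C6).
    """
    per_pair = {"extended": 10, "exp61": 3, "lj1261": 2}[form]
    n_pairs = n_types * (n_types + 1) // 2
    return per_pair * n_pairs + (n_types if include_charges else 0)


# --------------------------------------------------------------------------
# precomputed per-pair-type distance tables

class DimerTable:
    """Flattened view of a reference dataset, grouped by atom-type pair.

    For every pair type the intermolecular distances are stored as an
    (n_records, n_entries) array whose column order is the fixed atom-pair
    enumeration of that type; all fitting stages evaluate models through
    this table.  Charge sites are the atoms of monomer A followed by
    those of B (shared when the dataset is a homodimer of one monomer
    object).
    """

    def __init__(self, refs):
        if not refs:
            raise ValueError("empty dataset")
        self.refs = list(refs)
        cfg0 = refs[0].config
        self.mA, self.mB = cfg0.monomerA, cfg0.monomerB
        self.homodimer = self.mA is self.mB
        self.n_rec = len(refs)
        self.n_sites = self.mA.n_atoms + (0 if self.homodimer else self.mB.n_atoms)
        off = 0 if self.homodimer else self.mA.n_atoms
        groups = _pair_groups(self.mA, self.mB)
        self.pair_keys = sorted(groups)
        self.d, self.siteA, self.siteB = {}, {}, {}
        for key in self.pair_keys:
            ia, ib = groups[key]
            self.siteA[key] = ia
            self.siteB[key] = ib + off
            self.d[key] = np.stack(
                [ref.config.distances()[ia, ib] for ref in refs])
        self.R = np.array([r.config.R for r in refs])
        self.elst = np.array([r.energies.elst for r in refs])
        self.exch = np.array([r.energies.exch for r in refs])
        self.indx = np.array([r.energies.indx for r in refs])
        self.dispx = np.array([r.energies.dispx for r in refs])
        self.total = np.array([r.energies.total for r in refs])
        self.weight = np.array([r.weight for r in refs])

    def site_charges(self) -> np.ndarray:
        """Monomer charges laid out on the charge sites."""
        if self.homodimer:
            return self.mA.charges.copy()
        return np.concatenate([self.mA.charges, self.mB.charges])

    def qq(self, key, q: np.ndarray) -> np.ndarray:
        """Charge products for every atom-pair entry of one pair type."""
        return q[self.siteA[key]] * q[self.siteB[key]]

    def powersum(self, key, n, damped_delta=None, qq=None) -> np.ndarray:
        """Per-record sum of [qq] [f_n(delta, r)] / r^n for one pair type."""
        r = self.d[key]
        v = 1.0 / r ** n
        if damped_delta is not None:
            v = v * tang_toennies(n, damped_delta, r)
        if qq is not None:
            v = v * qq
        return v.sum(axis=1)

    def charge_constraints(self):
        """(A, b) with A q = b expressing fixed total charge per monomer."""
        if self.homodimer:
            A = np.ones((1, self.n_sites))
            b = np.array([self.mA.total_charge])
        else:
            nA = self.mA.n_atoms
            A = np.zeros((2, self.n_sites))
            A[0, :nA] = 1.0
            A[1, nA:] = 1.0
            b = np.array([self.mA.total_charge, self.mB.total_charge])
        return A, b

    def model_total(self, ff: ForceField, q: np.ndarray = None) -> np.ndarray:
        """Model total energies for all records."""
        if q is None:
            q = self.site_charges()
        out = np.zeros(self.n_rec)
        for key in self.pair_keys:
            p = ff.get(*key)
            e = pair_energy(ff.form, p, self.qq(key, q), self.d[key])
            out += e.sum(axis=1)
        return out


def contact_distance(mA: RigidMonomer, mB: RigidMonomer) -> float:
    """Outer estimate of the van-der-Waals contact COM separation.

    Sum of each molecule's extent (largest atom offset plus its vdW
    radius); beyond ~2.5 times this the interaction is asymptotic.
    """
    rA = mA.radius() + max(VDW_RADII.get(e, 1.7) for e in mA.elements)
    rB = mB.radius() + max(VDW_RADII.get(e, 1.7) for e in mB.elements)
    return rA + rB


def _tail_mask(tab: DimerTable, cfg: FitConfig):
    thr = cfg.asymptotic_R_threshold
    if thr is None:
        thr = 2.5 * contact_distance(tab.mA, tab.mB)
    return tab.R > thr, thr


def _nullspace(A: np.ndarray) -> np.ndarray:
    _, s, Vt = np.linalg.svd(A)
    rank = int(np.sum(s > 1e-12))
    return Vt[rank:].T


def _canonical_sign(q: np.ndarray) -> np.ndarray:
    """Flip the whole charge vector so its first charged site is positive."""
    for qi in q:
        if abs(qi) > 1e-8:
            return -q if qi < 0 else q
    return q


# --------------------------------------------------------------------------
# stage 1: long range

def fit_long_range(tab: DimerTable, cfg: FitConfig = None):
    """Charges from the electrostatic tail, C6/C8 from the 2nd-order tail.

    Charges are fitted per atom under a total-charge constraint per
    monomer, using the undamped Coulomb model on the asymptotic subset
    (damping is exponentially negligible there).  C6/C8 come from
    non-negative linear least squares on the same subset.  The charge set
    has a global sign ambiguity; the convention is that the first charged
    site is positive.

    Returns (charges per site, C6 per pair, C8 per pair).
    """
    cfg = cfg or FitConfig()
    mask, thr = _tail_mask(tab, cfg)
    A, b = tab.charge_constraints()
    N = _nullspace(A)
    n_coef = N.shape[1] + 2 * len(tab.pair_keys)
    if mask.sum() < 3 * max(n_coef, 1):
        raise ValueError(
            f"only {int(mask.sum())} asymptotic points beyond R > {thr:.2f} A; "
            f"need at least {3 * n_coef} for {n_coef} coefficients")
    q0, *_ = np.linalg.lstsq(A, b, rcond=None)
    y_el = tab.elst[mask]
    inv_r = {key: (1.0 / tab.d[key][mask]) for key in tab.pair_keys}

    def charge_resid(z):
        q = q0 + N @ z
        model = np.zeros(int(mask.sum()))
        for key in tab.pair_keys:
            model += KC * (inv_r[key] * tab.qq(key, q)).sum(axis=1)
        return model - y_el

    rng = np.random.default_rng(cfg.seed)
    best = (np.inf, np.zeros(N.shape[1]))
    starts = [np.zeros(N.shape[1])] + [
        0.3 * rng.standard_normal(N.shape[1]) for _ in range(cfg.n_starts)]
    for z0 in starts:
        if N.shape[1] == 0:
            best = (0.0, z0)
            break
        res = least_squares(charge_resid, z0, ftol=cfg.ftol, xtol=cfg.xtol,
                            gtol=cfg.gtol, max_nfev=cfg.max_nfev)
        if res.cost < best[0]:
            best = (res.cost, res.x)
    q = _canonical_sign(q0 + N @ best[1])

    # resolving C6 from C8 needs the deep tail, where residual damping
    # is negligible compared with the r^-8/r^-6 contrast
    cmask = tab.R > 1.5 * thr
    if cmask.sum() < 3 * 2 * len(tab.pair_keys):
        cmask = mask

    def _nnls_on(sel):
        cols = [tab.powersum(key, 6)[sel] for key in tab.pair_keys]
        cols += [tab.powersum(key, 8)[sel] for key in tab.pair_keys]
        M = np.column_stack(cols)
        y = -(tab.indx[sel] + tab.dispx[sel])
        # column normalization keeps the ridge scale-free
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        Mr = np.vstack([M / norms, np.sqrt(cfg.ridge) * np.eye(M.shape[1])])
        yr = np.concatenate([y, np.zeros(M.shape[1])])
        coef, _ = nnls(Mr, yr)
        return coef / norms

    coef = _nnls_on(cmask)
    if not np.any(coef > 0):
        # the deep tail can drown in noise; the full asymptotic subset
        # trades a small damping bias for signal (the damping stage
        # refines the coefficients afterwards anyway)
        coef = _nnls_on(mask)
    C6 = dict(zip(tab.pair_keys, coef[: len(tab.pair_keys)]))
    C8 = dict(zip(tab.pair_keys, coef[len(tab.pair_keys):]))
    return q, C6, C8


# --------------------------------------------------------------------------
# stage 2: electrostatic damping

def fit_electrostatic_damping(tab: DimerTable, charges: np.ndarray,
                              cfg: FitConfig = None, refine_charges: bool = True):
    """Fit delta_1 per pair to the electrostatic component over all R.

    The tail-fitted charges serve as the starting point; by default they
    are refined jointly with delta_1, since the damped model holds at
    every separation and the close-range points sharpen the charges far
    beyond what the asymptotic subset alone can deliver.  Pairs whose
    charge products all vanish are unidentifiable: they are flagged and
    assigned the default delta_1 = 2.0/Angstrom.

    Returns (delta1 per pair, refined charges, flags).
    """
    cfg = cfg or FitConfig()
    qq0 = {k: tab.qq(k, charges) for k in tab.pair_keys}
    active = [k for k in tab.pair_keys if np.abs(qq0[k]).max() > 1e-10]
    flags = {k: "default (uncharged pair)" for k in tab.pair_keys if k not in active}
    delta1 = {k: 2.0 for k in tab.pair_keys}
    if not active:
        return delta1, charges.copy(), flags

    A, b = tab.charge_constraints()
    N = _nullspace(A)
    nz = N.shape[1] if refine_charges else 0
    q_base, *_ = np.linalg.lstsq(A, b, rcond=None)
    z0 = N.T @ (charges - q_base) if nz else np.zeros(0)

    def unpack(x):
        q = (q_base + N @ x[:nz]) if nz else charges
        d1 = {k: np.exp(xi) for k, xi in zip(active, x[nz:])}
        return q, d1

    def resid(x):
        q, d1 = unpack(x)
        model = np.zeros(tab.n_rec)
        for k in active:
            model += KC * tab.powersum(k, 1, damped_delta=d1[k],
                                       qq=tab.qq(k, q))
        return model - tab.elst

    x0 = np.concatenate([z0, np.log(np.full(len(active), 2.0))])
    lo = np.concatenate([np.full(nz, -np.inf), np.full(len(active), np.log(0.05))])
    hi = np.concatenate([np.full(nz, np.inf), np.full(len(active), np.log(50.0))])
    res = least_squares(resid, x0, bounds=(lo, hi), ftol=cfg.ftol,
                        xtol=cfg.xtol, gtol=cfg.gtol, max_nfev=cfg.max_nfev)
    if res.status <= 0:
        flags["convergence"] = res.message
    q, d1 = unpack(res.x)
    delta1.update({k: float(v) for k, v in d1.items()})
    return delta1, _canonical_sign(np.asarray(q, float)), flags


# --------------------------------------------------------------------------
# stage 3: dispersion damping

def fit_dispersion_damping(tab: DimerTable, C6: dict, C8: dict,
                           cfg: FitConfig = None, refine_C: bool = True):
    """Fit delta_6, delta_8 per pair to the induction+dispersion sum.

    The tail-fitted C6/C8 initialise the fit and by default are refined
    jointly with the damping parameters over all separations (close-range
    data are what resolves per-pair coefficients when the atom types sit
    close together in the molecule).  Non-negativity of C6/C8 is kept by
    a square parametrization.

    Returns (delta6, delta8, refined C6, refined C8, flags).
    """
    cfg = cfg or FitConfig()
    keys = tab.pair_keys
    if all(C6[k] == 0 and C8[k] == 0 for k in keys):
        raise ValueError("all C6 and C8 are zero: nothing to damp")
    y = tab.indx + tab.dispx
    nC = 2 * len(keys) if refine_C else 0

    def unpack(x):
        if refine_C:
            c6 = {k: x[2 * i] ** 2 for i, k in enumerate(keys)}
            c8 = {k: x[2 * i + 1] ** 2 for i, k in enumerate(keys)}
        else:
            c6, c8 = C6, C8
        d6 = {k: np.exp(x[nC + 2 * i]) for i, k in enumerate(keys)}
        d8 = {k: np.exp(x[nC + 2 * i + 1]) for i, k in enumerate(keys)}
        return c6, c8, d6, d8

    def resid(x):
        c6, c8, d6, d8 = unpack(x)
        model = np.zeros(tab.n_rec)
        for k in keys:
            model -= c6[k] * tab.powersum(k, 6, damped_delta=d6[k])
            model -= c8[k] * tab.powersum(k, 8, damped_delta=d8[k])
        return model - y

    lo = np.concatenate([np.full(nC, 0.0), np.full(2 * len(keys), np.log(0.05))])
    hi = np.concatenate([np.full(nC, np.inf), np.full(2 * len(keys), np.log(50.0))])
    best = None
    for d0 in (2.0, 1.4, 2.8)[: max(1, cfg.n_starts - 1)]:
        x0 = []
        if refine_C:
            for k in keys:
                x0 += [np.sqrt(max(C6[k], 1.0)), np.sqrt(max(C8[k], 1.0))]
        x0 += [np.log(d0)] * (2 * len(keys))
        res = least_squares(resid, np.array(x0), bounds=(lo, hi), ftol=cfg.ftol,
                            xtol=cfg.xtol, gtol=cfg.gtol, max_nfev=cfg.max_nfev,
                            x_scale="jac")
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-20 * tab.n_rec:
            break
    c6, c8, d6, d8 = unpack(best.x)
    flags = {} if best.status > 0 else {"convergence": best.message}
    return ({k: float(d6[k]) for k in keys}, {k: float(d8[k]) for k in keys},
            {k: float(c6[k]) for k in keys}, {k: float(c8[k]) for k in keys},
            flags)


# --------------------------------------------------------------------------
# stage 4: repulsion

def fit_repulsion(tab: DimerTable, ff_frozen: ForceField, charges: np.ndarray,
                  cfg: FitConfig = None) -> ForceField:
    """Fit alpha, beta, a1, a2, A12 per pair to the total energies.

    All long-range and damping parameters stay frozen; the residual is
    the weighted difference between the full extended model and the
    reference totals.  Multi-start over beta avoids the worst local
    minima of the exponential model.
    """
    cfg = cfg or FitConfig()
    keys = tab.pair_keys
    frozen = np.zeros(tab.n_rec)
    for k in keys:
        p = ff_frozen.get(*k)
        frozen += KC * tab.powersum(k, 1, damped_delta=p.delta1,
                                    qq=tab.qq(k, charges))
        frozen -= p.C6 * tab.powersum(k, 6, damped_delta=p.delta6)
        frozen -= p.C8 * tab.powersum(k, 8, damped_delta=p.delta8)
    target = tab.total - frozen
    w = np.sqrt(default_weights(tab.total, cfg.E0) * tab.weight)

    def resid(x):
        model = np.zeros(tab.n_rec)
        for i, k in enumerate(keys):
            al, lb, a1, a2, lA = x[5 * i: 5 * i + 5]
            r = tab.d[k]
            v = (1.0 + a1 * r + a2 * r * r) * np.exp(al - np.exp(lb) * r)
            v = v + np.exp(lA) / r ** 12
            model += v.sum(axis=1)
        return w * (model - target)

    lo = np.tile([-10.0, np.log(0.5), -50.0, -50.0, -20.0], len(keys))
    hi = np.tile([60.0, np.log(10.0), 50.0, 50.0, 40.0], len(keys))
    best = None
    for beta0 in (2.5, 3.5, 4.5)[: max(1, cfg.n_starts - 1)]:
        x0 = np.tile([8.0, np.log(beta0), 0.0, 0.0, np.log(10.0)], len(keys))
        res = least_squares(resid, x0, bounds=(lo, hi), ftol=cfg.ftol,
                            xtol=cfg.xtol, gtol=cfg.gtol, max_nfev=cfg.max_nfev,
                            x_scale="jac")
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-18 * tab.n_rec:
            break
    ff = ff_frozen.copy()
    for i, k in enumerate(keys):
        al, lb, a1, a2, lA = best.x[5 * i: 5 * i + 5]
        p = ff.get(*k)
        ff.pair_table[k] = p.copy(alpha=float(al), beta=float(np.exp(lb)),
                                  a1=float(a1), a2=float(a2),
                                  A12=float(np.exp(lA)))
    ff._fit_cost = float(best.cost)
    return ff


# --------------------------------------------------------------------------
# full protocols

def apply_charges(m: RigidMonomer, charges: np.ndarray) -> RigidMonomer:
    """Return a copy of the monomer carrying fitted per-atom charges."""
    return RigidMonomer(elements=list(m.elements), coords=m.coords.copy(),
                        charges=np.asarray(charges[: m.n_atoms], float),
                        types=list(m.types), masses=m.masses.copy(),
                        name=m.name)


def _finalize(tab, ff, charges, cfg, extra=None) -> FitReport:
    mA = apply_charges(tab.mA, charges)
    mB = mA if tab.homodimer else apply_charges(
        tab.mB, charges[tab.mA.n_atoms:])
    model = tab.model_total(ff, charges)
    neg = tab.total < 0
    rn = float(np.sqrt(np.mean((model[neg] - tab.total[neg]) ** 2))) if neg.any() else float("nan")
    ra = float(np.sqrt(np.mean((model - tab.total) ** 2)))
    per_comp = {}
    if ff.form == "extended":
        elst_model = np.zeros(tab.n_rec)
        sec_model = np.zeros(tab.n_rec)
        for k in tab.pair_keys:
            p = ff.get(*k)
            elst_model += KC * tab.powersum(k, 1, damped_delta=p.delta1,
                                            qq=tab.qq(k, charges))
            sec_model -= p.C6 * tab.powersum(k, 6, damped_delta=p.delta6)
            sec_model -= p.C8 * tab.powersum(k, 8, damped_delta=p.delta8)
        per_comp["elst"] = float(np.sqrt(np.mean((elst_model - tab.elst) ** 2)))
        per_comp["indx+dispx"] = float(
            np.sqrt(np.mean((sec_model - tab.indx - tab.dispx) ** 2)))
    A, _ = tab.charge_constraints()
    n_par = ({"extended": 10, "exp61": 3, "lj1261": 2}[ff.form]
             * len(tab.pair_keys) + (tab.n_sites - A.shape[0]))
    report = FitReport(fitted_ff=ff, charges=np.asarray(charges, float),
                       rmse_negative=rn, rmse_all=ra,
                       per_component_rmse=per_comp, n_parameters=n_par,
                       diagnostics=extra or {})
    report.monomerA, report.monomerB = mA, mB
    if cfg.remediate and ff.form in ("extended", "exp61"):
        holes = detect_holes(ff, mA, mB, barrier_min=cfg.barrier_min, seed=cfg.seed)
        if any(h["flagged"] for h in holes):
            remediate_holes(ff, mA, mB, barrier_min=cfg.barrier_min, seed=cfg.seed)
            holes = detect_holes(ff, mA, mB, barrier_min=cfg.barrier_min, seed=cfg.seed)
        report.hole_report = holes
    return report


def fit_extended(refs, cfg: FitConfig = None) -> FitReport:
    """Run the staged extended-form fit on a reference dataset."""
    cfg = cfg or FitConfig()
    tab = refs if isinstance(refs, DimerTable) else DimerTable(refs)
    charges, C6, C8 = fit_long_range(tab, cfg)
    delta1, charges, flags = fit_electrostatic_damping(tab, charges, cfg)
    delta6, delta8, C6, C8, dflags = fit_dispersion_damping(tab, C6, C8, cfg)
    ff = ForceField("extended")
    for k in tab.pair_keys:
        ff.pair_table[k] = PairParameters(C6=C6[k], C8=C8[k], delta1=delta1[k],
                                          delta6=delta6[k], delta8=delta8[k])
    ff = fit_repulsion(tab, ff, charges, cfg)
    if cfg.joint_polish:
        ff, charges = _joint_polish(tab, ff, charges, cfg)
    return _finalize(tab, ff, charges, cfg, extra={**flags, **dflags})


def _joint_polish(tab: DimerTable, ff: ForceField, charges: np.ndarray,
                  cfg: FitConfig):
    """Optional final pass: refine all extended-form parameters jointly
    against the weighted totals, starting from the staged solution."""
    keys = tab.pair_keys
    A, b = tab.charge_constraints()
    N = _nullspace(A)
    q_base, *_ = np.linalg.lstsq(A, b, rcond=None)
    nz = N.shape[1]
    z0 = N.T @ (charges - q_base)
    w = np.sqrt(default_weights(tab.total, cfg.E0) * tab.weight)

    def unpack(x):
        q = q_base + N @ x[:nz]
        table = {}
        for i, k in enumerate(keys):
            v = x[nz + 10 * i: nz + 10 * i + 10]
            table[k] = PairParameters(
                alpha=v[0], beta=np.exp(v[1]), a1=v[2], a2=v[3],
                A12=np.exp(v[4]), C6=v[5] ** 2, C8=v[6] ** 2,
                delta1=np.exp(v[7]), delta6=np.exp(v[8]),
                delta8=np.exp(v[9]))
        return q, table

    def resid(x):
        q, table = unpack(x)
        model = np.zeros(tab.n_rec)
        for k in keys:
            model += pair_energy("extended", table[k], tab.qq(k, q),
                                 tab.d[k]).sum(axis=1)
        return w * (model - tab.total)

    x0 = list(z0)
    for k in keys:
        p = ff.get(*k)
        x0 += [p.alpha, np.log(p.beta), p.a1, p.a2,
               np.log(max(p.A12, 1e-8)), np.sqrt(p.C6), np.sqrt(p.C8),
               np.log(p.delta1), np.log(p.delta6), np.log(p.delta8)]
    lo = np.concatenate([np.full(nz, -np.inf),
                         np.tile([-10.0, np.log(0.5), -50.0, -50.0, -20.0,
                                  0.0, 0.0, np.log(0.05), np.log(0.05),
                                  np.log(0.05)], len(keys))])
    hi = np.concatenate([np.full(nz, np.inf),
                         np.tile([60.0, np.log(10.0), 50.0, 50.0, 40.0,
                                  1e3, 1e4, np.log(50.0), np.log(50.0),
                                  np.log(50.0)], len(keys))])
    res = least_squares(resid, np.clip(np.array(x0), lo, hi),
                        bounds=(lo, hi), ftol=cfg.ftol, xtol=cfg.xtol,
                        gtol=cfg.gtol, max_nfev=cfg.max_nfev, x_scale="jac")
    q, table = unpack(res.x)
    out = ForceField("extended")
    for k in keys:
        p = table[k]
        out.pair_table[k] = PairParameters(
            alpha=float(p.alpha), beta=float(p.beta), a1=float(p.a1),
            a2=float(p.a2), A12=float(p.A12), C6=float(p.C6),
            C8=float(p.C8), delta1=float(p.delta1), delta6=float(p.delta6),
            delta8=float(p.delta8))
    return out, _canonical_sign(np.asarray(q, float))


def _fit_simple(refs, form: str, cfg: FitConfig = None) -> FitReport:
    cfg = cfg or FitConfig()
    tab = refs if isinstance(refs, DimerTable) else DimerTable(refs)
    charges, C6, C8 = fit_long_range(tab, cfg)
    keys = tab.pair_keys
    w = np.sqrt(default_weights(tab.total, cfg.E0) * tab.weight)
    A, b = tab.charge_constraints()
    N = _nullspace(A)
    q_base, *_ = np.linalg.lstsq(A, b, rcond=None)
    nz = N.shape[1]
    z0 = N.T @ (charges - q_base)

    def unpack(x):
        q = q_base + N @ x[:nz]
        pars = {}
        for i, k in enumerate(keys):
            a, lb, lC = x[nz + 3 * i: nz + 3 * i + 3]
            pars[k] = (np.exp(a), np.exp(lb), np.exp(lC))
        return q, pars

    def resid(x):
        q, pars = unpack(x)
        model = np.zeros(tab.n_rec)
        for k in keys:
            Aa, bb, cc = pars[k]
            r = tab.d[k]
            if form == "exp61":
                v = Aa * np.exp(-bb * r) - cc / r ** 6
            else:  # lj1261; bb is unused
                v = Aa / r ** 12 - cc / r ** 6
            v = v + KC * tab.qq(k, q) / r
            model += v.sum(axis=1)
        return w * (model - tab.total)

    x0 = list(z0)
    for k in keys:
        c0 = max(C6[k], 1e-3)
        if form == "exp61":
            x0 += [np.log(1e5), np.log(3.5), np.log(c0)]
        else:
            x0 += [np.log(1e4), 0.0, np.log(c0)]
    lo = np.concatenate([np.full(nz, -np.inf),
                         np.tile([-20.0, np.log(0.5), -20.0], len(keys))])
    hi = np.concatenate([np.full(nz, np.inf),
                         np.tile([45.0, np.log(10.0), 45.0], len(keys))])
    best = None
    for scale in (1.0, 2.0):
        xs = np.array(x0, float)
        xs[nz::3] += np.log(scale)
        res = least_squares(resid, xs, bounds=(lo, hi), ftol=cfg.ftol,
                            xtol=cfg.xtol, gtol=cfg.gtol,
                            max_nfev=cfg.max_nfev, x_scale="jac")
        if best is None or res.cost < best.cost:
            best = res
    q, pars = unpack(best.x)
    q = _canonical_sign(np.asarray(q, float))
    ff = ForceField(form)
    for k in keys:
        Aa, bb, cc = pars[k]
        if form == "exp61":
            ff.pair_table[k] = PairParameters(A=float(Aa), beta=float(bb),
                                              C6=float(cc))
        else:
            ff.pair_table[k] = PairParameters(A12=float(Aa), C6=float(cc))
    return _finalize(tab, ff, q, cfg)


def fit_exp61(refs, cfg: FitConfig = None) -> FitReport:
    """Fit the Buckingham exp-6-1 baseline to total energies."""
    return _fit_simple(refs, "exp61", cfg)


def fit_lj1261(refs, cfg: FitConfig = None) -> FitReport:
    """Fit the Lennard-Jones 12-6-1 baseline to total energies."""
    return _fit_simple(refs, "lj1261", cfg)


# --------------------------------------------------------------------------
# diagnostics

def rmse_negative(ff: ForceField, refs, charges: np.ndarray = None) -> float:
    """RMSE of the model over records with negative reference total.

    Returns NaN (flagged empty set) when no record is attractive.  If
    ``charges`` is omitted, the monomers' own charges are used.
    """
    tab = refs if isinstance(refs, DimerTable) else DimerTable(refs)
    model = tab.model_total(ff, charges)
    neg = tab.total < 0
    if not neg.any():
        warnings.warn("no negative-energy records; rmse_negative is NaN")
        return float("nan")
    return float(np.sqrt(np.mean((model[neg] - tab.total[neg]) ** 2)))


def rmse_all(ff: ForceField, refs, charges: np.ndarray = None) -> float:
    tab = refs if isinstance(refs, DimerTable) else DimerTable(refs)
    model = tab.model_total(ff, charges)
    return float(np.sqrt(np.mean((model - tab.total) ** 2)))


def detect_holes(ff: ForceField, mA: RigidMonomer, mB: RigidMonomer,
                 n_orientations: int = 12, seed: int = 0,
                 r_min: float = 0.3, dr: float = 0.02,
                 barrier_min: float = 100.0) -> list:
    """Scan radially inward for unphysical short-range minima ("holes").

    For each random relative orientation the dimer energy is evaluated on
    a dense center-of-mass distance grid from well outside van der Waals
    contact down to r_min.  A hole is a region where the energy drops
    below the physical (outermost) minimum after crossing a repulsive
    barrier; the barrier height relative to the physical minimum is
    reported per orientation and flagged when below ``barrier_min``.
    """
    from .oracle import _random_rotation  # local import to avoid a cycle
    rng = np.random.default_rng(seed)
    R_max = 3.0 * contact_distance(mA, mB)
    groups = _pair_groups(mA, mB)
    report = []
    for io in range(n_orientations):
        rot = _random_rotation(rng)
        direction = _random_rotation(rng)[:, 0]
        R_grid = np.arange(R_max, r_min, -dr)
        energies, radii = [], []
        for R in R_grid:
            cfg = DimerConfiguration(mA, mB, rotB=rot, tranB=R * direction)
            dist = cfg.distances()
            if dist.min() < 0.05:
                break
            e = 0.0
            for key, (ia, ib) in groups.items():
                p = ff.get(*key)
                qq = mA.charges[ia] * mB.charges[ib]
                e += float(np.sum(pair_energy(ff.form, p, qq, dist[ia, ib])))
            energies.append(e)
            radii.append(R)
        entry = {"orientation": io, "has_hole": False, "barrier": float("inf"),
                 "r_hole": None, "flagged": False}
        E = np.array(energies)
        if len(E) >= 3:
            i_phys = None
            for i in range(1, len(E) - 1):
                if E[i] <= E[i - 1] and E[i] < E[i + 1]:
                    i_phys = i
                    break
            if i_phys is not None:
                inner = E[i_phys:]
                j = int(np.argmin(inner)) + i_phys
                if E[j] < E[i_phys] - 1e-9 and j > i_phys:
                    barrier = float(np.max(E[i_phys:j + 1]) - E[i_phys])
                    entry.update(has_hole=True, barrier=barrier,
                                 r_hole=float(radii[j]),
                                 flagged=barrier < barrier_min)
        report.append(entry)
    return report


def remediate_holes(ff: ForceField, mA: RigidMonomer, mB: RigidMonomer,
                    barrier_min: float = 100.0, seed: int = 0,
                    max_doublings: int = 20) -> ForceField:
    """Raise the repulsive core until all hole barriers exceed barrier_min.

    Scales A12 (extended form) or the exponential prefactor A (exp-6-1)
    by exponential search on a common factor followed by bisection;
    12-6-1 force fields are returned unchanged (they cannot have holes
    for positive A12).
    """
    if ff.form == "lj1261":
        return ff
    attr = "A12" if ff.form == "extended" else "A"
    base = {k: getattr(p, attr) for k, p in ff.pair_table.items()}

    def ok(scale):
        for k, p in ff.pair_table.items():
            ff.pair_table[k] = p.copy(
                **{attr: max(base[k], 1e-3) * scale})
        holes = detect_holes(ff, mA, mB, seed=seed, barrier_min=barrier_min)
        return not any(h["flagged"] for h in holes)

    lo, hi = 1.0, 1.0
    for _ in range(max_doublings):
        if ok(hi):
            break
        lo, hi = hi, hi * 2
    else:
        raise RuntimeError("hole remediation failed to bracket a safe A12 scale")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-3 * hi:
            break
    ok(hi)
    return ff
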