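"""Synthetic reference-energy oracle.

Stands in for the quantum-chemistry stage: component-resolved dimer
interaction energies (electrostatics, first-order exchange, induction,
dispersion) are produced by a *hidden* ground-truth potential of the
extended analytic form, with optional independent Gaussian noise per
component.  Everything downstream (fitting, crystal search, iterative
refinement) only sees the tabulated reference energies, exactly as it
would with real ab initio data supplied in the same tabular format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefield import (DimerConfiguration, ForceField, RigidMonomer,
                         dimer_component_energies)

__all__ = [
    "ComponentEnergies",
    "DimerReference",
    "GroundTruth",
    "sample_dimer_configurations",
    "evaluate_reference",
    "radial_scan",
    "write_dataset",
    "read_dataset",
]


@dataclass
class ComponentEnergies:
    """Component-resolved interaction energies, kJ/mol.

    elst  : electrostatics
    exch  : first-order exchange (repulsion)
    indx  : second-order induction + exchange-induction
    dispx : dispersion + exchange-dispersion
    """

    elst: float
    exch: float
    indx: float
    dispx: float

    @property
    def total(self) -> float:
        return self.elst + self.exch + self.indx + self.dispx


@dataclass
class DimerReference:
    """One reference grid point: a dimer geometry plus its energies."""

    config: DimerConfiguration
    energies: ComponentEnergies
    weight: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass
class GroundTruth:
    """Hidden truth potential + component-splitting rule + noise model.

    component_split maps the n=6 and n=8 damped terms onto the dispersion
    and induction channels.  The default assigns -f6*C6/r^6 to dispx and
    -f8*C8/r^8 to indx; any split is fine for exercising the fit, which
    only ever uses the indx+dispx sum.
    """

    truth_ff: ForceField
    noise_sigma: float = 0.0
    seed: int = 0
    component_split: dict = field(
        default_factory=lambda: {"dispx": ("dispx",), "indx": ("indx",)})
    charges: np.ndarray = None  # truth per-atom charges (per monomer)

    def __post_init__(self):
        if self.truth_ff.form != "extended":
            raise ValueError("ground truth must use the extended form")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def with_truth_charges(self, cfg: DimerConfiguration) -> DimerConfiguration:
        """Re-dress a configuration's monomers with the truth charges.

        Configurations mined from predicted crystals carry fitted
        charges; the hidden reference potential must always be evaluated
        with its own charge set.
        """
        if self.charges is None:
            return cfg

        def dress(m):
            from .forcefield import RigidMonomer as _RM
            return _RM(elements=list(m.elements), coords=m.coords.copy(),
                       charges=np.asarray(self.charges[: m.n_atoms], float),
                       types=list(m.types), masses=m.masses.copy(),
                       name=m.name)

        mA = dress(cfg.monomerA)
        mB = mA if cfg.monomerB is cfg.monomerA else dress(cfg.monomerB)
        return DimerConfiguration(mA, mB, rotB=cfg.rotB, tranB=cfg.tranB,
                                  rotA=cfg.rotA, tranA=cfg.tranA)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (from a uniform unit quaternion)."""
    u1, u2, u3 = rng.random(3)
    q = np.array([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ])
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def sample_dimer_configurations(mA: RigidMonomer, mB: RigidMonomer, n: int,
                                seed: int, R_range=(3.0, 12.0),
                                min_contact: float = 1.5,
                                tail_fraction: float = 0.3,
                                max_attempts: int = 10000) -> list:
    """Sample n dimer configurations with random relative orientations.

    Center-of-mass separations: a fraction (1 - tail_fraction) is drawn
    uniformly over R_range (the interaction region), the rest log-spaced
    over (R_max, 3*R_max) to anchor the asymptotics.  Orientations are
    uniform rotations; configurations violating the minimum atom-atom
    contact are rejected and resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = R_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid R_range {R_range}")
    if min_contact <= 0:
        raise ValueError("min_contact must be > 0")
    rng = np.random.default_rng(seed)
    n_tail = int(round(tail_fraction * n))
    n_core = n - n_tail
    R_core = rng.uniform(lo, hi, size=n_core)
    R_tail = np.geomspace(hi, 3 * hi, n_tail + 1)[1:] if n_tail else np.array([])
    configs = []
    for R in np.concatenate([R_core, R_tail]):
        for attempt in range(max_attempts):
            rot = _random_rotation(rng)
            direction = _random_rotation(rng)[:, 0]
            cfg = DimerConfiguration(mA, mB, rotB=rot, tranB=R * direction)
            if cfg.min_distance() >= min_contact:
                configs.append(cfg)
                break
        else:
            raise RuntimeError(
                f"could not satisfy min_contact={min_contact} A at R={R:.2f} A "
                f"after {max_attempts} attempts")
    return configs


def evaluate_reference(gt: GroundTruth, configs) -> list:
    """Evaluate the hidden truth on each configuration.

    Components follow the truth potential's term structure; independent
    Gaussian noise of sd noise_sigma is added per component and the total
    is re-summed afterwards, so the component sum is conserved exactly.
    """
    rng = np.random.default_rng(gt.seed)
    refs = []
    for cfg in configs:
        comp = dimer_component_energies(gt.truth_ff, gt.with_truth_charges(cfg))
        split = gt.component_split
        dispx = sum(comp[c] for c in split["dispx"])
        indx = sum(comp[c] for c in split["indx"])
        e = ComponentEnergies(elst=comp["elst"], exch=comp["exch"],
                              indx=indx, dispx=dispx)
        if gt.noise_sigma > 0:
            eps = rng.normal(0.0, gt.noise_sigma, size=4)
            e = ComponentEnergies(elst=e.elst + eps[0], exch=e.exch + eps[1],
                                  indx=e.indx + eps[2], dispx=e.dispx + eps[3])
        refs.append(DimerReference(config=cfg, energies=e))
    return refs


def radial_scan(gt: GroundTruth, mA: RigidMonomer, mB: RigidMonomer,
                rotB: np.ndarray, direction, R_list) -> pd.DataFrame:
    """Noise-free component energies along a center-of-mass approach.

    Rows with atom overlaps (any intermolecular distance < 0.1 A) are
    flagged and their energies set to NaN rather than raising.
    """
    R_list = np.asarray(R_list, dtype=float)
    if np.any(np.diff(R_list) < 0):
        raise ValueError("R_list must be sorted ascending")
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    rows = []
    for R in R_list:
        cfg = DimerConfiguration(mA, mB, rotB=rotB, tranB=R * direction)
        if cfg.min_distance() < 0.1:
            rows.append({"R": R, "elst": np.nan, "exch": np.nan,
                         "indx": np.nan, "dispx": np.nan, "total": np.nan,
                         "overlap": True})
            continue
        comp = dimer_component_energies(gt.truth_ff, cfg)
        split = gt.component_split
        rows.append({"R": R, "elst": comp["elst"], "exch": comp["exch"],
                     "indx": sum(comp[c] for c in split["indx"]),
                     "dispx": sum(comp[c] for c in split["dispx"]),
                     "total": comp["total"], "overlap": False})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# tabular dataset I/O

def write_dataset(refs, path) -> None:
    """Write references as a TSV: id, flattened B pose, R, energies, weight.

    The monomers themselves are not stored; datasets are always read back
    against the monomer pair they were generated for.
    """
    rows = []
    for i, ref in enumerate(refs):
        cfg = ref.config
        row = {"id": i, "R": cfg.R}
        for j in range(3):
            for k in range(3):
                row[f"rotB{j}{k}"] = cfg.rotB[j, k]
        for j in range(3):
            row[f"tranB{j}"] = cfg.tranB[j]
        e = ref.energies
        row.update(elst=e.elst, exch=e.exch, indx=e.indx, dispx=e.dispx,
                   total=e.total, weight=ref.weight)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_dataset(path, mA: RigidMonomer, mB: RigidMonomer) -> list:
    df = pd.read_csv(path, sep="\t")
    refs = []
    for _, row in df.iterrows():
        rot = np.array([[row[f"rotB{j}{k}"] for k in range(3)] for j in range(3)])
        tran = np.array([row[f"tranB{j}"] for j in range(3)])
        cfg = DimerConfiguration(mA, mB, rotB=rot, tranB=tran)
        e = ComponentEnergies(elst=row["elst"], exch=row["exch"],
                              indx=row["indx"], dispx=row["dispx"])
        refs.append(DimerReference(config=cfg, energies=e, weight=row["weight"]))
    return refs
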