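"""End-to-end orchestration: dataset -> fit -> pack -> minimize -> rank.

A run is driven by a RunConfig (optionally loaded from a YAML file).  The
reference-energy stage is pluggable: either the built-in synthetic
oracle (a hidden extended-form potential) or an external tabular dataset
in the same format.  Outputs are written as plain-text tables, CIF
files, and a JSON reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .altcsp import alt_csp_loop
from .crystal import density, lattice_energy, read_cif, write_cif
from .fitting import FitConfig, fit_exp61, fit_extended, fit_lj1261
from .forcefield import (ForceField, PairParameters, RigidMonomer,
                         read_xyz, save_forcefield)
from .minimize import minimize_set
from .oracle import (GroundTruth, evaluate_reference, read_dataset,
                     sample_dimer_configurations, write_dataset)
from .packing import (CandidateSet, GenerationConfig, grid_generate,
                      random_generate_step1, random_generate_step2,
                      select_densest)
from .rank_cluster import (cluster_structures, landscape_table,
                           rank_polymorphs, rmsd_n)

__all__ = ["RunConfig", "run_csp", "compare_forms", "fixture_monomers",
           "default_ground_truth", "build_reference_dataset"]

log = logging.getLogger("aiffcsp")


# --------------------------------------------------------------------------
# fixture molecules (exact coordinates embedded; COM re-centering is
# automatic in RigidMonomer)

def fixture_monomers() -> dict:
    """Small rigid molecules for synthetic studies.

    diatomic   : polar heteronuclear diatomic, one shared atom type so a
                 single pair-parameter set governs all atom pairs
    methanolish: six-atom methanol-like polar molecule (C, O, 4 H)
    ring       : planar aromatic C6H6 ring
    """
    diatomic = RigidMonomer(
        elements=["N", "O"],
        coords=[[0.0, 0.0, 0.0], [0.0, 0.0, 1.15]],
        charges=[0.30, -0.30], types=["X", "X"], name="diatomic")
    methanolish = RigidMonomer(
        elements=["C", "O", "H", "H", "H", "H"],
        coords=[[0.047, 0.664, 0.0], [0.047, -0.758, 0.0],
                [-0.986, 1.031, 0.0], [0.557, 1.045, 0.889],
                [0.557, 1.045, -0.889], [-0.869, -1.058, 0.0]],
        charges=[0.145, -0.683, 0.040, 0.040, 0.040, 0.418],
        types=["C", "O", "H", "H", "H", "Ho"], name="methanolish")
    cc, ch = 1.391, 1.088
    ring_coords, ring_el, ring_q, ring_t = [], [], [], []
    for k in range(6):
        th = np.pi / 3 * k
        ring_coords.append([cc * np.cos(th), cc * np.sin(th), 0.0])
        ring_el.append("C")
        ring_q.append(-0.115)
        ring_t.append("C")
    for k in range(6):
        th = np.pi / 3 * k
        rr = cc + ch
        ring_coords.append([rr * np.cos(th), rr * np.sin(th), 0.0])
        ring_el.append("H")
        ring_q.append(0.115)
        ring_t.append("H")
    ring = RigidMonomer(elements=ring_el, coords=ring_coords,
                        charges=ring_q, types=ring_t, name="ring")
    return {"diatomic": diatomic, "methanolish": methanolish, "ring": ring}


_TRUTH_BASE = {
    # per-type (alpha, beta, C6) bases; pairs combine by averaging/geometric
    "X": (9.0, 3.2, 1100.0),
    "C": (9.5, 3.4, 1300.0),
    "O": (8.8, 3.8, 700.0),
    "N": (9.1, 3.6, 900.0),
    "H": (6.5, 3.9, 120.0),
    "Ho": (5.5, 4.1, 60.0),
}


def default_ground_truth(monomer: RigidMonomer, noise_sigma: float = 0.0,
                         seed: int = 0) -> GroundTruth:
    """A hidden extended-form truth potential for the monomer's types.

    Pair parameters come from per-type bases with standard combination
    rules (arithmetic mean for exponents, geometric mean for dispersion);
    damping parameters track the repulsion steepness.
    """
    types = sorted(set(monomer.types))
    ff = ForceField("extended")
    for i, t1 in enumerate(types):
        for t2 in types[i:]:
            a1b, b1, c1 = _TRUTH_BASE.get(t1, (8.0, 3.5, 500.0))
            a2b, b2, c2 = _TRUTH_BASE.get(t2, (8.0, 3.5, 500.0))
            alpha = 0.5 * (a1b + a2b)
            beta = 0.5 * (b1 + b2)
            C6 = float(np.sqrt(c1 * c2))
            ff.set(t1, t2, PairParameters(
                alpha=alpha, beta=beta, a1=-0.18, a2=0.02,
                A12=3.0 * C6, C6=C6, C8=7.0 * C6,
                delta1=0.55 * beta, delta6=0.60 * beta, delta8=0.65 * beta))
    return GroundTruth(truth_ff=ff, noise_sigma=noise_sigma, seed=seed,
                       charges=monomer.charges.copy())


def build_reference_dataset(monomer: RigidMonomer, gt: GroundTruth,
                            n_points: int = 700, seed: int = 0,
                            R_range=None, min_contact: float = 1.5):
    """Sample dimer configurations and score them with the oracle."""
    from .fitting import contact_distance
    if R_range is None:
        c = contact_distance(monomer, monomer)
        R_range = (0.55 * c, 2.2 * c)
    cfgs = sample_dimer_configurations(monomer, monomer, n_points, seed=seed,
                                       R_range=R_range,
                                       min_contact=min_contact)
    return evaluate_reference(gt, cfgs)


# --------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    monomer: str = "diatomic"        # fixture name or XYZ path
    dataset: str = None              # external TSV; None -> oracle
    noise_sigma: float = 0.0
    n_points: int = 700
    form: str = "extended"
    generation: GenerationConfig = field(default_factory=lambda:
                                         GenerationConfig(
                                             space_groups=["P1", "P-1"],
                                             per_group_quota_step1=60,
                                             per_group_quota_step2=60))
    fit: FitConfig = field(default_factory=FitConfig)
    cutoff: float = 15.0             # final-energy cutoff
    search_cutoff: float = 10.0      # cutoff during batch minimization
    reference_cif: str = None
    altcsp: bool = False
    altcsp_threshold: float = 1.0
    altcsp_max_iter: int = 4
    top_n: int = 20
    outdir: str = "csp_run"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generation", None)
        fit = raw.pop("fit", None)
        cfg = cls(**raw)
        if gen:
            cfg.generation = GenerationConfig(**gen)
        if fit:
            cfg.fit = FitConfig(**fit)
        return cfg


def _load_monomer(spec: str) -> RigidMonomer:
    fixtures = fixture_monomers()
    if spec in fixtures:
        return fixtures[spec]
    p = Path(spec)
    if not p.exists():
        raise FileNotFoundError(
            f"monomer {spec!r} is neither a fixture "
            f"({sorted(fixtures)}) nor an existing XYZ file")
    return read_xyz(p)


# --------------------------------------------------------------------------
# stages

def _generate_candidates(monomer, rough_ff, gen: GenerationConfig,
                         seed: int) -> CandidateSet:
    if gen.mode == "grid":
        cands = grid_generate(monomer, gen)
        return select_densest(cands, gen.per_geometry_keep)
    out = CandidateSet.empty()
    for gi, group in enumerate(gen.space_groups):
        est = random_generate_step1(monomer, group,
                                    gen.per_group_quota_step1, rough_ff, gen,
                                    seed=seed + 1000 * gi)
        cs = random_generate_step2(monomer, group, est,
                                   gen.per_group_quota_step2, rough_ff, gen,
                                   seed=seed + 1000 * gi + 500)
        out.extend(cs)
        log.info("group %s: %d candidates", group, len(cs))
    return out


def run_csp(config: RunConfig):
    """Execute the full protocol; returns (PolymorphSet, report dict)."""
    t_start = time.time()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"stages": {}, "seed": config.seed, "version": __version__}

    def stage(name):
        report["stages"][name] = {"t": time.time() - t_start}
        log.info("stage: %s (%.1f s)", name, time.time() - t_start)

    # stage: reference data
    stage("dataset")
    monomer = _load_monomer(config.monomer)
    if config.dataset:
        refs = read_dataset(config.dataset, monomer, monomer)
        gt = None
    else:
        gt = default_ground_truth(monomer, noise_sigma=config.noise_sigma,
                                  seed=config.seed)
        refs = build_reference_dataset(monomer, gt, n_points=config.n_points,
                                       seed=config.seed)
        write_dataset(refs, outdir / "dataset.tsv")
    report["stages"]["dataset"]["n_points"] = len(refs)

    # stage: fitting
    stage("fit")
    fit_cfg = config.fit
    if config.form == "extended":
        fit_report = fit_extended(refs, fit_cfg)
    elif config.form == "exp61":
        fit_report = fit_exp61(refs, fit_cfg)
    else:
        fit_report = fit_lj1261(refs, fit_cfg)
    rough_report = fit_lj1261(refs, fit_cfg)
    save_forcefield(fit_report.fitted_ff, outdir / "ff.txt")
    save_forcefield(rough_report.fitted_ff, outdir / "ff_rough.txt")
    report["stages"]["fit"]["rmse_negative"] = fit_report.rmse_negative
    report["stages"]["fit"]["rmse_all"] = fit_report.rmse_all
    report["stages"]["fit"]["n_parameters"] = fit_report.n_parameters
    fitted_monomer = fit_report.monomerA
    rough_monomer = rough_report.monomerA
    # candidate generation and minimization use the fitted charges
    rough_ff = rough_report.fitted_ff

    # stage: generation
    stage("generate")
    cands = _generate_candidates(rough_monomer, rough_ff, config.generation,
                                 config.seed)
    report["stages"]["generate"]["n_candidates"] = len(cands)

    # re-dress candidate structures with the target-fit charges
    target_cands = []
    for s in cands.structures:
        s2 = s.copy()
        for pose in s2.asymmetric_unit:
            pose.monomer = fitted_monomer
        target_cands.append(s2)

    # stage: staged minimization (search cutoff), then a single
    # final-energy evaluation at the production cutoff
    stage("minimize")
    results = minimize_set(rough_ff, fit_report.fitted_ff, target_cands,
                           cutoff=config.search_cutoff,
                           rough_maxiter=40, maxiter=100)
    ok = [r for r in results if np.isfinite(r.energy) and not r.collapse_flag]
    report["stages"]["minimize"]["n_minimized"] = len(ok)
    report["stages"]["minimize"]["n_collapsed"] = sum(
        1 for r in results if r.collapse_flag)

    # stage: clustering and ranking
    stage("rank")
    entries = []
    for i, r in enumerate(results):
        if not np.isfinite(r.energy) or r.collapse_flag:
            continue
        try:
            e_final = lattice_energy(fit_report.fitted_ff, r.structure,
                                     cutoff=config.cutoff)
        except ValueError:
            continue  # degenerate cell that slipped through
        entries.append({"structure": r.structure, "energy": e_final, "id": i})
    pset = rank_polymorphs(cluster_structures(entries))
    table = landscape_table(pset)
    table.to_csv(outdir / "landscape.tsv", sep="\t", index=False)
    report["stages"]["rank"]["n_clusters"] = int(len(table))

    # optional alt-CSP refinement
    if config.altcsp and gt is not None:
        stage("altcsp")
        pset, state = alt_csp_loop(
            fit_report, gt, entries, rough_ff=rough_ff,
            threshold=config.altcsp_threshold,
            max_iter=config.altcsp_max_iter, top_n=config.top_n,
            initial_refs=refs, cutoff=config.cutoff)
        report["stages"]["altcsp"]["converged"] = state.converged
        report["stages"]["altcsp"]["iterations"] = state.iteration
        report["stages"]["altcsp"]["history"] = state.history
        table = landscape_table(pset)
        table.to_csv(outdir / "landscape.tsv", sep="\t", index=False)

    # optional reference comparison
    if config.reference_cif:
        ref = read_cif(config.reference_cif, monomer=fitted_monomer)
        reps = sorted([e for e in pset.entries if e.get("rank") is not None],
                      key=lambda e: e["rank"])[: config.top_n]
        overlaps = [(e["rank"], rmsd_n(e["structure"], ref).rmsd)
                    for e in reps]
        matched = [(rk, r) for rk, r in overlaps if r < 0.8]
        report["reference"] = {
            "rank_of_match": matched[0][0] if matched else None,
            "best_rmsd": min(r for _, r in overlaps) if overlaps else None}

    # outputs
    cif_dir = outdir / "cifs"
    cif_dir.mkdir(exist_ok=True)
    reps = sorted([e for e in pset.entries if e.get("rank") is not None],
                  key=lambda e: e["rank"])
    for e in reps[: config.top_n]:
        write_cif(e["structure"], cif_dir / f"rank_{e['rank']:03d}.cif")
    index = pd.DataFrame([{"rank": e["rank"], "id": e["id"],
                           "energy": e["energy"], "density": e["density"],
                           "space_group": e["structure"].space_group.symbol}
                          for e in reps])
    index.to_csv(outdir / "index.tsv", sep="\t", index=False)
    report["wall_time_s"] = time.time() - t_start
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"config": _config_dict(config), "report": report}, fh,
                  indent=2, default=str)
    return pset, report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def planted_truth_study(monomer_name: str = "diatomic", seed: int = 0,
                        space_groups=("P1", "P-1"), quota: int = 40,
                        n_points: int = 500, noise_sigma: float = 0.0,
                        form: str = "extended", search_cutoff: float = 10.0,
                        cutoff: float = 15.0, top_n: int = 20):
    """Recovery experiment against a hidden truth potential.

    One candidate pool is generated; it is minimized twice -- once with
    the hidden truth potential (whose global minimum defines the
    "experimental" reference crystal) and once with the force field
    fitted to the oracle data.  Returns a dict with the fitted-run rank
    of the structure matching the reference, the overlap RMSD, and the
    supporting objects.
    """
    from .fitting import apply_charges
    monomer = fixture_monomers()[monomer_name]
    gt = default_ground_truth(monomer, noise_sigma=noise_sigma, seed=seed)
    refs = build_reference_dataset(monomer, gt, n_points=n_points, seed=seed)
    fit_cfg = FitConfig(seed=seed)
    if form == "extended":
        fit_report = fit_extended(refs, fit_cfg)
    else:
        fit_report = fit_exp61(refs, fit_cfg)
    rough_report = fit_lj1261(refs, fit_cfg)
    gen = GenerationConfig(space_groups=list(space_groups),
                           per_group_quota_step1=max(40, quota),
                           per_group_quota_step2=quota, seed=seed)
    cands = _generate_candidates(rough_report.monomerA,
                                 rough_report.fitted_ff, gen, seed)

    truth_monomer = apply_charges(monomer, gt.charges)

    def _rank_with(ff, mon):
        target = []
        for s in cands.structures:
            s2 = s.copy()
            for pose in s2.asymmetric_unit:
                pose.monomer = mon
            target.append(s2)
        results = minimize_set(rough_report.fitted_ff, ff, target,
                               cutoff=search_cutoff, rough_maxiter=40,
                               maxiter=100)
        entries = []
        for i, r in enumerate(results):
            if not np.isfinite(r.energy) or r.collapse_flag:
                continue
            try:
                e_final = lattice_energy(ff, r.structure, cutoff=cutoff)
            except ValueError:
                continue  # degenerate cell that slipped through
            entries.append({"structure": r.structure, "energy": e_final,
                            "id": i})
        return rank_polymorphs(cluster_structures(entries)), entries

    truth_pset, _ = _rank_with(gt.truth_ff, truth_monomer)
    truth_reps = sorted([e for e in truth_pset.entries if e.get("rank")],
                        key=lambda e: e["rank"])
    reference = truth_reps[0]["structure"]

    fitted_pset, fitted_entries = _rank_with(fit_report.fitted_ff,
                                             fit_report.monomerA)
    reps = sorted([e for e in fitted_pset.entries if e.get("rank")],
                  key=lambda e: e["rank"])
    overlaps = [(e["rank"], rmsd_n(e["structure"], reference).rmsd)
                for e in reps[:top_n]]
    matched = [(rk, r) for rk, r in overlaps if r < 0.8]
    return {"rank_of_match": matched[0][0] if matched else None,
            "rmsd_of_match": matched[0][1] if matched else None,
            "overlaps": overlaps,
            "reference": reference,
            "fit_report": fit_report,
            "rough_report": rough_report,
            "ground_truth": gt,
            "dataset": refs,
            "candidates": cands,
            "fitted_pset": fitted_pset,
            "fitted_entries": fitted_entries,
            "truth_pset": truth_pset}


def compare_forms(config: RunConfig):
    """Run identical CSPs with extended and exp-6-1 fitted force fields.

    Returns a two-row table (form, rmse_negative, rank of the reference
    structure when one is supplied).
    """
    rows = []
    for form in ("extended", "exp61"):
        cfg = RunConfig(**{**_config_dict(config)})
        cfg.generation = config.generation
        cfg.fit = config.fit
        cfg.form = form
        cfg.outdir = str(Path(config.outdir) / form)
        pset, report = run_csp(cfg)
        row = {"form": form,
               "rmse_negative": report["stages"]["fit"]["rmse_negative"],
               "n_clusters": report["stages"]["rank"]["n_clusters"]}
        if "reference" in report:
            row["rank_of_match"] = report["reference"]["rank_of_match"]
            row["best_rmsd"] = report["reference"]["best_rmsd"]
        rows.append(row)
    return pd.DataFrame(rows)
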