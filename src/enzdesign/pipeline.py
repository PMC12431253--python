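"""End-to-end orchestration: ensemble -> mutate -> two-state score -> rank.

run_design executes the full design flow on a config (YAML-loadable), logs
every stage with the config hash and seed, and emits deterministic TSV/JSON
outputs.  run_resolution_suite applies the structural/H-bond resolution
analyses (pairwise RMSD matrices, RMSF profiles, occupancy, activity
association) to user-supplied multi-model ensembles, e.g. predicted
structures.  The experimental-validation loop is a human-in-the-loop
boundary: the tool emits ranked candidates, it never claims activity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core_structures import (Selection, pairwise_rmsd_matrix,
                              read_structure, rmsf_profile, write_structure)
from .energy_model import EnergyModelSpec
from .ensemble_gen import BoundConfig, build_design_ensemble
from .hbond_analysis import (HBondCriteria, HBondDefinition, OccupancyTable,
                             activity_association, load_activity_table,
                             occupancy)
from .mutagenesis import mutate_ensemble, parse_variant_name
from .pssm import compute_pssm, read_msa_fasta, score_mutation
from .rank_filter import (Candidate, FilterThresholds, WT_NAME, apply_filters,
                          ensemble_delta_e, min_substrate_distance,
                          rank_stability, ranked_to_tsv)
from . import synthetic_data

logger = logging.getLogger("enzdesign")

__all__ = ["RunConfig", "RunReport", "ConfigError", "run_design",
           "run_resolution_suite"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration for a design run.

    Either `seed_pdb` points at a structure or `toy_n_res` requests a
    generated toy enzyme.  Variants are given as mutation names
    (e.g. 'A6S' or 'A6S_A8G').
    """

    rng_seed: int = 0
    out_dir: str = "run_out"
    seed_pdb: str | None = None
    toy_n_res: int = 20
    n_conformers: int = 8
    variants: list[str] = field(default_factory=list)
    msa_path: str | None = None
    msa_n_seqs: int = 40
    msa_conservation: float = 0.6
    energy_specs: list[dict] = field(default_factory=lambda: [{}])
    thresholds: dict = field(default_factory=dict)
    bound_config: dict = field(default_factory=dict)
    minimize_max_iter: int = 100
    stability: dict = field(default_factory=lambda: {
        "n_subsamples": 20, "subsample_size": 8, "top_k": 3})

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.validate(raw)

    @classmethod
    def validate(cls, raw: dict) -> "RunConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.n_conformers < 1:
            raise ConfigError("n_conformers must be >= 1")
        if not cfg.variants:
            raise ConfigError("at least one variant is required")
        return cfg

    def config_hash(self) -> str:
        # out_dir is a sink, not a compute input: same science, same hash
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    rng_seed: int
    ranked_tsv: str
    stability: dict
    rmsf: dict
    exclusions: list
    timings: dict
    out_dir: str


def _stage(name: str, config_hash: str, seed: int):
    logger.info("stage=%s config=%s seed=%d", name, config_hash, seed)
    return time.time()


def run_design(config: RunConfig) -> RunReport:
    """Execute the full design flow; deterministic per (config, seed)."""
    chash = config.config_hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    exclusions: list = []

    t = _stage("seed_structure", chash, config.rng_seed)
    if config.seed_pdb:
        seed = read_structure(Path(config.seed_pdb).read_text()).members[0]
        seed.meta.setdefault("triad", {})
    else:
        seed = synthetic_data.make_toy_enzyme(config.toy_n_res,
                                              config.rng_seed)
    timings["seed_structure"] = time.time() - t

    t = _stage("ensemble", chash, config.rng_seed)
    triad = seed.meta.get("triad", {})
    # substrate is stripped before ensemble generation (states add it back),
    # so the anchored set here is the catalytic triad side-chain residues
    anchor_ids = tuple(sorted(set(triad.values())))
    bc = BoundConfig(anchor_res_ids=anchor_ids, **config.bound_config)
    apo = synthetic_data.strip_substrate(seed)
    ensemble = build_design_ensemble(apo, config.n_conformers, bc,
                                     rng_seed=config.rng_seed)
    (out / "ensemble.pdb").write_text(write_structure(ensemble))
    timings["ensemble"] = time.time() - t

    t = _stage("pssm", chash, config.rng_seed)
    if config.msa_path:
        msa = read_msa_fasta(Path(config.msa_path).read_text())
    else:
        msa, msa_gt = synthetic_data.make_msa(
            config.toy_n_res, config.msa_n_seqs, config.msa_conservation,
            rng_seed=config.rng_seed)
        msa_gt.write(out / "msa_ground_truth.json")
    pssm = compute_pssm(msa)
    timings["pssm"] = time.time() - t

    t = _stage("score", chash, config.rng_seed)
    es_tpl = synthetic_data.toy_substrate_template(seed)
    specs = [EnergyModelSpec(**{"spec_id": f"spec{i}", **s})
             for i, s in enumerate(config.energy_specs)]
    variants = [parse_variant_name(v) for v in config.variants]
    tables_by_condition: dict[str, dict] = {}
    for spec in specs:
        wt_tbl = ensemble_delta_e(ensemble, es_tpl, es_tpl, spec,
                                  variant=WT_NAME,
                                  max_iter=config.minimize_max_iter)
        exclusions.extend((spec.spec_id, WT_NAME, *e) for e in wt_tbl.excluded)
        tables = {WT_NAME: wt_tbl}
        for var in variants:
            mut_ens = mutate_ensemble(ensemble, var)
            tbl = ensemble_delta_e(mut_ens, es_tpl, es_tpl, spec,
                                   variant=var.name,
                                   max_iter=config.minimize_max_iter)
            exclusions.extend((spec.spec_id, var.name, *e)
                              for e in tbl.excluded)
            tables[var.name] = tbl
        tables_by_condition[spec.spec_id] = tables
    timings["score"] = time.time() - t

    t = _stage("rank", chash, config.rng_seed)
    from .rank_filter import normalize_median

    base_tables = tables_by_condition[specs[0].spec_id]
    candidates = []
    for var in variants:
        de = normalize_median(base_tables[var.name], base_tables[WT_NAME])
        pscore = min(score_mutation(pssm, m.res_id, m.to_aa)
                     for m in var.mutations)
        dist = min(min_substrate_distance(seed, m.res_id,
                                          synthetic_data.SUBSTRATE_RES_NAME)
                   for m in var.mutations)
        candidates.append(Candidate(var.name, de, pscore, dist))
    ranked = apply_filters(candidates, FilterThresholds(**config.thresholds))
    ranked_tsv = ranked_to_tsv(ranked)
    (out / "ranked.tsv").write_text(ranked_tsv)
    timings["rank"] = time.time() - t

    t = _stage("stability", chash, config.rng_seed)
    if len(variants) >= 3:
        report = rank_stability(tables_by_condition,
                                rng_seed=config.rng_seed,
                                **config.stability)
        stability = {
            "condition_ids": report.condition_ids,
            "mean_offdiag_rho": report.mean_offdiag_rho,
            "rho_matrix": report.rho_matrix.tolist(),
            "topk_overlap": report.topk_overlap.tolist(),
            "top_k": report.top_k,
        }
    else:
        stability = {"skipped": "needs >= 3 variants"}
    (out / "stability.json").write_text(
        json.dumps(stability, indent=2, sort_keys=True))
    timings["stability"] = time.time() - t

    t = _stage("rmsf", chash, config.rng_seed)
    rmsf = rmsf_profile(ensemble, Selection.ca(), fit=True)
    with open(out / "rmsf.tsv", "w") as fh:
        fh.write("res_id\trmsf\n")
        for rid in sorted(rmsf):
            fh.write(f"{rid}\t{rmsf[rid]:.4f}\n")
    timings["rmsf"] = time.time() - t

    with open(out / "exclusions.log", "w") as fh:
        for row in exclusions:
            fh.write("\t".join(str(x) for x in row) + "\n")
    meta = {"config_hash": chash, "rng_seed": config.rng_seed,
            "timings": timings}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2,
                                                  sort_keys=True))
    return RunReport(chash, config.rng_seed, ranked_tsv, stability,
                     {int(k): float(v) for k, v in rmsf.items()},
                     exclusions, timings, str(out))


def run_resolution_suite(pdb_paths: list[str],
                         active_site_res_ids=(16, 82, 83, 229, 251),
                         bond_definitions: list[HBondDefinition] | None = None,
                         criteria: HBondCriteria = HBondCriteria(),
                         activity_path: str | None = None,
                         out_dir: str | None = None,
                         rng_seed: int = 0) -> dict:
    """Structural/H-bond resolution analyses on user-supplied model ensembles.

    Emits pairwise C-alpha and active-site-backbone RMSD matrices, RMSF
    profiles per ensemble, per-ensemble occupancy (when bond definitions are
    given) and, when an activity table is available, the occupancy-activity
    association report.
    """
    if len(pdb_paths) < 1:
        raise ConfigError("at least one input ensemble is required")
    ensembles = {Path(p).stem: read_structure(Path(p).read_text(),
                                              label=Path(p).stem)
                 for p in pdb_paths}
    reps = [e.members[0] for e in ensembles.values()]
    if len(reps) >= 2:
        ca_mat = pairwise_rmsd_matrix(reps, Selection.ca())
        as_mat = pairwise_rmsd_matrix(
            reps, Selection.active_site_backbone(active_site_res_ids))
    else:
        ca_mat = as_mat = np.zeros((1, 1))
    report: dict = {
        "labels": list(ensembles),
        "rmsd_ca": ca_mat.tolist(),
        "rmsd_active_site": as_mat.tolist(),
        "rmsf": {},
    }
    for name, ens in ensembles.items():
        if len(ens) >= 2:
            report["rmsf"][name] = {
                int(k): float(v)
                for k, v in rmsf_profile(ens, Selection.ca()).items()}
    if bond_definitions:
        table = OccupancyTable()
        for name, ens in ensembles.items():
            table.add_cell(name, "model", occupancy(ens, bond_definitions,
                                                    criteria))
        report["occupancy"] = table.rows.to_dict(orient="records")
        if activity_path is not None or len(ensembles) >= 4:
            act = load_activity_table(activity_path)
            try:
                assoc = activity_association(table, act, rng_seed=rng_seed)
                report["association"] = assoc.to_dict(orient="records")
            except ValueError as exc:
                report["association"] = {"skipped": str(exc)}
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "resolution.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report
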