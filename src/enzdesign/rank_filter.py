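"""Variant scoring, filtering, ranking and rank-stability analysis.

Per frame i of a design ensemble, dE_i = E(ES*_i) - E(ES_i) after
minimization of both complex states.  Mutant tables are normalized against
the wild type and summarised by the median (dE~_v, "delta-E-tilde"): values
below 1 predict transition-state stabilization.  Selection applies three
strict filters — dE~ < 0.985, PSSM > -4.0 bits, minimum heavy-atom distance
to the substrate < 5 A — and survivors rank ascending by dE~.

Because the source protocol's rankings proved sensitive to parameterization
and frame choice, the stability analysis re-ranks variants under swapped
energy specs and frame subsamples and reports pairwise Spearman rho and
top-k overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .core_structures import Ensemble, Structure
from .energy_model import (DivergenceError, EnergyModelSpec,
                           StateKind, SubstrateTemplate, build_state, minimize)

__all__ = [
    "DeltaETable",
    "Candidate",
    "RankedVariant",
    "StabilityReport",
    "FilterThresholds",
    "NormalizationError",
    "IncompleteCandidateError",
    "compute_delta_e",
    "ensemble_delta_e",
    "normalize_median",
    "apply_filters",
    "rank_stability",
    "min_substrate_distance",
]

WT_NAME = "WT"


class NormalizationError(ValueError):
    pass


class IncompleteCandidateError(ValueError):
    pass


@dataclass
class DeltaETable:
    """Per-frame two-state energies for one variant on one frame set."""

    variant: str
    frames: np.ndarray          # frame indices into the wild-type ensemble
    e_es: np.ndarray
    e_es_star: np.ndarray
    spec_id: str = "default"
    frame_set_id: str = "full"
    excluded: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.e_es = np.asarray(self.e_es, dtype=float)
        self.e_es_star = np.asarray(self.e_es_star, dtype=float)

    @property
    def delta_e(self) -> np.ndarray:
        return self.e_es_star - self.e_es

    def subset(self, frame_ids: np.ndarray) -> "DeltaETable":
        sel = np.isin(self.frames, frame_ids)
        return DeltaETable(self.variant, self.frames[sel], self.e_es[sel],
                           self.e_es_star[sel], self.spec_id,
                           frame_set_id="subset", excluded=list(self.excluded))


@dataclass
class Candidate:
    name: str
    delta_e_norm: float | None
    pssm_score: float | None
    min_substrate_distance: float | None


@dataclass
class FilterThresholds:
    delta_e: float = 0.985       # pass iff dE~ strictly below
    pssm: float = -4.0           # pass iff strictly above (bits)
    distance: float = 5.0        # pass iff strictly below (A)


@dataclass
class RankedVariant:
    name: str
    delta_e_norm: float
    pssm_score: float
    min_substrate_distance: float
    passes: dict[str, bool]
    passes_all: bool
    rank: int


@dataclass
class StabilityReport:
    condition_ids: list[str]
    rho_matrix: np.ndarray
    topk_overlap: np.ndarray
    top_k: int
    mean_offdiag_rho: float
    rankings: dict[str, list[str]]


# ---------------------------------------------------------------------------
# dE computation
# ---------------------------------------------------------------------------

def ensemble_delta_e(ensemble: Ensemble,
                     es_template: SubstrateTemplate,
                     es_star_template: SubstrateTemplate,
                     spec: EnergyModelSpec | None = None,
                     variant: str = WT_NAME,
                     max_iter: int = 200,
                     restraint_target: float = 1.9,
                     restraint_k: float = 200.0) -> DeltaETable:
    """Two-state minimized energies per frame of one ensemble.

    Frames whose minimization diverges are excluded and recorded, never
    silently dropped.
    """
    spec = spec or EnergyModelSpec()
    frames, e_es, e_star = [], [], []
    excluded: list[tuple[int, str]] = []
    for i, member in enumerate(ensemble.members):
        try:
            s_es = build_state(member, es_template, StateKind.ES)
            s_star = build_state(member, es_star_template, StateKind.ES_STAR,
                                 restraint_target=restraint_target,
                                 restraint_k=restraint_k)
            r_es = minimize(s_es, spec, max_iter=max_iter)
            r_star = minimize(s_star, spec, max_iter=max_iter)
        except (DivergenceError, Exception) as exc:
            if isinstance(exc, (KeyboardInterrupt, SystemExit)):
                raise
            excluded.append((i, f"{type(exc).__name__}: {exc}"))
            continue
        frames.append(i)
        e_es.append(r_es.energy)
        e_star.append(r_star.energy)
    return DeltaETable(variant, np.array(frames), np.array(e_es),
                       np.array(e_star), spec_id=spec.spec_id,
                       excluded=excluded)


def compute_delta_e(mutant_ensemble: Ensemble, wt_ensemble: Ensemble,
                    es_template: SubstrateTemplate,
                    es_star_template: SubstrateTemplate,
                    spec: EnergyModelSpec | None = None,
                    variant: str = "mutant",
                    max_iter: int = 200) -> tuple[DeltaETable, DeltaETable]:
    """(mutant, wild-type) dE tables on frame-aligned ensembles."""
    if len(mutant_ensemble) != len(wt_ensemble):
        raise ValueError("mutant and wild-type ensembles must be frame-aligned")
    mut = ensemble_delta_e(mutant_ensemble, es_template, es_star_template,
                           spec, variant=variant, max_iter=max_iter)
    wt = ensemble_delta_e(wt_ensemble, es_template, es_star_template,
                          spec, variant=WT_NAME, max_iter=max_iter)
    return mut, wt


def normalize_median(mutant: DeltaETable, wt: DeltaETable,
                     mode: str = "per_frame_ratio",
                     wt_floor: float = 1e-6) -> float:
    """Wild-type-normalized median dE~_v.

    Default mode 'per_frame_ratio': median over shared frames of
    dE_mut,i / dE_wt,i (frames with |dE_wt| below `wt_floor` are skipped).
    Alternate 'median_of_medians': median(dE_mut) / median(dE_wt).
    Divergence-excluded frames are dropped pairwise by the shared-frame
    intersection, preserving alignment.
    """
    shared = np.intersect1d(mutant.frames, wt.frames)
    if shared.size == 0:
        raise NormalizationError("no shared valid frames")
    m = mutant.subset(shared).delta_e
    w = wt.subset(shared).delta_e
    if mode == "per_frame_ratio":
        ok = np.abs(w) > wt_floor
        if not np.any(ok):
            raise NormalizationError(
                "all wild-type frames below the normalization floor")
        return float(np.median(m[ok] / w[ok]))
    if mode == "median_of_medians":
        wmed = float(np.median(w))
        if abs(wmed) <= wt_floor:
            raise NormalizationError("wild-type median below the floor")
        return float(np.median(m)) / wmed
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# Filters and ranking
# ---------------------------------------------------------------------------

def min_substrate_distance(structure: Structure, res_id: int,
                           substrate_res_name: str = "EST",
                           chain: str = "A") -> float:
    """Minimum heavy-atom distance (A) from a residue to the substrate."""
    res = np.array([a.coords for a in structure.atoms
                    if a.chain == chain and a.res_id == res_id
                    and a.element != "H"])
    sub = np.array([a.coords for a in structure.atoms
                    if a.res_name == substrate_res_name and a.element != "H"])
    if res.size == 0 or sub.size == 0:
        raise ValueError("residue or substrate atoms not found")
    d = np.linalg.norm(res[:, None, :] - sub[None, :, :], axis=2)
    return float(d.min())


def apply_filters(candidates: list[Candidate],
                  thresholds: FilterThresholds | None = None) -> list[RankedVariant]:
    """Strict three-filter selection and ascending-dE~ ranking.

    passes = (dE~ < 0.985) and (pssm > -4.0) and (dist < 5.0), all strict.
    The rank is a permutation over all candidates (ascending dE~, ties by
    name); the pass flags mark the survivors.
    """
    th = thresholds or FilterThresholds()
    for c in candidates:
        for fieldname in ("delta_e_norm", "pssm_score", "min_substrate_distance"):
            v = getattr(c, fieldname)
            if v is None or not np.isfinite(v):
                raise IncompleteCandidateError(
                    f"candidate {c.name}: missing {fieldname}")
    order = sorted(candidates, key=lambda c: (c.delta_e_norm, c.name))
    out = []
    for rank, c in enumerate(order, start=1):
        passes = {
            "delta_e": c.delta_e_norm < th.delta_e,
            "pssm": c.pssm_score > th.pssm,
            "distance": c.min_substrate_distance < th.distance,
        }
        out.append(RankedVariant(
            name=c.name, delta_e_norm=c.delta_e_norm, pssm_score=c.pssm_score,
            min_substrate_distance=c.min_substrate_distance, passes=passes,
            passes_all=all(passes.values()), rank=rank))
    return out


def ranked_to_tsv(ranked: list[RankedVariant]) -> str:
    lines = ["name\tdelta_e_norm\tpssm\tdist\tpass_delta_e\tpass_pssm"
             "\tpass_distance\tpass_all\trank"]
    for r in ranked:
        lines.append(
            f"{r.name}\t{r.delta_e_norm:.6f}\t{r.pssm_score:.4f}"
            f"\t{r.min_substrate_distance:.3f}\t{int(r.passes['delta_e'])}"
            f"\t{int(r.passes['pssm'])}\t{int(r.passes['distance'])}"
            f"\t{int(r.passes_all)}\t{r.rank}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rank stability
# ---------------------------------------------------------------------------

def _rank_vector(tables: dict[str, DeltaETable], mode: str,
                 frame_ids: np.ndarray | None = None) -> list[str]:
    wt = tables[WT_NAME]
    if frame_ids is not None:
        wt = wt.subset(frame_ids)
    scores = {}
    for name, tbl in tables.items():
        if name == WT_NAME:
            continue
        t = tbl.subset(frame_ids) if frame_ids is not None else tbl
        scores[name] = normalize_median(t, wt, mode=mode)
    return sorted(scores, key=lambda n: (scores[n], n))


def rank_stability(tables_by_condition: dict[str, dict[str, DeltaETable]],
                   n_subsamples: int = 20,
                   subsample_size: int | None = 8,
                   top_k: int = 3,
                   rng_seed: int = 0,
                   mode: str = "per_frame_ratio") -> StabilityReport:
    """Pairwise Spearman rho and top-k overlap of variant rankings.

    Conditions are the given (energy spec / parameterization) table sets,
    each expanded by `n_subsamples` frame subsets drawn without replacement
    (deterministic per rng_seed).  Requires >= 3 variants beyond wild type.
    """
    base = next(iter(tables_by_condition.values()))
    variants = sorted(n for n in base if n != WT_NAME)
    if len(variants) < 3:
        raise ValueError("rank stability needs at least 3 variants")
    for cid, tables in tables_by_condition.items():
        if WT_NAME not in tables:
            raise ValueError(f"condition {cid}: wild-type table missing")

    rng = np.random.default_rng(rng_seed)
    rankings: dict[str, list[str]] = {}
    for cid, tables in sorted(tables_by_condition.items()):
        all_frames = tables[WT_NAME].frames
        if n_subsamples and subsample_size and subsample_size < all_frames.size:
            for s in range(n_subsamples):
                sub = np.sort(rng.choice(all_frames, size=subsample_size,
                                         replace=False))
                rankings[f"{cid}/sub{s}"] = _rank_vector(tables, mode, sub)
        else:
            rankings[cid] = _rank_vector(tables, mode)

    cids = list(rankings)
    n = len(cids)
    rho = np.eye(n)
    overlap = np.ones((n, n))
    pos = {cid: {v: r for r, v in enumerate(rankings[cid])} for cid in cids}
    for a in range(n):
        for b in range(a + 1, n):
            ra = [pos[cids[a]][v] for v in variants]
            rb = [pos[cids[b]][v] for v in variants]
            r, _ = spearmanr(ra, rb)
            rho[a, b] = rho[b, a] = r
            ta = set(rankings[cids[a]][:top_k])
            tb = set(rankings[cids[b]][:top_k])
            overlap[a, b] = overlap[b, a] = len(ta & tb) / top_k
    off = rho[np.triu_indices(n, k=1)]
    return StabilityReport(
        condition_ids=cids, rho_matrix=rho, topk_overlap=overlap,
        top_k=top_k, mean_offdiag_rho=float(off.mean()) if off.size else 1.0,
        rankings=rankings)
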