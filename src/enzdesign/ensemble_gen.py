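"""Distance-geometry conformer generation (CONCOORD-style).

Conformers are sampled by perturbing a seed structure and iteratively
projecting atom pairs back inside distance bounds derived from the seed:
tight bounds for covalent 1-2/1-3/1-4 relationships, loose bounds for
non-bonded contacts, and very tight "anchor" bounds that freeze the
catalytic-triad/substrate geometry so every conformer keeps the seed's
transition-state-like active site.  The design ensemble is the seed plus N
generated conformers (N=95 by default, giving the canonical 96 members).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .core_structures import Ensemble, Structure

__all__ = [
    "DistanceBound",
    "BoundSet",
    "BoundConfig",
    "ConfigError",
    "NonConvergenceError",
    "derive_bounds",
    "generate_conformer",
    "build_design_ensemble",
    "max_bound_violation",
]

# Covalent radii (A) for bond detection; generous default for odd elements.
_COVALENT_RADII = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "H": 0.31,
                   "P": 1.07}


class ConfigError(ValueError):
    pass


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, worst_violation: float):
        super().__init__(msg)
        self.worst_violation = worst_violation


@dataclass(frozen=True)
class DistanceBound:
    atom_i: int
    atom_j: int
    lower: float
    upper: float
    klass: str  # bond12 | angle13 | dihedral14 | contact | anchor

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ConfigError("bound between an atom and itself")
        if not (0 < self.lower <= self.upper):
            raise ConfigError(f"invalid bound interval [{self.lower}, {self.upper}]")


@dataclass
class BoundConfig:
    """Tolerances per bound class (A), qualitative CONCOORD hierarchy."""

    bond12_tol: float = 0.05
    angle13_tol: float = 0.10
    dihedral14_tol: float = 0.30
    contact_cutoff: float = 6.0
    contact_tol: float = 0.50
    anchor_tol: float = 0.05
    anchor_res_ids: tuple[int, ...] = ()
    satisfaction_tol: float = 0.01
    perturbation_sigma: float = 0.8
    max_sweeps: int = 5000


@dataclass
class BoundSet:
    bounds: list[DistanceBound]
    source: Structure
    config: BoundConfig = field(default_factory=BoundConfig)
    anchored_atoms: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=bool))


def _bond_graph(structure: Structure) -> list[set[int]]:
    """Detect covalent bonds from interatomic distances vs covalent radii."""
    coords = structure.coords
    radii = np.array([_COVALENT_RADII.get(a.element, 0.9)
                      for a in structure.atoms])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.3, output_type="ndarray")
    adj: list[set[int]] = [set() for _ in structure.atoms]
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        if d < 1.3 * (radii[i] + radii[j]):
            adj[i].add(j)
            adj[j].add(i)
    return adj


def derive_bounds(seed: Structure, config: BoundConfig | None = None) -> BoundSet:
    """Derive the per-class distance bounds from a seed structure.

    bond12/angle13/dihedral14 bounds are seed distance +- class tolerance,
    contacts within the cutoff get +- contact tolerance, and all heavy-atom
    pairs inside the anchored residue set get +- anchor tolerance.
    """
    config = config or BoundConfig()
    coords = seed.coords
    adj = _bond_graph(seed)
    n = len(seed)

    heavy = np.array([a.element != "H" for a in seed.atoms])
    anchor_set = set(config.anchor_res_ids)
    for rid in anchor_set:
        if not any(a.res_id == rid for a in seed.atoms):
            raise ConfigError(f"anchored residue {rid} absent from seed")
    # anchored set: side-chain heavy atoms of the listed residues (plus any
    # non-protein atoms of those residues, e.g. a bound substrate fragment)
    anchored = np.array(
        [a.res_id in anchor_set and a.element != "H"
         and a.name not in ("N", "CA", "C", "O") for a in seed.atoms])

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[i] - coords[j]))

    klass_of: dict[tuple[int, int], str] = {}
    # 1-2 / 1-3 / 1-4 over the bond graph
    for i in range(n):
        for j in adj[i]:
            if i < j:
                klass_of[(i, j)] = "bond12"
    for i in range(n):
        for j in adj[i]:
            for k in adj[j]:
                if k > i and k not in adj[i]:
                    klass_of.setdefault((i, k), "angle13")
    for i in range(n):
        for j in adj[i]:
            for k in adj[j]:
                if k == i:
                    continue
                for l in adj[k]:
                    if l <= i or l == j or l in adj[i]:
                        continue
                    key = (i, l)
                    if key not in klass_of:
                        klass_of[key] = "dihedral14"

    tol = {"bond12": config.bond12_tol, "angle13": config.angle13_tol,
           "dihedral14": config.dihedral14_tol}
    bounds: list[DistanceBound] = []
    for (i, j), kl in sorted(klass_of.items()):
        d = dist(i, j)
        bounds.append(DistanceBound(i, j, max(d - tol[kl], 1e-3), d + tol[kl], kl))

    # non-bonded contacts between heavy atoms within the cutoff
    tree = cKDTree(coords)
    for i, j in sorted(map(tuple, tree.query_pairs(r=config.contact_cutoff))):
        if (i, j) in klass_of or not (heavy[i] and heavy[j]):
            continue
        d = dist(i, j)
        bounds.append(DistanceBound(
            i, j, max(d - config.contact_tol, 1e-3), d + config.contact_tol,
            "contact"))

    # anchor bounds: all intra-set heavy-atom pairs of the anchored residues
    anchor_idx = np.flatnonzero(anchored)
    for ai in range(len(anchor_idx)):
        for aj in range(ai + 1, len(anchor_idx)):
            i, j = int(anchor_idx[ai]), int(anchor_idx[aj])
            d = dist(i, j)
            bounds.append(DistanceBound(
                i, j, max(d - config.anchor_tol, 1e-3), d + config.anchor_tol,
                "anchor"))

    return BoundSet(bounds=bounds, source=seed, config=config,
                    anchored_atoms=anchored)


def max_bound_violation(coords: np.ndarray, bounds: Iterable[DistanceBound]) -> float:
    worst = 0.0
    for b in bounds:
        d = float(np.linalg.norm(coords[b.atom_i] - coords[b.atom_j]))
        if d < b.lower:
            worst = max(worst, b.lower - d)
        elif d > b.upper:
            worst = max(worst, d - b.upper)
    return worst


# --- projection inner loop: sequential shake-like sweeps ------------------

def _project_sweeps_python(coords, ii, jj, lo, hi, order, tol, max_sweeps):
    n_bounds = len(ii)
    for sweep in range(max_sweeps):
        worst = 0.0
        for k in range(n_bounds):
            b = order[sweep % order.shape[0], k]
            i, j = ii[b], jj[b]
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            d = (dx * dx + dy * dy + dz * dz) ** 0.5
            if d < 1e-9:
                d = 1e-9
            target = d
            if d < lo[b]:
                target = lo[b]
            elif d > hi[b]:
                target = hi[b]
            if target != d:
                viol = abs(d - target)
                if viol > worst:
                    worst = viol
                f = 0.5 * (target - d) / d
                coords[i, 0] -= f * dx
                coords[i, 1] -= f * dy
                coords[i, 2] -= f * dz
                coords[j, 0] += f * dx
                coords[j, 1] += f * dy
                coords[j, 2] += f * dz
        if worst <= tol * 0.5:
            return sweep + 1
    return -1


try:  # JIT for the 95-conformer acceptance runtime; fallback is identical
    from numba import njit

    _project_sweeps = njit(cache=False)(_project_sweeps_python)
except Exception:  # pragma: no cover - numba is pre-installed
    _project_sweeps = _project_sweeps_python


def generate_conformer(bound_set: BoundSet, rng_seed: int) -> Structure:
    """Sample one conformer satisfying every bound (within satisfaction_tol).

    Random isotropic perturbation of the seed followed by sequential pairwise
    bound projection with rng-shuffled pair order per sweep; deterministic
    given rng_seed.
    """
    cfg = bound_set.config
    rng = np.random.default_rng(rng_seed)
    base = bound_set.source.coords
    # anchored atoms carry +-anchor_tol internal bounds: starting them at the
    # seed geometry keeps the projection feasible (they stay quasi-rigid)
    sigma = np.full(len(base), cfg.perturbation_sigma)
    if bound_set.anchored_atoms.size == len(base):
        sigma[bound_set.anchored_atoms] = min(cfg.perturbation_sigma,
                                              0.5 * cfg.anchor_tol)

    bounds = bound_set.bounds
    ii = np.array([b.atom_i for b in bounds], dtype=np.int64)
    jj = np.array([b.atom_j for b in bounds], dtype=np.int64)
    lo = np.array([b.lower for b in bounds], dtype=np.float64)
    hi = np.array([b.upper for b in bounds], dtype=np.float64)
    n_orders = 17
    worst = np.inf
    for _restart in range(5):  # deterministic restarts on stalled projections
        coords = base + rng.normal(0.0, 1.0, base.shape) * sigma[:, None]
        # pre-drawn shuffled orders, cycled over sweeps (keeps the jit loop pure)
        order = np.stack([rng.permutation(len(bounds))
                          for _ in range(n_orders)])
        sweeps = _project_sweeps(coords, ii, jj, lo, hi,
                                 order.astype(np.int64),
                                 cfg.satisfaction_tol, cfg.max_sweeps)
        worst = max_bound_violation(coords, bounds)
        if sweeps > 0 and worst <= cfg.satisfaction_tol:
            out = bound_set.source.copy(label=f"conformer[{rng_seed}]")
            out.set_coords(coords)
            return out
    raise NonConvergenceError(
        f"bound projection did not converge (worst violation {worst:.4f} A)",
        worst_violation=worst)


def build_design_ensemble(seed: Structure, n_conformers: int = 95,
                          config: BoundConfig | None = None,
                          rng_seed: int = 0) -> Ensemble:
    """Seed + n generated conformers; member 0 is the unmodified seed.

    The default of 95 conformers yields the canonical 96-member design
    ensemble (generated conformers plus the original crystal seed).
    """
    if n_conformers < 1:
        raise ConfigError("n_conformers must be >= 1")
    bound_set = derive_bounds(seed, config)
    members = [seed.copy(label="seed")]
    for k in range(n_conformers):
        try:
            members.append(generate_conformer(bound_set, rng_seed + 1 + k))
        except NonConvergenceError as exc:
            raise NonConvergenceError(
                f"conformer {k + 1}: {exc}", exc.worst_violation) from exc
    return Ensemble(members, label="design_ensemble")
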