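"""Two-state molecular-mechanics energy evaluation and minimization.

The reactant complex (ES: substrate docked, not covalently bound) and the
tetrahedral-intermediate complex (ES*: serine O-gamma restrained to the
substrate carbonyl carbon at the transition-state bond length, 1.9 A by
default) are evaluated with a deliberately simple, swappable force field:
pairwise Lennard-Jones + Coulomb with a distance-dependent dielectric
eps(r) = 4r, harmonic bond/angle terms referenced to the input geometry, and
the ES* harmonic restraint.  1-2 and 1-3 pairs are excluded from non-bonded
terms.  Fidelity target is ordinal behaviour of variant rankings, not
reproduction of any production force field's energies — the model spec is a
first-class object precisely so the rank-stability analysis can swap it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .core_structures import Structure, StructureError, _kabsch

__all__ = [
    "StateKind",
    "ComplexState",
    "EnergyModelSpec",
    "MinimizationResult",
    "SubstrateTemplate",
    "OverlapError",
    "DivergenceError",
    "TemplateError",
    "COULOMB_CONSTANT",
    "build_state",
    "evaluate_energy",
    "minimize",
]

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)

# Lennard-Jones parameters per element: (well depth kcal/mol, rmin/2 A)
_LJ_PARAMS = {
    "C": (0.086, 1.908),
    "N": (0.170, 1.824),
    "O": (0.210, 1.661),
    "S": (0.250, 2.000),
    "H": (0.0157, 0.600),
    "P": (0.200, 2.100),
}
_LJ_DEFAULT = (0.100, 1.900)

# Partial-charge template table (per residue name, per atom name).  Shipped as
# data; unknown atoms default to 0.  Values are AMBER-flavoured magnitudes,
# chosen for determinism, not parameterization fidelity.
_BACKBONE_CHARGES = {"N": -0.42, "CA": 0.03, "C": 0.60, "O": -0.57}
PARTIAL_CHARGES: dict[str, dict[str, float]] = {
    "*": dict(_BACKBONE_CHARGES),
    "SER": {"CB": 0.21, "OG": -0.66},
    "THR": {"CB": 0.27, "OG1": -0.67, "CG2": -0.02},
    "CYS": {"CB": 0.11, "SG": -0.31},
    "ASP": {"CB": -0.03, "CG": 0.80, "OD1": -0.80, "OD2": -0.80},
    "GLU": {"CB": 0.0, "CG": -0.02, "CD": 0.80, "OE1": -0.80, "OE2": -0.80},
    "ASN": {"CB": -0.08, "CG": 0.71, "OD1": -0.60, "ND2": -0.91},
    "GLN": {"CB": -0.06, "CG": -0.02, "CD": 0.70, "OE1": -0.61, "NE2": -0.94},
    "HIS": {"CB": -0.08, "CG": 0.19, "ND1": -0.38, "CD2": 0.13,
            "CE1": 0.21, "NE2": -0.57},
    "LYS": {"CB": -0.01, "CG": 0.01, "CD": -0.05, "CE": 0.33, "NZ": -0.39},
    "ARG": {"CB": -0.0, "CG": 0.04, "CD": 0.05, "NE": -0.53, "CZ": 0.81,
            "NH1": -0.45, "NH2": -0.45},
    "TYR": {"CB": -0.01, "CG": -0.11, "CD1": -0.19, "CD2": -0.19,
            "CE1": -0.24, "CE2": -0.24, "CZ": 0.32, "OH": -0.56},
    "TRP": {"CB": -0.01, "CG": -0.14, "CD1": -0.16, "NE1": -0.34,
            "CD2": 0.12, "CE2": 0.14, "CE3": -0.24, "CZ2": -0.26,
            "CZ3": -0.20, "CH2": -0.11},
    # ester-like toy substrate: carbonyl C/O, ester O + methyl, alpha C, tail OH
    "EST": {"C1": 0.65, "O1": -0.55, "O2": -0.45, "C2": 0.10,
            "C3": 0.05, "O3": -0.60},
}


class OverlapError(StructureError):
    """Atom pair closer than 0.1 A: corrupt geometry."""


class DivergenceError(RuntimeError):
    pass


class TemplateError(ValueError):
    pass


class StateKind(enum.Enum):
    ES = "ES"
    ES_STAR = "ES_STAR"


@dataclass(frozen=True)
class EnergyModelSpec:
    """A named, deterministic parameter set for the two-state evaluation."""

    spec_id: str = "default"
    lj_on: bool = True
    coulomb_on: bool = True
    bonds_on: bool = True
    angles_on: bool = True
    dielectric: str = "4r"          # "4r" or "constant"
    dielectric_constant: float = 1.0
    coulomb_k: float = COULOMB_CONSTANT
    charge_scale: float = 1.0        # substrate-parameterization knob
    lj_scale: float = 1.0
    bond_k: float = 300.0            # kcal/mol/A^2
    angle_k: float = 50.0            # kcal/mol/rad^2

    def with_id(self, spec_id: str, **kwargs) -> "EnergyModelSpec":
        return replace(self, spec_id=spec_id, **kwargs)


@dataclass
class SubstrateTemplate:
    """Substrate fragment posed in the seed's active-site frame.

    `anchor_atoms` names three protein atoms (chain, res_id, name) whose
    positions in the reference pose are stored in `anchor_ref_coords`; at
    build time the fragment is rigidly moved by the transform that carries
    the reference anchors onto the current protein's anchors.
    """

    fragment: Structure
    anchor_atoms: tuple[tuple[str, int, str], ...]
    anchor_ref_coords: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        if len(self.anchor_atoms) != 3:
            raise TemplateError("exactly 3 anchor atoms are required")
        self.anchor_ref_coords = np.asarray(self.anchor_ref_coords, float)
        if self.anchor_ref_coords.shape != (3, 3):
            raise TemplateError("anchor_ref_coords must be 3x3")


@dataclass
class ComplexState:
    structure: Structure
    state: StateKind
    covalent_restraint: tuple[int, int, float, float] | None = None
    # (atom index i, atom index j, target length A, force constant kcal/mol/A^2)
    energy_offset: float = 0.0  # biasing hook used by recovery tests

    def __post_init__(self) -> None:
        if self.state is StateKind.ES and self.covalent_restraint is not None:
            raise StructureError("ES state must not carry a covalent restraint")


@dataclass
class MinimizationResult:
    structure: Structure
    energy: float
    iterations: int
    converged: bool
    grad_norm: float
    trace: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# Topology (bonds from covalent distances; reference values from input)
# ---------------------------------------------------------------------------

_COVALENT_RADII = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "H": 0.31,
                   "P": 1.07}


class _Topology:
    def __init__(self, structure: Structure):
        coords = structure.coords
        n = len(structure)
        radii = np.array([_COVALENT_RADII.get(a.element, 0.9)
                          for a in structure.atoms])
        from scipy.spatial import cKDTree

        tree = cKDTree(coords)
        adj: list[set[int]] = [set() for _ in range(n)]
        bonds = []
        for i, j in sorted(map(tuple, tree.query_pairs(r=2.3))):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < 1.3 * (radii[i] + radii[j]):
                adj[i].add(j)
                adj[j].add(i)
                bonds.append((i, j, d))
        angles = []
        for j in range(n):
            nb = sorted(adj[j])
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    i, k = nb[x], nb[y]
                    v1 = coords[i] - coords[j]
                    v2 = coords[k] - coords[j]
                    cosv = np.clip(
                        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1.0, 1.0)
                    angles.append((i, j, k, float(np.arccos(cosv))))
        self.bonds = bonds
        self.angles = angles
        self.neighbors = adj
        self.bond_i = np.array([b[0] for b in bonds], dtype=int)
        self.bond_j = np.array([b[1] for b in bonds], dtype=int)
        self.bond_r0 = np.array([b[2] for b in bonds])
        self.ang_i = np.array([a[0] for a in angles], dtype=int)
        self.ang_j = np.array([a[1] for a in angles], dtype=int)
        self.ang_k = np.array([a[2] for a in angles], dtype=int)
        self.ang_th0 = np.array([a[3] for a in angles])
        excl = set()
        for i, j, _ in bonds:
            excl.add((min(i, j), max(i, j)))
        for i, j, k, _ in angles:
            excl.add((min(i, k), max(i, k)))
        self.excluded_pairs = excl

        self.charges = np.array([self._charge(a) for a in structure.atoms])
        eps, rmin = [], []
        for a in structure.atoms:
            e, r = _LJ_PARAMS.get(a.element, _LJ_DEFAULT)
            eps.append(e)
            rmin.append(r)
        self.lj_eps = np.array(eps)
        self.lj_rmin_half = np.array(rmin)

        iu = np.triu_indices(n, k=1)
        mask = np.ones(len(iu[0]), dtype=bool)
        if excl:
            flat = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(*iu))}
            for i, j in excl:
                k = flat.get((i, j))
                if k is not None:
                    mask[k] = False
        self.pair_i = iu[0][mask]
        self.pair_j = iu[1][mask]
        self._pair_cache: dict = {}

    def nonbonded_pairs(self, restraint) -> tuple[np.ndarray, np.ndarray]:
        """Non-bonded pair lists; a covalent restraint removes the forming
        bond and the 1-3 pairs it creates, exactly as a real bond would."""
        if restraint is None:
            return self.pair_i, self.pair_j
        key = (restraint[0], restraint[1])
        if key not in self._pair_cache:
            ra, rb = key
            drop = {(min(ra, rb), max(ra, rb))}
            for x, y in ((ra, rb), (rb, ra)):
                for nb in self.neighbors[y]:
                    if nb != x:
                        drop.add((min(x, nb), max(x, nb)))
            keep = np.array([(int(i), int(j)) not in drop
                             for i, j in zip(self.pair_i, self.pair_j)])
            self._pair_cache[key] = (self.pair_i[keep], self.pair_j[keep])
        return self._pair_cache[key]

    @staticmethod
    def _charge(atom) -> float:
        res = PARTIAL_CHARGES.get(atom.res_name, {})
        if atom.name in res:
            return res[atom.name]
        return PARTIAL_CHARGES["*"].get(atom.name, 0.0)


def build_topology(structure: Structure) -> _Topology:
    return _Topology(structure)


# ---------------------------------------------------------------------------
# State construction
# ---------------------------------------------------------------------------

def build_state(protein: Structure, substrate_template: SubstrateTemplate,
                state: StateKind | str,
                restraint_target: float = 1.9,
                restraint_k: float = 200.0,
                serine_og: tuple[str, int, str] | None = None,
                carbonyl_c_name: str = "C1") -> ComplexState:
    """Place the substrate by rigid alignment of the anchor frame.

    ES* additionally registers the harmonic Ser-O-gamma -- carbonyl-C
    restraint at `restraint_target` (default 1.9 A, the TS 1 bond length).
    """
    state = StateKind(state)
    cur = []
    for (chain, res_id, name) in substrate_template.anchor_atoms:
        a = protein.find_atom(chain, res_id, name)
        if a is None:
            raise TemplateError(f"anchor atom {(chain, res_id, name)} missing")
        cur.append(a.coords)
    cur = np.array(cur)
    ref = substrate_template.anchor_ref_coords
    # collinear anchors make the frame degenerate
    v1, v2 = ref[1] - ref[0], ref[2] - ref[0]
    if np.linalg.norm(np.cross(v1, v2)) < 1e-6:
        raise TemplateError("anchor atoms are collinear: degenerate frame")
    R, t, _ = _kabsch(ref, cur)
    frag = substrate_template.fragment.copy()
    frag.set_coords(frag.coords @ R.T + t)

    atoms = [a.copy() for a in protein.atoms] + [a.copy() for a in frag.atoms]
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    complex_structure = Structure(atoms, label=f"{protein.label}|{state.value}",
                                  meta=dict(protein.meta))

    restraint = None
    if state is StateKind.ES_STAR:
        if serine_og is None:
            ser = [a for a in protein.atoms
                   if a.res_name == "SER" and a.name == "OG"]
            if not ser:
                raise TemplateError("no serine OG found for the ES* restraint")
            serine_og = ser[0].key
        index = complex_structure.atom_index()
        if serine_og not in index:
            raise TemplateError(f"restraint atom {serine_og} missing")
        og_idx = index[serine_og]
        c_idx = None
        for i, a in enumerate(complex_structure.atoms):
            if a.res_name == frag.atoms[0].res_name and a.name == carbonyl_c_name:
                c_idx = i
        if c_idx is None:
            raise TemplateError(f"carbonyl atom {carbonyl_c_name} missing")
        restraint = (og_idx, c_idx, restraint_target, restraint_k)
    return ComplexState(complex_structure, state, restraint)


# ---------------------------------------------------------------------------
# Energy and gradient
# ---------------------------------------------------------------------------

def _energy_gradient(coords: np.ndarray, topo: _Topology,
                     spec: EnergyModelSpec,
                     restraint: tuple[int, int, float, float] | None,
                     offset: float,
                     want_grad: bool = True) -> tuple[float, np.ndarray]:
    n = len(coords)
    grad = np.zeros_like(coords)
    energy = offset

    if n > 1:
        from scipy.spatial.distance import pdist

        dmin = float(pdist(coords).min())
        if dmin < 0.1:
            raise OverlapError(f"atom pair at {dmin:.3f} A (< 0.1 A)")
    pi, pj = topo.nonbonded_pairs(restraint)
    dvec = coords[pi] - coords[pj]
    r = np.sqrt((dvec ** 2).sum(axis=1))
    unit = dvec / np.maximum(r, 1e-12)[:, None]

    if spec.lj_on and r.size:
        eps = spec.lj_scale * np.sqrt(topo.lj_eps[pi] * topo.lj_eps[pj])
        rmin = topo.lj_rmin_half[pi] + topo.lj_rmin_half[pj]
        q6 = (rmin / r) ** 6
        e_lj = eps * (q6 * q6 - 2.0 * q6)
        energy += float(e_lj.sum())
        if want_grad:
            de_dr = eps * (-12.0 * q6 * q6 + 12.0 * q6) / r
            f = de_dr[:, None] * unit
            np.add.at(grad, pi, f)
            np.subtract.at(grad, pj, f)

    if spec.coulomb_on and r.size:
        qq = (spec.charge_scale ** 2) * topo.charges[pi] * topo.charges[pj]
        if spec.dielectric == "4r":
            e_c = spec.coulomb_k * qq / (4.0 * r ** 2)
            de_dr = -2.0 * e_c / r
        else:
            e_c = spec.coulomb_k * qq / (spec.dielectric_constant * r)
            de_dr = -e_c / r
        energy += float(e_c.sum())
        if want_grad:
            f = de_dr[:, None] * unit
            np.add.at(grad, pi, f)
            np.subtract.at(grad, pj, f)

    if spec.bonds_on and topo.bond_i.size:
        v = coords[topo.bond_i] - coords[topo.bond_j]
        d = np.sqrt((v ** 2).sum(axis=1))
        dd = d - topo.bond_r0
        energy += float(spec.bond_k * (dd ** 2).sum())
        if want_grad:
            g = (2.0 * spec.bond_k * dd / np.maximum(d, 1e-12))[:, None] * v
            np.add.at(grad, topo.bond_i, g)
            np.subtract.at(grad, topo.bond_j, g)

    if spec.angles_on and topo.ang_i.size:
        v1 = coords[topo.ang_i] - coords[topo.ang_j]
        v2 = coords[topo.ang_k] - coords[topo.ang_j]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        cosv = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
        th = np.arccos(cosv)
        dth_all = th - topo.ang_th0
        energy += float(spec.angle_k * (dth_all ** 2).sum())
        if want_grad:
            sinv = np.maximum(np.sqrt(1.0 - cosv ** 2), 1e-8)
            pref = (-2.0 * spec.angle_k * dth_all / sinv)
            g_i = pref[:, None] * (v2 / (n1 * n2)[:, None]
                                   - (cosv / n1 ** 2)[:, None] * v1)
            g_k = pref[:, None] * (v1 / (n1 * n2)[:, None]
                                   - (cosv / n2 ** 2)[:, None] * v2)
            np.add.at(grad, topo.ang_i, g_i)
            np.add.at(grad, topo.ang_k, g_k)
            np.subtract.at(grad, topo.ang_j, g_i + g_k)

    if restraint is not None:
        i, j, r0, k_r = restraint
        v = coords[i] - coords[j]
        d = float(np.linalg.norm(v))
        energy += k_r * (d - r0) ** 2
        if want_grad and d > 1e-12:
            g = 2.0 * k_r * (d - r0) * v / d
            grad[i] += g
            grad[j] -= g

    return energy, grad


def evaluate_energy(state: ComplexState, spec: EnergyModelSpec | None = None,
                    topology: _Topology | None = None) -> float:
    """Potential energy (kcal/mol, arbitrary offset) of a complex state."""
    spec = spec or EnergyModelSpec()
    topo = topology or build_topology(state.structure)
    coords = state.structure.coords
    if not np.all(np.isfinite(coords)):
        raise StructureError("non-finite coordinates")
    e, _ = _energy_gradient(coords, topo, spec, state.covalent_restraint,
                            state.energy_offset, want_grad=False)
    return e


def minimize(state: ComplexState, spec: EnergyModelSpec | None = None,
             max_iter: int = 2000, grad_tol: float = 0.01,
             initial_step: float = 1e-3) -> MinimizationResult:
    """Steepest descent with step halving; energy trace is monotone.

    Deterministic given inputs.  Convergence: RMS gradient <= grad_tol
    (kcal/mol/A).  max_iter=0 evaluates in place (frozen geometry).
    """
    spec = spec or EnergyModelSpec()
    topo = build_topology(state.structure)
    coords = state.structure.coords
    energy, grad = _energy_gradient(coords, topo, spec,
                                    state.covalent_restraint,
                                    state.energy_offset)
    if not np.isfinite(energy):
        raise DivergenceError("non-finite starting energy")
    trace = [energy]
    step = initial_step
    it = 0
    gnorm = float(np.sqrt((grad ** 2).mean()))
    while it < max_iter and gnorm > grad_tol:
        it += 1
        trial = coords - step * grad
        try:
            e_new, g_new = _energy_gradient(trial, topo, spec,
                                            state.covalent_restraint,
                                            state.energy_offset)
        except OverlapError:
            e_new = np.inf
            g_new = grad
        if not np.isfinite(e_new) and step < 1e-14:
            raise DivergenceError("non-finite energy during descent")
        if e_new < energy:
            coords, energy, grad = trial, e_new, g_new
            trace.append(energy)
            step = min(step * 1.2, 0.05)
            gnorm = float(np.sqrt((grad ** 2).mean()))
        else:
            step *= 0.5
            if step < 1e-14:
                break
    out = state.structure.copy()
    out.set_coords(coords)
    return MinimizationResult(
        structure=out, energy=energy, iterations=it,
        converged=gnorm <= grad_tol, grad_norm=gnorm,
        trace=np.array(trace))
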