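"""In-silico point mutation with a minimal deterministic rotamer search.

Side chains are rebuilt from idealized internal-coordinate templates (a
desk-scale stand-in for a full rotamer library): each chi angle is sampled on
the grid {-60, 60, 180} degrees and the combination with the lowest steric
clash count wins, ties broken by grid order.  Backbone atoms (N, CA, C, O)
are never touched.  Ring residues use idealized chains whose rings close only
approximately; this is documented as a fidelity limitation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core_structures import Atom, Ensemble, Structure

__all__ = [
    "MutationSpec",
    "Variant",
    "MutationError",
    "AA_1TO3",
    "AA_3TO1",
    "apply_mutation",
    "apply_variant",
    "enumerate_singles",
    "enumerate_doubles",
    "parse_variant_name",
]

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
AA_3TO1 = {v: k for k, v in AA_1TO3.items()}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BONDI = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
CHI_GRID = (-60.0, 60.0, 180.0)


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpec:
    """One point substitution, named '{from}{res_id}{to}' (e.g. 'H14G')."""

    chain: str
    res_id: int
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if self.from_aa not in AA_1TO3 or self.to_aa not in AA_1TO3:
            raise MutationError(f"unknown amino-acid code in {self}")
        if self.from_aa == self.to_aa:
            raise MutationError("to_aa must differ from from_aa")

    @property
    def name(self) -> str:
        return f"{self.from_aa}{self.res_id}{self.to_aa}"


@dataclass(frozen=True)
class Variant:
    """One or more point mutations; doubles join names with '_'."""

    mutations: tuple[MutationSpec, ...]

    @property
    def name(self) -> str:
        return "_".join(m.name for m in self.mutations)


def parse_variant_name(name: str, chain: str = "A") -> Variant:
    specs = []
    for part in name.split("_"):
        if len(part) < 3:
            raise MutationError(f"unparseable mutation name {part!r}")
        specs.append(MutationSpec(chain, int(part[1:-1]), part[0], part[-1]))
    return Variant(tuple(specs))


# ---------------------------------------------------------------------------
# Internal-coordinate side-chain templates
# ---------------------------------------------------------------------------
# Each entry: (atom, element, parent, ref2, ref3, bond A, angle deg, dihedral)
# where dihedral is ("chi", k, offset_deg) or a fixed float (deg).  Atoms are
# placed by NeRF in listing order; CB is placed first from the backbone frame.

_CB = ("CB", "C", "CA", "N", "C", 1.53, 110.4, 123.0)


def _t(name, el, p, r2, r3, b, a, d):
    return (name, el, p, r2, r3, b, a, d)


SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, _t("OG", "O", "CB", "CA", "N", 1.42, 110.8, ("chi", 1, 0))],
    "CYS": [_CB, _t("SG", "S", "CB", "CA", "N", 1.81, 113.8, ("chi", 1, 0))],
    "THR": [_CB,
            _t("OG1", "O", "CB", "CA", "N", 1.42, 109.6, ("chi", 1, 0)),
            _t("CG2", "C", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, -120))],
    "VAL": [_CB,
            _t("CG1", "C", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, 0)),
            _t("CG2", "C", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, 120))],
    "LEU": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.53, 116.3, ("chi", 1, 0)),
            _t("CD1", "C", "CG", "CB", "CA", 1.52, 110.5, ("chi", 2, 0)),
            _t("CD2", "C", "CG", "CB", "CA", 1.52, 110.5, ("chi", 2, 120))],
    "ILE": [_CB,
            _t("CG1", "C", "CB", "CA", "N", 1.53, 110.5, ("chi", 1, 0)),
            _t("CG2", "C", "CB", "CA", "N", 1.52, 110.5, ("chi", 1, -120)),
            _t("CD1", "C", "CG1", "CB", "CA", 1.52, 113.8, ("chi", 2, 0))],
    "MET": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.53, 114.1, ("chi", 1, 0)),
            _t("SD", "S", "CG", "CB", "CA", 1.81, 112.7, ("chi", 2, 0)),
            _t("CE", "C", "SD", "CG", "CB", 1.79, 100.9, ("chi", 3, 0))],
    "ASP": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.52, 112.6, ("chi", 1, 0)),
            _t("OD1", "O", "CG", "CB", "CA", 1.25, 118.4, ("chi", 2, 0)),
            _t("OD2", "O", "CG", "CB", "CA", 1.25, 118.4, ("chi", 2, 180))],
    "ASN": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.52, 112.6, ("chi", 1, 0)),
            _t("OD1", "O", "CG", "CB", "CA", 1.23, 120.8, ("chi", 2, 0)),
            _t("ND2", "N", "CG", "CB", "CA", 1.33, 116.4, ("chi", 2, 180))],
    "GLU": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.53, 114.1, ("chi", 1, 0)),
            _t("CD", "C", "CG", "CB", "CA", 1.52, 112.6, ("chi", 2, 0)),
            _t("OE1", "O", "CD", "CG", "CB", 1.25, 118.4, ("chi", 3, 0)),
            _t("OE2", "O", "CD", "CG", "CB", 1.25, 118.4, ("chi", 3, 180))],
    "GLN": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.53, 114.1, ("chi", 1, 0)),
            _t("CD", "C", "CG", "CB", "CA", 1.52, 112.6, ("chi", 2, 0)),
            _t("OE1", "O", "CD", "CG", "CB", 1.23, 120.8, ("chi", 3, 0)),
            _t("NE2", "N", "CD", "CG", "CB", 1.33, 116.4, ("chi", 3, 180))],
    "LYS": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.53, 114.1, ("chi", 1, 0)),
            _t("CD", "C", "CG", "CB", "CA", 1.52, 111.3, ("chi", 2, 0)),
            _t("CE", "C", "CD", "CG", "CB", 1.52, 111.3, ("chi", 3, 0)),
            _t("NZ", "N", "CE", "CD", "CG", 1.49, 111.7, ("chi", 4, 0))],
    "ARG": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.53, 114.1, ("chi", 1, 0)),
            _t("CD", "C", "CG", "CB", "CA", 1.52, 111.3, ("chi", 2, 0)),
            _t("NE", "N", "CD", "CG", "CB", 1.46, 111.5, ("chi", 3, 0)),
            _t("CZ", "C", "NE", "CD", "CG", 1.33, 124.2, ("chi", 4, 0)),
            _t("NH1", "N", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
            _t("NH2", "N", "CZ", "NE", "CD", 1.33, 120.0, 180.0)],
    "HIS": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.50, 113.8, ("chi", 1, 0)),
            _t("ND1", "N", "CG", "CB", "CA", 1.38, 122.7, ("chi", 2, 0)),
            _t("CD2", "C", "CG", "CB", "CA", 1.36, 131.0, ("chi", 2, 180)),
            _t("CE1", "C", "ND1", "CG", "CB", 1.32, 109.0, 180.0),
            _t("NE2", "N", "CD2", "CG", "CB", 1.37, 107.0, 180.0)],
    "PHE": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.50, 113.8, ("chi", 1, 0)),
            _t("CD1", "C", "CG", "CB", "CA", 1.39, 120.7, ("chi", 2, 0)),
            _t("CD2", "C", "CG", "CB", "CA", 1.39, 120.7, ("chi", 2, 180)),
            _t("CE1", "C", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
            _t("CE2", "C", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
            _t("CZ", "C", "CE1", "CD1", "CG", 1.39, 120.0, 0.0)],
    "TYR": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.50, 113.8, ("chi", 1, 0)),
            _t("CD1", "C", "CG", "CB", "CA", 1.39, 120.7, ("chi", 2, 0)),
            _t("CD2", "C", "CG", "CB", "CA", 1.39, 120.7, ("chi", 2, 180)),
            _t("CE1", "C", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
            _t("CE2", "C", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
            _t("CZ", "C", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
            _t("OH", "O", "CZ", "CE1", "CD1", 1.36, 120.0, 180.0)],
    "TRP": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.50, 113.8, ("chi", 1, 0)),
            _t("CD1", "C", "CG", "CB", "CA", 1.37, 127.0, ("chi", 2, 0)),
            _t("CD2", "C", "CG", "CB", "CA", 1.43, 126.6, ("chi", 2, 180)),
            _t("NE1", "N", "CD1", "CG", "CB", 1.37, 110.1, 180.0),
            _t("CE2", "C", "CD2", "CG", "CB", 1.41, 107.3, 180.0),
            _t("CE3", "C", "CD2", "CG", "CB", 1.40, 133.9, 0.0),
            _t("CZ2", "C", "CE2", "CD2", "CG", 1.40, 122.4, 180.0),
            _t("CZ3", "C", "CE3", "CD2", "CG", 1.40, 118.6, 180.0),
            _t("CH2", "C", "CZ2", "CE2", "CD2", 1.40, 117.5, 180.0)],
    "PRO": [_CB,
            _t("CG", "C", "CB", "CA", "N", 1.50, 104.5, ("chi", 1, 0)),
            _t("CD", "C", "CG", "CB", "CA", 1.50, 105.0, -35.0)],
}

N_CHI = {res: max([d[1] for *_, d in [(t[-1],) for t in tmpl]
                   if isinstance(d, tuple)] or [0])
         for res, tmpl in SIDECHAIN_TEMPLATES.items()}


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given references a-b-c, bond c-d, angle b-c-d, dihedral a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise MutationError("degenerate reference frame for side-chain placement")
    n /= norm
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dih),
        bond * np.sin(angle) * np.sin(dih),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def measure_dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _build_sidechain(res_name: str, frame: dict[str, np.ndarray],
                     chis: tuple[float, ...]) -> list[tuple[str, str, np.ndarray]]:
    placed = dict(frame)  # N, CA, C coordinates of the target residue
    out: list[tuple[str, str, np.ndarray]] = []
    for name, el, p, r2, r3, bond, angle, dih in SIDECHAIN_TEMPLATES[res_name]:
        if isinstance(dih, tuple):
            _, k, offset = dih
            dval = chis[k - 1] + offset
        else:
            dval = dih
        pos = nerf_place(placed[r3], placed[r2], placed[p], bond, angle, dval)
        placed[name] = pos
        out.append((name, el, pos))
    return out


def _clash_count(new_atoms: list[np.ndarray], new_elements: list[str],
                 other_coords: np.ndarray, other_elements: list[str],
                 factor: float = 0.8) -> int:
    if not new_atoms or other_coords.size == 0:
        return 0
    P = np.array(new_atoms)
    d = np.linalg.norm(P[:, None, :] - other_coords[None, :, :], axis=2)
    r_new = np.array([_BONDI.get(e, 1.7) for e in new_elements])
    r_oth = np.array([_BONDI.get(e, 1.7) for e in other_elements])
    lim = factor * (r_new[:, None] + r_oth[None, :])
    return int((d < lim).sum())


def apply_mutation(structure: Structure, spec: MutationSpec,
                   clash_factor: float = 0.8,
                   chi_grid: tuple[float, ...] = CHI_GRID) -> Structure:
    """Replace one residue's side chain; backbone atoms stay bitwise unchanged.

    The chi combination minimizing the steric clash count (heavy-atom pairs
    closer than `clash_factor` x sum of Bondi radii, against all atoms outside
    the mutated residue and the adjacent backbone) is chosen; if no clash-free
    rotamer exists the result carries meta['clash_warning'].
    """
    res_atoms = [a for a in structure.atoms
                 if a.chain == spec.chain and a.res_id == spec.res_id]
    if not res_atoms:
        raise MutationError(f"residue {spec.chain}{spec.res_id} not found")
    present = AA_3TO1.get(res_atoms[0].res_name)
    if present != spec.from_aa:
        raise MutationError(
            f"residue {spec.res_id} is {res_atoms[0].res_name}, "
            f"spec says {spec.from_aa}")
    new_res3 = AA_1TO3[spec.to_aa]

    frame = {}
    for bb in ("N", "CA", "C"):
        a = structure.find_atom(spec.chain, spec.res_id, bb)
        if a is None:
            raise MutationError(f"backbone atom {bb} missing at {spec.res_id}")
        frame[bb] = a.coords.copy()

    # environment = everything outside the residue and the flanking backbone
    env_coords, env_elements = [], []
    for a in structure.atoms:
        if a.chain == spec.chain and a.res_id == spec.res_id:
            continue
        if (a.chain == spec.chain and abs(a.res_id - spec.res_id) == 1
                and a.name in ("N", "CA", "C", "O")):
            continue
        env_coords.append(a.coords)
        env_elements.append(a.element)
    env_coords = np.array(env_coords) if env_coords else np.zeros((0, 3))

    n_chi = N_CHI[new_res3]
    best = None
    for chis in itertools.product(chi_grid, repeat=n_chi) or [()]:
        atoms = _build_sidechain(new_res3, frame, chis)
        score = _clash_count([p for *_, p in atoms], [e for _, e, _ in atoms],
                             env_coords, env_elements, clash_factor)
        if best is None or score < best[0]:
            best = (score, atoms)
        if score == 0:
            break
    score, side_atoms = best

    out_atoms: list[Atom] = []
    for a in structure.atoms:
        if a.chain == spec.chain and a.res_id == spec.res_id:
            if a.name in ("N", "CA", "C", "O"):
                b = a.copy()
                b.res_name = new_res3
                out_atoms.append(b)
            # side-chain atoms (and hydrogens) of the old residue are dropped
        else:
            out_atoms.append(a.copy())
    # insert the new side chain right after the residue backbone
    insert_at = max(i for i, a in enumerate(out_atoms)
                    if a.chain == spec.chain and a.res_id == spec.res_id) + 1
    for off, (name, el, pos) in enumerate(side_atoms):
        out_atoms.insert(insert_at + off,
                         Atom(0, name, el, new_res3, spec.res_id, spec.chain, pos))
    for i, a in enumerate(out_atoms, start=1):
        a.serial = i
    out = Structure(out_atoms, label=f"{structure.label}|{spec.name}",
                    meta=dict(structure.meta))
    if score > 0:
        out.meta["clash_warning"] = {"mutation": spec.name, "clashes": score}
    return out


def apply_variant(structure: Structure, variant: Variant,
                  clash_factor: float = 0.8) -> Structure:
    out = structure
    for spec in variant.mutations:
        out = apply_mutation(out, spec, clash_factor=clash_factor)
    return out


def mutate_ensemble(ensemble: Ensemble, variant: Variant,
                    clash_factor: float = 0.8) -> Ensemble:
    return Ensemble([apply_variant(m, variant, clash_factor)
                     for m in ensemble.members], label=variant.name)


def enumerate_singles(structure: Structure,
                      positions: list[int] | None = None,
                      excluded: frozenset[str] | set[str] = frozenset(),
                      chain: str = "A") -> list[MutationSpec]:
    """All 19-minus-exclusions substitutions per position, stably ordered."""
    if positions is None:
        positions = sorted({a.res_id for a in structure.atoms
                            if a.chain == chain and a.res_name in AA_3TO1})
    specs: list[MutationSpec] = []
    for pos in positions:
        res = [a for a in structure.atoms
               if a.chain == chain and a.res_id == pos]
        if not res:
            raise MutationError(f"position {pos} not in chain {chain}")
        from_aa = AA_3TO1.get(res[0].res_name)
        if from_aa is None:
            raise MutationError(f"position {pos} is not a standard residue")
        for to_aa in AMINO_ACIDS:
            if to_aa == from_aa or to_aa in excluded:
                continue
            specs.append(MutationSpec(chain, pos, from_aa, to_aa))
    return specs


def enumerate_doubles(template_specs: list[MutationSpec],
                      structure: Structure,
                      positions: list[int],
                      excluded: frozenset[str] | set[str] = frozenset(),
                      chain: str = "A") -> list[Variant]:
    """Cross product of template singles x candidate singles, canonical names.

    Generated doubles are ordered by ascending residue id within the name.
    """
    tpl_positions = {t.res_id for t in template_specs}
    if tpl_positions & set(positions):
        raise MutationError(
            "template and candidate positions overlap: "
            f"{sorted(tpl_positions & set(positions))}")
    singles = enumerate_singles(structure, positions, excluded, chain)
    variants: list[Variant] = []
    seen: set[str] = set()
    for tpl in template_specs:
        for s in singles:
            pair = tuple(sorted((tpl, s), key=lambda m: (m.res_id, m.to_aa)))
            v = Variant(pair)
            if v.name not in seen:
                seen.add(v.name)
                variants.append(v)
    return variants
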