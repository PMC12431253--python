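"""Structure/ensemble data model, PDB I/O, selections, superposition and RMSD/RMSF.

Coordinates are in Angstrom throughout; residue numbering is 1-based as in PDB
records and never re-indexed.  Structures may lack hydrogens — operations that
need them (the hydrogen-bond angle test) define their own fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "Selection",
    "SuperpositionResult",
    "FlexibilityProfile",
    "StructureError",
    "MalformedInputError",
    "TopologyError",
    "DegenerateSelectionError",
    "InsufficientFramesError",
    "read_structure",
    "write_structure",
    "superpose",
    "apply_transform",
    "pairwise_rmsd_matrix",
    "rmsf_profile",
    "ACTIVE_SITE_RESIDUES",
]

# Residues whose backbone defines the canonical active-site selection
# (catalytic triad S82/H251/D229 plus oxyanion-hole residues 16 and 83).
ACTIVE_SITE_RESIDUES = (16, 82, 83, 229, 251)
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Base class for structural-model errors."""


class MalformedInputError(StructureError):
    """Unparseable or internally inconsistent PDB input."""


class TopologyError(StructureError):
    """Atom sets differ where topology identity is required."""


class DegenerateSelectionError(StructureError):
    """Selection yields too few or geometrically degenerate atom pairs."""


class InsufficientFramesError(StructureError):
    """Operation needs more ensemble members than provided."""


@dataclass
class Atom:
    """A single atom with PDB-style identity and Cartesian coordinates (A)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    chain: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise StructureError(f"atom {self.name}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: non-finite coordinates")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_id, self.name)

    def copy(self) -> "Atom":
        return Atom(self.serial, self.name, self.element, self.res_name,
                    self.res_id, self.chain, self.coords.copy())


@dataclass
class Structure:
    """An ordered list of atoms; atom order is stable under round-trip I/O."""

    atoms: list[Atom]
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("a Structure needs at least one atom")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.key in seen:
                raise MalformedInputError(
                    f"duplicate atom {a.key} within one structure/model")
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        for a, x in zip(self.atoms, xyz):
            a.coords = x.copy()

    def copy(self, label: str | None = None) -> "Structure":
        return Structure([a.copy() for a in self.atoms],
                         label if label is not None else self.label,
                         dict(self.meta))

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        return {a.key: i for i, a in enumerate(self.atoms)}

    def find_atom(self, chain: str, res_id: int, name: str) -> Atom | None:
        for a in self.atoms:
            if a.chain == chain and a.res_id == res_id and a.name == name:
                return a
        return None

    def residue_ids(self) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        for a in self.atoms:
            k = (a.chain, a.res_id)
            if not out or out[-1] != k:
                if k not in out:
                    out.append(k)
        return out


def _topology_signature(s: Structure) -> tuple:
    return tuple((a.chain, a.res_id, a.name) for a in s.atoms)


@dataclass
class Ensemble:
    """Ordered, topology-identical multi-conformer set."""

    members: list[Structure]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise StructureError("an Ensemble needs at least one member")
        sig0 = _topology_signature(self.members[0])
        for i, m in enumerate(self.members[1:], start=1):
            if _topology_signature(m) != sig0:
                raise TopologyError(
                    f"member {i} differs in atom set/order from member 0")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n_atoms(self) -> int:
        return len(self.members[0])

    def coords(self) -> np.ndarray:
        """(n_members, n_atoms, 3) coordinate array."""
        return np.stack([m.coords for m in self.members])


class Selection:
    """Predicate over (chain, res_id, atom name) applied to structures.

    Applying a selection to topology-identical structures yields
    index-identical subsets (the predicate only looks at atom identity).
    """

    def __init__(self, predicate: Callable[[str, int, str], bool], name: str = ""):
        self.predicate = predicate
        self.name = name

    def indices(self, structure: Structure) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(structure.atoms)
             if self.predicate(a.chain, a.res_id, a.name)],
            dtype=int,
        )

    @staticmethod
    def ca() -> "Selection":
        return Selection(lambda c, r, n: n == "CA", name="CA")

    @staticmethod
    def backbone(res_ids: Iterable[int] | None = None) -> "Selection":
        rset = None if res_ids is None else set(res_ids)
        return Selection(
            lambda c, r, n: n in BACKBONE_ATOMS and (rset is None or r in rset),
            name="backbone",
        )

    @staticmethod
    def active_site_backbone(
        res_ids: Iterable[int] = ACTIVE_SITE_RESIDUES,
    ) -> "Selection":
        sel = Selection.backbone(res_ids)
        sel.name = "active_site_backbone"
        return sel

    @staticmethod
    def atoms(keys: Iterable[tuple[str, int, str]]) -> "Selection":
        kset = set(keys)
        return Selection(lambda c, r, n: (c, r, n) in kset, name="atoms")

    @staticmethod
    def named(name: str, **kwargs) -> "Selection":
        if name == "CA":
            return Selection.ca()
        if name == "active_site_backbone":
            res = kwargs.get("res_ids", ACTIVE_SITE_RESIDUES)
            return Selection.active_site_backbone(res)
        raise KeyError(f"unknown named selection {name!r}")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray    # 3x3, det +1
    translation: np.ndarray  # 3-vector, A
    rmsd: float              # A, least-squares minimum over the selection


FlexibilityProfile = dict  # res_id -> RMSF (A)


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/HETATM/MODEL/ENDMDL/TER subset)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str) -> tuple[Atom, str, float]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17]
        res_name = line[17:20].strip()
        chain = line[21:22]
        res_id = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise MalformedInputError(f"unparseable record: {line.rstrip()!r}") from exc
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1]
    atom = Atom(serial, name, element, res_name, res_id,
                chain if chain.strip() else "A", np.array([x, y, z]))
    return atom, altloc, occupancy


def _resolve_altlocs(records: list[tuple[Atom, str, float]]) -> list[Atom]:
    """Keep the highest-occupancy conformer; ties break by altloc letter order."""
    chosen: dict[tuple[str, int, str], tuple[float, str, int, Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for idx, (atom, altloc, occ) in enumerate(records):
        key = atom.key
        if key not in chosen:
            chosen[key] = (occ, altloc, idx, atom)
            order.append(key)
        else:
            prev_occ, prev_alt, prev_idx, _ = chosen[key]
            if altloc == prev_alt:
                raise MalformedInputError(f"duplicate atom {key} in model")
            if occ > prev_occ or (occ == prev_occ and altloc < prev_alt):
                chosen[key] = (occ, altloc, prev_idx, atom)
    return [chosen[k][3] for k in order]


def read_structure(pdb_text: str, label: str = "") -> Ensemble:
    """Parse PDB text into an Ensemble (one member per MODEL block).

    Text without MODEL records yields a single-member ensemble.  The altloc
    policy keeps the highest-occupancy conformer (ties by altloc letter).
    Coordinates are read at PDB precision, 0.001 A.
    """
    models: list[list[tuple[Atom, str, float]]] = []
    current: list[tuple[Atom, str, float]] = []
    saw_model = False
    for line in pdb_text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            saw_model = True
            if current:
                models.append(current)
                current = []
        elif rec == "ENDMDL":
            models.append(current)
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line))
    if current or not models:
        if current:
            models.append(current)
    if not saw_model and len(models) > 1:  # pragma: no cover - defensive
        models = [sum(models, [])]
    members: list[Structure] = []
    for i, recs in enumerate(models):
        if not recs:
            raise MalformedInputError(f"model {i + 1} contains no atoms")
        members.append(Structure(_resolve_altlocs(recs), label=f"{label}#{i}"))
    if not members:
        raise MalformedInputError("no ATOM/HETATM records found")
    try:
        return Ensemble(members, label=label)
    except TopologyError as exc:
        raise TopologyError(f"inconsistent atom sets across models: {exc}") from exc


_STD_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _format_atom_line(atom: Atom, serial: int) -> str:
    record = "ATOM  " if atom.res_name in _STD_RES else "HETATM"
    name = atom.name
    # PDB convention: 1-char element names start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    return (
        f"{record}{serial:5d} {name:<4s} {atom.res_name:<3s} {atom.chain}"
        f"{atom.res_id:4d}    {atom.coords[0]:8.3f}{atom.coords[1]:8.3f}"
        f"{atom.coords[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_structure(ensemble: Ensemble | Structure) -> str:
    """Serialize to PDB text; multi-member ensembles get MODEL/ENDMDL blocks."""
    if isinstance(ensemble, Structure):
        ensemble = Ensemble([ensemble])
    lines: list[str] = []
    multi = len(ensemble) > 1
    for m, member in enumerate(ensemble.members, start=1):
        if multi:
            lines.append(f"MODEL {m:8d}")
        serial = 0
        prev_chain = None
        for atom in member.atoms:
            if prev_chain is not None and atom.chain != prev_chain:
                lines.append("TER")
            serial += 1
            lines.append(_format_atom_line(atom, serial))
            prev_chain = atom.chain
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Superposition (Kabsch) and RMSD/RMSF analytics
# ---------------------------------------------------------------------------

def _matched_coords(
    mobile: Structure, reference: Structure, sel: Selection
) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = sel.indices(reference)
    if ref_idx.size == 0:
        raise DegenerateSelectionError("selection matches no atoms")
    mob_index = mobile.atom_index()
    pairs_m, pairs_r = [], []
    for i in ref_idx:
        key = reference.atoms[i].key
        j = mob_index.get(key)
        if j is not None:
            pairs_r.append(reference.atoms[i].coords)
            pairs_m.append(mobile.atoms[j].coords)
    if len(pairs_m) < 3:
        raise DegenerateSelectionError(
            f"only {len(pairs_m)} matched atom pairs; need >= 3")
    return np.array(pairs_m), np.array(pairs_r)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of P onto Q. Returns (R, t, rmsd); x' = R x + t."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear) point sets have rank < 2
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise DegenerateSelectionError("selected atoms are (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def superpose(mobile: Structure, reference: Structure,
              sel: Selection) -> SuperpositionResult:
    """Kabsch least-squares superposition of `mobile` onto `reference`.

    The returned rotation has det +1 (reflections corrected); applying
    (rotation, translation) to the mobile selection attains the reported RMSD.
    """
    P, Q = _matched_coords(mobile, reference, sel)
    R, t, rmsd = _kabsch(P, Q)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_transform(structure: Structure, result: SuperpositionResult) -> Structure:
    out = structure.copy()
    out.set_coords(structure.coords @ result.rotation.T + result.translation)
    return out


def pairwise_rmsd_matrix(structures: Sequence[Structure],
                         sel: Selection) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise best-fit RMSDs (A)."""
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = superpose(structures[i], structures[j], sel).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


def rmsf_profile(ensemble: Ensemble, sel: Selection,
                 fit: bool = True) -> FlexibilityProfile:
    """Per-residue RMSF (A) of the selected atoms about their frame-mean position.

    If `fit`, every member is first superposed onto member 0 on the selection.
    Residues with several selected atoms report the mean of per-atom RMSFs.
    """
    if len(ensemble) < 2:
        raise InsufficientFramesError("RMSF needs at least 2 ensemble members")
    ref = ensemble.members[0]
    members = ensemble.members
    if fit:
        members = [ref] + [
            apply_transform(m, superpose(m, ref, sel)) for m in members[1:]
        ]
    idx = sel.indices(ref)
    if idx.size == 0:
        raise DegenerateSelectionError("selection matches no atoms")
    coords = np.stack([m.coords[idx] for m in members])  # (F, A, 3)
    mean = coords.mean(axis=0)
    msf = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom
    rmsf_atom = np.sqrt(msf)
    profile: dict[int, float] = {}
    counts: dict[int, int] = {}
    for k, i in enumerate(idx):
        rid = ref.atoms[i].res_id
        profile[rid] = profile.get(rid, 0.0) + rmsf_atom[k]
        counts[rid] = counts.get(rid, 0) + 1
    return {rid: profile[rid] / counts[rid] for rid in profile}
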