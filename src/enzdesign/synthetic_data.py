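"""Synthetic inputs with planted ground truth for every pipeline stage.

Everything the design pipeline consumes can be generated here with known
answers: a toy serine-hydrolase-like protein with a catalytic triad and an
ester fragment in its pocket, Gaussian flexibility ensembles with stated
per-residue RMSF targets, paired two-state energy tables with planted
per-variant offsets, hydrogen-bond frame sets with set occupancies, and MSAs
with controlled per-column conservation.  All generators are deterministic
under (config, rng_seed) via named RNG substreams, and each writes a
GroundTruth sidecar describing exactly what was planted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core_structures import Atom, Ensemble, Structure, StructureError
from .energy_model import SubstrateTemplate
from .hbond_analysis import HBondDefinition
from .mutagenesis import (MutationSpec, _build_sidechain, apply_mutation,
                          nerf_place)
from .pssm import AA_ORDER, MSA
from .rank_filter import WT_NAME, DeltaETable

__all__ = [
    "GroundTruth",
    "make_toy_enzyme",
    "toy_substrate_template",
    "make_flex_ensemble",
    "plant_variant_effects",
    "make_hbond_frames",
    "make_msa",
]

SUBSTRATE_RES_NAME = "EST"

# named substreams keep generator draws independent of call order
_STREAMS = {"toy": 11, "flex": 23, "effects": 37, "hbond": 53, "msa": 71}


def _rng(rng_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(rng_seed) % (2 ** 31), _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Planted parameters serialized alongside every generated dataset."""

    generator: str
    rng_seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


# ---------------------------------------------------------------------------
# Toy enzyme
# ---------------------------------------------------------------------------

def _build_backbone(n_res: int) -> list[Atom]:
    """Ideal-geometry helix-loop-helix backbone (N, CA, C, O per residue)."""
    # phi/psi per residue: helix, loop (extended-ish), helix
    third = n_res // 3
    phi_psi = []
    for i in range(n_res):
        if i < third or i >= n_res - third:
            phi_psi.append((-57.0, -47.0))
        else:
            phi_psi.append((-100.0, 120.0))

    atoms: list[Atom] = []
    # bootstrap the first residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.46, 0.0, 0.0])
    c0 = ca0 + 1.52 * np.array([np.cos(np.deg2rad(69.0)),
                                np.sin(np.deg2rad(69.0)), 0.0])
    coords = {(1, "N"): n0, (1, "CA"): ca0, (1, "C"): c0}
    for i in range(2, n_res + 1):
        phi_prev, psi_prev = phi_psi[i - 2]
        n_new = nerf_place(coords[(i - 1, "N")], coords[(i - 1, "CA")],
                           coords[(i - 1, "C")], 1.33, 116.2, psi_prev)
        ca_new = nerf_place(coords[(i - 1, "CA")], coords[(i - 1, "C")],
                            n_new, 1.46, 121.7, 180.0)  # omega trans
        phi, _ = phi_psi[i - 1]
        c_new = nerf_place(coords[(i - 1, "C")], n_new, ca_new,
                           1.52, 111.0, phi)
        coords[(i, "N")] = n_new
        coords[(i, "CA")] = ca_new
        coords[(i, "C")] = c_new
    # carbonyl O: in the peptide plane, opposite the next N (or psi=180 cap)
    for i in range(1, n_res + 1):
        if i < n_res:
            c = coords[(i, "C")]
            u1 = coords[(i + 1, "N")] - c
            u2 = coords[(i, "CA")] - c
            bis = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            o = c - 1.23 * bis / max(np.linalg.norm(bis), 1e-9)
        else:
            o = nerf_place(coords[(i, "N")], coords[(i, "CA")],
                           coords[(i, "C")], 1.23, 120.5, 180.0)
        coords[(i, "O")] = o

    serial = 0
    for i in range(1, n_res + 1):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            serial += 1
            atoms.append(Atom(serial, name, el, "ALA", i, "A",
                              coords[(i, name)].copy()))
        frame = {bb: coords[(i, bb)] for bb in ("N", "CA", "C")}
        for name, el, pos in _build_sidechain("ALA", frame, ()):
            serial += 1
            atoms.append(Atom(serial, name, el, "ALA", i, "A", pos))
    return atoms


def make_toy_enzyme(n_res: int = 20, rng_seed: int = 0) -> Structure:
    """Toy protein with a Ser/His/Asp 'triad' and an ester fragment in a pocket.

    Deterministic per seed; triad residue ids and the substrate residue id
    are recorded in structure.meta.  n_res must be at least 12 to host the
    triad with spacing.
    """
    if n_res < 12:
        raise StructureError("n_res must be >= 12 to host the triad")
    atoms = _build_backbone(n_res)
    protein = Structure(atoms, label=f"toy{n_res}")
    # alanine everywhere; carve the triad by mutation (reuses the rotamer search)
    ser_id, asp_id, his_id = n_res // 3, n_res // 2, (2 * n_res) // 3
    protein = apply_mutation(protein, MutationSpec("A", ser_id, "A", "S"))
    protein = apply_mutation(protein, MutationSpec("A", asp_id, "A", "D"))
    protein = apply_mutation(protein, MutationSpec("A", his_id, "A", "H"))

    og = protein.find_atom("A", ser_id, "OG")
    ca = protein.find_atom("A", ser_id, "CA")
    out_dir = og.coords - ca.coords
    out_dir /= np.linalg.norm(out_dir)
    # orthogonal frame for the fragment
    aux = np.array([0.0, 0.0, 1.0])
    if abs(out_dir @ aux) > 0.9:
        aux = np.array([0.0, 1.0, 0.0])
    u = np.cross(out_dir, aux)
    u /= np.linalg.norm(u)
    v = np.cross(out_dir, u)

    c1 = og.coords + 2.9 * out_dir  # carbonyl C, attack target
    sub_coords = {
        "C1": c1,
        "O1": c1 + 1.23 * (0.4 * out_dir + 0.92 * u),      # carbonyl O
        "O2": c1 + 1.34 * (0.3 * out_dir - 0.95 * u),      # ester O
        "C2": c1 + 1.34 * (0.3 * out_dir - 0.95 * u) + 1.43 * v,  # methyl
        "C3": c1 + 1.52 * (0.9 * out_dir - 0.1 * v),        # alpha C
        "O3": c1 + 1.52 * (0.9 * out_dir - 0.1 * v) + 1.42 * u,   # tail OH
    }
    sub_id = n_res + 1
    serial = len(protein.atoms)
    sub_atoms = []
    for name in ("C1", "O1", "O2", "C2", "C3", "O3"):
        serial += 1
        sub_atoms.append(Atom(serial, name, name[0], SUBSTRATE_RES_NAME,
                              sub_id, "A", sub_coords[name]))
    full = Structure(protein.atoms + sub_atoms, label=f"toy{n_res}",
                     meta={"triad": {"SER": ser_id, "HIS": his_id,
                                     "ASP": asp_id},
                           "substrate_res_id": sub_id,
                           "rng_seed": int(rng_seed)})
    for i, a in enumerate(full.atoms, start=1):
        a.serial = i
    return full


def toy_substrate_template(toy: Structure) -> SubstrateTemplate:
    """Substrate template + anchor frame extracted from a toy enzyme."""
    sub_id = toy.meta["substrate_res_id"]
    triad = toy.meta["triad"]
    frag_atoms = [a.copy() for a in toy.atoms if a.res_id == sub_id]
    anchors = (("A", triad["SER"], "OG"), ("A", triad["SER"], "CA"),
               ("A", triad["HIS"], "CA"))
    ref = np.array([toy.find_atom(*spec).coords for spec in anchors])
    return SubstrateTemplate(
        fragment=Structure(frag_atoms, label="substrate"),
        anchor_atoms=anchors, anchor_ref_coords=ref)


def strip_substrate(toy: Structure) -> Structure:
    sub_id = toy.meta.get("substrate_res_id")
    atoms = [a.copy() for a in toy.atoms if a.res_id != sub_id]
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return Structure(atoms, label=toy.label + "|apo", meta=dict(toy.meta))


# ---------------------------------------------------------------------------
# Flexibility ensembles
# ---------------------------------------------------------------------------

def make_flex_ensemble(seed_structure: Structure,
                       per_res_sigma: dict[int, float] | float,
                       n_frames: int = 96,
                       rng_seed: int = 0) -> tuple[Ensemble, GroundTruth]:
    """Frames = seed + per-residue isotropic Gaussian noise.

    Expected RMSF of a residue with noise level sigma is sigma * sqrt(3)
    (three independent axes).  The default frame count of 96 mirrors the
    canonical design-ensemble size.
    """
    if n_frames < 2:
        raise StructureError("a flexibility ensemble needs >= 2 frames")
    res_ids = sorted({a.res_id for a in seed_structure.atoms})
    if isinstance(per_res_sigma, dict):
        sigma = {r: float(per_res_sigma.get(r, 0.0)) for r in res_ids}
    else:
        sigma = {r: float(per_res_sigma) for r in res_ids}
    if any(s < 0 for s in sigma.values()):
        raise ValueError("sigma must be non-negative")
    rng = _rng(rng_seed, "flex")
    atom_sigma = np.array([sigma[a.res_id] for a in seed_structure.atoms])
    base = seed_structure.coords
    members = []
    for f in range(n_frames):
        noise = rng.normal(0.0, 1.0, base.shape) * atom_sigma[:, None]
        m = seed_structure.copy(label=f"frame{f}")
        m.set_coords(base + noise)
        members.append(m)
    gt = GroundTruth("make_flex_ensemble", rng_seed, {
        "per_res_sigma": sigma, "n_frames": n_frames,
        "target_rmsf": {r: s * float(np.sqrt(3.0)) for r, s in sigma.items()},
    })
    return Ensemble(members, label="flex"), gt


# ---------------------------------------------------------------------------
# Planted variant energy effects
# ---------------------------------------------------------------------------

def plant_variant_effects(deltas: dict[str, float],
                          noise_sigma: float = 0.1,
                          n_frames: int = 96,
                          rng_seed: int = 0,
                          base_mean: float = 10.0,
                          base_sd: float = 1.0,
                          spec_id: str = "synthetic",
                          ) -> tuple[dict[str, DeltaETable], GroundTruth]:
    """Paired dE tables with planted per-variant ES* offsets.

    dE_wt,i ~ Normal(base_mean, base_sd); dE_var,i = dE_wt,i + delta_var +
    Normal(0, noise_sigma).  The wild type must be included with delta 0.
    The positive barrier-like base keeps ratio normalization well-defined;
    the ~1 kcal/mol planted spacing sits at the scale of the activity
    effects the protocol is meant to resolve (< 2 kcal/mol).
    """
    if WT_NAME not in deltas:
        raise ValueError("the wild type (delta 0) must be included")
    if abs(deltas[WT_NAME]) > 0:
        raise ValueError("wild-type delta must be 0")
    rng = _rng(rng_seed, "effects")
    frames = np.arange(n_frames)
    base = rng.normal(base_mean, base_sd, n_frames)
    tables: dict[str, DeltaETable] = {
        WT_NAME: DeltaETable(WT_NAME, frames, np.zeros(n_frames), base.copy(),
                             spec_id=spec_id)
    }
    for name in sorted(n for n in deltas if n != WT_NAME):
        noise = rng.normal(0.0, noise_sigma, n_frames)
        tables[name] = DeltaETable(
            name, frames, np.zeros(n_frames),
            base + deltas[name] + noise, spec_id=spec_id)
    gt = GroundTruth("plant_variant_effects", rng_seed, {
        "deltas": dict(deltas), "noise_sigma": noise_sigma,
        "n_frames": n_frames, "base_mean": base_mean, "base_sd": base_sd,
    })
    return tables, gt


# ---------------------------------------------------------------------------
# Hydrogen-bond frames
# ---------------------------------------------------------------------------

def make_hbond_frames(defns: list[HBondDefinition],
                      target_occ: dict[str, float],
                      joint_mode: str = "independent",
                      n_frames: int = 100,
                      rng_seed: int = 0) -> tuple[Ensemble, GroundTruth]:
    """Frames in which each bond is geometrically formed with probability p.

    Formed geometry: donor-acceptor 2.8 A with a 165-degree D-H-A angle;
    broken geometry: 4.5 A.  joint_mode 'independent' draws bonds
    independently; 'all_or_none' drives all bonds with one coin per frame.
    Bonds are laid out 20 A apart so they never interact.
    """
    if joint_mode not in ("independent", "all_or_none"):
        raise ValueError(f"unknown joint_mode {joint_mode!r}")
    specs = [d.donor for d in defns] + [d.acceptor for d in defns]
    if len(set(specs)) != len(specs):
        raise ValueError(
            "synthetic H-bond frames need distinct donor/acceptor atoms per "
            "bond (use synthetic_bond_definitions)")
    for b, p in target_occ.items():
        if not (0.0 <= p <= 100.0):
            raise ValueError(f"occupancy {p} for bond {b} outside [0, 100]")
    rng = _rng(rng_seed, "hbond")

    members = []
    realized = {d.bond_id: 0 for d in defns}
    for f in range(n_frames):
        if joint_mode == "all_or_none":
            coin = rng.random()
            formed = {d.bond_id: coin < target_occ[d.bond_id] / 100.0
                      for d in defns}
        else:
            formed = {d.bond_id: rng.random() < target_occ[d.bond_id] / 100.0
                      for d in defns}
        atoms = []
        serial = 0
        for k, d in enumerate(defns):
            base = np.array([20.0 * k, 0.0, 0.0])
            da = 2.8 if formed[d.bond_id] else 4.5
            donor_pos = base
            acceptor_pos = base + np.array([da, 0.0, 0.0])
            # hydrogen 1.0 A from the donor at an exact 165-deg D-H-A angle
            theta = np.deg2rad(165.0)
            gamma = np.arcsin(np.sin(theta) / da)
            beta = np.pi - theta - gamma
            h_pos = base + np.array([np.cos(beta), np.sin(beta), 0.0])
            serial += 1
            atoms.append(Atom(serial, d.donor[2], d.donor[2][0], "XXX",
                              d.donor[1], d.donor[0], donor_pos))
            serial += 1
            atoms.append(Atom(serial, "H" + d.bond_id, "H", "XXX",
                              d.donor[1], d.donor[0], h_pos))
            serial += 1
            atoms.append(Atom(serial, d.acceptor[2], d.acceptor[2][0], "XXX",
                              d.acceptor[1], d.acceptor[0], acceptor_pos))
            if formed[d.bond_id]:
                realized[d.bond_id] += 1
        members.append(Structure(atoms, label=f"hb{f}"))
    gt = GroundTruth("make_hbond_frames", rng_seed, {
        "target_occ": dict(target_occ), "joint_mode": joint_mode,
        "n_frames": n_frames,
        "realized_occ": {b: 100.0 * c / n_frames for b, c in realized.items()},
    })
    return Ensemble(members, label="hbond_frames"), gt


def synthetic_bond_definitions(n: int = 4) -> list[HBondDefinition]:
    """n bonds with mutually distinct donor/acceptor atoms for frame synthesis."""
    return [
        HBondDefinition(str(k + 1), donor=("A", 100 + k, "N"),
                        acceptor=("A", 200 + k, "O"),
                        hydrogen=("A", 100 + k, "H" + str(k + 1)),
                        label=f"synthetic bond {k + 1}")
        for k in range(n)
    ]


def hydrogen_spec_for(defn: HBondDefinition) -> HBondDefinition:
    """The same definition with the generator's explicit hydrogen attached."""
    return HBondDefinition(defn.bond_id, defn.donor, defn.acceptor,
                           hydrogen=(defn.donor[0], defn.donor[1],
                                     "H" + defn.bond_id),
                           label=defn.label)


# ---------------------------------------------------------------------------
# MSAs
# ---------------------------------------------------------------------------

def make_msa(length: int, n_seqs: int,
             conservation: dict[int, float] | float = 0.5,
             rng_seed: int = 0) -> tuple[MSA, GroundTruth]:
    """MSA with per-column target consensus frequency `conservation`.

    Each column draws its consensus residue with probability c and spreads
    the remaining (1 - c)/19 uniformly over the other residues, so c = 1/20
    reproduces the uniform background (PSSM scores near 0) and c = 1 gives a
    fully conserved column.
    """
    if n_seqs < 2:
        raise ValueError("an MSA needs at least 2 sequences")
    if isinstance(conservation, dict):
        cons = np.array([float(conservation.get(c, 0.5))
                         for c in range(length)])
    else:
        cons = np.full(length, float(conservation))
    if np.any((cons < 0) | (cons > 1)):
        raise ValueError("conservation must lie in [0, 1]")
    rng = _rng(rng_seed, "msa")
    consensus = "".join(rng.choice(list(AA_ORDER), size=length))
    seqs = []
    others = {a: [b for b in AA_ORDER if b != a] for a in AA_ORDER}
    for _ in range(n_seqs):
        chars = []
        for c in range(length):
            if rng.random() < cons[c]:
                chars.append(consensus[c])
            else:
                chars.append(others[consensus[c]][int(rng.integers(19))])
        seqs.append("".join(chars))
    gt = GroundTruth("make_msa", rng_seed, {
        "length": length, "n_seqs": n_seqs,
        "conservation": cons.tolist(), "consensus": consensus,
    })
    return MSA(seqs), gt
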