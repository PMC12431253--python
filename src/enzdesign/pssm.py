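"""Position-specific scoring matrix for the evolutionary-conservation filter.

Log-odds scores in base-2 bits with background-scaled pseudocounts:

    score(p, a) = log2( (count(p, a) + pc * bg(a))
                        / ((N_eff(p) + pc) * bg(a)) )

where N_eff(p) is the non-gap count at column p.  Gaps are excluded from
counts; an all-gap column is computed from pseudocounts alone and flagged.
Candidate substitutions scoring <= -4.0 bits are rejected by the
conservation filter downstream (strict inequality, PSSM > -4.0 passes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MSA",
    "PSSMMatrix",
    "MappingError",
    "AA_ORDER",
    "compute_pssm",
    "score_mutation",
    "read_msa_fasta",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
GAP_CHARS = set("-.")


class MappingError(KeyError):
    pass


@dataclass
class MSA:
    """Aligned sequences of uniform length over the 20 amino acids + gap."""

    sequences: list[str]
    identifiers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an MSA needs at least 2 sequences")
        length = len(self.sequences[0])
        for s in self.sequences:
            if len(s) != length:
                raise ValueError("aligned sequences must have uniform length")
        self.sequences = [s.upper() for s in self.sequences]
        if not self.identifiers:
            self.identifiers = [f"seq{i}" for i in range(len(self.sequences))]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n"
                       for i, s in zip(self.identifiers, self.sequences))


def read_msa_fasta(text: str) -> MSA:
    """Read an aligned FASTA via Biopython's AlignIO."""
    from Bio import AlignIO

    aln = AlignIO.read(io.StringIO(text), "fasta")
    return MSA([str(rec.seq) for rec in aln], [rec.id for rec in aln])


@dataclass
class PSSMMatrix:
    scores: np.ndarray            # (L, 20) bits
    background: np.ndarray        # (20,)
    pseudocount: float
    n_eff: np.ndarray             # (L,) non-gap counts
    all_gap_columns: list[int]

    def score(self, column: int, aa: str) -> float:
        if aa not in _AA_INDEX:
            raise MappingError(f"unknown amino acid {aa!r}")
        return float(self.scores[column, _AA_INDEX[aa]])

    def to_tsv(self) -> str:
        lines = ["position\t" + "\t".join(AA_ORDER)]
        for p in range(self.scores.shape[0]):
            row = "\t".join(f"{v:.4f}" for v in self.scores[p])
            lines.append(f"{p + 1}\t{row}")
        return "\n".join(lines) + "\n"


def compute_pssm(msa: MSA, background: np.ndarray | None = None,
                 pseudocount: float = 1.0) -> PSSMMatrix:
    """Log-odds PSSM (bits) with background-scaled pseudocounts.

    No sequence weighting is applied by default; the background defaults to
    uniform (0.05 per residue).
    """
    if background is None:
        background = np.full(20, 0.05)
    background = np.asarray(background, float)
    if background.shape != (20,) or np.any(background <= 0):
        raise ValueError("background must be 20 strictly positive frequencies")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")

    L = msa.length
    counts = np.zeros((L, 20))
    n_eff = np.zeros(L)
    for seq in msa.sequences:
        for p, aa in enumerate(seq):
            if aa in GAP_CHARS:
                continue
            idx = _AA_INDEX.get(aa)
            if idx is None:
                continue  # unknown letters (X etc.) treated as gaps
            counts[p, idx] += 1
            n_eff[p] += 1

    num = counts + pseudocount * background[None, :]
    den = (n_eff[:, None] + pseudocount) * background[None, :]
    scores = np.log2(num / den)
    all_gap = [int(p) for p in np.flatnonzero(n_eff == 0)]
    return PSSMMatrix(scores=scores, background=background,
                      pseudocount=pseudocount, n_eff=n_eff,
                      all_gap_columns=all_gap)


def score_mutation(pssm: PSSMMatrix, res_id: int, to_aa: str,
                   offset_map: dict[int, int] | int = 0) -> float:
    """Conservation score (bits) of placing `to_aa` at structure residue res_id.

    `offset_map` maps structure residue ids to 0-based alignment columns;
    an integer is shorthand for `column = res_id - 1 + offset`.
    """
    if isinstance(offset_map, dict):
        if res_id not in offset_map:
            raise MappingError(f"res_id {res_id} not in alignment map")
        column = offset_map[res_id]
    else:
        column = res_id - 1 + int(offset_map)
    if not (0 <= column < pssm.scores.shape[0]):
        raise MappingError(
            f"res_id {res_id} maps to column {column}, outside the alignment")
    return pssm.score(column, to_aa)
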