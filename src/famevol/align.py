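"""Pairwise global alignment, identity matrices and codon back-translation.

Global protein alignment uses Needleman-Wunsch with affine gaps via
Bio.Align.PairwiseAligner (BLOSUM62, gap open 10 / extend 0.5 by default,
ClustalW-like). Percent identity is defined as identical residue pairs over
total alignment columns, gap columns included in the denominator — the
convention is fixed here because published identity figures rarely state
theirs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "PairwiseAlignment",
    "global_align",
    "percent_identity",
    "identity_matrix",
    "backtranslate_alignment",
]

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences differ in length")


def _make_aligner(
    matrix: str | None,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # first gap position costs open + extend, later positions extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identical residue pairs / total alignment columns x 100."""
    if len(aligned_a) != len(aligned_b) or not aligned_a:
        raise ValueError("aligned sequences must be equal-length, non-empty")
    matches = sum(
        a == b and a != GAP for a, b in zip(aligned_a, aligned_b)
    )
    return 100.0 * matches / len(aligned_a)


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str | None = "BLOSUM62",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    With ``matrix=None`` a simple match/mismatch scheme is used instead of a
    substitution matrix. Among co-optimal alignments the aligner's first
    traceback is returned, which is deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty input sequence")
    aligner = _make_aligner(matrix, match, mismatch, gap_open, gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())
    best = aln[0]
    ga, gb = str(best[0]), str(best[1])
    return PairwiseAlignment(
        aligned_a=ga,
        aligned_b=gb,
        score=float(best.score),
        identity_pct=percent_identity(ga, gb),
    )


def identity_matrix(proteins: dict[str, str], **align_kwargs) -> pd.DataFrame:
    """Symmetric all-against-all percent-identity matrix (diagonal 100)."""
    ids = list(proteins)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    mat = np.full((len(ids), len(ids)), 100.0)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pid = global_align(
                proteins[ids[i]], proteins[ids[j]], **align_kwargs
            ).identity_pct
            mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=ids, columns=ids)


def _translate(cds: str) -> str:
    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def backtranslate_alignment(
    protein_alignment: dict[str, str], cds: dict[str, str]
) -> dict[str, str]:
    """Thread each CDS through its gapped protein to get a codon alignment.

    Every protein gap column becomes a ``---`` codon column; the CDS must
    translate exactly to the ungapped protein (a trailing stop codon is
    tolerated and trimmed).
    """
    out: dict[str, str] = {}
    for pid, gapped in protein_alignment.items():
        if pid not in cds:
            raise KeyError(f"no CDS for {pid}")
        nt = cds[pid].upper()
        ungapped = gapped.replace(GAP, "")
        coding = nt[:-3] if _is_stop(nt[-3:]) else nt
        if len(coding) != 3 * len(ungapped):
            raise ValueError(f"CDS length mismatch for {pid}")
        if _translate(coding) != ungapped.upper():
            raise ValueError(f"CDS does not translate to protein for {pid}")
        codons = iter(
            coding[i : i + 3] for i in range(0, len(coding), 3)
        )
        out[pid] = "".join(
            "---" if aa == GAP else next(codons) for aa in gapped
        )
    return out


def _is_stop(codon: str) -> bool:
    return codon.upper() in {"TAA", "TAG", "TGA"}
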