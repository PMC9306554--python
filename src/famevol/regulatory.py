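"""Promoter extraction, cis-element scanning and qPCR relative expression.

Promoters are the 1,500-2,000 bp immediately upstream of the start codon
(strand-aware; default 2,000 bp). Cis-acting elements are counted by exact
IUPAC-consensus matching on both strands — every overlapping occurrence
counts, and a position matching a palindromic consensus on both strands is
counted once. The shipped consensus table covers the hormone-, light-,
stress- and development-responsive elements commonly reported for plant
promoters (ABRE, CGTCA-motif, G-box, MBS, ARE, LTR, ...); counts from it
are a deterministic re-scan, not a reproduction of PlantCARE's
database-model output.

Relative expression follows the 2^-ddCt method: per replicate,
dCt = Ct_target - Ct_reference; ddCt subtracts the calibrator sample's mean
dCt; fold change is 2^-ddCt, reported as mean and SD across replicates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "MotifDefinition",
    "MotifHitMatrix",
    "DEFAULT_MOTIFS",
    "iupac_to_regex",
    "extract_promoter",
    "scan_motifs",
    "ddct_expression",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str  # IUPAC string
    category: str  # hormone | light | stress | development

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbols {sorted(bad)} in {self.name}")


# Literature consensus strings for the commonly scored plant cis-elements.
DEFAULT_MOTIFS: tuple[MotifDefinition, ...] = (
    MotifDefinition("ABRE", "ACGTG", "hormone"),
    MotifDefinition("CGTCA-motif", "CGTCA", "hormone"),
    MotifDefinition("TGACG-motif", "TGACG", "hormone"),
    MotifDefinition("TCA-element", "CCATCTTTTT", "hormone"),
    MotifDefinition("P-box", "CCTTTTG", "hormone"),
    MotifDefinition("GARE-motif", "TCTGTTG", "hormone"),
    MotifDefinition("TATC-box", "TATCCCA", "hormone"),
    MotifDefinition("AuxRE", "TGTCTC", "hormone"),
    MotifDefinition("TGA-box", "TGACGTAA", "hormone"),
    MotifDefinition("G-box", "CACGTG", "light"),
    MotifDefinition("Box 4", "ATTAAT", "light"),
    MotifDefinition("O2-site", "GATGAYRTGR", "development"),
    MotifDefinition("CAT-box", "GCCACT", "development"),
    MotifDefinition("GCN4-motif", "TGAGTCA", "development"),
    MotifDefinition("AACA-motif", "AACAAAC", "development"),
    MotifDefinition("WUN-motif", "AAATTTCCT", "stress"),
    MotifDefinition("MBS", "CAACTG", "stress"),
    MotifDefinition("TC-rich repeats", "ATTTTCTTCA", "stress"),
    MotifDefinition("ARE", "AAACCA", "stress"),
    MotifDefinition("LTR", "CCGAAA", "stress"),
)


@dataclass(frozen=True)
class MotifHitMatrix:
    counts: pd.DataFrame  # gene x motif integer counts
    hits: pd.DataFrame  # gene, motif, position (0-based), strand


def iupac_to_regex(consensus: str) -> str:
    """IUPAC consensus to a regex character-class pattern."""
    parts = []
    for sym in consensus.upper():
        opts = IUPAC[sym]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def is_palindromic(consensus: str) -> bool:
    """True when the consensus equals its own IUPAC reverse complement."""
    return consensus.upper() == _revcomp(consensus.upper())


def _find_all(pattern: str, seq: str) -> list[int]:
    # lookahead so overlapping occurrences are all found
    return [m.start() for m in re.finditer(f"(?={pattern})", seq)]


def scan_motifs(
    promoters: dict[str, str],
    motifs: tuple[MotifDefinition, ...] | list[MotifDefinition] = DEFAULT_MOTIFS,
) -> MotifHitMatrix:
    """Count cis-element occurrences per promoter on both strands.

    A minus-strand hit is a match of the reverse complement of the
    consensus in the promoter sequence, recorded at its position on the
    given strand. Palindromic consensi are counted once per position.
    """
    rows = []
    counts = {}
    for mdef in motifs:
        fwd = iupac_to_regex(mdef.consensus)
        rev = iupac_to_regex(_revcomp(mdef.consensus))
        palindrome = is_palindromic(mdef.consensus)
        for gene, seq in promoters.items():
            s = seq.upper()
            plus = _find_all(fwd, s)
            minus = [] if palindrome else _find_all(rev, s)
            for pos in plus:
                rows.append((gene, mdef.name, pos, "+"))
            for pos in minus:
                rows.append((gene, mdef.name, pos, "-"))
            counts[(gene, mdef.name)] = len(plus) + len(minus)
    hit_df = pd.DataFrame(rows, columns=["gene", "motif", "position", "strand"])
    genes = list(promoters)
    names = [m.name for m in motifs]
    mat = pd.DataFrame(
        [[counts[(g, n)] for n in names] for g in genes],
        index=genes,
        columns=names,
        dtype=int,
    )
    return MotifHitMatrix(counts=mat, hits=hit_df)


def extract_promoter(
    gene: pd.Series | dict,
    genome: dict[str, str],
    length_bp: int = 2000,
) -> str:
    """Strand-aware promoter upstream of the start codon.

    ``gene`` needs chrom, strand and the genomic start codon position
    (cds_start for + strand genes, cds_end for -), 1-based inclusive. The
    window ends immediately before the start codon and is reverse
    complemented for minus-strand genes; at chromosome edges it is clipped
    with a warning.
    """
    if not (1500 <= length_bp <= 2000):
        warnings.warn(
            f"promoter length {length_bp} bp outside the usual 1500-2000 bp window"
        )
    chrom = gene["chrom"]
    strand = gene["strand"]
    seq = genome[chrom]
    if strand == "+":
        cds_start = int(gene["cds_start"])
        lo = cds_start - length_bp  # 1-based
        if lo < 1:
            warnings.warn(f"promoter clipped at chromosome start ({gene})")
            lo = 1
        return seq[lo - 1 : cds_start - 1]
    if strand == "-":
        cds_end = int(gene["cds_end"])
        hi = cds_end + length_bp
        if hi > len(seq):
            warnings.warn(f"promoter clipped at chromosome end ({gene})")
            hi = len(seq)
        return _revcomp(seq[cds_end : hi])
    raise ValueError(f"bad strand {strand!r}")


def ddct_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression from a long-format Ct table.

    ``ct`` has columns gene, sample, replicate, Ct. The reference gene must
    be measured in every sample; fold changes are relative to the
    calibrator sample and reported as per-(gene, sample) mean and SD across
    replicates. Adding a constant to all Ct values of one replicate (a
    machine offset) leaves the result unchanged.
    """
    required = {"gene", "sample", "replicate", "Ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    ref = ct[ct["gene"] == reference_gene].set_index(["sample", "replicate"])["Ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    if targets.empty:
        raise ValueError("no target genes in Ct table")
    missing = set(zip(targets["sample"], targets["replicate"])) - set(ref.index)
    if missing:
        raise ValueError(f"reference gene missing for sample/replicate: {sorted(missing)}")
    targets["dct"] = targets["Ct"].to_numpy() - ref.loc[
        list(zip(targets["sample"], targets["replicate"]))
    ].to_numpy()
    out_rows = []
    for gene, sub in targets.groupby("gene", sort=False):
        cal = sub[sub["sample"] == calibrator_sample]
        if cal.empty:
            raise ValueError(f"calibrator sample missing for gene {gene}")
        cal_mean = cal["dct"].mean()
        for sample, ssub in sub.groupby("sample", sort=False):
            folds = 2.0 ** -(ssub["dct"] - cal_mean)
            out_rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "fold_change": float(folds.mean()),
                    "fold_sd": float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
                    "n_replicates": len(folds),
                }
            )
    return pd.DataFrame(out_rows)
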