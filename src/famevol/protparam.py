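"""Protein physicochemical descriptors and hydropathy profiles.

Computes the per-protein summary table used to characterise a gene family:
residue count, average-isotope molecular weight, theoretical isoelectric
point (pI), grand average of hydropathicity (GRAVY) and sliding-window
Kyte-Doolittle hydropathy tracks. Values follow the ExPASy ProtParam
conventions (average residue masses, Bjellqvist pKa set) so that the table
is comparable with the web tool's output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw

__all__ = [
    "PhysChemProfile",
    "HydropathyTrack",
    "molecular_weight",
    "isoelectric_point",
    "gravy",
    "hydropathy_profile",
    "physchem_profile",
    "physchem_table",
    "KYTE_DOOLITTLE",
    "PKA_SETS",
]

# Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

STANDARD_AA = frozenset(KYTE_DOOLITTLE)
AMBIGUOUS_AA = frozenset("XBZUJO*")

# pKa sets for the charge model. "bjellqvist" is the ExPASy ProtParam set
# (N-terminal pKa depends on the first residue; C-terminal on the last).
PKA_SETS: dict[str, dict] = {
    "bjellqvist": {
        "nterm_default": 7.5,
        "nterm_by_residue": {
            "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
            "T": 6.82, "V": 7.44, "E": 7.7,
        },
        "cterm_default": 3.55,
        "cterm_by_residue": {"D": 4.55, "E": 4.75},
        "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
        "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    },
    "emboss": {
        "nterm_default": 8.6,
        "nterm_by_residue": {},
        "cterm_default": 3.6,
        "cterm_by_residue": {},
        "positive": {"K": 10.8, "R": 12.5, "H": 6.5},
        "negative": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    },
}

# Mean of the 20 average residue masses; placeholder for ambiguous residues
# under the lenient policy.
_MEAN_RESIDUE_MASS = float(
    np.mean([_bio_mw(a, seq_type="protein") - 18.0153 for a in sorted(STANDARD_AA)])
)
_WATER = 18.0153


@dataclass(frozen=True)
class HydropathyTrack:
    """Sliding-window mean Kyte-Doolittle hydropathy along a protein."""

    window: int
    values: np.ndarray

    def __len__(self) -> int:  # number of windows
        return len(self.values)


@dataclass(frozen=True)
class PhysChemProfile:
    """One row of a family physicochemistry table."""

    protein_id: str
    aa_count: int
    mw_kda: float
    pi: float
    gravy: float
    signal_peptide: bool | None = None
    track: HydropathyTrack | None = field(default=None, compare=False)


def _clean(sequence: str, strict: bool, what: str) -> str:
    """Validate residues; drop ambiguous ones under the lenient policy."""
    seq = sequence.upper().rstrip("*")
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - STANDARD_AA
    if not bad:
        return seq
    unknown = bad - AMBIGUOUS_AA
    if unknown or strict:
        raise ValueError(f"non-standard residues {sorted(bad)} in {what}")
    warnings.warn(
        f"ambiguous residues {sorted(bad)} skipped in {what}", stacklevel=3
    )
    return "".join(a for a in seq if a in STANDARD_AA)


def molecular_weight(sequence: str, strict: bool = False) -> float:
    """Average-isotope molecular weight in kDa.

    Sum of average residue masses plus one water. Ambiguous residues
    contribute the mean residue mass unless ``strict``.
    """
    seq = sequence.upper().rstrip("*")
    if not seq:
        raise ValueError("empty protein sequence")
    n_ambig = sum(1 for a in seq if a not in STANDARD_AA)
    if n_ambig:
        if strict:
            raise ValueError("non-standard residues under strict policy")
        core = "".join(a for a in seq if a in STANDARD_AA)
        mass = (_bio_mw(core, seq_type="protein") if core else _WATER)
        mass += n_ambig * _MEAN_RESIDUE_MASS
        return mass / 1000.0
    return _bio_mw(seq, seq_type="protein") / 1000.0


def _net_charge(seq: str, ph: float, pka: dict) -> float:
    pos = dict(pka["positive"])
    pos["Nterm"] = pka["nterm_by_residue"].get(seq[0], pka["nterm_default"])
    neg = dict(pka["negative"])
    neg["Cterm"] = pka["cterm_by_residue"].get(seq[-1], pka["cterm_default"])
    counts = {a: seq.count(a) for a in set(seq)}
    charge = 0.0
    for group, pk in pos.items():
        n = 1 if group == "Nterm" else counts.get(group, 0)
        charge += n / (1.0 + 10.0 ** (ph - pk))
    for group, pk in neg.items():
        n = 1 if group == "Cterm" else counts.get(group, 0)
        charge -= n / (1.0 + 10.0 ** (pk - ph))
    return charge


def isoelectric_point(
    sequence: str, pka_set: str = "bjellqvist", strict: bool = False
) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero.

    Bisection on pH in (0, 14) to ``|charge| < 1e-4``. The ``pka_set``
    selects the charge model: ``"bjellqvist"`` (ExPASy) or ``"emboss"``.
    """
    seq = _clean(sequence, strict, "isoelectric_point")
    pka = PKA_SETS[pka_set]
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(100):
        ph = 0.5 * (lo + hi)
        q = _net_charge(seq, ph, pka)
        if abs(q) < 1e-4:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def gravy(sequence: str, strict: bool = False) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle over residues."""
    seq = _clean(sequence, strict, "gravy")
    return float(np.mean([KYTE_DOOLITTLE[a] for a in seq]))


def hydropathy_profile(
    sequence: str, window: int = 9, strict: bool = False
) -> HydropathyTrack:
    """Sliding-window mean hydropathy; window must be odd and <= length."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    seq = _clean(sequence, strict, "hydropathy_profile")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    vals = np.array([KYTE_DOOLITTLE[a] for a in seq])
    win = np.lib.stride_tricks.sliding_window_view(vals, window)
    return HydropathyTrack(window=window, values=win.mean(axis=1))


def physchem_profile(
    protein_id: str,
    sequence: str,
    window: int | None = None,
    signal_peptide: bool | None = None,
    pka_set: str = "bjellqvist",
) -> PhysChemProfile:
    """Full descriptor row for one protein (optionally with a track)."""
    seq = sequence.upper().rstrip("*")
    track = None
    if window is not None and window <= len(seq):
        track = hydropathy_profile(seq, window)
    return PhysChemProfile(
        protein_id=protein_id,
        aa_count=len(seq),
        mw_kda=round(molecular_weight(seq), 2),
        pi=round(isoelectric_point(seq, pka_set), 2),
        gravy=round(gravy(seq), 3),
        signal_peptide=signal_peptide,
        track=track,
    )


def physchem_table(
    proteins: dict[str, str],
    annotations: pd.DataFrame | None = None,
    pka_set: str = "bjellqvist",
) -> pd.DataFrame:
    """Family-wide physicochemistry table.

    ``annotations`` may carry an externally predicted ``signal_peptide``
    column indexed by protein id; it is passed through untouched.
    """
    sp = {}
    if annotations is not None and "signal_peptide" in annotations:
        sp = annotations["signal_peptide"].to_dict()
    rows = []
    for pid, seq in proteins.items():
        p = physchem_profile(pid, seq, signal_peptide=sp.get(pid), pka_set=pka_set)
        rows.append(
            {
                "protein_id": p.protein_id,
                "aa_count": p.aa_count,
                "mw_kda": p.mw_kda,
                "pi": p.pi,
                "gravy": p.gravy,
                "signal_peptide": p.signal_peptide,
            }
        )
    return pd.DataFrame(rows)
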