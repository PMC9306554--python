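"""Duplicate-pair classification and Nei-Gojobori (1986) Ka/Ks.

Ka (nonsynonymous substitutions per nonsynonymous site) and Ks (synonymous
substitutions per synonymous site) are estimated by the NG86 counting
method on a pairwise codon alignment:

* per-codon synonymous site fractions from the 9 single-nucleotide
  neighbours (mutations to stop codons count as nonsynonymous, so
  S + N = 3 x codons), averaged over the two sequences;
* codon differences resolved by averaging over all minimal mutational
  pathways, excluding pathways through stop-codon intermediates;
* proportions ps = Sd/S, pn = Nd/N corrected with Jukes-Cantor,
  d = -(3/4) ln(1 - (4/3) p); Ks = d(ps), Ka = d(pn).

Ka/Ks > 1 suggests positive selection, < 1 purifying selection. A sliding
window (default 150 bp window, 9 bp step — both codon multiples) localises
selective pressure along the gene.

Duplicate gene pairs are classified from coordinates: pairs above an
identity threshold (default 80%) are tandem when on the same chromosome
within 200 kb (midpoint separation), segmental otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from math import log

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "DuplicationCriteria",
    "KaKsResult",
    "SlidingWindowTrack",
    "DuplicatePair",
    "ng86_kaks",
    "sliding_window_kaks",
    "classify_duplicates",
    "pairs_table",
    "window_table",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_BASES = "ACGT"


@dataclass(frozen=True)
class DuplicationCriteria:
    """Thresholds for calling duplicate pairs and their mode."""

    min_identity_pct: float = 80.0
    tandem_max_kb: float = 200.0
    tandem_is_proximal: bool = True  # <= threshold on one chromosome => tandem

    def __post_init__(self) -> None:
        if not (0 < self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must be in (0, 100]")
        if self.tandem_max_kb <= 0:
            raise ValueError("tandem_max_kb must be positive")


@dataclass(frozen=True)
class KaKsResult:
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences (pathway-averaged)
    Nd: float  # nonsynonymous differences
    codons: int  # codon columns compared
    ka: float | None
    ks: float | None
    ratio: float | None
    notes: tuple[str, ...] = ()

    @property
    def ps(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def pn(self) -> float:
        return self.Nd / self.N if self.N else 0.0


@dataclass(frozen=True)
class SlidingWindowTrack:
    window_bp: int
    step_bp: int
    starts_bp: tuple[int, ...]  # 1-based window starts in the alignment
    midpoints_bp: tuple[float, ...]
    ratios: tuple[float | None, ...]
    results: tuple[KaKsResult, ...] = field(compare=False, default=())


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity_pct: float
    mode: str  # "tandem" | "segmental"
    kaks: KaKsResult | None = None
    track: SlidingWindowTrack | None = None


@lru_cache(maxsize=4096)
def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site count of one codon (sums to 3)."""
    aa = _AA[codon]
    syn = 0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            neighbour = codon[:pos] + alt + codon[pos + 1 :]
            if neighbour not in STOP_CODONS and _AA[neighbour] == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def _step_type(c1: str, c2: str) -> str:
    return "syn" if _AA[c1] == _AA[c2] else "nonsyn"


@lru_cache(maxsize=65536)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (Sd, Nd) over minimal mutational pathways c1 -> c2.

    Pathways visiting a stop-codon intermediate are excluded; if every
    pathway is blocked, all are used with stop steps counted as
    nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        return (1.0, 0.0) if _step_type(c1, c2) == "syn" else (0.0, 1.0)

    def walk(order: tuple[int, ...], allow_stops: bool):
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                # endpoints are screened, so this is an intermediate
                if not allow_stops:
                    return None
                nd += 1.0
            elif cur in STOP_CODONS:
                nd += 1.0
            elif _step_type(cur, nxt) == "syn":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    valid = [w for o in permutations(diff) if (w := walk(o, False)) is not None]
    if not valid:
        valid = [walk(o, True) for o in permutations(diff)]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def _jc_correct(p: float) -> tuple[float | None, str | None]:
    if p >= 0.75:
        return None, f"proportion {p:.3f} >= 3/4: Jukes-Cantor undefined"
    return -0.75 * log(1.0 - (4.0 / 3.0) * p) + 0.0, None


def _usable_codon(c: str) -> bool:
    return all(b in _BASES for b in c) and c not in STOP_CODONS


def ng86_kaks(aligned_cds_a: str, aligned_cds_b: str) -> KaKsResult:
    """NG86 Ka/Ks for one aligned CDS pair.

    Codon columns containing gaps, ambiguous bases or stop codons in either
    sequence are excluded pairwise. Ka/Ks is ``None`` when Ks is zero or a
    Jukes-Cantor correction is undefined (flagged in ``notes``).
    """
    a, b = aligned_cds_a.upper(), aligned_cds_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    if len(a) % 3:
        raise ValueError("alignment length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        codons += 1
        sa, na = _codon_site_fractions(ca)
        sb, nb = _codon_site_fractions(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if codons == 0:
        raise ValueError("no comparable codon columns")
    notes: list[str] = []
    ks, err = _jc_correct(Sd / S) if S > 0 else (None, "no synonymous sites")
    if err:
        notes.append(f"Ks: {err}")
    ka, err = _jc_correct(Nd / N) if N > 0 else (None, "no nonsynonymous sites")
    if err:
        notes.append(f"Ka: {err}")
    ratio = None
    if ka is not None and ks is not None:
        if ks > 0:
            ratio = ka / ks
        else:
            notes.append("Ks = 0: ratio undefined")
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, codons=codons,
        ka=ka, ks=ks, ratio=ratio, notes=tuple(notes),
    )


def sliding_window_kaks(
    aligned_cds_a: str,
    aligned_cds_b: str,
    window_bp: int = 150,
    step_bp: int = 9,
) -> SlidingWindowTrack:
    """Windowed NG86 scan along a codon alignment.

    Window and step must be codon multiples; windows are placed at
    0, step, 2*step, ... while they fit, giving
    floor((L - window)/step) + 1 windows. Undefined ratios stay ``None``.
    """
    if window_bp % 3 or step_bp % 3:
        raise ValueError("window and step must be multiples of 3 bp")
    L = len(aligned_cds_a)
    if L < window_bp:
        raise ValueError("alignment shorter than window")
    starts, mids, ratios, results = [], [], [], []
    pos = 0
    while pos + window_bp <= L:
        res = ng86_kaks(
            aligned_cds_a[pos : pos + window_bp],
            aligned_cds_b[pos : pos + window_bp],
        )
        starts.append(pos + 1)
        mids.append(pos + window_bp / 2.0)
        ratios.append(res.ratio)
        results.append(res)
        pos += step_bp
    return SlidingWindowTrack(
        window_bp=window_bp,
        step_bp=step_bp,
        starts_bp=tuple(starts),
        midpoints_bp=tuple(mids),
        ratios=tuple(ratios),
        results=tuple(results),
    )


def classify_duplicates(
    gene_models: pd.DataFrame,
    identity: pd.DataFrame,
    criteria: DuplicationCriteria = DuplicationCriteria(),
) -> list[DuplicatePair]:
    """Call duplicate pairs and their duplication mode.

    ``gene_models`` needs columns gene, chrom, start, end (an optional
    species column restricts pairing to within-species, since duplication
    is a within-genome event). Pairs whose percent identity exceeds
    ``min_identity_pct`` are duplicates: same chromosome with midpoint
    separation within ``tandem_max_kb`` means tandem, anything else
    segmental (direction configurable through ``tandem_is_proximal``).
    Genes without coordinates are skipped with a warning.
    """
    gm = gene_models.set_index("gene")
    mid = (gm["start"] + gm["end"]) / 2.0
    pairs: list[DuplicatePair] = []
    ids = list(identity.index)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            pid = float(identity.loc[ga, gb])
            if pid <= criteria.min_identity_pct:
                continue
            if ga not in gm.index or gb not in gm.index:
                warnings.warn(f"missing coordinates for pair {ga}/{gb}; skipped")
                continue
            if (
                "species" in gm.columns
                and gm.loc[ga, "species"] != gm.loc[gb, "species"]
            ):
                continue
            same_chrom = gm.loc[ga, "chrom"] == gm.loc[gb, "chrom"]
            proximal = (
                same_chrom
                and abs(mid[ga] - mid[gb]) <= criteria.tandem_max_kb * 1000.0
            )
            tandem = proximal if criteria.tandem_is_proximal else (
                same_chrom and not proximal
            )
            pairs.append(
                DuplicatePair(
                    gene_a=ga,
                    gene_b=gb,
                    identity_pct=pid,
                    mode="tandem" if tandem else "segmental",
                )
            )
    return pairs


def pairs_table(pairs: list[DuplicatePair]) -> pd.DataFrame:
    """Duplicate-pair summary (pair, mode, Ka, Ks, Ka/Ks); undefined ratios
    are left empty."""
    rows = []
    for p in pairs:
        k = p.kaks
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "identity_pct": round(p.identity_pct, 2),
                "mode": p.mode,
                "ka": None if k is None or k.ka is None else round(k.ka, 3),
                "ks": None if k is None or k.ks is None else round(k.ks, 3),
                "ka_ks": None if k is None or k.ratio is None else round(k.ratio, 3),
            }
        )
    return pd.DataFrame(rows)


def window_table(pairs: list[DuplicatePair]) -> pd.DataFrame:
    """Long-format per-window Ka/Ks track for every pair with a scan."""
    rows = []
    for p in pairs:
        if p.track is None:
            continue
        for start, mid, ratio in zip(
            p.track.starts_bp, p.track.midpoints_bp, p.track.ratios
        ):
            rows.append(
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "window_start_bp": start,
                    "window_mid_bp": mid,
                    "ka_ks": None if ratio is None else round(ratio, 3),
                }
            )
    return pd.DataFrame(rows)
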