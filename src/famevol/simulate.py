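"""Synthetic multi-species gene families with known ground truth.

Generates the full input bundle a comparative gene-family study consumes —
coding and protein FASTA, gene models on synthetic chromosome scaffolds,
promoters with planted cis-elements, and triplicate qPCR Ct tables — while
recording the truth every downstream estimator should recover: the
duplication mode of each duplicate pair (tandem = same chromosome within
the distance threshold; segmental = different chromosome), the dN/dS ratio
(omega) each branch evolved under, exact planted motif counts, and true
relative expression fold changes.

Codon evolution is a proposal-acceptance scheme: single-nucleotide changes
proposed uniformly; proposals creating stop codons are rejected;
synonymous proposals are always accepted and nonsynonymous ones with
probability min(1, omega). The number of accepted substitutions is
Poisson with mean ``subs_per_codon x codons``, so NG86 applied to a
simulated pair should estimate Ka/Ks close to omega. There are no indels,
so the true alignment of homologs is the identity.

Promoter backgrounds are rejection-sampled to contain no occurrence of any
listed motif on either strand before planting, which makes planted counts
exact rather than statistical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .regulatory import (
    DEFAULT_MOTIFS,
    MotifDefinition,
    iupac_to_regex,
    IUPAC,
    scan_motifs,
)

__all__ = [
    "DuplicationEvent",
    "FamilySimConfig",
    "SequenceRecord",
    "SyntheticTruth",
    "evolve_cds",
    "simulate_family",
    "plant_promoters",
    "simulate_qpcr",
    "assemble_genome",
    "write_family",
]

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
DEFAULT_OMEGA = 0.3  # purifying selection, the norm for duplicate pairs

# default planting rates use motifs whose consensi do not contain or
# reverse-complement one another, so planted counts stay exact
DEFAULT_PLANT_RATES = {"ABRE": 2.0, "MBS": 1.0, "ARE": 1.0, "LTR": 1.0}


@dataclass(frozen=True)
class DuplicationEvent:
    species: str  # species index name, e.g. "sp1"
    mode: str  # "tandem" | "segmental"
    parent_gene: str  # ancestral gene name, e.g. "g1"

    def __post_init__(self) -> None:
        if self.mode not in {"tandem", "segmental"}:
            raise ValueError(f"unknown duplication mode {self.mode!r}")


@dataclass(frozen=True)
class FamilySimConfig:
    """Study conditions for one simulated family.

    Defaults mirror a six-species Rosaceae-scale family: ~14 ancestral
    genes per species, 300-codon CDS, 0.3 substitutions/codon divergence,
    200 kb tandem threshold, 2 kb promoters, 0.2-cycle Ct noise.
    """

    n_species: int = 6
    n_ancestral_genes: int = 14
    duplication_events: tuple[DuplicationEvent, ...] = ()
    omega_map: dict = field(default_factory=dict)  # branch/gene id -> omega
    cds_length_codons: int = 300
    subs_per_codon: float = 0.3
    tandem_max_kb: float = 200.0
    promoter_length_bp: int = 2000
    motif_plant_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_PLANT_RATES)
    )
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_length_codons < 30:
            raise ValueError("cds_length_codons must be >= 30")
        if any(w < 0 for w in self.omega_map.values()):
            raise ValueError("all omega values must be >= 0")
        if not (1500 <= self.promoter_length_bp <= 2000):
            raise ValueError("promoter_length_bp must be in [1500, 2000]")
        if self.subs_per_codon < 0 or self.ct_noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.n_species < 1 or self.n_ancestral_genes < 1:
            raise ValueError("need at least one species and one gene")


@dataclass(frozen=True)
class SequenceRecord:
    gene: str
    species: str
    chrom: str
    start: int  # 1-based inclusive gene span
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, 1-based inclusive
    cds: str
    protein: str
    promoter: str | None = None


@dataclass
class SyntheticTruth:
    pair_modes: dict  # (parent gene id, duplicate gene id) -> mode
    branch_omega: dict  # gene id -> omega its terminal branch evolved under
    motif_counts: pd.DataFrame  # gene x motif planted counts
    expression: pd.DataFrame  # gene, sample, fold (truth fold changes)
    alignments: dict  # ancestral gene -> {gene id -> protein} (true MSA)


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in STOPS:
            codons.append(c)
    return "".join(codons)


def evolve_cds(
    ancestral_cds: str,
    omega: float,
    expected_subs_per_codon: float,
    seed: int | np.random.Generator,
) -> str:
    """Evolve a CDS under a given dN/dS by proposal-acceptance.

    Draws Poisson(rate x codons) accepted substitutions; each accepted
    substitution is a uniform single-nucleotide proposal that is rejected
    if it creates a stop codon, accepted if synonymous, and accepted with
    probability min(1, omega) if nonsynonymous.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if len(ancestral_cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    seq = list(ancestral_cds.upper())
    n_codons = len(seq) // 3
    for i in range(0, len(seq), 3):
        if "".join(seq[i : i + 3]) in STOPS:
            raise ValueError("ancestral CDS contains an internal stop codon")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_subs = rng.poisson(expected_subs_per_codon * n_codons)
    accepted = 0
    guard = 0
    max_iter = 1000 * (n_subs + 10)
    while accepted < n_subs:
        guard += 1
        if guard > max_iter:
            raise RuntimeError("substitution sampler failed to converge")
        pos = int(rng.integers(0, len(seq)))
        alt = BASES[int(rng.integers(0, 4))]
        if alt == seq[pos]:
            continue
        cstart = 3 * (pos // 3)
        old_codon = "".join(seq[cstart : cstart + 3])
        new_codon = (
            old_codon[: pos - cstart] + alt + old_codon[pos - cstart + 1 :]
        )
        if new_codon in STOPS:
            continue
        synonymous = _translate(old_codon) == _translate(new_codon)
        if synonymous or rng.random() < min(1.0, omega):
            seq[pos] = alt
            accepted += 1
    return "".join(seq)


def _exon_layout(
    cds_bp: int, start: int, rng: np.random.Generator
) -> tuple[tuple[tuple[int, int], ...], int]:
    """Split a CDS into exons with random introns; returns exon spans and
    gene end (1-based inclusive, relative to ``start``)."""
    n_exons = int(rng.integers(1, 7))
    n_exons = min(n_exons, cds_bp // 30)
    n_exons = max(n_exons, 1)
    cuts = np.sort(rng.choice(np.arange(1, cds_bp), size=n_exons - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [cds_bp]]))
    introns = rng.integers(50, 501, size=n_exons - 1)
    exons = []
    pos = start
    for k, size in enumerate(sizes):
        exons.append((pos, pos + int(size) - 1))
        pos += int(size)
        if k < n_exons - 1:
            pos += int(introns[k])
    return tuple(exons), exons[-1][1]


def _place_gene(
    chrom_len: int, span_hint: int, rng: np.random.Generator, margin: int
) -> int:
    lo = margin + 1
    hi = chrom_len - span_hint - margin
    if hi <= lo:
        raise ValueError("chromosome too short for gene placement")
    return int(rng.integers(lo, hi))


def simulate_family(
    config: FamilySimConfig,
) -> tuple[dict[str, SequenceRecord], pd.DataFrame, SyntheticTruth]:
    """Simulate the family: sequences, gene models and ground truth.

    Species are named sp1..spN, ancestral genes g1..gM; the ortholog of gK
    in species spJ is ``spJ_gK`` and duplicates append ``dL``. Terminal
    branches look up omega in ``config.omega_map`` by gene id first, then
    species name, falling back to 0.3.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    species = [f"sp{i + 1}" for i in range(cfg.n_species)]
    anc_genes = [f"g{i + 1}" for i in range(cfg.n_ancestral_genes)]
    for ev in cfg.duplication_events:
        if ev.species not in species or ev.parent_gene not in anc_genes:
            raise ValueError(f"duplication references unknown gene: {ev}")

    # chromosome scaffolds, ~1-5 Mb
    chrom_lengths: dict[str, int] = {}
    chroms_of: dict[str, list[str]] = {}
    for sp in species:
        chroms_of[sp] = []
        for c in range(4):
            name = f"{sp}_chr{c + 1}"
            chrom_lengths[name] = int(rng.integers(1_000_000, 5_000_001))
            chroms_of[sp].append(name)

    ancestral = {g: _random_cds(cfg.cds_length_codons, rng) for g in anc_genes}
    cds_bp = 3 * cfg.cds_length_codons
    margin = cfg.promoter_length_bp + 100

    def omega_for(gene_id: str, sp: str) -> float:
        return cfg.omega_map.get(gene_id, cfg.omega_map.get(sp, DEFAULT_OMEGA))

    records: dict[str, SequenceRecord] = {}
    branch_omega: dict[str, float] = {}
    placements: dict[str, tuple[str, int, int]] = {}  # gene -> chrom, start, end

    def add_record(gene_id, sp, cds, chrom, start):
        strand = "+" if rng.random() < 0.5 else "-"
        exons, end = _exon_layout(cds_bp, start, rng)
        records[gene_id] = SequenceRecord(
            gene=gene_id,
            species=sp,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            exons=exons,
            cds=cds,
            protein=_translate(cds),
        )
        placements[gene_id] = (chrom, start, end)

    for sp in species:
        for g in anc_genes:
            gid = f"{sp}_{g}"
            om = omega_for(gid, sp)
            cds = evolve_cds(ancestral[g], om, cfg.subs_per_codon, rng)
            chrom = chroms_of[sp][int(rng.integers(0, len(chroms_of[sp])))]
            start = _place_gene(chrom_lengths[chrom], 2 * cds_bp + 3000, rng, margin)
            add_record(gid, sp, cds, chrom, start)
            branch_omega[gid] = om

    pair_modes: dict[tuple[str, str], str] = {}
    dup_counter: dict[str, int] = {}
    for ev in cfg.duplication_events:
        parent_id = f"{ev.species}_{ev.parent_gene}"
        dup_counter[parent_id] = dup_counter.get(parent_id, 0) + 1
        dup_id = f"{parent_id}d{dup_counter[parent_id]}"
        om = omega_for(dup_id, ev.species)
        cds = evolve_cds(records[parent_id].cds, om, cfg.subs_per_codon, rng)
        pchrom, pstart, pend = placements[parent_id]
        span_hint = 2 * cds_bp + 3000
        if ev.mode == "tandem":
            chrom = pchrom
            max_sep = int(cfg.tandem_max_kb * 1000) - span_hint - 1000
            sep = int(rng.integers(2000, max(2001, max_sep)))
            start = pend + sep
            if start + span_hint + margin > chrom_lengths[chrom]:
                start = max(margin + 1, pstart - sep - span_hint)
        else:
            others = [c for c in chroms_of[ev.species] if c != pchrom]
            chrom = others[int(rng.integers(0, len(others)))]
            start = _place_gene(chrom_lengths[chrom], span_hint, rng, margin)
        add_record(dup_id, ev.species, cds, chrom, start)
        branch_omega[dup_id] = om
        pair_modes[(parent_id, dup_id)] = ev.mode

    # promoters with planted cis-elements
    motif_table = tuple(
        m for m in DEFAULT_MOTIFS if m.name in cfg.motif_plant_rates
    )
    promoters, motif_counts = plant_promoters(
        list(records),
        motif_table,
        cfg.motif_plant_rates,
        promoter_length_bp=cfg.promoter_length_bp,
        seed=rng,
    )
    for gid, prom in promoters.items():
        r = records[gid]
        records[gid] = SequenceRecord(
            gene=r.gene, species=r.species, chrom=r.chrom, start=r.start,
            end=r.end, strand=r.strand, exons=r.exons, cds=r.cds,
            protein=r.protein, promoter=prom,
        )

    # true relative expression: calibrator plus two contrast samples
    expr_rows = []
    for gid in records:
        for sample in ("calibrator", "tissue1", "tissue2"):
            fold = 1.0 if sample == "calibrator" else float(
                2.0 ** rng.normal(0.0, 1.5)
            )
            expr_rows.append({"gene": gid, "sample": sample, "fold": fold})
    expression = pd.DataFrame(expr_rows)

    alignments = {
        g: {
            gid: rec.protein
            for gid, rec in records.items()
            if gid.split("_", 1)[1].split("d")[0] == g
        }
        for g in anc_genes
    }

    gene_models = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "species": r.species,
                "chrom": r.chrom,
                "chrom_length": chrom_lengths[r.chrom],
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "n_exons": len(r.exons),
                "cds_start": r.start if r.strand == "+" else None,
                "cds_end": r.end if r.strand == "-" else None,
            }
            for r in records.values()
        ]
    )
    truth = SyntheticTruth(
        pair_modes=pair_modes,
        branch_omega=branch_omega,
        motif_counts=motif_counts,
        expression=expression,
        alignments=alignments,
    )
    return records, gene_models, truth


def _concrete_instance(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC[s][int(rng.integers(0, len(IUPAC[s])))] for s in consensus.upper()
    )


def _background(
    length: int,
    motifs: tuple[MotifDefinition, ...],
    rng: np.random.Generator,
    max_iter: int = 200,
) -> str:
    """Random sequence free of every listed motif on both strands,
    produced by iterative resampling of offending windows."""
    import re

    pats = []
    for m in motifs:
        fwd = iupac_to_regex(m.consensus)
        rev = iupac_to_regex(str(Seq(m.consensus.upper()).reverse_complement()))
        for p in {fwd, rev}:
            pats.append((re.compile(f"(?={p})"), len(m.consensus)))
    seq = list("".join(BASES[i] for i in rng.integers(0, 4, size=length)))
    for _ in range(max_iter):
        s = "".join(seq)
        dirty = False
        for pat, width in pats:
            for match in pat.finditer(s):
                dirty = True
                a = match.start()
                for k in range(a, min(a + width, length)):
                    seq[k] = BASES[int(rng.integers(0, 4))]
        if not dirty:
            return "".join(seq)
    raise RuntimeError(
        "could not build a motif-free background: motif set too permissive"
    )


def plant_promoters(
    genes: list[str],
    motif_table: tuple[MotifDefinition, ...],
    rates: dict[str, float],
    promoter_length_bp: int = 2000,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 50,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Promoters with exact known cis-element counts.

    Per gene, each motif's planted count is Poisson with mean
    ``rates[name]`` (0 if absent). The background contains no spurious
    occurrence of any listed motif, and planting is verified by a full
    double-strand re-scan, so truth counts are exact. Raises when the
    motif set is too permissive to satisfy exactly.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    unknown = set(rates) - {m.name for m in motif_table}
    if unknown:
        raise ValueError(f"rates reference motifs not in table: {sorted(unknown)}")
    names = [m.name for m in motif_table]
    by_name = {m.name: m for m in motif_table}
    promoters: dict[str, str] = {}
    counts_rows = []
    for gene in genes:
        planned = {
            n: int(rng.poisson(rates.get(n, 0.0))) for n in names
        }
        ok = False
        for _ in range(max_attempts):
            seq = list(_background(promoter_length_bp, motif_table, rng))
            occupied: list[tuple[int, int]] = []
            feasible = True
            for name in names:
                width = len(by_name[name].consensus)
                for _k in range(planned[name]):
                    placed = False
                    for _try in range(200):
                        pos = int(rng.integers(0, promoter_length_bp - width + 1))
                        if all(
                            pos + width <= a or pos >= b for a, b in occupied
                        ):
                            inst = _concrete_instance(by_name[name].consensus, rng)
                            seq[pos : pos + width] = list(inst)
                            occupied.append((pos, pos + width))
                            placed = True
                            break
                    if not placed:
                        feasible = False
                        break
                if not feasible:
                    break
            if not feasible:
                continue
            s = "".join(seq)
            scanned = scan_motifs({gene: s}, motif_table).counts.loc[gene]
            if all(int(scanned[n]) == planned[n] for n in names):
                promoters[gene] = s
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not plant motifs exactly for {gene}: motif set too permissive"
            )
        counts_rows.append({"gene": gene, **planned})
    counts = pd.DataFrame(counts_rows).set_index("gene")
    return promoters, counts


def simulate_qpcr(
    true_rel_expr: pd.DataFrame,
    ct_noise_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
    reference_gene: str = "TUB1",
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate Ct table implied by true fold changes.

    ``true_rel_expr`` has columns gene, sample, fold (relative to the
    calibrator sample, whose fold must be 1). The reference gene cycles at
    a constant expected Ct across samples; target Ct is
    base - log2(fold) + noise.
    """
    if (true_rel_expr["fold"] <= 0).any():
        raise ValueError("fold changes must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    genes = list(dict.fromkeys(true_rel_expr["gene"]))
    samples = list(dict.fromkeys(true_rel_expr["sample"]))
    base_ct = {g: float(rng.uniform(22.0, 28.0)) for g in genes}
    ref_ct = 18.0
    rows = []
    fold = true_rel_expr.set_index(["gene", "sample"])["fold"]
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd else 0.0
            rows.append(
                {
                    "gene": reference_gene,
                    "sample": sample,
                    "replicate": rep,
                    "Ct": ref_ct + noise,
                }
            )
            for g in genes:
                noise = (
                    float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd else 0.0
                )
                rows.append(
                    {
                        "gene": g,
                        "sample": sample,
                        "replicate": rep,
                        "Ct": base_ct[g] - np.log2(fold[(g, sample)]) + noise,
                    }
                )
    return pd.DataFrame(rows)


def assemble_genome(
    records: dict[str, SequenceRecord],
    chrom_lengths: dict[str, int],
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Random chromosome sequences with each gene's exons (and its promoter
    immediately upstream, strand-aware) embedded at its coordinates."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    genome = {
        c: np.frombuffer(
            "".join(BASES[i] for i in rng.integers(0, 4, size=n)).encode(),
            dtype="S1",
        ).copy()
        for c, n in chrom_lengths.items()
    }
    for r in records.values():
        chrom = genome[r.chrom]
        # on the minus strand the genomic text is the reverse complement of
        # the CDS, laid across the exons left-to-right in genomic order
        cds = r.cds if r.strand == "+" else str(Seq(r.cds).reverse_complement())
        offset = 0
        for a, b in r.exons:
            width = b - a + 1
            chrom[a - 1 : b] = np.frombuffer(
                cds[offset : offset + width].encode(), dtype="S1"
            )
            offset += width
        if r.promoter is not None:
            plen = len(r.promoter)
            if r.strand == "+":
                lo = r.start - plen
                if lo >= 1:
                    chrom[lo - 1 : r.start - 1] = np.frombuffer(
                        r.promoter.encode(), dtype="S1"
                    )
            else:
                hi = r.end + plen
                if hi <= len(chrom):
                    rc = str(Seq(r.promoter).reverse_complement())
                    chrom[r.end : hi] = np.frombuffer(rc.encode(), dtype="S1")
    return {c: arr.tobytes().decode() for c, arr in genome.items()}


def write_family(
    outdir: str | Path,
    records: dict[str, SequenceRecord],
    gene_models: pd.DataFrame,
    truth: SyntheticTruth,
    ct_table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the simulated bundle: CDS/protein/promoter FASTA, GFF3,
    chromosome-length TSV, motif-truth TSV, optional Ct CSV, truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def fasta(path: Path, seqs: dict[str, str]) -> None:
        with open(path, "w") as fh:
            for k, v in seqs.items():
                fh.write(f">{k}\n")
                for i in range(0, len(v), 60):
                    fh.write(v[i : i + 60] + "\n")

    paths["cds"] = out / "family_cds.fasta"
    fasta(paths["cds"], {g: r.cds for g, r in records.items()})
    paths["protein"] = out / "family_protein.fasta"
    fasta(paths["protein"], {g: r.protein for g, r in records.items()})
    if any(r.promoter for r in records.values()):
        paths["promoters"] = out / "family_promoters.fasta"
        fasta(
            paths["promoters"],
            {g: r.promoter for g, r in records.items() if r.promoter},
        )

    paths["gff3"] = out / "family.gff3"
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g, r in records.items():
            fh.write(
                f"{r.chrom}\tfamevol\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID=gene:{g}\n"
            )
            fh.write(
                f"{r.chrom}\tfamevol\tmRNA\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID=mrna:{g};Parent=gene:{g}\n"
            )
            for k, (a, b) in enumerate(r.exons, 1):
                fh.write(
                    f"{r.chrom}\tfamevol\texon\t{a}\t{b}\t.\t{r.strand}\t.\t"
                    f"ID=exon:{g}.{k};Parent=mrna:{g}\n"
                )
                fh.write(
                    f"{r.chrom}\tfamevol\tCDS\t{a}\t{b}\t.\t{r.strand}\t0\t"
                    f"ID=cds:{g};Parent=mrna:{g}\n"
                )

    paths["chrom_lengths"] = out / "chrom_lengths.tsv"
    gene_models[["chrom", "chrom_length"]].drop_duplicates().to_csv(
        paths["chrom_lengths"], sep="\t", index=False
    )
    paths["gene_models"] = out / "gene_models.tsv"
    gene_models.to_csv(paths["gene_models"], sep="\t", index=False)
    paths["motif_truth"] = out / "motif_truth.tsv"
    truth.motif_counts.to_csv(paths["motif_truth"], sep="\t")
    if ct_table is not None:
        paths["ct"] = out / "ct_values.csv"
        ct_table.to_csv(paths["ct"], index=False)
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "pair_modes": {
                    f"{a}|{b}": m for (a, b), m in truth.pair_modes.items()
                },
                "branch_omega": truth.branch_omega,
                "expression": truth.expression.to_dict(orient="records"),
            },
            fh,
            indent=1,
        )
    return paths
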