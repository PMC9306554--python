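"""Family identification, gene-structure summaries and pipeline orchestration.

The identification stage mirrors the usual gene-family workflow: candidates
come from an external homology search (a BLASTP hit table can be passed
through) or an internal global-alignment screen against the reference
family; candidates lacking a complete family domain are dropped, and
redundant entries (identical sequence, or isoforms of one locus) are
collapsed keeping the longest. Every rejection is recorded in an audit log.

``run_pipeline`` chains the stages — identification, physicochemistry,
identity matrix, NJ phylogeny, duplication/Ka-Ks, promoter scanning and
relative expression — writing each stage's tables plus a manifest of
parameters and input checksums. Reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
import yaml

from . import align, phylo, protparam, regulatory, selection
from .io import read_fasta

__all__ = [
    "CandidateFilterConfig",
    "StructureSummary",
    "filter_candidates",
    "summarize_structure",
    "run_pipeline",
]


@dataclass(frozen=True)
class CandidateFilterConfig:
    domain_completeness: float = 0.9  # fraction of the domain model span
    min_screen_identity: float = 30.0  # internal screen, percent
    min_screen_coverage: float = 0.5  # aligned fraction of the candidate
    max_evalue: float = 1e-3  # for an external hit table
    redundancy: str = "both"  # "sequence" | "locus" | "both"

    def __post_init__(self) -> None:
        if not (0 < self.domain_completeness <= 1):
            raise ValueError("domain_completeness must be in (0, 1]")
        if self.redundancy not in {"sequence", "locus", "both"}:
            raise ValueError("redundancy must be sequence, locus or both")


@dataclass(frozen=True)
class StructureSummary:
    genes: pd.DataFrame  # gene, chrom, start, end, strand, n_exons (sorted)
    exon_histogram: pd.DataFrame  # subgroup x exon-count counts


def _locus(gene_id: str) -> str:
    return gene_id.rsplit(".", 1)[0]


def filter_candidates(
    candidates: dict[str, str],
    domain_spans: pd.DataFrame,
    config: CandidateFilterConfig = CandidateFilterConfig(),
    hit_table: pd.DataFrame | None = None,
    query_proteins: dict[str, str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Retain family candidates; log every rejection with its reason.

    ``domain_spans`` has columns id, start, end, model_length (one row per
    candidate with a detected domain). A candidate passes when (1) it has
    homology support — a hit-table row with evalue <= max_evalue, or an
    internal alignment screen against ``query_proteins`` — (2) its domain
    span covers at least ``domain_completeness`` of the model, and (3) it
    is not redundant (identical sequence or same locus; longest kept).
    """
    audit: list[dict] = []
    spans = domain_spans.set_index("id")
    hits = None
    if hit_table is not None:
        best = hit_table.groupby("id")["evalue"].min()
        hits = best[best <= config.max_evalue].index

    survivors: dict[str, str] = {}
    for cid, seq in candidates.items():
        if hits is not None:
            if cid not in hits:
                audit.append(
                    {"id": cid, "retained": False, "reason": "no significant hit"}
                )
                continue
        elif query_proteins is not None:
            support = False
            for q in query_proteins.values():
                aln = align.global_align(seq, q)
                both = sum(
                    a != "-" and b != "-"
                    for a, b in zip(aln.aligned_a, aln.aligned_b)
                )
                if (
                    aln.identity_pct >= config.min_screen_identity
                    and both / len(seq) >= config.min_screen_coverage
                ):
                    support = True
                    break
            if not support:
                audit.append(
                    {"id": cid, "retained": False, "reason": "below screen threshold"}
                )
                continue
        if cid not in spans.index:
            audit.append({"id": cid, "retained": False, "reason": "no domain"})
            continue
        row = spans.loc[cid]
        coverage = (row["end"] - row["start"] + 1) / row["model_length"]
        if coverage < config.domain_completeness:
            audit.append(
                {
                    "id": cid,
                    "retained": False,
                    "reason": f"truncated domain ({coverage:.2f} of model)",
                }
            )
            continue
        survivors[cid] = seq

    # redundancy collapse: keep the longest representative
    retained: dict[str, str] = {}
    seen_seq: dict[str, str] = {}
    by_locus: dict[str, str] = {}
    for cid in sorted(survivors, key=lambda c: (-len(survivors[c]), c)):
        seq = survivors[cid]
        if config.redundancy in {"sequence", "both"} and seq in seen_seq:
            audit.append(
                {
                    "id": cid,
                    "retained": False,
                    "reason": f"redundant (identical to {seen_seq[seq]})",
                }
            )
            continue
        if config.redundancy in {"locus", "both"} and _locus(cid) in by_locus:
            audit.append(
                {
                    "id": cid,
                    "retained": False,
                    "reason": f"redundant (same locus as {by_locus[_locus(cid)]})",
                }
            )
            continue
        seen_seq[seq] = cid
        by_locus[_locus(cid)] = cid
        retained[cid] = seq
        audit.append({"id": cid, "retained": True, "reason": "retained"})

    retained = {c: retained[c] for c in candidates if c in retained}
    return retained, pd.DataFrame(audit)


def summarize_structure(
    gff3: str | Path,
    subgroups: dict[str, str] | None = None,
) -> StructureSummary:
    """Exon counts and locations from a GFF3, with per-subgroup histograms.

    Genes are keyed by the gene feature's ID (a ``gene:`` prefix is
    stripped). An mRNA without exon children is an error.
    """
    db = gffutils.create_db(
        str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for gene in db.features_of_type("gene"):
        gid = gene.id.split(":", 1)[-1]
        n_exons = 0
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = list(db.children(mrna, featuretype="exon"))
            if not exons:
                raise ValueError(f"mRNA {mrna.id} has no exon features")
            n_exons = max(n_exons, len(exons))
        if n_exons == 0:
            exons = list(db.children(gene, featuretype="exon"))
            if not exons:
                raise ValueError(f"gene {gid} has no exon features")
            n_exons = len(exons)
        rows.append(
            {
                "gene": gid,
                "chrom": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand,
                "n_exons": n_exons,
                "subgroup": (subgroups or {}).get(gid, "unassigned"),
            }
        )
    genes = (
        pd.DataFrame(rows)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    hist = (
        genes.groupby(["subgroup", "n_exons"]).size().unstack(fill_value=0)
    )
    return StructureSummary(genes=genes, exon_histogram=hist)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run every stage the config provides inputs for.

    Config keys (paths unless noted): proteins_fasta (required),
    domain_table_tsv + optional hit_table_tsv and query_fasta
    (identification), alignment_fasta (phylogeny; protein FASTA of equal
    lengths also works), cds_fasta + gene_models_tsv (duplication and
    Ka/Ks), promoters_fasta (cis-element scan), ct_csv + reference_gene +
    calibrator_sample (expression), and parameters seed,
    bootstrap_replicates, min_identity_pct, tandem_max_kb. Missing optional
    inputs mark their stage "skipped" in the manifest; missing required
    files fail fast naming the stage.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"parameters": {k: v for k, v in config.items()}, "stages": {}, "inputs": {}}

    def record_input(key: str) -> Path | None:
        p = config.get(key)
        if p is None:
            return None
        path = Path(p)
        if not path.exists():
            raise FileNotFoundError(f"{key}: {p}")
        manifest["inputs"][key] = _sha256(path)
        return path

    proteins_path = record_input("proteins_fasta")
    if proteins_path is None:
        raise ValueError("identification: proteins_fasta is required")
    proteins = read_fasta(proteins_path)

    # 1. identification
    domain_path = record_input("domain_table_tsv")
    if domain_path is not None:
        hit_path = record_input("hit_table_tsv")
        query_path = record_input("query_fasta")
        retained, audit = filter_candidates(
            proteins,
            pd.read_csv(domain_path, sep="\t"),
            hit_table=None if hit_path is None else pd.read_csv(hit_path, sep="\t"),
            query_proteins=None if query_path is None else read_fasta(query_path),
        )
        audit.to_csv(out / "identification_audit.tsv", sep="\t", index=False)
        proteins = retained
        manifest["stages"]["identification"] = {
            "status": "ok",
            "retained": len(retained),
        }
    else:
        manifest["stages"]["identification"] = {"status": "skipped"}

    # 2. physicochemistry
    table = protparam.physchem_table(proteins)
    table.to_csv(out / "physchem.tsv", sep="\t", index=False)
    manifest["stages"]["protparam"] = {"status": "ok", "proteins": len(table)}

    # 3. identity matrix
    if len(proteins) >= 2:
        idm = align.identity_matrix(proteins)
        idm.round(2).to_csv(out / "identity_matrix.tsv", sep="\t")
        manifest["stages"]["identity"] = {"status": "ok"}
    else:
        idm = None
        manifest["stages"]["identity"] = {"status": "skipped"}

    # 4. phylogeny
    aln_path = record_input("alignment_fasta")
    aligned = read_fasta(aln_path) if aln_path else None
    if aligned is None and len({len(s) for s in proteins.values()}) == 1:
        aligned = proteins  # already columnwise comparable (e.g. simulator)
    if aligned is not None and len(aligned) >= 4:
        tree = phylo.bootstrap_supports(
            aligned,
            n_replicates=int(config.get("bootstrap_replicates", 100)),
            seed=seed,
        )
        (out / "tree.nwk").write_text(phylo.to_newick(tree) + "\n")
        refs = config.get("subgroup_references")
        if refs:
            assigned = phylo.assign_subgroups(tree, refs)
            pd.Series(assigned, name="subgroup").rename_axis("gene").to_csv(
                out / "subgroups.tsv", sep="\t"
            )
        manifest["stages"]["phylogeny"] = {"status": "ok", "taxa": len(aligned)}
    else:
        manifest["stages"]["phylogeny"] = {"status": "skipped"}

    # 5. duplication + Ka/Ks
    cds_path = record_input("cds_fasta")
    gm_path = record_input("gene_models_tsv")
    if cds_path is not None and gm_path is not None and idm is not None:
        cds = read_fasta(cds_path)
        gene_models = pd.read_csv(gm_path, sep="\t")
        criteria = selection.DuplicationCriteria(
            min_identity_pct=float(config.get("min_identity_pct", 80.0)),
            tandem_max_kb=float(config.get("tandem_max_kb", 200.0)),
        )
        pairs = selection.classify_duplicates(gene_models, idm, criteria)
        scored = []
        for p in pairs:
            pa = align.global_align(proteins[p.gene_a], proteins[p.gene_b])
            codon = align.backtranslate_alignment(
                {p.gene_a: pa.aligned_a, p.gene_b: pa.aligned_b}, cds
            )
            kk = selection.ng86_kaks(codon[p.gene_a], codon[p.gene_b])
            track = None
            if len(codon[p.gene_a]) >= 150:
                track = selection.sliding_window_kaks(
                    codon[p.gene_a], codon[p.gene_b]
                )
            scored.append(
                selection.DuplicatePair(
                    p.gene_a, p.gene_b, p.identity_pct, p.mode, kk, track
                )
            )
        selection.pairs_table(scored).to_csv(
            out / "duplicate_pairs.tsv", sep="\t", index=False
        )
        selection.window_table(scored).to_csv(
            out / "kaks_windows.tsv", sep="\t", index=False
        )
        manifest["stages"]["selection"] = {"status": "ok", "pairs": len(scored)}
    else:
        manifest["stages"]["selection"] = {"status": "skipped"}

    # 6. promoter cis-elements
    prom_path = record_input("promoters_fasta")
    if prom_path is not None:
        hits = regulatory.scan_motifs(read_fasta(prom_path))
        hits.counts.rename_axis("gene").to_csv(out / "motif_counts.tsv", sep="\t")
        hits.hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        manifest["stages"]["promoters"] = {"status": "ok"}
    else:
        manifest["stages"]["promoters"] = {"status": "skipped"}

    # 7. relative expression
    ct_path = record_input("ct_csv")
    if ct_path is not None:
        rel = regulatory.ddct_expression(
            pd.read_csv(ct_path),
            reference_gene=config.get("reference_gene", "TUB1"),
            calibrator_sample=config.get("calibrator_sample", "calibrator"),
        )
        rel.to_csv(out / "relative_expression.csv", index=False)
        manifest["stages"]["expression"] = {"status": "ok"}
    else:
        manifest["stages"]["expression"] = {"status": "skipped"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    report = ["# Gene-family pipeline report", ""]
    for stage, info in manifest["stages"].items():
        report.append(f"- **{stage}**: {info['status']}")
    (out / "report.md").write_text("\n".join(report) + "\n")
    return manifest
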