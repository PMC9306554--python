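# Methods

This note documents the models and procedures famevol implements, the
conventions it fixes where the field's tools are silent, and what its
synthetic-data tests do and do not demonstrate.

## Scope and design

The package reproduces the standard comparative gene-family workflow as a
library: identification filtering, per-protein physicochemistry, pairwise
identity, distance-based phylogeny, duplication classification, Ka/Ks,
promoter element counting and qPCR relative expression. Heavy external
steps that are not part of the analysis itself — homology search (BLASTP),
domain detection (SMART/HMMs), multiple sequence alignment, signal-peptide
and GPI-site prediction — are consumed as inputs (hit tables, domain
spans, aligned FASTA, annotation columns), with an internal
global-alignment screen as an offline fallback for identification. The
public surface is the importable API plus `examples/`; orchestration is a
single config-driven `run_pipeline` rather than a shell CLI, since the
package is used from Python.

## Protein physicochemistry

Molecular weight is the sum of average-isotope residue masses plus one
water (reported in kDa to 2 decimals); GRAVY is the arithmetic mean of
Kyte–Doolittle hydropathy values (3 decimals); hydropathy tracks are
sliding-window means (odd window, default 9 residues). The isoelectric
point solves net charge = 0 by bisection on pH ∈ (0, 14) to |charge| <
1e−4 under Henderson–Hasselbalch. The default pKa set is
Bjellqvist/ExPASy (with residue-specific terminal pKas), because family
tables in the literature are produced with the ExPASy ProtParam tool; an
EMBOSS set is selectable. Ambiguous residues (X/B/Z/U…) are skipped with
a warning for GRAVY/pI and given the mean residue mass for MW; a strict
mode raises instead. Real proteomes contain such residues, so silent
failure and silent precision are both avoided.

## Pairwise alignment and identity

Global protein alignment is Needleman–Wunsch with affine gaps
(BLOSUM62, gap open 10, extend 0.5 — ClustalW-like defaults), delegated
to Biopython's `PairwiseAligner`; the first optimal traceback is used,
which is deterministic for fixed inputs. Percent identity is defined as
identical residue pairs divided by total alignment columns (gaps in the
denominator). Published identity figures rarely state their denominator
or alignment parameters, so values like a reported 53.3% for a specific
pair are not exactly reproducible by construction; the package fixes its
own convention and treats literature values as qualitative context only.
Codon alignments are produced by threading each CDS through its gapped
protein (one protein gap → one `---` codon), after verifying the CDS
translates exactly to the ungapped protein.

## Phylogeny

Distances from an MSA use pairwise deletion of gap-containing columns;
p-distance or Poisson correction d = −ln(1−p) (default, the common
protein choice when no model is specified). Saturated pairs (p ≥ 1 under
Poisson) either raise or are clamped to a large finite distance
(bootstrap uses clamping so replicates never abort). Neighbor-joining
follows Saitou–Nei with the Q-criterion; ties are broken by taxon-id
order (each working cluster keyed by its smallest leaf label), so output
is independent of input order; negative limb lengths are clamped to zero
and logged. On additive matrices NJ provably recovers the generating tree
exactly — the test suite verifies topology and all patristic distances on
random trees of up to 12 taxa. Bootstrap resamples alignment columns with
replacement; edge support is the percentage of replicate trees containing
the same bipartition, stored as internal node labels in Newick output
(branch lengths to 6 decimals). Subgroup assignment gives each unlabeled
leaf the label of the nearest reference leaf by patristic distance, with
ties resolved toward the larger reference group and then lexically.

## Duplication and selection

Duplicate pairs are gene pairs above a percent-identity threshold
(default 80) within one species; a pair on one chromosome with midpoint
separation ≤ 200 kb is tandem, anything else segmental. The proximal
reading of the distance rule is the literature convention and the
default; both the threshold and the direction are configurable because
some text descriptions invert it. Midpoint distance is used because it is
unambiguous for nested or overlapping gene models.

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions from the nine single-nucleotide neighbours, with mutations to
stop codons counted as nonsynonymous — this keeps the conservation
invariant S + N = 3 × codons, which the suite asserts on every input —
and sites averaged over the two sequences. Codon differences are averaged
over all minimal mutational pathways; pathways through stop-codon
intermediates are excluded (if all are blocked, all pathways are used
with stop steps counted as nonsynonymous). Jukes–Cantor correction
d = −(3/4)ln(1 − (4/3)p) is applied to ps = Sd/S and pn = Nd/N; p ≥ 3/4
makes the correction undefined and is flagged, not dropped, as is the
undefined ratio when Ks = 0 (written as an empty field, never 0 or
infinity). At extreme divergence the pathway-averaged Sd can exceed S —
a known property of the counting method — and surfaces as the same
flagged condition. Biopython's independent NG86 implementation (which
does not exclude stop pathways) agrees to within 0.01 on simulated pairs
and is used as a cross-check, never as the implementation. The sliding
window is 150 bp with 9 bp steps (both codon multiples; non-multiples are
rejected since NG86 is codon-based), giving floor((L−window)/step)+1
windows; undefined windows stay undefined rather than interpolated.

## Promoters and expression

Promoters are the 1,500–2,000 bp (default 2,000, the upper bound being
the common convention) immediately upstream of the start codon,
strand-aware and clipped with a warning at chromosome edges. Cis-elements
are counted by exact IUPAC-consensus matching on both strands: every
overlapping occurrence counts; a minus-strand hit is a match of the
reverse-complemented consensus recorded at its position on the given
strand; palindromic consensi are counted once per position. The shipped
table carries literature consensus strings for the commonly scored plant
elements (ABRE, CGTCA/TGACG, TCA-element, P-box, GARE, TATC-box, AuxRE,
TGA-box, G-box, Box 4, O2-site, CAT-box, GCN4, AACA, WUN, MBS, TC-rich,
ARE, LTR). These are deterministic consensus re-scans: they will not
numerically match PlantCARE's database-model output and are not meant to.

Relative expression is 2^−ΔΔCt computed per replicate
(ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the calibrator sample's
mean ΔCt), reported as mean and SD of the per-replicate fold changes.
The result is invariant to a constant Ct offset applied to a whole
replicate (machine offset), and the calibrator's fold is exactly 1 in the
noise-free case (with noise, the arithmetic mean of 2^−x carries the
usual small lognormal upward bias — a property of the method, not of the
implementation).

## The simulator

`simulate_family` generates the entire input bundle with recorded truth.
Species scaffolds are four synthetic chromosomes of 1–5 Mb (only relative
positions matter to any analysis). Each ancestral gene (default 14, in 6
species — a Rosaceae-scale family) starts as a random stop-free CDS
(default 300 codons); terminal branches evolve it by a
proposal–acceptance scheme: uniform single-nucleotide proposals,
proposals creating stops rejected, synonymous changes always accepted,
nonsynonymous accepted with probability min(1, ω); the number of accepted
substitutions is Poisson(rate × codons) with default rate 0.3
substitutions/codon. This makes ω directly interpretable as the quantity
NG86 estimates without full codon-model machinery, and the recovery tests
confirm mean estimated Ka/Ks within ±0.15 of ω for ω ∈ {0.2, 0.5, 1.0}.
Duplication events place a tandem copy on the parent's chromosome within
the 200 kb threshold and a segmental copy on a different chromosome. Exon
structures (1–6 exons, 50–500 bp introns) tile the CDS. There are no
indels, no gene loss and no recombination, so the true alignment is the
identity — which is exactly what makes exact recovery checks possible.
Promoter backgrounds are rejection-sampled (iterative resampling of
offending windows) to contain no occurrence of any listed motif on either
strand before planting Poisson-distributed counts of concrete motif
instances, verified by a full re-scan; planted counts are therefore exact
rather than statistical. This requires the planted motif subset to be
free of mutual matches (including reverse complements and substrings);
the default subset (ABRE, MBS, ARE, LTR) satisfies this, and an
unsatisfiable set fails loudly after bounded attempts. Ct tables put the
reference gene at a constant expected 18 cycles and targets at
base − log2(fold) + N(0, σ) with σ = 0.2 cycles and triplicates.

Everything is driven by one `numpy` generator seeded from the config, so
identical configs give byte-identical output files.

What passing tests show — and do not. The simulator emulates the
*structure* of real data (coordinates, strandedness, codon constraint,
motif placement, replicate noise), not its biology: no indels or
alignment error, no rate heterogeneity across sites, no GC bias, no
transition/transversion bias, promoters with uniform base composition.
Passing recovery tests therefore demonstrates the estimators are
implemented correctly and are unbiased under their own assumptions; they
do not demonstrate robustness to alignment error or compositional
heterogeneity in real genomes.

## Numerical and bookkeeping choices

Coordinates are 1-based inclusive on disk (GFF3) and converted at I/O
boundaries. MW is reported to 2 decimals (kDa), pI to 2, GRAVY to 3,
Ka/Ks to 3, matching the precision such tables are printed at. Problem
sizes in the test and acceptance runs (300-codon genes, 50-seed Monte
Carlo, 100-trial oracle comparisons, 200 promoters) were chosen as the
smallest sizes at which the statistical checks have comfortable power.

## Known limitations

Identification accepts external hit/domain tables rather than running
BLASTP/HMM searches; the internal screen is a global-alignment heuristic,
not a substitute for a profile search. NG86 is the classic counting
method — no Li93/YN00/ML codon models, no transition/transversion
weighting. MSA construction is out of scope (an aligned FASTA is an
input; the simulator's no-indel families are trivially aligned).
PlantCARE-style probabilistic motif models, amplification-efficiency
correction (Pfaffl), and synteny-based (collinearity) duplication calling
are deliberately not implemented.
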