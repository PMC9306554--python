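"""Neighbor-joining phylogeny with bootstrap supports and subgroup
assignment.

Distances are Poisson-corrected from the protein alignment; bootstrap
resamples columns. Subgroups propagate from labeled reference leaves to
their nearest neighbours by patristic distance — the way family subclades
(e.g. a COBRA-like vs a COBL7-like group) are assigned from a few
reference members.
"""

from famevol import phylo
from famevol.simulate import FamilySimConfig, simulate_family

records, _, truth = simulate_family(
    FamilySimConfig(n_species=3, n_ancestral_genes=2, cds_length_codons=120, seed=5)
)
msa = {g: r.protein for g, r in records.items()}  # no indels: already aligned

tree = phylo.bootstrap_supports(msa, n_replicates=100, seed=0)
print(phylo.to_newick(tree))

groups = phylo.assign_subgroups(tree, {"sp1_g1": "GroupA", "sp1_g2": "GroupB"})
for gene, grp in sorted(groups.items()):
    print(f"  {gene}: {grp}")
# every g1 ortholog should land in GroupA, every g2 ortholog in GroupB
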