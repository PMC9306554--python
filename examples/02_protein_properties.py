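"""Physicochemical profile of a protein set: residue count, molecular
weight (kDa), isoelectric point, GRAVY and a hydropathy track.

Negative GRAVY means the protein is on balance hydrophilic, the usual
situation for members of cell-wall gene families; the hydropathy track
localises hydrophobic stretches (candidate signal peptides / GPI-anchor
regions at the termini).
"""

from famevol.protparam import hydropathy_profile, physchem_table
from famevol.simulate import FamilySimConfig, simulate_family

records, _, _ = simulate_family(
    FamilySimConfig(n_species=1, n_ancestral_genes=4, cds_length_codons=150, seed=1)
)
proteins = {g: r.protein for g, r in records.items()}

table = physchem_table(proteins)
print(table.to_string(index=False))

gene = next(iter(proteins))
track = hydropathy_profile(proteins[gene], window=9)
print(f"\n{gene}: hydropathy windows={len(track)}, "
      f"min={track.values.min():.2f}, max={track.values.max():.2f}")
# each window value is the mean Kyte-Doolittle score of 9 residues
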