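"""Promoter cis-element counting and 2^-ddCt relative expression.

Promoters are scanned on both strands for IUPAC consensus elements
(hormone / light / stress / development responsive). The qPCR stage turns
triplicate Ct values into fold changes relative to a calibrator sample,
normalised by a reference gene.
"""

import pandas as pd

from famevol.regulatory import DEFAULT_MOTIFS, ddct_expression, scan_motifs
from famevol.simulate import plant_promoters, simulate_qpcr

# promoters with known planted counts
motifs = tuple(m for m in DEFAULT_MOTIFS if m.name in {"ABRE", "MBS", "ARE"})
promoters, truth = plant_promoters(
    ["gene1", "gene2", "gene3"], motifs, {"ABRE": 2.0, "MBS": 1.0, "ARE": 1.0},
    seed=9,
)
counts = scan_motifs(promoters, motifs).counts
print("scanned counts (== planted truth):")
print(counts)
assert (counts.loc[truth.index, truth.columns] == truth).all().all()

# expression: truth fold changes -> Ct table -> recovered fold changes
expr = pd.DataFrame(
    [
        {"gene": "gene1", "sample": "calibrator", "fold": 1.0},
        {"gene": "gene1", "sample": "fruit_15dap", "fold": 6.0},
        {"gene": "gene1", "sample": "leaf", "fold": 0.3},
    ]
)
ct = simulate_qpcr(expr, ct_noise_sd=0.2, seed=2)
rel = ddct_expression(ct, reference_gene="TUB1", calibrator_sample="calibrator")
print("\nrecovered relative expression (truth: 1.0, 6.0, 0.3):")
print(rel.to_string(index=False))
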