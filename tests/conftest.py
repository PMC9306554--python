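import random

import dendropy
import numpy as np
import pandas as pd
import pytest

from famevol.simulate import DuplicationEvent, FamilySimConfig, simulate_family


@pytest.fixture(scope="session")
def family():
    """Small two-species family with one tandem and one segmental event."""
    cfg = FamilySimConfig(
        n_species=2,
        n_ancestral_genes=3,
        duplication_events=(
            DuplicationEvent("sp1", "tandem", "g1"),
            DuplicationEvent("sp2", "segmental", "g2"),
        ),
        cds_length_codons=60,
        seed=7,
    )
    return simulate_family(cfg)


def random_additive_instance(n_taxa: int, rng: np.random.Generator):
    """A random binary tree with positive branch lengths and its exact
    patristic distance matrix (an additive matrix by construction)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=tns,
        rng=random.Random(int(rng.integers(1 << 30))),
    )
    for e in tree.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    D = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for a in tns:
        for b in tns:
            if a is not b:
                D.loc[a.label, b.label] = pdm.patristic_distance(a, b)
    return tree, D
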