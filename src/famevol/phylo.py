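"""Distance-based phylogenetics: MSA distances, neighbor-joining, bootstrap.

Distances come from an aligned protein FASTA with pairwise deletion of
gapped columns, either uncorrected (p-distance) or Poisson-corrected
(d = -ln(1-p)), the common default for protein NJ trees. Tree construction
is Saitou-Nei neighbor-joining with deterministic tie-breaking by taxon id,
negative branch lengths clamped to zero. Bootstrap resamples alignment
columns with replacement; edge support is the percentage of replicate trees
containing the same bipartition.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "msa_distances",
    "nj_tree",
    "bootstrap_supports",
    "assign_subgroups",
    "bipartitions",
    "to_newick",
]

GAP = "-"


def _check_aligned(aligned: dict[str, str]) -> int:
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return lengths.pop()


def msa_distances(
    aligned: dict[str, str],
    model: str = "poisson",
    on_saturation: str = "error",
) -> pd.DataFrame:
    """Pairwise distance matrix from an MSA.

    Per pair, columns where either sequence has a gap are deleted;
    p = mismatches / compared columns. ``model="p"`` returns p itself,
    ``model="poisson"`` returns -ln(1-p). For p >= 1 the Poisson correction
    is undefined: ``on_saturation`` chooses ``"error"`` or ``"clamp"``
    (p clamped just below 1, yielding a large finite distance).
    """
    if model not in {"p", "poisson"}:
        raise ValueError("model must be 'p' or 'poisson'")
    _check_aligned(aligned)
    ids = list(aligned)
    arr = {k: np.frombuffer(v.upper().encode(), dtype="S1") for k, v in aligned.items()}
    gap = GAP.encode()
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[ids[i]], arr[ids[j]]
            keep = (a != gap) & (b != gap)
            compared = int(keep.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]} and {ids[j]}"
                )
            p = float((a[keep] != b[keep]).sum()) / compared
            if model == "p":
                d = p
            else:
                if p >= 1.0:
                    if on_saturation == "error":
                        raise ValueError(
                            f"saturated pair {ids[i]}/{ids[j]} (p={p}); "
                            "Poisson correction undefined"
                        )
                    p = 1.0 - 1e-6
                d = -np.log(1.0 - p)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining from a symmetric distance matrix.

    Ties in the Q criterion are broken by taxon-id order (each working
    cluster is keyed by its lexicographically smallest leaf). Negative limb
    lengths are clamped to zero with a warning. Returns an unrooted tree
    with a trifurcating seed node.
    """
    ids = list(distances.index)
    if len(ids) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(ids)
    nodes: dict[str, dendropy.Node] = {}
    for t in ids:
        node = dendropy.Node(taxon=tns.get_taxon(t))
        nodes[t] = node
    D: dict[str, dict[str, float]] = {
        a: {b: float(distances.loc[a, b]) for b in ids if b != a} for a in ids
    }
    active = sorted(ids)

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                logger.info("negative NJ branch length %.6g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * D[a][b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        dab = D[a][b]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = clamp(la)
        nodes[b].edge.length = clamp(lb)
        key = min(a, b)
        newd = {
            c: 0.5 * (D[a][c] + D[b][c] - dab)
            for c in active
            if c not in (a, b)
        }
        for c in list(newd):
            D[c].pop(a, None)
            D[c].pop(b, None)
            D[c][key] = newd[c]
        D.pop(a)
        D.pop(b)
        D[key] = newd
        nodes.pop(a)
        nodes.pop(b)
        nodes[key] = parent
        active = sorted(set(active) - {a, b} | {key})

    a, b, c = active
    va = clamp(0.5 * (D[a][b] + D[a][c] - D[b][c]))
    vb = clamp(0.5 * (D[a][b] + D[b][c] - D[a][c]))
    vc = clamp(0.5 * (D[a][c] + D[b][c] - D[a][b]))
    root = dendropy.Node()
    for key, v in ((a, va), (b, vb), (c, vc)):
        root.add_child(nodes[key])
        nodes[key].edge.length = v
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as normalized leaf-label sets.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf is recorded, making the set
    invariant to rooting and taxon order.
    """
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(labels)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if anchor in side:
            side = labels - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(frozenset(side))
    return out


def bootstrap_supports(
    aligned: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of an internal edge of the full-alignment tree is the percent
    of replicate trees containing the same bipartition, stored as the
    internal node's label. ``n_replicates=0`` returns the unadorned tree.
    """
    if len(aligned) < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    length = _check_aligned(aligned)
    base = nj_tree(msa_distances(aligned, model=model, on_saturation="clamp"))
    if n_replicates == 0:
        return base
    ids = list(aligned)
    mat = np.array([list(aligned[k].upper()) for k in ids])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        idx = rng.integers(0, length, size=length)
        rep = {k: "".join(mat[i, idx]) for i, k in enumerate(ids)}
        dm = msa_distances(rep, model=model, on_saturation="clamp")
        for bp in bipartitions(nj_tree(dm)):
            counts[bp] = counts.get(bp, 0) + 1
    labels = {leaf.taxon.label for leaf in base.leaf_node_iter()}
    anchor = min(labels)
    for node in base.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if anchor in side:
            side = labels - side
        if 2 <= len(side) <= len(labels) - 2:
            pct = 100.0 * counts.get(frozenset(side), 0) / n_replicates
            node.label = str(int(round(pct)))
    return base


def assign_subgroups(
    tree: dendropy.Tree, reference: dict[str, str]
) -> dict[str, str]:
    """Label every leaf with the subgroup of its nearest reference leaf.

    Nearest is by patristic (path) distance; ties go to the subgroup with
    more reference taxa, then lexicographically. Reference leaves keep
    their own label.
    """
    leaf_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = set(reference) - set(leaf_labels)
    if missing:
        raise ValueError(f"reference taxa not in tree: {sorted(missing)}")
    groups = set(reference.values())
    if not groups:
        raise ValueError("no reference labels supplied")
    group_sizes = {g: sum(1 for v in reference.values() if v == g) for g in groups}
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    out: dict[str, str] = {}
    for leaf in leaf_labels:
        if leaf in reference:
            out[leaf] = reference[leaf]
            continue
        t = tns.get_taxon(leaf)
        best = None  # (dist, -group_size, group)
        for ref, grp in reference.items():
            d = pdm.patristic_distance(t, tns.get_taxon(ref))
            cand = (d, -group_sizes[grp], grp)
            if best is None or cand < best:
                best = cand
        out[leaf] = best[2]
    return out


def to_newick(tree: dendropy.Tree) -> str:
    """Newick string with internal-node labels (supports) and 6-decimal
    branch lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    ).strip()
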