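"""Neighbor-joining trees, bootstrap support and phylogenetic-diversity
taxon reduction.

Two trees drive the analysis: a species tree from a single marker gene
(rpoB-like) and an operon tree from the naive concatenation of the seven
uniformly conserved operon proteins (cyp112, cyp114, fd, sdr, cyp117, cps,
ks — labels b, c, d, e, f, h, i).  Distances are p-distances with pairwise
gap deletion (a Poisson correction is available), trees are built with the
Saitou-Nei neighbor-joining agglomeration and rooted on the outgroup's
pendant edge.  Taxon sets are reduced by greedy phylogenetic-diversity
maximization, which is optimal for PD on trees.
"""

from __future__ import annotations

import io
import math

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

__all__ = [
    "CONCAT_ORDER",
    "concat_operon",
    "p_distance",
    "nj_tree",
    "root_with_outgroup",
    "bootstrap_support",
    "pd_reduce",
    "split_fusion_slots",
    "UndefinedDistanceError",
]

# cyp112, cyp114, fd, sdr, cyp117, cps, ks: the uniformly conserved core
CONCAT_ORDER = ("b", "c", "d", "e", "f", "h", "i")

_GAP_CHARS = frozenset("-.?X")


class UndefinedDistanceError(ValueError):
    """A pair of rows shares no comparable (gap-free) columns."""


def concat_operon(
    per_genome: dict[str, dict[str, str]],
    order: tuple[str, ...] = CONCAT_ORDER,
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Concatenate the conserved operon genes per genome, in fixed order.

    Genomes missing any required family are excluded rather than failing;
    the second return value maps each excluded genome to its missing
    families.  Fusion genes should be resolved into their constituent slots
    first (see :func:`split_fusion_slots`).
    """
    concatenated: dict[str, str] = {}
    excluded: dict[str, list[str]] = {}
    for genome in sorted(per_genome):
        seqs = per_genome[genome]
        missing = [lbl for lbl in order if not seqs.get(lbl)]
        if missing:
            excluded[genome] = missing
        else:
            concatenated[genome] = "".join(seqs[lbl] for lbl in order)
    return concatenated, excluded


def split_fusion_slots(
    sequence: str,
    labels: tuple[str, str],
    d_subject_span: tuple[int, int],
) -> dict[str, str]:
    """Cut a fusion gene's sequence into its constituent family slots.

    ``d_subject_span`` is the 1-based inclusive span of the ferredoxin (d)
    query on the fusion subject, taken from the supporting hit.  For a
    cyp114-fd fusion (labels ``('c','d')``) the upstream part is the c slot;
    for fd-sdr (``('d','e')``) the downstream part is the e slot.
    """
    start, end = d_subject_span
    if not (1 <= start <= end <= len(sequence)):
        raise ValueError(f"span {d_subject_span} outside sequence of length {len(sequence)}")
    d_part = sequence[start - 1 : end]
    if labels == ("c", "d"):
        return {"c": sequence[: start - 1], "d": d_part}
    if labels == ("d", "e"):
        return {"d": d_part, "e": sequence[end:]}
    raise ValueError(f"unsupported fusion labels {labels!r}")


def p_distance(
    alignment: dict[str, str], correction: str | None = None
) -> DistanceMatrix:
    """Pairwise p-distance with pairwise gap deletion.

    ``correction='poisson'`` applies -ln(1 - p).  A pair with zero
    comparable columns raises :class:`UndefinedDistanceError`.
    """
    ids = list(alignment)
    if len({len(s) for s in alignment.values()}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    mat = np.array([list(alignment[i]) for i in ids], dtype="U1")
    valid = ~np.isin(mat, list(_GAP_CHARS))
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            ncols = int(both.sum())
            if ncols == 0:
                raise UndefinedDistanceError(
                    f"no comparable columns between {ids[i]} and {ids[j]}"
                )
            p = float((mat[i][both] != mat[j][both]).sum()) / ncols
            if correction == "poisson":
                if p >= 1.0:
                    raise UndefinedDistanceError(
                        f"saturated distance between {ids[i]} and {ids[j]}"
                    )
                p = -math.log(1.0 - p)
            dm[i, j] = dm[j, i] = p
    return DistanceMatrix(dm, ids)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (Saitou-Nei agglomeration).

    Negative branch lengths are clamped to zero; taxon order in the matrix
    fixes all tie-breaks, so permuting taxa yields an isomorphic tree.
    Fewer than 3 taxa is an error.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    skbio_tree = _skbio_nj(dm, neg_as_zero=True)
    newick = io.StringIO()
    skbio_tree.write(newick, format="newick")
    tree = dendropy.Tree.get(data=newick.getvalue(), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root on the midpoint of the outgroup's pendant edge."""
    tree = tree.clone(depth=1)
    node = tree.find_node_with_taxon_label(outgroup_label)
    if node is None:
        raise LookupError(f"outgroup {outgroup_label!r} is not a leaf of the tree")
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return tree


def _bipartitions(tree: dendropy.Tree, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Nontrivial splits, each normalized to the side without the first taxon."""
    anchor = min(taxa)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(taxa) - 1:
            continue
        if anchor in below:
            below = taxa - below
        splits.add(below)
    return splits


def bootstrap_support(
    alignment: dict[str, str],
    n_replicates: int = 100,
    seed: int = 0,
    correction: str | None = None,
    return_replicates: bool = False,
):
    """NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate, an NJ tree is
    built per replicate, and each internal bipartition of the reference tree
    receives the percentage of replicates containing it (stored as the
    internal node label, Fig.-legend style).  Deterministic under the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(alignment)
    mat = np.array([list(alignment[i]) for i in ids], dtype="U1")
    ncols = mat.shape[1]
    taxa = frozenset(ids)
    anchor = min(taxa)

    reference = nj_tree(p_distance(alignment, correction))
    counts: dict[frozenset[str], int] = {}
    replicates: list[dendropy.Tree] = []
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep_aln = {
            ids[i]: "".join(mat[i][cols]) for i in range(len(ids))
        }
        try:
            rep_tree = nj_tree(p_distance(rep_aln, correction))
        except UndefinedDistanceError:
            continue
        replicates.append(rep_tree)
        for split in _bipartitions(rep_tree, taxa):
            counts[split] = counts.get(split, 0) + 1

    for node in reference.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(taxa) - 1:
            continue
        if anchor in below:
            below = taxa - below
        support = 100.0 * counts.get(below, 0) / n_replicates
        node.label = f"{support:.1f}"
    if return_replicates:
        return reference, replicates
    return reference


def pd_reduce(
    tree: dendropy.Tree, k: int, keep: tuple[str, ...] = ()
) -> set[str]:
    """Select k leaves maximizing phylogenetic diversity (greedy, optimal).

    PD of a leaf subset is the total branch length of the minimal subtree
    spanning it.  The greedy strategy — seed with the most distant leaf pair,
    then repeatedly add the leaf contributing the most new branch length —
    attains the optimum on trees.  ``keep`` forces labels (reference,
    outgroup) into the subset.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, {n}]")
    for lbl in keep:
        if lbl not in labels:
            raise LookupError(f"keep label {lbl!r} not a leaf")
    if len(keep) > k:
        raise ValueError("more mandatory-keep labels than k")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in leaves}

    def dist(a: str, b: str) -> float:
        return pdm.patristic_distance(taxa[a], taxa[b])

    chosen: list[str] = sorted(keep)
    if len(chosen) < 2:
        best_pair, best_len = None, -1.0
        for i in range(n):
            for j in range(i + 1, n):
                d = dist(labels[i], labels[j])
                if d > best_len:
                    best_len, best_pair = d, tuple(sorted((labels[i], labels[j])))
        if not chosen:
            chosen = list(best_pair)
        else:
            far = max(
                (lbl for lbl in sorted(labels) if lbl not in chosen),
                key=lambda lbl: dist(chosen[0], lbl),
            )
            chosen.append(far)

    # The spanned subtree is tracked as a connected marked node set on the
    # rooted representation; its root-most node is kept so candidates whose
    # rootward walk misses the subtree can attach by descending to it.
    node_of = {lf.taxon.label: lf for lf in leaves}
    depth: dict[int, float] = {}
    parent: dict[int, object] = {}
    ancestors: dict[int, set[int]] = {}
    for node in tree.preorder_node_iter():
        p = node.parent_node
        parent[id(node)] = p
        depth[id(node)] = (depth[id(p)] + (node.edge.length or 0.0)) if p else 0.0
        ancestors[id(node)] = (ancestors[id(p)] | {id(p)}) if p else set()

    marked: set[int] = set()
    top: object = None  # root-most marked node

    def attachment(label: str) -> tuple[float, object, object]:
        """(new branch length, node where the walk stops, new top or None)."""
        node = node_of[label]
        gained = 0.0
        while parent[id(node)] is not None:
            if id(node) in marked:
                return gained, node, None
            if top is not None and id(node) in ancestors[id(top)]:
                # descend from this ancestor to the subtree's top
                return gained + depth[id(top)] - depth[id(node)], node, node
            gained += node.edge.length or 0.0
            node = parent[id(node)]
        if id(node) in marked:
            return gained, node, None
        return gained + (depth[id(top)] if top is not None else 0.0), node, node

    def mark(label: str) -> None:
        nonlocal top
        _, stop, new_top = attachment(label)
        node = node_of[label]
        while node is not stop:
            marked.add(id(node))
            node = parent[id(node)]
        marked.add(id(stop))
        if new_top is not None:
            walker = top
            while walker is not new_top:
                marked.add(id(walker))
                walker = parent[id(walker)]
            top = new_top

    first = chosen[0]
    marked.add(id(node_of[first]))
    top = node_of[first]
    for lbl in chosen[1:]:
        mark(lbl)
    while len(chosen) < k:
        best_lbl, best_gain = None, -1.0
        for lbl in sorted(labels):
            if lbl in chosen:
                continue
            gain, _, _ = attachment(lbl)
            if gain > best_gain:
                best_gain, best_lbl = gain, lbl
        chosen.append(best_lbl)
        mark(best_lbl)
    return set(chosen)


def subset_pd(tree: dendropy.Tree, subset: set[str]) -> float:
    """Total branch length of the minimal subtree spanning ``subset``.

    An edge belongs to the spanning subtree iff subset leaves lie on both of
    its sides; computed directly from that definition, independently of the
    greedy bookkeeping in :func:`pd_reduce`.
    """
    total_subset = set(subset)
    pd = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()} & total_subset
        if below and total_subset - below:
            pd += node.edge.length or 0.0
    return pd
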