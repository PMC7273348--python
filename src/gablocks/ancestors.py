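"""Maximum-parsimony ancestral gene-block reconstruction.

Given a rooted tree and a gene block per leaf, infer a block for every
internal node minimizing the total event count — deletions, duplications and
splits — summed over all edges, where each edge is scored with the pairwise
event distance.

Ancestral blocks are searched over canonical states: a copy-number vector
over the observed families plus a sub-block count, realized in reference
gene order.  The search is a joint Sankoff dynamic program over these
states; when the state product is small it is exhaustive, and at larger
scale it is pruned to the families whose counts actually vary across the
leaves (constant families are fixed at their shared value), with the full
segment-count range retained.  Scoring edges with the true event distance —
rather than summing per-character increments independently — is what keeps
the restricted-split semantics (splits are counted over the families shared
by the two endpoint blocks) correct when presence changes and splits
co-occur on one edge.

Tie-breaks are deterministic: prefer presence, then lower copy number, then
fewer sub-blocks, then reference label order.  Gains appear in the
"deletions" column as unordered presence changes (the cumulative brackets
have three columns only: deletions, duplications, splits).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .blocks import Gene, GeneBlock
from .events import EventCount, event_distance

__all__ = [
    "AncestralReconstruction",
    "reconstruct",
    "oracle_reconstruct",
    "compare_trees",
    "annotate_flags",
    "OracleSizeError",
]


class OracleSizeError(ValueError):
    pass


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"__anc{id(node)}"


@dataclass
class AncestralReconstruction:
    tree: dendropy.Tree
    node_blocks: dict[str, GeneBlock]
    node_cumulative: dict[str, EventCount]
    total_events: int
    edge_events: dict[str, EventCount] = field(default_factory=dict)
    exhaustive: bool = True

    def to_table(self) -> pd.DataFrame:
        from .blocks import render_block

        rows = []
        for label, block in self.node_blocks.items():
            cum = self.node_cumulative[label]
            rows.append(
                {
                    "node": label,
                    "block": render_block(block),
                    "flags": block.flags,
                    "deletions": cum.deletions,
                    "duplications": cum.duplications,
                    "splits": cum.splits,
                }
            )
        return pd.DataFrame(rows)

    def annotated_newick(self) -> str:
        """Newick with internal labels carrying block string + cumulative triple."""
        from .blocks import render_block

        tree = self.tree.clone(depth=1)
        for node in tree.preorder_node_iter():
            label = _node_label(node)
            cum = self.node_cumulative[label]
            info = (
                f"{label}|{render_block(self.node_blocks[label])}"
                f"|[{cum.deletions} {cum.duplications} {cum.splits}]"
            )
            if node.is_leaf():
                node.taxon.label = info
            else:
                node.label = info
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


# --- canonical block states -----------------------------------------------


def _as_block(b) -> GeneBlock:
    if isinstance(b, GeneBlock):
        return b
    from .blocks import parse_block

    return GeneBlock(segments=[]) if b == "" else parse_block(b)


def _leaf_profile(block: GeneBlock, include_pseudo: bool):
    """(family->copies, segment count) over functional genes of a leaf block."""
    counts: dict[str, int] = {}
    nseg = 0
    for seg in block.segments:
        labels = [
            g.label for g in seg if include_pseudo or g.status == "full"
        ]
        if labels:
            nseg += 1
        for lbl in labels:
            counts[lbl] = counts.get(lbl, 0) + 1
    return counts, nseg


def _assemble(families: tuple[str, ...], counts: tuple[int, ...], k: int) -> GeneBlock:
    """Realize a canonical state in reference gene order with k sub-blocks."""
    genes = [
        Gene(fam) for fam, c in zip(families, counts) for _ in range(c)
    ]
    if not genes:
        return GeneBlock(segments=[])
    k = max(1, min(k, len(genes)))
    base, extra = divmod(len(genes), k)
    segments = []
    i = 0
    for s in range(k):
        size = base + (1 if s < extra else 0)
        segments.append(genes[i : i + size])
        i += size
    return GeneBlock(segments=segments)


def _state_sort_key(families, state):
    counts, k = state
    presence = sum(1 for c in counts if c > 0)
    return (-presence, sum(counts), k, counts)


def reconstruct(
    tree: dendropy.Tree,
    leaf_blocks: dict[str, GeneBlock | str],
    include_pseudo: bool = False,
    max_states: int = 256,
) -> AncestralReconstruction:
    """Maximum-parsimony ancestral blocks on a rooted tree.

    Every leaf label of the tree must appear in ``leaf_blocks`` (block
    objects or block strings; empty blocks are allowed).  The tree must be
    rooted (a bifurcating seed node).  Returns the per-node blocks, per-node
    cumulative event counts (events in the subtree below each node, ordered
    deletions/duplications/splits) and the total event count.
    """
    if len(tree.seed_node.child_nodes()) != 2:
        raise ValueError(
            "tree must be rooted (bifurcating root); use root_with_outgroup first"
        )
    tree = tree.clone(depth=1)
    n_anon = itertools.count(1)
    for node in tree.preorder_internal_node_iter():
        if not node.label:
            node.label = f"anc{next(n_anon)}"
    root = tree.seed_node
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in leaf_blocks]
    if missing:
        raise ValueError(f"no block for leaves: {missing}")
    blocks = {l: _as_block(b) for l, b in leaf_blocks.items()}

    profiles = {l: _leaf_profile(blocks[l], include_pseudo) for l in leaves}
    families = tuple(sorted({f for counts, _ in profiles.values() for f in counts}))
    if not families:
        # all leaves empty: the empty block everywhere, zero events
        return _finalize(tree, blocks, {}, families, include_pseudo, True)

    max_copies = {
        f: max(counts.get(f, 0) for counts, _ in profiles.values()) for f in families
    }
    max_k = max(max(nseg for _, nseg in profiles.values()), 1)

    # candidate per-family count ranges; constant families may be frozen
    full_product = max_k
    for f in families:
        full_product *= max_copies[f] + 1
    if full_product <= max_states:
        ranges = {f: range(max_copies[f] + 1) for f in families}
        exhaustive = True
    else:
        ranges = {}
        for f in families:
            observed = {counts.get(f, 0) for counts, _ in profiles.values()}
            if len(observed) == 1:
                ranges[f] = [observed.pop()]
            else:
                ranges[f] = range(max_copies[f] + 1)
        pruned_product = max_k
        for f in families:
            pruned_product *= len(ranges[f])
        exhaustive = False
        if pruned_product > max_states:
            # freeze the least variable families at their majority value
            variability = sorted(
                families,
                key=lambda f: (len(ranges[f]), f),
            )
            for f in variability:
                if pruned_product <= max_states:
                    break
                if len(ranges[f]) > 1:
                    values = [counts.get(f, 0) for counts, _ in profiles.values()]
                    majority = max(sorted(set(values)), key=values.count)
                    pruned_product //= len(ranges[f])
                    ranges[f] = [majority]

    states = []
    for combo in itertools.product(*(ranges[f] for f in families)):
        total = sum(combo)
        if total == 0:
            states.append((combo, 0))
        else:
            for k in range(1, min(max_k, total) + 1):
                states.append((combo, k))
    states.sort(key=lambda s: _state_sort_key(families, s))

    assembled = {s: _assemble(families, s[0], s[1]) for s in states}
    dist_cache: dict = {}

    def dist(sa, block_b) -> int:
        key = (sa, id(block_b))
        if key not in dist_cache:
            dist_cache[key] = event_distance(
                assembled[sa], block_b, include_pseudo=include_pseudo
            ).total
        return dist_cache[key]

    state_dist_cache: dict = {}

    def sdist(sa, sb) -> int:
        key = (sa, sb)
        if key not in state_dist_cache:
            state_dist_cache[key] = event_distance(
                assembled[sa], assembled[sb], include_pseudo=include_pseudo
            ).total
        return state_dist_cache[key]

    # bottom-up Sankoff
    cost: dict[str, dict] = {}
    for node in tree.postorder_node_iter():
        label = _node_label(node)
        if node.is_leaf():
            continue
        table = {}
        children = node.child_nodes()
        for s in states:
            c = 0
            for child in children:
                if child.is_leaf():
                    c += dist(s, blocks[child.taxon.label])
                else:
                    ctab = cost[_node_label(child)]
                    c += min(ctab[s2] + sdist(s, s2) for s2 in states)
            table[s] = c
        cost[label] = table

    # top-down assignment with deterministic tie-breaks (states pre-sorted)
    assignment: dict[str, tuple] = {}
    root_label = _node_label(root)
    best_root = min(states, key=lambda s: (cost[root_label][s],))
    assignment[root_label] = best_root
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is root:
            continue
        label = _node_label(node)
        parent_state = assignment[_node_label(node.parent_node)]
        assignment[label] = min(
            states, key=lambda s: (cost[label][s] + sdist(parent_state, s),)
        )

    node_blocks = dict(blocks)
    for label, s in assignment.items():
        node_blocks[label] = assembled[s]
    return _finalize(tree, node_blocks, assignment, families, include_pseudo, exhaustive)


def _finalize(tree, node_blocks, assignment, families, include_pseudo, exhaustive):
    edge_events: dict[str, EventCount] = {}
    node_cumulative: dict[str, EventCount] = {}
    for node in tree.postorder_node_iter():
        label = _node_label(node)
        if label not in node_blocks:  # all-empty corner case
            node_blocks[label] = GeneBlock(segments=[])
        cum = EventCount(0, 0, 0)
        for child in node.child_nodes():
            clabel = _node_label(child)
            ev = event_distance(
                node_blocks[label], node_blocks[clabel], include_pseudo=include_pseudo
            )
            edge_events[clabel] = ev
            cum = cum + ev + node_cumulative[clabel]
        node_cumulative[label] = cum
    total = node_cumulative[_node_label(tree.seed_node)].total
    return AncestralReconstruction(
        tree=tree,
        node_blocks=node_blocks,
        node_cumulative=node_cumulative,
        total_events=total,
        edge_events=edge_events,
        exhaustive=exhaustive,
    )


def oracle_reconstruct(
    tree: dendropy.Tree,
    leaf_blocks: dict[str, GeneBlock | str],
    include_pseudo: bool = False,
) -> int:
    """Minimal total event count by exhaustive state enumeration.

    A straightforward bottom-up minimization over the complete canonical
    state space (every copy-number combination of every observed family
    crossed with every sub-block count), with no per-family pruning and no
    shared machinery with :func:`reconstruct`'s candidate construction.
    Limits: at most 6 leaves, 4 families, 2 copies per family and 2
    sub-blocks per leaf block.
    """
    if len(tree.seed_node.child_nodes()) != 2:
        raise ValueError("tree must be rooted")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) > 6:
        raise OracleSizeError("more than 6 leaves")
    blocks = {l: _as_block(b) for l, b in leaf_blocks.items()}
    profiles = {l: _leaf_profile(blocks[l], include_pseudo) for l in leaves}
    families = tuple(sorted({f for counts, _ in profiles.values() for f in counts}))
    if len(families) > 4:
        raise OracleSizeError("more than 4 families")
    if any(
        c > 2 for counts, _ in profiles.values() for c in counts.values()
    ) or any(nseg > 2 for _, nseg in profiles.values()):
        raise OracleSizeError("leaf blocks exceed 2 copies or 2 sub-blocks")
    if not families:
        return 0

    states = []
    for combo in itertools.product(range(3), repeat=len(families)):
        if sum(combo) == 0:
            states.append((combo, 0))
        else:
            for k in range(1, min(2, sum(combo)) + 1):
                states.append((combo, k))
    realized = {s: _assemble(families, s[0], s[1]) for s in states}

    memo: dict = {}

    def d(key_a, block_a, key_b, block_b) -> int:
        key = (key_a, key_b)
        if key not in memo:
            memo[key] = event_distance(
                block_a, block_b, include_pseudo=include_pseudo
            ).total
        return memo[key]

    def subtree_costs(node) -> dict:
        """state -> minimal cost of the subtree when node takes that state."""
        if node.is_leaf():
            # leaf state is its observed block; represent as cost from parent
            return None
        child_tables = [(c, subtree_costs(c)) for c in node.child_nodes()]
        table = {}
        for s in states:
            total = 0
            for child, ctab in child_tables:
                if ctab is None:
                    label = child.taxon.label
                    total += d(s, realized[s], label, blocks[label])
                else:
                    total += min(
                        ctab[s2] + d(s, realized[s], s2, realized[s2])
                        for s2 in states
                    )
            table[s] = total
        return table

    root_table = subtree_costs(tree.seed_node)
    return min(root_table.values())


def compare_trees(
    leaf_blocks: dict[str, GeneBlock | str],
    trees: dict[str, dendropy.Tree],
    include_pseudo: bool = False,
) -> pd.DataFrame:
    """Total reconstructed events per candidate phylogeny, most parsimonious
    first.  All trees must carry the same leaf set."""
    leaf_sets = {
        name: frozenset(lf.taxon.label for lf in t.leaf_node_iter())
        for name, t in trees.items()
    }
    if len(set(leaf_sets.values())) > 1:
        raise ValueError(f"leaf sets differ across trees: {leaf_sets}")
    rows = []
    for name in sorted(trees):
        rec = reconstruct(trees[name], leaf_blocks, include_pseudo=include_pseudo)
        rows.append({"tree": name, "total_events": rec.total_events})
    return (
        pd.DataFrame(rows)
        .sort_values(["total_events", "tree"], kind="stable")
        .reset_index(drop=True)
    )


def annotate_flags(reconstruction: AncestralReconstruction) -> dict[str, str]:
    """Per-node flags: ``*`` full cyp115, ``!`` pseudo cyp115, ``?`` ggps2."""
    return {
        label: block.flags
        for label, block in reconstruction.node_blocks.items()
    }
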