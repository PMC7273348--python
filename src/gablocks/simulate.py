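"""Ground-truthed synthetic gene-block evolution.

The generator emulates the statistical structure the analysis assumes: a
Yule species tree; a reference-like operon block evolving along it by
deletion, duplication, split, gene gain, whole-operon horizontal transfer and
pseudogenizing truncation (a continuous-time thinning process, simulated
exactly with the Gillespie algorithm across contemporaneous lineages); operon
DNA with elevated GC relative to the genomic background; and a marker gene
(rpoB-like) plus operon genes diverging by substitutions, so that
identity/E-value thresholds, neighbor gaps and tree building behave like the
real inputs.

Every simulation yields an event log whose replay from the root block
reproduces each leaf block exactly — the ground truth against which ortholog
calling, block assembly and parsimony reconstruction are scored.
"""

from __future__ import annotations

import copy
import heapq
import itertools
import math
import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .blocks import Gene, GeneBlock, parse_block
from .genome_io import GeneFeature, Genome
from .orthology import FAMILY_NAMES

__all__ = [
    "SimulationConfig",
    "EventRecord",
    "EventLog",
    "Cohort",
    "sample_tree",
    "evolve_blocks",
    "replay_log",
    "evolve_sequences",
    "emit_genomes",
    "simulate_cohort",
    "random_sequence",
    "default_templates",
    "ConfigurationError",
]

ALPHABET = tuple(FAMILY_NAMES)  # a..k

# template ORF lengths (bp), loosely modeled on the reference operon genes
TEMPLATE_LENGTHS = {
    "a": 1350,  # cyp115
    "b": 1344,  # cyp112
    "c": 1380,  # cyp114
    "d": 300,  # fd (ferredoxin, short)
    "e": 759,  # sdr
    "f": 1371,  # cyp117
    "g": 903,  # ggps
    "h": 1506,  # cps
    "i": 1524,  # ks
    "j": 522,  # idi
    "k": 930,  # ggps2
}
MARKER_LENGTH = 1240  # rpoB-like species marker


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Event rates are per-unit-of-branch-length intensities: deletion per
    present family, duplication per functional gene copy, split per internal
    gene adjacency, gain per absent reference family, pseudogenization per
    functional gene copy, and HGT per lineage.  Substitution rates are per
    site per unit branch length.
    """

    n_leaves: int = 12
    birth_rate: float = 1.0
    root_block: str = "abcdefghij"  # the reference (gammaproteobacterial) layout
    rate_deletion: float = 0.06
    rate_duplication: float = 0.02
    rate_split: float = 0.03
    rate_gain: float = 0.01
    rate_hgt: float = 0.0
    rate_pseudogenize: float = 0.02
    gc_background: float = 0.60
    gc_operon: float = 0.68
    marker_sub_rate: float = 0.08
    operon_sub_rate: float = 0.05
    intra_block_gap: tuple[int, int] = (50, 400)
    split_gap: tuple[int, int] = (600, 2000)
    flank_length: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rate_deletion",
            "rate_duplication",
            "rate_split",
            "rate_gain",
            "rate_hgt",
            "rate_pseudogenize",
            "marker_sub_rate",
            "operon_sub_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("gc_background", "gc_operon"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not self.intra_block_gap[1] <= 500 < self.split_gap[0]:
            raise ConfigurationError(
                "intra_block_gap max must be <= 500 < split_gap min "
                "(the neighbor threshold separates the two regimes)"
            )
        if self.n_leaves < 2:
            raise ConfigurationError("n_leaves must be >= 2")


@dataclass(frozen=True)
class EventRecord:
    branch: str  # label of the child node of the edge the event lies on
    time: float  # absolute time from the root
    etype: str  # deletion | duplication | split | gain | hgt | pseudogenize
    family: str | None = None
    segment: int | None = None
    position: int | None = None
    donor: str | None = None  # hgt only


@dataclass
class EventLog:
    records: list[EventRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def count(self, etype: str | None = None) -> int:
        if etype is None:
            return len(self.records)
        return sum(1 for r in self.records if r.etype == etype)

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "branch": r.branch,
                    "time": r.time,
                    "event": r.etype,
                    "family": r.family,
                    "segment": r.segment,
                    "position": r.position,
                    "donor": r.donor,
                }
                for r in self.records
            ]
        )


def sample_tree(n_leaves: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Sample a Yule (pure-birth) tree with uniquely labeled leaves.

    Leaves are labeled ``T01..``, internal nodes ``N1..`` in preorder; all
    branch lengths are strictly positive and the same seed yields a
    byte-identical Newick string.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        rng=rng,
    )
    width = max(2, len(str(n_leaves)))
    leaf_i = itertools.count(1)
    node_i = itertools.count(1)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.taxon.label = f"T{next(leaf_i):0{width}d}"
        else:
            node.label = f"N{next(node_i)}"
        if node.parent_node is not None and (node.edge.length or 0) <= 0:
            node.edge.length = 1e-6
    tree.seed_node.edge.length = None
    return tree


def node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def node_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node_label(node)] = 0.0
        else:
            depths[node_label(node)] = (
                depths[node_label(node.parent_node)] + node.edge.length
            )
    return depths


# --- block state machinery -------------------------------------------------


def _block_state(block: GeneBlock | str) -> list[list[Gene]]:
    if isinstance(block, str):
        block = parse_block(block)
    return [list(seg) for seg in block.segments]


def _state_to_block(state: list[list[Gene]], genome_id: str) -> GeneBlock:
    return GeneBlock(genome_id=genome_id, segments=[list(s) for s in state if s])


def _present_families(state) -> list[str]:
    return sorted({g.label for seg in state for g in seg})


def _full_positions(state) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i, seg in enumerate(state)
        for j, g in enumerate(seg)
        if g.status == "full"
    ]


def _adjacencies(state) -> list[tuple[int, int]]:
    """(segment, cut position) pairs: cutting seg before index j+1."""
    return [(i, j + 1) for i, seg in enumerate(state) for j in range(len(seg) - 1)]


def apply_event(state: list[list[Gene]], rec: EventRecord) -> None:
    """Apply one (non-hgt) event record in place."""
    if rec.etype == "deletion":
        for seg in state:
            seg[:] = [g for g in seg if g.label != rec.family]
        state[:] = [seg for seg in state if seg]
    elif rec.etype == "duplication":
        seg = state[rec.segment]
        seg.insert(rec.position + 1, Gene(rec.family, "full"))
    elif rec.etype == "split":
        seg = state[rec.segment]
        state[rec.segment : rec.segment + 1] = [
            seg[: rec.position],
            seg[rec.position :],
        ]
    elif rec.etype == "gain":
        if rec.segment is None or rec.segment >= len(state):
            state.append([Gene(rec.family, "full")])
        else:
            state[rec.segment].insert(rec.position, Gene(rec.family, "full"))
    elif rec.etype == "pseudogenize":
        seg = state[rec.segment]
        seg[rec.position] = Gene(seg[rec.position].label, "pseudo")
    else:  # pragma: no cover
        raise ValueError(f"cannot apply event type {rec.etype!r}")


def _intensities(state, cfg: SimulationConfig) -> dict[str, float]:
    present = _present_families(state)
    full = _full_positions(state)
    return {
        "deletion": cfg.rate_deletion * len(present),
        "duplication": cfg.rate_duplication * len(full),
        "split": cfg.rate_split * len(_adjacencies(state)),
        "gain": cfg.rate_gain * (len(ALPHABET) - len(present)),
        "pseudogenize": cfg.rate_pseudogenize * len(full),
        "hgt": cfg.rate_hgt,
    }


@dataclass
class _Lineage:
    node: dendropy.Node
    t_start: float
    t_end: float
    state: list[list[Gene]]

    @property
    def label(self) -> str:
        return node_label(self.node)


def evolve_blocks(
    tree: dendropy.Tree, config: SimulationConfig
) -> tuple[dict[str, GeneBlock], EventLog]:
    """Evolve the root block along the tree; return leaf blocks + event log.

    Events on contemporaneous lineages are interleaved in global time order
    (exact Gillespie simulation), which makes whole-block HGT well defined:
    the recipient lineage's block is replaced by a copy of the current block
    of a uniformly chosen lineage alive at the event time, and the donor
    branch is recorded.
    """
    root_state = _block_state(config.root_block)
    if not any(root_state):
        raise ConfigurationError("root_block must be nonempty")
    rng = np.random.default_rng(config.seed)
    depths = node_depths(tree)
    log = EventLog()
    leaf_blocks: dict[str, GeneBlock] = {}

    live: dict[str, _Lineage] = {}
    heap: list = []
    counter = itertools.count()

    def schedule(lin: _Lineage, now: float) -> None:
        total = sum(_intensities(lin.state, config).values())
        if total <= 0:
            t_next = lin.t_end
        else:
            t_next = min(now + rng.exponential(1.0 / total), lin.t_end)
        heapq.heappush(heap, (t_next, next(counter), lin.label))

    def spawn_children(node: dendropy.Node, state) -> None:
        for child in node.child_nodes():
            lin = _Lineage(
                node=child,
                t_start=depths[node_label(node)],
                t_end=depths[node_label(child)],
                state=copy.deepcopy(state),
            )
            live[lin.label] = lin
            schedule(lin, lin.t_start)

    spawn_children(tree.seed_node, root_state)

    while heap:
        t, _, label = heapq.heappop(heap)
        lin = live.get(label)
        if lin is None:
            continue
        if t >= lin.t_end:
            del live[label]
            if lin.node.is_leaf():
                leaf_blocks[label] = _state_to_block(lin.state, label)
            else:
                spawn_children(lin.node, lin.state)
            continue
        weights = _intensities(lin.state, config)
        total = sum(weights.values())
        if total <= 0:
            heapq.heappush(heap, (lin.t_end, next(counter), label))
            continue
        etypes = sorted(weights)
        probs = np.array([weights[e] for e in etypes]) / total
        etype = etypes[rng.choice(len(etypes), p=probs)]
        rec = _draw_event(lin, etype, t, rng, live)
        if rec is not None:
            log.records.append(rec)
            if rec.etype == "hgt":
                lin.state = copy.deepcopy(live[rec.donor].state)
            else:
                apply_event(lin.state, rec)
        schedule(lin, t)

    log.records.sort(key=lambda r: r.time)
    return leaf_blocks, log


def _draw_event(
    lin: _Lineage, etype: str, t: float, rng, live: dict[str, _Lineage]
) -> EventRecord | None:
    state = lin.state
    if etype == "deletion":
        fams = _present_families(state)
        fam = fams[rng.integers(len(fams))]
        return EventRecord(lin.label, t, "deletion", family=fam)
    if etype == "duplication":
        pos = _full_positions(state)
        i, j = pos[rng.integers(len(pos))]
        return EventRecord(
            lin.label, t, "duplication", family=state[i][j].label, segment=i, position=j
        )
    if etype == "split":
        adj = _adjacencies(state)
        i, j = adj[rng.integers(len(adj))]
        return EventRecord(
            lin.label, t, "split", family=state[i][j - 1].label, segment=i, position=j
        )
    if etype == "gain":
        absent = sorted(set(ALPHABET) - set(_present_families(state)))
        if not absent:
            return None
        fam = absent[rng.integers(len(absent))]
        if state:
            i = int(rng.integers(len(state)))
            j = int(rng.integers(len(state[i]) + 1))
        else:
            i, j = None, None
        return EventRecord(lin.label, t, "gain", family=fam, segment=i, position=j)
    if etype == "pseudogenize":
        pos = _full_positions(state)
        i, j = pos[rng.integers(len(pos))]
        return EventRecord(
            lin.label, t, "pseudogenize", family=state[i][j].label, segment=i, position=j
        )
    if etype == "hgt":
        donors = sorted(lbl for lbl in live if lbl != lin.label)
        if not donors:
            return None
        donor = donors[rng.integers(len(donors))]
        return EventRecord(lin.label, t, "hgt", donor=donor)
    raise ValueError(etype)  # pragma: no cover


def replay_log(
    tree: dendropy.Tree, root_block: GeneBlock | str, log: EventLog
) -> dict[str, GeneBlock]:
    """Re-apply a recorded event history; reproduces the leaf blocks exactly."""
    depths = node_depths(tree)
    nodes = {node_label(n): n for n in tree.preorder_node_iter()}
    states: dict[str, list[list[Gene]]] = {}

    def state_at_start(label: str):
        node = nodes[label]
        parent = node.parent_node
        if parent is tree.seed_node or parent is None:
            return copy.deepcopy(_block_state(root_block))
        return copy.deepcopy(states[node_label(parent)])

    # process records in time order, tracking each lineage's current state
    current: dict[str, list[list[Gene]]] = {}

    def get_state(label: str, t: float):
        if label not in current:
            current[label] = _materialize(label, t)
        return current[label]

    def _materialize(label: str, t: float):
        node = nodes[label]
        parent = node.parent_node
        if parent is tree.seed_node or parent is None:
            return copy.deepcopy(_block_state(root_block))
        return copy.deepcopy(get_state(node_label(parent), t))

    # lineage state inherits from the parent's *final* state; records are in
    # time order and parents end before children start, so by the time a
    # child's first record arrives the parent state is final.
    for rec in sorted(log.records, key=lambda r: r.time):
        state = get_state(rec.branch, rec.time)
        if rec.etype == "hgt":
            donor_state = get_state(rec.donor, rec.time)
            current[rec.branch] = copy.deepcopy(donor_state)
        else:
            apply_event(state, rec)

    leaf_blocks = {}
    for leaf in tree.leaf_node_iter():
        label = node_label(leaf)
        leaf_blocks[label] = _state_to_block(get_state(label, depths[label]), label)
    return leaf_blocks


# --- sequences -------------------------------------------------------------

_BASES = "ACGT"


def random_sequence(length: int, gc: float, rng) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASES[i] for i in idx)


def default_templates(config: SimulationConfig, rng=None) -> dict[str, str]:
    """Per-family operon gene templates plus the ``marker`` template."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 101)
    templates = {
        lbl: random_sequence(length, config.gc_operon, rng)
        for lbl, length in TEMPLATE_LENGTHS.items()
    }
    templates["marker"] = random_sequence(MARKER_LENGTH, config.gc_background, rng)
    return templates


def _substitute(seq: str, n_subs: int, gc: float, rng) -> str:
    if n_subs <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    positions = rng.integers(0, len(arr), size=n_subs)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array([b"A", b"C", b"G", b"T"])
    arr[positions] = bases[rng.choice(4, size=n_subs, p=p)]
    return arr.tobytes().decode()


def evolve_sequences(
    tree: dendropy.Tree,
    templates: dict[str, str],
    sub_rate: float,
    gc: float,
    seed: int,
    hgt_records: list[EventRecord] = (),
) -> dict[str, dict[str, str]]:
    """Evolve template sequences along the tree, honoring whole-block HGT.

    Substitutions accumulate as Poisson(rate x length x time) uniform-site
    replacements with GC-biased base choice (so the configured GC is
    maintained in expectation).  At an HGT event the recipient lineage's
    whole template set is replaced by the donor lineage's sequences at that
    time, which reroutes the operon genealogy exactly as the block transfer
    does.  Returns per-leaf template sets.
    """
    rng = np.random.default_rng(seed)
    depths = node_depths(tree)
    nodes = {node_label(n): n for n in tree.preorder_node_iter()}
    hgt = sorted(
        (r for r in hgt_records if r.etype == "hgt"), key=lambda r: r.time
    )

    # lineage -> (sequences, time up to which they are evolved)
    state: dict[str, tuple[dict[str, str], float]] = {}

    def start_time(label: str) -> float:
        parent = nodes[label].parent_node
        return depths[node_label(parent)] if parent is not None else 0.0

    def seqs_at(label: str, t: float) -> dict[str, str]:
        if label not in state:
            parent = nodes[label].parent_node
            if parent is None or parent is tree.seed_node:
                state[label] = (dict(templates), start_time(label))
            else:
                parent_seqs = seqs_at(node_label(parent), start_time(label))
                state[label] = (dict(parent_seqs), start_time(label))
        seqs, t0 = state[label]
        t = min(t, depths[label])
        if t > t0:
            evolved = {
                name: _substitute(
                    s, rng.poisson(sub_rate * len(s) * (t - t0)), gc, rng
                )
                for name, s in sorted(seqs.items())
            }
            state[label] = (evolved, t)
        return state[label][0]

    for rec in hgt:
        donor_seqs = seqs_at(rec.donor, rec.time)
        seqs_at(rec.branch, rec.time)  # evolve recipient up to the event
        state[rec.branch] = (dict(donor_seqs), rec.time)

    return {
        node_label(leaf): dict(seqs_at(node_label(leaf), depths[node_label(leaf)]))
        for leaf in tree.leaf_node_iter()
    }


# --- genome emission -------------------------------------------------------


def emit_genomes(
    leaf_blocks: dict[str, GeneBlock],
    config: SimulationConfig,
    gene_sequences: dict[str, dict[str, str]] | dict[str, str],
    marker_sequences: dict[str, str] | None = None,
) -> dict[str, Genome]:
    """Assemble one synthetic genome per leaf.

    The operon sits on one contig between background flanks: genes within a
    sub-block are separated by intra-block gaps (<= the neighbor threshold),
    consecutive sub-blocks by split gaps (> the threshold); all gap and flank
    sequence is background-GC DNA.  Pseudogenized genes are truncated from
    the 3' end to a uniform 20-59% of their template so the downstream <60%
    pseudogene rule fires by construction.  The marker gene goes on a second
    contig.

    ``gene_sequences`` is either one template per family (applied to every
    leaf) or a per-leaf mapping of per-family sequences.
    """
    rng = np.random.default_rng(config.seed + 202)
    genomes: dict[str, Genome] = {}
    for leaf in sorted(leaf_blocks):
        block = leaf_blocks[leaf]
        if leaf in gene_sequences and isinstance(gene_sequences[leaf], dict):
            seqs = gene_sequences[leaf]
        else:
            seqs = gene_sequences  # shared templates
        for gene in block.genes:
            if gene.label not in seqs:
                raise ConfigurationError(
                    f"no template sequence for family {gene.label!r}"
                )
        parts: list[str] = [random_sequence(config.flank_length, config.gc_background, rng)]
        features: list[tuple[int, int, str, str]] = []  # start, end, label, fid
        cursor = len(parts[0])
        idx = itertools.count(1)
        for s_i, seg in enumerate(block.segments):
            if s_i > 0:
                gap = int(rng.integers(config.split_gap[0], config.split_gap[1] + 1))
                parts.append(random_sequence(gap, config.gc_background, rng))
                cursor += gap
            for g_i, gene in enumerate(seg):
                if g_i > 0:
                    gap = int(
                        rng.integers(
                            config.intra_block_gap[0], config.intra_block_gap[1] + 1
                        )
                    )
                    # spacers inside a sub-block are part of the transferred
                    # unit and carry the operon's composition
                    parts.append(random_sequence(gap, config.gc_operon, rng))
                    cursor += gap
                seq = seqs[gene.label]
                if gene.status == "pseudo":
                    frac = rng.uniform(0.20, 0.59)
                    seq = seq[: max(1, int(len(seq) * frac))]
                fid = f"{leaf}_g{next(idx):02d}_{gene.label}"
                features.append((cursor, cursor + len(seq), gene.label, fid))
                parts.append(seq)
                cursor += len(seq)
        parts.append(random_sequence(config.flank_length, config.gc_background, rng))
        contig = "".join(parts)

        genome = Genome(genome_id=leaf, contigs={"chr1": contig})
        for start, end, label, fid in features:
            genome.features.append(
                GeneFeature(
                    genome_id=leaf,
                    contig_id="chr1",
                    start=start,
                    end=end,
                    strand="+",
                    feature_id=fid,
                    family_hint=label,
                    sequence=contig[start:end],
                )
            )
        if marker_sequences is not None:
            mseq = marker_sequences[leaf]
            pad = random_sequence(1000, config.gc_background, rng)
            pad2 = random_sequence(1000, config.gc_background, rng)
            genome.contigs["chr2"] = pad + mseq + pad2
            genome.features.append(
                GeneFeature(
                    genome_id=leaf,
                    contig_id="chr2",
                    start=len(pad),
                    end=len(pad) + len(mseq),
                    strand="+",
                    feature_id=f"{leaf}_marker",
                    family_hint="marker",
                    sequence=mseq,
                )
            )
        genome.sort_features()
        genomes[leaf] = genome
    return genomes


# --- one-call cohort -------------------------------------------------------


@dataclass
class Cohort:
    """Everything one synthetic study needs, with its ground truth."""

    config: SimulationConfig
    tree: dendropy.Tree
    leaf_blocks: dict[str, GeneBlock]
    event_log: EventLog
    templates: dict[str, str]
    operon_seqs: dict[str, dict[str, str]]
    marker_seqs: dict[str, str]
    genomes: dict[str, Genome]


def simulate_cohort(config: SimulationConfig, emit: bool = True) -> Cohort:
    """Run the full generator: tree, blocks, sequences and genomes."""
    tree = sample_tree(config.n_leaves, config.birth_rate, config.seed)
    leaf_blocks, log = evolve_blocks(tree, config)
    templates = default_templates(config)
    operon_templates = {lbl: templates[lbl] for lbl in ALPHABET}
    operon_seqs = evolve_sequences(
        tree,
        operon_templates,
        config.operon_sub_rate,
        config.gc_operon,
        config.seed + 301,
        hgt_records=log.records,
    )
    marker = evolve_sequences(
        tree,
        {"marker": templates["marker"]},
        config.marker_sub_rate,
        config.gc_background,
        config.seed + 302,
    )
    marker_seqs = {leaf: seqs["marker"] for leaf, seqs in marker.items()}
    genomes = (
        emit_genomes(leaf_blocks, config, operon_seqs, marker_seqs) if emit else {}
    )
    return Cohort(
        config=config,
        tree=tree,
        leaf_blocks=leaf_blocks,
        event_log=log,
        templates=templates,
        operon_seqs=operon_seqs,
        marker_seqs=marker_seqs,
        genomes=genomes,
    )


def hgt_scenario(config: SimulationConfig, min_hgt: int = 1, max_tries: int = 30) -> Cohort:
    """A cohort conditioned on containing at least ``min_hgt`` HGT events.

    Deterministic under the config seed: seeds ``seed, seed+1000, ...`` are
    tried in order until the simulated history contains the required number
    of whole-operon transfers (the study condition, not an outcome filter).
    """
    if config.rate_hgt <= 0:
        raise ConfigurationError("hgt_scenario requires rate_hgt > 0")
    for attempt in range(max_tries):
        cohort = simulate_cohort(
            replace(config, seed=config.seed + 1000 * attempt), emit=False
        )
        if cohort.event_log.count("hgt") >= min_hgt:
            return cohort
    raise RuntimeError(
        f"no history with >= {min_hgt} HGT events in {max_tries} tries; "
        "raise rate_hgt"
    )


def expected_deletions(tree: dendropy.Tree, rate: float, n_root_families: int) -> float:
    """Exact expectation of logged deletion events under the pure-loss process.

    Each family present at a branch top is lost independently at the given
    rate, so E[deletions] = F0 * sum over branches of
    P(survival to the branch top) * (1 - exp(-rate * branch length)).
    Serves as the independent path-walk oracle for rate-recovery tests.
    """
    depths = node_depths(tree)
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        top = depths[node_label(node.parent_node)]
        length = node.edge.length
        total += math.exp(-rate * top) * (1.0 - math.exp(-rate * length))
    return n_root_families * total
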