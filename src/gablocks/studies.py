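"""Seeded study scenarios built from the simulator.

These functions define the package's standing computational experiments:
oracle cross-validation of the event distance and the parsimony
reconstruction, recovery of simulated event histories, the operon-vs-species
tree parsimony contrast under whole-operon HGT (the computational core of
the HGT argument), the GC screen, and NJ topology recovery on additive
matrices.  The scenario parameters are fixed study conditions; callers
supply only the base seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import replace

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .ancestors import oracle_reconstruct, reconstruct
from .events import event_distance, oracle_distance
from .gc_profile import region_contrast
from .phylo import CONCAT_ORDER, concat_operon, nj_tree, p_distance, _bipartitions
from .simulate import (
    SimulationConfig,
    evolve_blocks,
    hgt_scenario,
    sample_tree,
    simulate_cohort,
)

__all__ = [
    "enumerate_blocks",
    "distance_oracle_agreement",
    "parsimony_oracle_agreement",
    "event_recovery",
    "hgt_tree_contrast",
    "gc_screen",
    "nj_additive_recovery",
]


def enumerate_blocks(families: str = "abc", max_copies: int = 2, max_segments: int = 2):
    """Every block over the given families within the copy/segment limits."""
    blocks = set()
    for counts in itertools.product(range(max_copies + 1), repeat=len(families)):
        genes = [f for f, c in zip(families, counts) for _ in range(c)]
        n = len(genes)
        if n == 0:
            blocks.add(())
            continue
        blocks.add((tuple(sorted(genes)),))
        if n >= 2 and max_segments >= 2:
            for mask in range(1, 2**n - 1):
                left = tuple(sorted(genes[i] for i in range(n) if mask & (1 << i)))
                right = tuple(
                    sorted(genes[i] for i in range(n) if not mask & (1 << i))
                )
                blocks.add(tuple(sorted([left, right])))
    return sorted(blocks)


def _random_block(rng: random.Random, families: str, max_copies: int,
                  max_segments: int):
    picked = rng.sample(families, rng.randint(0, len(families)))
    genes = []
    for fam in picked:
        genes += [fam] * rng.randint(1, max_copies)
    rng.shuffle(genes)
    if not genes:
        return ()
    k = rng.randint(1, min(max_segments, len(genes)))
    cuts = sorted(rng.sample(range(1, len(genes)), k - 1)) if k > 1 else []
    segs, prev = [], 0
    for cut in cuts + [len(genes)]:
        segs.append(tuple(genes[prev:cut]))
        prev = cut
    return tuple(segs)


def distance_oracle_agreement(seed: int = 0, n_random: int = 500) -> dict:
    """event_distance vs oracle_distance: full 3-family enumeration plus
    random pairs within oracle limits.  Returns counts and the agreement
    fraction (1.0 expected)."""
    blocks = enumerate_blocks("abc", 2, 2)
    pairs = agree = 0
    for a in blocks:
        for b in blocks:
            pairs += 1
            agree += event_distance(a, b) == oracle_distance(a, b)
    rng = random.Random(seed)
    for _ in range(n_random):
        a = _random_block(rng, "abcdef", 3, 4)
        b = _random_block(rng, "abcdef", 3, 4)
        pairs += 1
        agree += event_distance(a, b) == oracle_distance(a, b)
    return {"pairs": pairs, "agree": agree, "fraction": agree / pairs}


_ORACLE_NEWICKS = [
    "((L1:1,L2:1):1,(L3:1,L4:1):1);",
    "(((L1:1,L2:1):1,L3:1):1,(L4:1,L5:1):1);",
    "((L1:1,(L2:1,L3:1):1):1,((L4:1,L5:1):1,L6:1):1);",
]


def parsimony_oracle_agreement(seed: int = 0, n_instances: int = 50) -> dict:
    """reconstruct().total_events vs oracle_reconstruct on random instances
    (<= 6 leaves, <= 4 families, <= 2 copies, <= 2 sub-blocks)."""
    rng = random.Random(seed)
    agree = 0
    for i in range(n_instances):
        tree = dendropy.Tree.get(data=_ORACLE_NEWICKS[i % 3], schema="newick")
        tree.is_rooted = True
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        leaf_blocks = {l: _random_block(rng, "abcd", 2, 2) for l in leaves}
        as_strings = {
            l: "|".join("".join(seg) for seg in b) for l, b in leaf_blocks.items()
        }
        agree += (
            reconstruct(tree, as_strings).total_events
            == oracle_reconstruct(tree, as_strings)
        )
    return {"instances": n_instances, "agree": agree, "fraction": agree / n_instances}


# event rates tuned to an expectation of ~2-3 events on an 8-leaf Yule tree
_RECOVERY_RATES = dict(
    rate_deletion=0.015,
    rate_duplication=0.005,
    rate_split=0.01,
    rate_gain=0.005,
    rate_hgt=0.0,
    rate_pseudogenize=0.005,
)


def event_recovery(seed: int = 0, n_sims: int = 100, n_leaves: int = 8) -> pd.DataFrame:
    """Reconstructed vs logged event counts on HGT-free simulations."""
    rows = []
    for i in range(n_sims):
        sim_seed = seed + i
        cfg = SimulationConfig(n_leaves=n_leaves, seed=sim_seed, **_RECOVERY_RATES)
        tree = sample_tree(n_leaves, 1.0, sim_seed)
        leaf_blocks, log = evolve_blocks(tree, cfg)
        rec = reconstruct(tree, leaf_blocks)
        rows.append(
            {"seed": sim_seed, "logged": len(log), "reconstructed": rec.total_events}
        )
    return pd.DataFrame(rows)


def _midpoint_rooted(tree: dendropy.Tree) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint()
    tree.is_rooted = True
    return tree


# whole-operon HGT with length-preserving block churn (pseudogenizing loss
# instead of outright deletion keeps every taxon's concatenation buildable)
_HGT_RATES = dict(
    rate_deletion=0.0,
    rate_duplication=0.02,
    rate_split=0.04,
    rate_gain=0.01,
    rate_hgt=0.15,
    rate_pseudogenize=0.06,
)


def hgt_tree_contrast(seed: int = 0, n_sims: int = 50, n_leaves: int = 12) -> pd.DataFrame:
    """Total reconstructed events under the operon-derived NJ tree vs the
    marker (species) NJ tree, on simulations containing whole-operon HGT.

    The operon tree follows the transferred sequences, grouping HGT partners
    that the species tree separates, so reconstructions on it need fewer
    events — the mechanism behind the operon-tree-vs-species-tree contrast.
    """
    rows = []
    for i in range(n_sims):
        cfg = SimulationConfig(n_leaves=n_leaves, seed=seed + i, **_HGT_RATES)
        cohort = hgt_scenario(cfg)
        species_tree = _midpoint_rooted(nj_tree(p_distance(cohort.marker_seqs)))
        concat, _ = concat_operon(
            {
                leaf: {l: seqs[l] for l in CONCAT_ORDER}
                for leaf, seqs in cohort.operon_seqs.items()
            }
        )
        operon_tree = _midpoint_rooted(nj_tree(p_distance(concat)))
        rows.append(
            {
                "seed": seed + i,
                "n_hgt": cohort.event_log.count("hgt"),
                "operon_tree_events": reconstruct(
                    operon_tree, cohort.leaf_blocks
                ).total_events,
                "species_tree_events": reconstruct(
                    species_tree, cohort.leaf_blocks
                ).total_events,
            }
        )
    return pd.DataFrame(rows)


def gc_screen(seed: int = 0, delta_points: float = 8.0) -> dict:
    """Mean operon-vs-flank GC delta under the configured contrast and under
    the null (no compositional difference), averaged over the cohort."""

    def cohort_delta(cfg: SimulationConfig) -> float:
        cohort = simulate_cohort(cfg)
        deltas = []
        for leaf, genome in sorted(cohort.genomes.items()):
            feats = [f for f in genome.features if f.contig_id == "chr1"]
            if not feats:
                continue
            span = (min(f.start for f in feats), max(f.end for f in feats))
            deltas.append(
                region_contrast(
                    genome.contigs["chr1"], span, flank=cfg.flank_length
                ).delta_points
            )
        return float(np.mean(deltas))

    # an intact operon isolates the compositional contrast from block churn
    base = SimulationConfig(
        n_leaves=8,
        seed=seed,
        gc_background=0.60,
        gc_operon=0.60 + delta_points / 100.0,
        rate_deletion=0.0,
        rate_duplication=0.0,
        rate_split=0.0,
        rate_gain=0.0,
        rate_hgt=0.0,
        rate_pseudogenize=0.0,
    )
    null = replace(base, gc_operon=0.60, seed=seed + 1)
    return {
        "hgt_delta_points": cohort_delta(base),
        "null_delta_points": cohort_delta(null),
    }


def nj_additive_recovery(seed: int = 0, n_matrices: int = 100, max_leaves: int = 12) -> dict:
    """NJ on additive matrices: fraction of generating topologies recovered."""
    rng = random.Random(seed)
    recovered = 0
    for i in range(n_matrices):
        n = rng.randint(4, max_leaves)
        true_tree = sample_tree(n, 1.0, seed + 7919 * i)
        pdm = true_tree.phylogenetic_distance_matrix()
        taxa = sorted(true_tree.taxon_namespace, key=lambda t: t.label)
        ids = [t.label for t in taxa]
        mat = [[pdm.patristic_distance(a, b) for b in taxa] for a in taxa]
        est = nj_tree(DistanceMatrix(mat, ids))
        taxset = frozenset(ids)
        recovered += _bipartitions(est, taxset) == _bipartitions(true_tree, taxset)
    return {
        "matrices": n_matrices,
        "recovered": recovered,
        "fraction": recovered / n_matrices,
    }
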