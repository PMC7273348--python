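"""The synthetic gene-block evolution generator and its ground truth."""

import math

import dendropy
import numpy as np
import pytest

from gablocks.blocks import render_block
from gablocks.gc_profile import gc_fraction
from gablocks.simulate import (
    ConfigurationError,
    SimulationConfig,
    default_templates,
    emit_genomes,
    evolve_blocks,
    evolve_sequences,
    expected_deletions,
    hgt_scenario,
    node_depths,
    node_label,
    replay_log,
    sample_tree,
    simulate_cohort,
)


class TestSampleTree:
    def test_two_leaf_tree(self):
        tree = sample_tree(2, 1.0, 7)
        assert len(tree.leaf_nodes()) == 2
        assert tree.length() > 0

    def test_seed_determinism(self):
        a = sample_tree(8, 1.0, 7).as_string(schema="newick")
        b = sample_tree(8, 1.0, 7).as_string(schema="newick")
        assert a == b

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            sample_tree(1, 1.0, 0)

    def test_leaf_depths_match_path_walk_oracle(self):
        tree = sample_tree(8, 1.0, 7)
        depths = node_depths(tree)

        def walk(leaf):
            total, node = 0.0, leaf
            while node.parent_node is not None:
                total += node.edge.length
                node = node.parent_node
            return total

        for leaf in tree.leaf_node_iter():
            assert depths[node_label(leaf)] == pytest.approx(walk(leaf))


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(rate_deletion=-0.1)

    def test_gc_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(gc_operon=1.2)

    def test_gap_regimes_must_straddle_threshold(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(intra_block_gap=(50, 600))
        with pytest.raises(ConfigurationError):
            SimulationConfig(split_gap=(400, 900))


class TestEvolveBlocks:
    def test_null_process_copies_root_everywhere(self):
        tree = sample_tree(6, 1.0, 3)
        cfg = SimulationConfig(
            n_leaves=6, seed=3, rate_deletion=0, rate_duplication=0,
            rate_split=0, rate_gain=0, rate_hgt=0, rate_pseudogenize=0,
        )
        leaf_blocks, log = evolve_blocks(tree, cfg)
        assert len(log) == 0
        assert all(render_block(b) == cfg.root_block for b in leaf_blocks.values())

    def test_deletion_only_regime(self):
        tree = sample_tree(8, 1.0, 5)
        cfg = SimulationConfig(
            n_leaves=8, seed=5, rate_deletion=0.5, rate_duplication=0,
            rate_split=0, rate_gain=0, rate_hgt=0, rate_pseudogenize=0,
        )
        leaf_blocks, log = evolve_blocks(tree, cfg)
        assert log.count() > 0
        assert all(r.etype == "deletion" for r in log.records)
        root_fams = set(cfg.root_block)
        assert any(
            root_fams - {g.label for g in b.genes} for b in leaf_blocks.values()
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_replay_reproduces_leaf_blocks(self, seed):
        tree = sample_tree(6, 1.0, seed)
        cfg = SimulationConfig(
            n_leaves=6, seed=seed, rate_deletion=0.1, rate_duplication=0.05,
            rate_split=0.08, rate_gain=0.04, rate_hgt=0.1, rate_pseudogenize=0.05,
        )
        leaf_blocks, log = evolve_blocks(tree, cfg)
        replayed = replay_log(tree, cfg.root_block, log)
        for leaf, block in leaf_blocks.items():
            assert render_block(replayed[leaf]) == render_block(block)
            assert [g.status for g in replayed[leaf].genes] == [
                g.status for g in block.genes
            ]

    def test_seed_determinism(self):
        tree = sample_tree(6, 1.0, 9)
        cfg = SimulationConfig(n_leaves=6, seed=9, rate_hgt=0.1)
        a_blocks, a_log = evolve_blocks(tree, cfg)
        b_blocks, b_log = evolve_blocks(tree, cfg)
        assert {k: render_block(v) for k, v in a_blocks.items()} == {
            k: render_block(v) for k, v in b_blocks.items()
        }
        assert a_log.records == b_log.records


def test_deletion_rate_recovery_against_exact_expectation():
    """Mean logged deletions over many seeds matches the exact expectation of
    the thinning process (per-branch survival recursion), within 3 SE."""
    tree = sample_tree(8, 1.0, 123)
    rate = 0.3
    expectation = expected_deletions(tree, rate, 10)
    counts = []
    for seed in range(500):
        cfg = SimulationConfig(
            n_leaves=8, seed=seed, rate_deletion=rate, rate_duplication=0,
            rate_split=0, rate_gain=0, rate_hgt=0, rate_pseudogenize=0,
        )
        _, log = evolve_blocks(tree, cfg)
        counts.append(log.count("deletion"))
    mean = np.mean(counts)
    se = np.std(counts, ddof=1) / math.sqrt(len(counts))
    assert abs(mean - expectation) <= 3 * se


class TestSequencesAndGenomes:
    def test_zero_substitution_rate_keeps_templates(self):
        tree = sample_tree(4, 1.0, 2)
        templates = {"x": "ACGT" * 50}
        leaf_seqs = evolve_sequences(tree, templates, 0.0, 0.5, seed=1)
        assert all(s["x"] == templates["x"] for s in leaf_seqs.values())

    def test_gc_control_on_long_segments(self):
        cfg = SimulationConfig(n_leaves=2, seed=8, gc_background=0.60, gc_operon=0.68)
        cohort = simulate_cohort(cfg)
        genome = cohort.genomes["T01"]
        contig = genome.contigs["chr1"]
        flank = contig[: cfg.flank_length]
        assert abs(gc_fraction(flank) - 0.60) <= 0.02
        operon_genes = "".join(
            genome.feature_sequence(f)
            for f in genome.features
            if f.contig_id == "chr1"
        )
        assert len(operon_genes) >= 10_000
        assert abs(gc_fraction(operon_genes) - 0.68) <= 0.02

    def test_gc_delta_matches_configuration_by_base_counting(self):
        cfg = SimulationConfig(n_leaves=2, seed=8, gc_background=0.60, gc_operon=0.68)
        cohort = simulate_cohort(cfg)
        genome = cohort.genomes["T01"]
        contig = genome.contigs["chr1"]
        genes = [f for f in genome.features if f.contig_id == "chr1"]
        gene_seq = "".join(genome.feature_sequence(f) for f in genes)
        flanks = contig[: cfg.flank_length] + contig[-cfg.flank_length :]
        delta = gc_fraction(gene_seq) - gc_fraction(flanks)
        assert abs(delta - 0.08) <= 0.02

    def test_pseudogenized_gene_is_truncated_below_sixty_percent(self):
        for seed in range(40):
            cfg = SimulationConfig(
                n_leaves=4, seed=seed, rate_pseudogenize=0.5, rate_deletion=0,
                rate_duplication=0, rate_split=0, rate_gain=0, rate_hgt=0,
            )
            cohort = simulate_cohort(cfg)
            if cohort.event_log.count("pseudogenize") == 0:
                continue
            found = False
            for leaf, block in cohort.leaf_blocks.items():
                genome = cohort.genomes[leaf]
                feats = {f.family_hint: f for f in genome.features}
                for gene in block.genes:
                    if gene.status == "pseudo":
                        feat = feats[gene.label]
                        template_len = len(cohort.templates[gene.label])
                        assert feat.length < 0.60 * template_len
                        found = True
            if found:
                return
        pytest.fail("no pseudogenization event produced in 40 seeds")

    def test_missing_template_is_a_configuration_error(self):
        cfg = SimulationConfig(n_leaves=2, seed=1)
        tree = sample_tree(2, 1.0, 1)
        leaf_blocks, _ = evolve_blocks(tree, cfg)
        with pytest.raises(ConfigurationError):
            emit_genomes(leaf_blocks, cfg, {"a": "ACGT"})

    def test_intra_and_split_gaps_straddle_the_neighbor_threshold(self):
        cfg = SimulationConfig(
            n_leaves=2, seed=13, rate_split=0.4, rate_deletion=0,
            rate_duplication=0, rate_gain=0, rate_hgt=0, rate_pseudogenize=0,
        )
        cohort = simulate_cohort(cfg)
        for leaf, block in cohort.leaf_blocks.items():
            genome = cohort.genomes[leaf]
            feats = [f for f in genome.features if f.contig_id == "chr1"]
            boundaries = []
            k = 0
            for seg in block.segments:
                boundaries.append(len(seg))
            gaps = [
                feats[i + 1].start - feats[i].end for i in range(len(feats) - 1)
            ]
            # walk segments: gaps inside a segment <= 500, between segments > 500
            idx = 0
            for s_i, seg in enumerate(block.segments):
                for g_i in range(len(seg) - 1):
                    assert gaps[idx] <= 500
                    idx += 1
                if s_i < len(block.segments) - 1:
                    assert gaps[idx] > 500
                    idx += 1


def test_hgt_scenario_contains_a_transfer_and_is_deterministic():
    cfg = SimulationConfig(n_leaves=8, seed=2, rate_hgt=0.3)
    a = hgt_scenario(cfg)
    b = hgt_scenario(cfg)
    assert a.event_log.count("hgt") >= 1
    assert [r for r in a.event_log.records] == [r for r in b.event_log.records]


def test_hgt_replaces_recipient_block_with_donor_copy():
    for seed in range(30):
        cfg = SimulationConfig(
            n_leaves=6, seed=seed, rate_hgt=0.5, rate_deletion=0,
            rate_duplication=0, rate_split=0, rate_gain=0, rate_pseudogenize=0,
        )
        tree = sample_tree(6, 1.0, seed)
        leaf_blocks, log = evolve_blocks(tree, cfg)
        if log.count("hgt"):
            # with no other events every block still equals the root block
            assert all(
                render_block(b) == cfg.root_block for b in leaf_blocks.values()
            )
            return
    pytest.fail("no HGT drawn in 30 seeds despite rate 0.5")
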