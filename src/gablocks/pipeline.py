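"""End-to-end orchestration: genomes in, reconstruction report out.

The stages mirror the analysis workflow: ortholog calling (external tabular
hits or the internal aligner) -> pseudogene rule -> block assembly ->
fusion detection -> pairwise event distances -> marker and operon trees ->
maximum-parsimony reconstruction per tree -> optional
phylogenetic-diversity reduction and re-run -> GC contrasts.  Every product
is written as TSV/Newick under the output directory together with a run log
recording the seed and thresholds, and a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import ancestors, blocks, gc_profile, orthology, phylo
from .genome_io import Genome, read_genome, write_tree

__all__ = ["PipelineConfig", "PipelineResult", "run", "run_cohort"]


@dataclass
class PipelineConfig:
    genomes: list[tuple[str, str, str]] = field(default_factory=list)  # (id, fasta, gff3)
    reference_fasta: str | None = None  # family queries, record ids = labels a..k
    hits_tables: dict[str, str] = field(default_factory=dict)  # genome -> outfmt6 TSV
    outgroup: str | None = None
    reference_taxon: str | None = None
    evalue_max: float = orthology.EVALUE_MAX
    neighbor_bp: int = blocks.NEIGHBOR_THRESHOLD
    pseudo_len_frac: float = orthology.PSEUDO_LEN_FRAC
    pseudo_ident: float = orthology.PSEUDO_IDENT_MIN
    fusion_cov: float = orthology.FUSION_COVERAGE
    min_block_genes: int = 2  # orthoblock validity ("no fewer than two")
    min_cohort_genes: int = 3  # strain-inclusion filter ("multiple (>2) clustered")
    flank_bp: int = 10000
    gc_window: int = 500
    bootstrap_n: int = 0
    reduce_k: int | None = None
    seed: int = 0
    outdir: str = "gablocks_out"


@dataclass
class PipelineResult:
    calls: dict[str, list]
    blocks: dict[str, blocks.GeneBlock]
    excluded_genomes: dict[str, str]
    distance_table: pd.DataFrame
    marker_tree: object | None
    operon_tree: object | None
    compare_full: pd.DataFrame | None
    compare_reduced: pd.DataFrame | None
    reduced_taxa: set[str] | None
    reconstructions: dict[str, ancestors.AncestralReconstruction]
    gc_contrasts: pd.DataFrame


def _log(lines: list[str], message: str) -> None:
    lines.append(message)


def _block_table(block_map: dict[str, blocks.GeneBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": gid,
                "block": blocks.render_block(b),
                "flags": b.flags,
                "contig": b.contig_id,
                "n_genes": b.n_genes,
            }
            for gid, b in sorted(block_map.items())
        ]
    )


def _distance_table(block_map: dict[str, blocks.GeneBlock]) -> pd.DataFrame:
    from .events import event_distance

    ids = sorted(block_map)
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ev = event_distance(block_map[a], block_map[b])
            rows.append(
                {
                    "genome_a": a,
                    "genome_b": b,
                    "deletions": ev.deletions,
                    "duplications": ev.duplications,
                    "splits": ev.splits,
                    "total": ev.total,
                }
            )
    return pd.DataFrame(rows)


def analyze_genome(
    genome: Genome,
    families: list[orthology.ReferenceFamily],
    config: PipelineConfig,
    hits: list[orthology.Hit] | None = None,
):
    """Calls + pseudogene rule + blocks + fusions for one genome."""
    if hits is None:
        operon_families = [f for f in families if f.label in orthology.FAMILY_NAMES]
        hits = orthology.search_hits(genome, operon_families)
    calls = orthology.call_orthologs(hits, families, evalue_max=config.evalue_max)
    subject_lengths = {
        f.feature_id: f.length for f in genome.features
    }
    calls = orthology.apply_pseudo_rule(
        calls,
        families,
        subject_lengths,
        len_frac=config.pseudo_len_frac,
        ident_min=config.pseudo_ident,
    )
    genome_blocks = blocks.build_blocks(
        calls,
        genome,
        threshold=config.neighbor_bp,
        min_genes=config.min_block_genes,
    )
    best_block = max(genome_blocks, key=lambda b: b.n_genes, default=None)
    if best_block is not None:
        calls = orthology.detect_fusions(
            calls, hits, best_block, coverage_min=config.fusion_cov
        )
        genome_blocks = blocks.build_blocks(
            calls,
            genome,
            threshold=config.neighbor_bp,
            min_genes=config.min_block_genes,
        )
        best_block = max(genome_blocks, key=lambda b: b.n_genes, default=None)
    return calls, genome_blocks, best_block, hits


def run_cohort(
    genomes: dict[str, Genome],
    reference_seqs: dict[str, str],
    config: PipelineConfig,
    marker_family: str = "marker",
    hits_by_genome: dict[str, list[orthology.Hit]] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory genomes (the synthetic route)."""
    os.makedirs(config.outdir, exist_ok=True)
    log: list[str] = [
        "config: "
        + json.dumps(
            {
                k: str(v)
                for k, v in asdict(config).items()
                if k not in ("genomes", "outdir")
            },
            sort_keys=True,
        )
    ]
    families = orthology.reference_families(
        {k: v for k, v in reference_seqs.items() if k in orthology.FAMILY_NAMES}
    )

    all_calls: dict[str, list] = {}
    block_map: dict[str, blocks.GeneBlock] = {}
    excluded: dict[str, str] = {}
    gene_seqs: dict[str, dict[str, str]] = {}
    marker_seqs: dict[str, str] = {}
    gc_rows: list[dict] = []

    for gid in sorted(genomes):
        genome = genomes[gid]
        hits = hits_by_genome.get(gid) if hits_by_genome else None
        calls, genome_blocks, best_block, hits = analyze_genome(
            genome, families, config, hits
        )
        all_calls[gid] = calls
        marker_feats = [f for f in genome.features if f.family_hint == marker_family]
        if marker_feats:
            marker_seqs[gid] = genome.feature_sequence(marker_feats[0])
        if best_block is None or best_block.n_genes < config.min_cohort_genes:
            excluded[gid] = (
                f"fewer than {config.min_cohort_genes} clustered operon genes"
            )
            _log(log, f"{gid}: excluded ({excluded[gid]})")
            continue
        block_map[gid] = best_block

        # per-family sequences for tree building (fusions split at the hit span)
        seqs: dict[str, str] = {}
        call_by_feat = {c.subject_feature_id: c for c in calls}
        for feat in genome.features:
            call = call_by_feat.get(feat.feature_id)
            if call is None or call.status == "pseudo":
                continue
            seq = genome.feature_sequence(feat)
            if call.status == "fusion":
                d_hits = [h for h in call.evidence if h.query_label == "d"]
                if d_hits:
                    span = (d_hits[0].subject_start, d_hits[0].subject_end)
                    try:
                        seqs.update(
                            phylo.split_fusion_slots(seq, call.labels, span)
                        )
                    except ValueError as exc:
                        _log(log, f"{gid}: fusion split failed ({exc})")
            else:
                seqs.setdefault(call.labels[0], seq)
        gene_seqs[gid] = seqs

        # GC screen on the block's contig
        contig = genome.contigs[best_block.contig_id]
        feats = [
            genome.feature_by_id(fid)
            for seg in best_block.feature_ids
            for fid in seg
        ]
        span = (min(f.start for f in feats), max(f.end for f in feats))
        contrast = gc_profile.region_contrast(contig, span, flank=config.flank_bp)
        gc_rows.append({"genome_id": gid, **contrast.to_dict()})

    dist = _distance_table(block_map)

    # trees: marker (species) and concatenated operon
    marker_tree = operon_tree = None
    compare_full = compare_reduced = None
    reduced = None
    reconstructions: dict[str, ancestors.AncestralReconstruction] = {}
    tree_taxa = sorted(set(block_map) & set(marker_seqs))
    concat, concat_excluded = phylo.concat_operon(
        {gid: gene_seqs[gid] for gid in tree_taxa}
    )
    for gid, missing in concat_excluded.items():
        _log(log, f"{gid}: excluded from operon tree (missing {','.join(missing)})")
    # naive concatenation assumes equal-length (aligned or indel-free) genes;
    # genomes deviating from the majority length (e.g. truncated genes that
    # escaped the pseudogene rule) are excluded rather than mis-scored
    if concat:
        lengths = pd.Series({gid: len(s) for gid, s in concat.items()})
        modal = lengths.mode().iloc[0]
        for gid in sorted(lengths.index[lengths != modal]):
            _log(log, f"{gid}: excluded from operon tree (length {lengths[gid]} != {modal})")
            del concat[gid]
    shared_taxa = sorted(set(concat))
    if config.outgroup and len(shared_taxa) >= 4 and config.outgroup in shared_taxa:
        marker_aln = {gid: marker_seqs[gid] for gid in shared_taxa}
        operon_aln = {gid: concat[gid] for gid in shared_taxa}
        if config.bootstrap_n > 0:
            marker_tree = phylo.bootstrap_support(
                marker_aln, config.bootstrap_n, seed=config.seed
            )
            operon_tree = phylo.bootstrap_support(
                operon_aln, config.bootstrap_n, seed=config.seed + 1
            )
        else:
            marker_tree = phylo.nj_tree(phylo.p_distance(marker_aln))
            operon_tree = phylo.nj_tree(phylo.p_distance(operon_aln))
        marker_rooted = phylo.root_with_outgroup(marker_tree, config.outgroup)
        operon_rooted = phylo.root_with_outgroup(operon_tree, config.outgroup)
        leaf_blocks = {gid: block_map[gid] for gid in shared_taxa}
        reconstructions["species"] = ancestors.reconstruct(marker_rooted, leaf_blocks)
        reconstructions["operon"] = ancestors.reconstruct(operon_rooted, leaf_blocks)
        compare_full = ancestors.compare_trees(
            leaf_blocks, {"species": marker_rooted, "operon": operon_rooted}
        )
        if config.reduce_k and 2 <= config.reduce_k < len(shared_taxa):
            keep = tuple(
                t
                for t in (config.reference_taxon, config.outgroup)
                if t in shared_taxa
            )
            reduced = phylo.pd_reduce(marker_rooted, config.reduce_k, keep=keep)
            sub_blocks = {gid: block_map[gid] for gid in reduced}
            sub_marker = _induced_subtree(marker_rooted, reduced)
            sub_operon = _induced_subtree(operon_rooted, reduced)
            compare_reduced = ancestors.compare_trees(
                sub_blocks, {"species": sub_marker, "operon": sub_operon}
            )
    elif config.outgroup:
        _log(log, "tree stage skipped: outgroup missing or too few shared taxa")

    gc_table = pd.DataFrame(gc_rows)
    _write_outputs(
        config,
        log,
        all_calls,
        block_map,
        dist,
        marker_tree,
        operon_tree,
        compare_full,
        compare_reduced,
        reduced,
        reconstructions,
        gc_table,
    )
    return PipelineResult(
        calls=all_calls,
        blocks=block_map,
        excluded_genomes=excluded,
        distance_table=dist,
        marker_tree=marker_tree,
        operon_tree=operon_tree,
        compare_full=compare_full,
        compare_reduced=compare_reduced,
        reduced_taxa=reduced,
        reconstructions=reconstructions,
        gc_contrasts=gc_table,
    )


def _induced_subtree(tree, taxa: set[str]):
    sub = tree.clone(depth=1)
    sub.retain_taxa_with_labels(sorted(taxa))
    sub.is_rooted = True
    # retain_taxa can leave a unifurcating root; collapse it
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        sub.seed_node = child
        child.parent_node = None
    return sub


def _write_outputs(
    config,
    log,
    all_calls,
    block_map,
    dist,
    marker_tree,
    operon_tree,
    compare_full,
    compare_reduced,
    reduced,
    reconstructions,
    gc_table,
):
    out = config.outdir
    _block_table(block_map).to_csv(os.path.join(out, "blocks.tsv"), sep="\t", index=False)
    call_rows = [
        {
            "genome_id": gid,
            "feature_id": c.subject_feature_id,
            "labels": "".join(c.labels),
            "status": c.status,
        }
        for gid, calls in sorted(all_calls.items())
        for c in calls
    ]
    pd.DataFrame(call_rows).to_csv(os.path.join(out, "calls.tsv"), sep="\t", index=False)
    dist.to_csv(os.path.join(out, "event_distances.tsv"), sep="\t", index=False)
    if marker_tree is not None:
        write_tree(marker_tree, os.path.join(out, "species_tree.nwk"))
        write_tree(operon_tree, os.path.join(out, "operon_tree.nwk"))
    if compare_full is not None:
        compare_full.to_csv(os.path.join(out, "compare_trees.tsv"), sep="\t", index=False)
    if compare_reduced is not None:
        compare_reduced.to_csv(
            os.path.join(out, "compare_trees_reduced.tsv"), sep="\t", index=False
        )
    if reduced is not None:
        with open(os.path.join(out, "reduced_taxa.txt"), "w") as fh:
            fh.write("\n".join(sorted(reduced)) + "\n")
    for name, rec in reconstructions.items():
        rec.to_table().to_csv(
            os.path.join(out, f"reconstruction_{name}.tsv"), sep="\t", index=False
        )
        with open(os.path.join(out, f"reconstruction_{name}.nwk"), "w") as fh:
            fh.write(rec.annotated_newick() + "\n")
    if len(gc_table):
        gc_table.to_csv(os.path.join(out, "gc_contrasts.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")


def run(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read genomes and reference, then run."""
    from Bio import SeqIO

    if not config.genomes:
        raise ValueError("no genomes configured")
    if not config.reference_fasta:
        raise ValueError("reference_fasta is required")
    genomes = {
        gid: read_genome(fasta, gff, genome_id=gid)
        for gid, fasta, gff in config.genomes
    }
    reference = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(config.reference_fasta, "fasta")
    }
    hits_by_genome = None
    if config.hits_tables:
        hits_by_genome = {
            gid: orthology.read_hits_table(path)
            for gid, path in config.hits_tables.items()
        }
    return run_cohort(genomes, reference, config, hits_by_genome=hits_by_genome)
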