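"""Orthologous gene blocks: the neighbor rule and the block string notation.

Two genes are neighbors when they sit on the same contig and strand and are
separated by at most ``neighbor_threshold`` (default 500) bp of intergenic
distance.  A gene block ("orthoblock") is a chain of at least two such
neighbors whose genes are homologous to the reference operon; sub-blocks more
than the threshold apart on the same contig are joined in the string notation
with the ``|`` separator (``bcdefghi|j``).

Block strings use one lowercase letter per gene family (``a``=cyp115 ...
``k``=ggps2); suffix flags mark full-length cyp115 (``*``), a cyp115
pseudogene/fragment (``!``) and the presence of ggps2 (``?``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_io import GeneFeature, Genome

__all__ = [
    "Gene",
    "GeneBlock",
    "BlockParseError",
    "are_neighbors",
    "build_blocks",
    "render_block",
    "parse_block",
    "NEIGHBOR_THRESHOLD",
]

NEIGHBOR_THRESHOLD = 500  # bp, inclusive ("500 nucleotides or fewer")

_BLOCK_RE = re.compile(r"^[a-k]+(\|[a-k]+)*$")


class BlockParseError(ValueError):
    pass


@dataclass(frozen=True)
class Gene:
    """One gene occurrence inside a block: family label plus functional status."""

    label: str
    status: str = "full"  # full | pseudo

    def __post_init__(self) -> None:
        if self.status not in ("full", "pseudo"):
            raise ValueError(f"bad gene status {self.status!r}")


@dataclass
class GeneBlock:
    """An ordered, split-aware string of gene-family labels for one genome."""

    genome_id: str = ""
    segments: list[list[Gene]] = field(default_factory=list)
    contig_id: str | None = None
    feature_ids: list[list[str]] = field(default_factory=list)

    @property
    def genes(self) -> list[Gene]:
        return [g for seg in self.segments for g in seg]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def flags(self) -> str:
        """Suffix flags: ``*`` full cyp115, ``!`` pseudo cyp115, ``?`` ggps2."""
        out = ""
        if any(g.label == "a" and g.status == "full" for g in self.genes):
            out += "*"
        if any(g.label == "a" and g.status == "pseudo" for g in self.genes):
            out += "!"
        if any(g.label == "k" for g in self.genes):
            out += "?"
        return out

    def is_orthoblock(self, min_genes: int = 2) -> bool:
        return self.n_genes >= min_genes

    def __str__(self) -> str:  # pragma: no cover - convenience
        return render_block(self)


def intergenic_gap(f1: GeneFeature, f2: GeneFeature) -> int:
    """Intergenic distance in bp between two features (0 when they overlap)."""
    if f1.contig_id != f2.contig_id:
        raise ValueError("gap undefined across contigs")
    lo, hi = (f1, f2) if f1.start <= f2.start else (f2, f1)
    return max(0, hi.start - lo.end)


def are_neighbors(
    f1: GeneFeature, f2: GeneFeature, threshold: int = NEIGHBOR_THRESHOLD
) -> bool:
    """True iff the two features are neighboring genes.

    Same contig, same strand, and an intergenic gap of at most ``threshold``
    bp (inclusive boundary).  Overlapping features have gap 0.
    """
    if f1.contig_id != f2.contig_id or f1.strand != f2.strand:
        return False
    return intergenic_gap(f1, f2) <= threshold


def build_blocks(
    calls,
    genome: Genome,
    threshold: int = NEIGHBOR_THRESHOLD,
    min_genes: int = 2,
    join_subblocks: bool = True,
) -> list[GeneBlock]:
    """Assemble gene blocks from ortholog calls on one genome.

    Features carrying calls are chained into sub-blocks by the neighbor rule;
    sub-blocks on the same contig are joined into a single block with ``|``
    separators (``join_subblocks=True``, the default) or reported as separate
    blocks.  Blocks with fewer than ``min_genes`` genes in total are dropped
    ("no fewer than two neighboring open reading frames").

    ``calls`` is an iterable of objects with ``subject_feature_id``,
    ``labels`` (tuple of one or two family labels) and ``status``
    (full/pseudo/fusion); see :mod:`gablocks.orthology`.
    """
    call_by_feature = {}
    for c in sorted(calls, key=lambda c: c.subject_feature_id):
        call_by_feature[c.subject_feature_id] = c
    called = [f for f in genome.features if f.feature_id in call_by_feature]
    called.sort(key=lambda f: (f.contig_id, f.start, f.end))

    def genes_of(feature: GeneFeature) -> list[Gene]:
        call = call_by_feature[feature.feature_id]
        status = "pseudo" if call.status == "pseudo" else "full"
        return [Gene(lbl, status) for lbl in call.labels]

    per_contig: dict[str, list[list[GeneFeature]]] = {}
    for feat in called:
        subs = per_contig.setdefault(feat.contig_id, [])
        if subs and are_neighbors(subs[-1][-1], feat, threshold):
            subs[-1].append(feat)
        else:
            subs.append([feat])

    out: list[GeneBlock] = []
    for contig_id in sorted(per_contig):
        subs = per_contig[contig_id]
        if join_subblocks:
            groups = [subs]
        else:
            groups = [[s] for s in subs]
        for group in groups:
            block = GeneBlock(
                genome_id=genome.genome_id,
                contig_id=contig_id,
                segments=[
                    [g for feat in sub for g in genes_of(feat)] for sub in group
                ],
                feature_ids=[[feat.feature_id for feat in sub] for sub in group],
            )
            if block.is_orthoblock(min_genes):
                out.append(block)
    return out


def render_block(block: GeneBlock, include_pseudo: bool = True) -> str:
    """Render the block string (``bcdefghi|j`` style).

    Pseudogenes are included by default; the per-block flags property carries
    their functional annotation.
    """
    parts = []
    for seg in block.segments:
        labels = "".join(
            g.label for g in seg if include_pseudo or g.status == "full"
        )
        if labels:
            parts.append(labels)
    return "|".join(parts)


def parse_block(text: str, genome_id: str = "") -> GeneBlock:
    """Parse a block string into a :class:`GeneBlock` (all genes full status)."""
    if not _BLOCK_RE.match(text):
        raise BlockParseError(f"invalid block string {text!r}")
    return GeneBlock(
        genome_id=genome_id,
        segments=[[Gene(ch) for ch in part] for part in text.split("|")],
    )
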