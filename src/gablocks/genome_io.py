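"""Reading and writing the standard formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals; GFF3 and
GenBank use 1-based inclusive coordinates, and the conversion happens exactly
once, at parse/write time.  Downstream gap arithmetic (the 500-bp neighbor
rule) relies on this single conversion site.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "Genome",
    "FormatError",
    "read_genome",
    "read_genbank",
    "write_genome",
    "read_tree",
    "write_tree",
    "read_alignment",
    "write_alignment",
]


class FormatError(ValueError):
    """A file violated its format contract (coordinates, strand, ragged rows...)."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated ORF: the unit of gene-block assembly.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``'+'`` or ``'-'``.
    ``family_hint`` optionally carries the annotated gene-family label (used by
    the synthetic route; the real route assigns families by homology search).
    """

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    feature_id: str
    family_hint: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.feature_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A genome: contig sequences plus an ordered list of features."""

    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    features: list[GeneFeature] = field(default_factory=list)

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.end))

    def feature_by_id(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Strand-aware nucleotide sequence of a feature."""
        seq = self.contigs[feat.contig_id][feat.start : feat.end]
        if feat.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def _validate_feature(genome: Genome, feat: GeneFeature) -> None:
    if feat.contig_id not in genome.contigs:
        raise FormatError(
            f"feature {feat.feature_id} on unknown contig {feat.contig_id!r}"
        )
    if feat.end > len(genome.contigs[feat.contig_id]):
        raise FormatError(
            f"feature {feat.feature_id} extends beyond contig {feat.contig_id} "
            f"({feat.end} > {len(genome.contigs[feat.contig_id])})"
        )


def read_genome(
    fasta_path: str,
    gff3_path: str,
    genome_id: str | None = None,
    feature_types: tuple[str, ...] = ("gene", "CDS", "pseudogene"),
) -> Genome:
    """Read a genome from a nucleotide FASTA plus a GFF3 annotation.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Features are sorted by (contig, start).  A feature on a contig absent from
    the FASTA, or extending beyond its contig, raises :class:`FormatError`.
    """
    import gffutils

    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(fasta_path))[0]
    genome = Genome(genome_id=genome_id)
    for rec in SeqIO.parse(fasta_path, "fasta"):
        genome.contigs[rec.id] = str(rec.seq)
    if not genome.contigs:
        raise FormatError(f"no FASTA records in {fasta_path}")

    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    seen_ids: set[str] = set()
    for ftype in feature_types:
        for gf in db.features_of_type(ftype):
            fid = gf.id
            if fid in seen_ids:
                continue
            seen_ids.add(fid)
            if gf.strand not in ("+", "-"):
                raise FormatError(f"feature {fid}: unknown strand {gf.strand!r}")
            family = gf.attributes.get("family", [None])[0]
            feat = GeneFeature(
                genome_id=genome_id,
                contig_id=gf.seqid,
                start=gf.start - 1,  # 1-based inclusive -> 0-based half-open
                end=gf.end,
                strand=gf.strand,
                feature_id=fid,
                family_hint=family,
            )
            _validate_feature(genome, feat)
            genome.features.append(feat)
    genome.sort_features()
    genome.features = [
        replace(f, sequence=genome.feature_sequence(f)) for f in genome.features
    ]
    return genome


def read_genbank(genbank_path: str, genome_id: str | None = None) -> Genome:
    """Read a GenBank flat file (sequence + CDS/gene features)."""
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(genbank_path))[0]
    genome = Genome(genome_id=genome_id)
    n = 0
    for rec in SeqIO.parse(genbank_path, "genbank"):
        genome.contigs[rec.id] = str(rec.seq)
        for bf in rec.features:
            if bf.type not in ("gene", "CDS"):
                continue
            n += 1
            fid = bf.qualifiers.get("locus_tag", [f"feat{n}"])[0]
            strand = "+" if (bf.location.strand or 1) >= 0 else "-"
            feat = GeneFeature(
                genome_id=genome_id,
                contig_id=rec.id,
                start=int(bf.location.start),  # Biopython is already 0-based
                end=int(bf.location.end),
                strand=strand,
                feature_id=fid,
            )
            _validate_feature(genome, feat)
            genome.features.append(feat)
    if not genome.contigs:
        raise FormatError(f"no GenBank records in {genbank_path}")
    genome.sort_features()
    return genome


def write_genome(genome: Genome, fasta_path: str, gff3_path: str) -> None:
    """Write a genome as FASTA + GFF3 (converting back to 1-based inclusive)."""
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs.items()
    ]
    SeqIO.write(records, fasta_path, "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in genome.contigs.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for f in sorted(genome.features, key=lambda f: (f.contig_id, f.start)):
            attrs = f"ID={f.feature_id}"
            if f.family_hint:
                attrs += f";family={f.family_hint}"
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "gablocks",
                        "gene",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_tree(source: str) -> dendropy.Tree:
    """Read a Newick tree from a path or a Newick string."""
    try:
        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:  # dendropy raises its own parse error hierarchy
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    return tree


def write_tree(tree: dendropy.Tree, path: str | None = None) -> str:
    """Emit Newick text (and write to ``path`` if given)."""
    text = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_alignment(source: str) -> dict[str, str]:
    """Read an aligned FASTA into an ordered ``{id: row}`` mapping.

    Ragged rows (records of unequal length) raise :class:`FormatError`.
    """
    try:
        if os.path.exists(source):
            aln = AlignIO.read(source, "fasta")
        else:
            with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
                fh.write(source)
                tmp = fh.name
            try:
                aln = AlignIO.read(tmp, "fasta")
            finally:
                os.unlink(tmp)
    except ValueError as exc:
        raise FormatError(f"bad alignment: {exc}") from exc
    return {rec.id: str(rec.seq) for rec in aln}


def write_alignment(alignment: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in alignment.items()]
    SeqIO.write(records, path, "fasta")
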