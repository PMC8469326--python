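"""Shared domain types and readers/writers for the standard formats.

External files keep the native conventions of their formats (GFF3 is
1-based inclusive); all internal interval arithmetic is 0-based
half-open, converted at the boundary.  Writers emit UTF-8 with Unix
line endings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
DNA_ALPHABET = set("ACGTN")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """An identified biological sequence (protein or nucleotide).

    ``aligned=True`` permits gap characters; protein records may not
    contain gaps otherwise.
    """

    id: str
    residues: str
    moltype: str = "protein"  # {"protein", "dna"}
    description: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if self.moltype not in ("protein", "dna"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        allowed = alphabet | {GAP} if self.aligned else alphabet
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise FormatError(
                    f"illegal character {ch!r} at position {pos} in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            moltype=self.moltype,
            description=self.description,
            aligned=False,
        )


@dataclass
class GeneModel:
    """A gene's chromosomal placement and exon structure.

    Coordinates are 1-based inclusive as in GFF3; exon lengths are
    therefore ``end - start + 1``.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) reversed")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene span "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons at ({s},{e})")
            prev_end = e
        if self.cds_length and self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise FormatError(f"aligned records have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, moltype: str = "protein", aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving input order.

    Raises FormatError on an empty file, duplicate ids, or characters
    outside the declared alphabet (the error names the position).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                moltype=moltype,
                description=desc,
                aligned=aligned,
            )
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_alignment(path, moltype: str = "protein") -> Alignment:
    """Read an aligned FASTA file."""
    return Alignment(read_fasta(path, moltype=moltype, aligned=True))


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    One GeneModel per gene feature; exons come from the gene's primary
    transcript (the one with the longest total CDS; exon features are
    used when no CDS is annotated).  Input need not be positionally
    sorted.  An exon outside its gene's span is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        best_exons: list[tuple[int, int]] = []
        best_cds = -1
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        if not transcripts:
            transcripts = [gene]
        for tx in transcripts:
            cds_parts = list(db.children(tx, featuretype="CDS"))
            cds_len = sum(c.end - c.start + 1 for c in cds_parts)
            exons = [(e.start, e.end) for e in db.children(tx, featuretype="exon")]
            if not exons:
                exons = [(c.start, c.end) for c in cds_parts]
            if cds_len > best_cds:
                best_cds = cds_len
                best_exons = sorted(exons)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                start=gene.start,
                end=gene.end,
                exons=best_exons,
                cds_length=max(best_cds, 0),
            )
        )
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon features)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.chromosome}\tiqfam\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            tx_id = f"{m.gene_id}.1"
            fh.write(
                f"{m.chromosome}\tiqfam\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tx_id};Parent={m.gene_id}\n"
            )
            for s, e in m.exons or [(m.start, m.end)]:
                fh.write(
                    f"{m.chromosome}\tiqfam\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={tx_id}\n"
                )


# ---------------------------------------------------------------------------
# Newick (dendropy-backed)

def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree as Newick with branch lengths and integer support
    values as internal-node labels.  Labels with metacharacters are
    quoted by the serializer."""
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(tree_to_newick(tree))
        fh.write("\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    sio = io.StringIO()
    tree.write(
        file=sio,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
    )
    return sio.getvalue().strip()


def read_newick(path_or_string, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Read a Newick tree from a path or literal string."""
    src = str(path_or_string)
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, **kwargs)
    return dendropy.Tree.get(path=src, **kwargs)
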