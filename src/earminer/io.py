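"""Readers and writers for the external formats the toolkit touches.

Coordinate conventions are strict: GFF3 is 1-based closed and converted at
this boundary; everything interval-shaped inside the package (BED intervals,
promoter arithmetic, peak overlap) is 0-based half-open.  Gene models keep
their native 1-based closed coordinates because downstream code anchors on
the TSS, a single 1-based position.

All readers validate rather than coerce: malformed coordinates, duplicate
identifiers and uncompilable motif patterns raise :class:`FormatError`
naming the offending record and, for line-oriented formats, the line number.
Gzip-compressed inputs (``*.gz``) are accepted transparently everywhere.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Seq import Seq as _BioSeq

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GeneModel",
    "GenomicInterval",
    "GeneSet",
    "GeneSetCollection",
    "CisMotif",
    "read_fasta",
    "write_fasta",
    "read_gff_genes",
    "read_bed",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_motif_table",
    "read_expression_matrix",
]

# 20 standard residues plus the degenerate codes we tolerate.  U
# (selenocysteine) is accepted and treated as "any" downstream.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AA = set(AMINO_ACIDS) | set("XBZU")
NUCLEOTIDES = set("ACGTN")


class FormatError(ValueError):
    """A file violated its format contract (bad coordinates, duplicate ids ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: a protein, transcript, contig or promoter."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """A gene with 1-based closed coordinates and a strand-aware TSS."""

    gene_id: str
    seq_id: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site, 1-based: start on +, end on -."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GenomicInterval:
    """A BED-style interval, 0-based half-open, e.g. an epigenetic mark peak."""

    seq_id: str
    start: int
    end: int
    name: str = ""
    mark: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"interval {self.name or self.seq_id}: require 0 <= start < end, "
                f"got [{self.start},{self.end})"
            )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class CisMotif:
    """A promoter cis-element given as a nucleotide regular expression."""

    name: str
    pattern: str

    def compiled(self) -> re.Pattern:
        try:
            return re.compile(self.pattern)
        except re.error as exc:  # pragma: no cover - exercised via read_motif_table
            raise FormatError(f"motif {self.name}: bad pattern {self.pattern!r}: {exc}")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _validate_protein(rec: SequenceRecord) -> None:
    bad = set(rec.seq) - EXTENDED_AA
    if bad:
        raise FormatError(
            f"record {rec.id}: invalid amino-acid residue(s) {sorted(bad)}"
        )


def read_fasta(path: str | Path, alphabet: str | None = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    ``alphabet='protein'`` rejects residues outside the 20 standard amino
    acids plus X/B/Z/U; ``alphabet=None`` skips validation (nucleotide
    contigs, promoters).  Duplicate ids and empty files raise.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for bio in SeqIO.parse(fh, "fasta"):
            if bio.id in seen:
                raise FormatError(f"duplicate sequence id {bio.id!r} in {path}")
            seen.add(bio.id)
            seq = str(bio.seq).upper()
            if not seq:
                raise FormatError(f"record {bio.id!r} in {path} has empty sequence")
            desc = bio.description[len(bio.id):].strip() if bio.description else ""
            rec = SequenceRecord(bio.id, seq, desc)
            if alphabet == "protein":
                _validate_protein(rec)
            records.append(rec)
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(_BioSeq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Extract gene features from a GFF3 file; all other feature types are ignored."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand, feat.start, feat.end))
    return genes


def read_bed(path: str | Path, mark: str = "") -> list[GenomicInterval]:
    """Read BED intervals (0-based half-open). ``mark`` labels all intervals."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates")
            name = parts[3] if len(parts) > 3 else ""
            try:
                out.append(GenomicInterval(parts[0], start, end, name, mark))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name<TAB>description<TAB>gene..."""
    coll = GeneSetCollection()
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >= 1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            seen.add(name)
            coll.sets.append(GeneSet(name, desc, frozenset(genes)))
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def read_edge_list(path: str | Path):
    """Read a TSV edge list (nodeA<TAB>nodeB[<TAB>weight]) into a networkx Graph."""
    import networkx as nx

    g = nx.Graph()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: edge line has < 2 columns")
            a, b = parts[0], parts[1]
            if a == b:
                raise FormatError(f"{path}:{lineno}: self-loop {a!r}")
            if len(parts) > 2:
                try:
                    g.add_edge(a, b, weight=float(parts[2]))
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}")
            else:
                g.add_edge(a, b)
    return g


def write_edge_list(graph, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            if "weight" in data:
                fh.write(f"{a}\t{b}\t{data['weight']:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_motif_table(path: str | Path) -> list[CisMotif]:
    """Read a TSV motif table: name<TAB>regular-expression."""
    motifs: list[CisMotif] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: motif line needs name and pattern")
            name, pattern = parts[0], parts[1]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate motif name {name!r}")
            seen.add(name)
            try:
                re.compile(pattern)
            except re.error as exc:
                raise FormatError(
                    f"{path}:{lineno}: motif {name!r} pattern fails to compile: {exc}"
                )
            motifs.append(CisMotif(name, pattern))
    return motifs


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix: first column gene ids, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    return df
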