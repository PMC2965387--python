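"""Readers and writers for the external formats the pipeline touches.

All in-memory coordinates are 0-based half-open. Disk formats keep their
native conventions (BLAST tabular and GFF3 are 1-based inclusive); the
conversion happens exactly once, here. Minus-strand features are stored
with ``start < end`` plus a strand flag, never with reversed coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GenomicInterval",
    "ReadAlignment",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_blast_tabular",
    "write_blast_tabular",
    "read_gff",
    "write_gff",
    "read_read_alignments",
    "write_read_alignments",
]

PLATFORMS = ("short", "long")  # mirrors Illumina / 454


class FormatError(ValueError):
    """Raised on malformed or contract-violating input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (nucleotide or amino acid)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig, with strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"invalid interval [{self.start},{self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp, strand-agnostic."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReadAlignment:
    """One sequencing read placed on the genome.

    ``platform`` is 'short' (36 nt Illumina-like) or 'long' (454-like).
    """

    read_id: str
    platform: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise FormatError(
                f"unknown platform {self.platform!r}; allowed: {', '.join(PLATFORMS)}"
            )


@dataclass
class GeneModel:
    """Exon-structured candidate gene with its peptide translation.

    ``source`` records provenance: 'supplied' for models taken from an
    existing annotation, 'projected' for models built by homology
    projection. ``complete`` means both a start and a stop codon were
    found; truncated models are permitted and flagged.
    """

    id: str
    contig: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    peptide: str = ""
    source: str = "projected"
    complete: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.id}: invalid strand {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise FormatError(f"gene {self.id}: overlapping exons")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file; residues are uppercased, order preserved.

    Raises FormatError on an empty file or a duplicate id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise FormatError(f"empty FASTA file: {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt-6 dialect, optional 13th frame column)

BLAST_COLUMNS = (
    "query subject pident length mismatches gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_blast_tabular(path):
    """Parse 12-column BLAST tabular output into HSPs.

    The standard columns are 1-based inclusive; they are converted to
    0-based half-open. ``sstart > send`` encodes a minus-strand hit. An
    optional 13th column carries the translation frame; without it the
    frame is taken as +1/-1 according to strand (the magnitude cannot be
    recovered from coordinates alone).
    """
    from .homology import HSP  # local import to avoid a cycle

    hsps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 or 13 columns, got {len(parts)}"
                )
            try:
                (query, subject, pident, _length, _mism, _gapo,
                 qstart, qend, sstart, send) = parts[:10]
                pident = float(pident)
                qstart, qend = int(qstart), int(qend)
                sstart, send = int(sstart), int(send)
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: malformed row ({exc})")
            if evalue < 0:
                raise FormatError(f"{path}: line {lineno}: negative e-value {evalue}")
            if sstart <= send:
                interval = GenomicInterval(subject, sstart - 1, send, "+")
                strand = "+"
            else:
                interval = GenomicInterval(subject, send - 1, sstart, "-")
                strand = "-"
            frame = int(parts[12]) if len(parts) == 13 else (1 if strand == "+" else -1)
            hsps.append(
                HSP(
                    query_id=query,
                    query_start=qstart - 1,
                    query_end=qend,
                    interval=interval,
                    frame=frame,
                    percent_identity=pident,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hsps


def write_blast_tabular(hsps, path) -> None:
    """Emit HSPs in the 13-column tabular dialect read_blast_tabular accepts."""
    with open(path, "w") as fh:
        for h in hsps:
            iv = h.interval
            if iv.strand == "+":
                sstart, send = iv.start + 1, iv.end
            else:
                sstart, send = iv.end, iv.start + 1
            aln_len = h.query_end - h.query_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, iv.contig, f"{h.percent_identity:.2f}", aln_len,
                        0, 0, h.query_start + 1, h.query_end, sstart, send,
                        f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.frame,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/exon/CDS dialect)


def write_gff(models, path) -> None:
    """Write gene models as GFF3.

    The peptide and completeness travel in the gene row's attributes so
    that read_gff(write_gff(models)) reproduces the models exactly.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            attrs = (
                f"ID={m.id};source_model={m.source};"
                f"complete={'true' if m.complete else 'false'};peptide={m.peptide}"
            )
            fh.write(
                f"{m.contig}\ttoxseek\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.contig}\ttoxseek\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.id}.t1;Parent={m.id}\n"
            )
            for i, e in enumerate(m.exons, start=1):
                for feat in ("exon", "CDS"):
                    fh.write(
                        f"{m.contig}\ttoxseek\t{feat}\t{e.start + 1}\t{e.end}\t.\t"
                        f"{m.strand}\t{'0' if feat == 'CDS' else '.'}\t"
                        f"ID={m.id}.{feat}{i};Parent={m.id}.t1\n"
                    )


def _parse_attrs(text: str) -> dict:
    out = {}
    for part in text.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff(path) -> list[GeneModel]:
    """Read gene models from the GFF3 dialect written by write_gff.

    Exon rows out of order on disk are sorted in memory. A gene row with
    strand '.' or a CDS outside its gene span is an error.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            contig, _src, feat, start, end, _score, strand, _phase, attrs = parts
            start_i, end_i = int(start) - 1, int(end)
            attrd = _parse_attrs(attrs)
            if feat == "gene":
                if strand not in ("+", "-"):
                    raise FormatError(
                        f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                    )
                gid = attrd.get("ID")
                if not gid:
                    raise FormatError(f"{path}: line {lineno}: gene row without ID")
                genes[gid] = {
                    "contig": contig,
                    "strand": strand,
                    "span": (start_i, end_i),
                    "exons": [],
                    "peptide": attrd.get("peptide", ""),
                    "source": attrd.get("source_model", "supplied"),
                    "complete": attrd.get("complete", "false") == "true",
                }
                order.append(gid)
            elif feat == "mRNA":
                mrna_to_gene[attrd.get("ID", "")] = attrd.get("Parent", "")
            elif feat in ("exon", "CDS"):
                parent = attrd.get("Parent", "")
                gid = mrna_to_gene.get(parent, parent)
                if gid not in genes:
                    raise FormatError(
                        f"{path}: line {lineno}: {feat} with unknown parent {parent!r}"
                    )
                g = genes[gid]
                if start_i < g["span"][0] or end_i > g["span"][1]:
                    raise FormatError(
                        f"{path}: line {lineno}: {feat} outside gene span of {gid}"
                    )
                if feat == "exon":
                    g["exons"].append(
                        GenomicInterval(contig, start_i, end_i, g["strand"])
                    )
    models = []
    for gid in order:
        g = genes[gid]
        models.append(
            GeneModel(
                id=gid,
                contig=g["contig"],
                strand=g["strand"],
                exons=sorted(g["exons"], key=lambda e: e.start),
                peptide=g["peptide"],
                source=g["source"],
                complete=g["complete"],
            )
        )
    return models


# ---------------------------------------------------------------------------
# Read-alignment table

_READS_HEADER = ["read_id", "platform", "contig", "start", "end", "strand"]


def read_read_alignments(path) -> list[ReadAlignment]:
    """Read the TSV of venom-gland read placements.

    Disk coordinates are 1-based inclusive; platform must be 'short' or
    'long' (Illumina-like / 454-like).
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_READS_HEADER,
                     dtype={"read_id": str, "platform": str, "contig": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ReadAlignment(
                read_id=row.read_id,
                platform=row.platform,
                interval=GenomicInterval(
                    row.contig, int(row.start) - 1, int(row.end), row.strand
                ),
            )
        )
    return out


def write_read_alignments(alignments, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(_READS_HEADER) + "\n")
        for a in alignments:
            iv = a.interval
            fh.write(
                f"{a.read_id}\t{a.platform}\t{iv.contig}\t{iv.start + 1}\t"
                f"{iv.end}\t{iv.strand}\n"
            )
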