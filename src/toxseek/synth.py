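"""Seeded generator of a complete toy venom-gene discovery study.

The generator emulates the structure of the real study design: a genome
carrying planted toxin genes (reverse-translated, mutated copies of toxin
database proteins, optionally with one intron) plus decoy genes with no
toxin homology; deep venom-gland read coverage over the expressed loci
from a short-read (Illumina-like, 36 nt) and a long-read (454-like,
180 nt) platform; six non-venom tissue EST collections in which a chosen
fraction of planted genes is broadly expressed; GO maps with one term
enriched among venom-expressed transcripts by construction; and a ground
truth table from which every expected classification is derivable.

Read alignments, not raw reads, are emitted: mapping is outside the
pipeline's scope. All randomness flows from the single seed, and outputs
are byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .formats_io import (
    GeneModel,
    GenomicInterval,
    ReadAlignment,
    SequenceRecord,
    write_fasta,
    write_gff,
    write_read_alignments,
)
from .homology import _B62, _B62_INDEX, reverse_complement

__all__ = ["GeneratorConfig", "TruthRow", "TruthTable", "generate",
           "mutate_protein", "reverse_translate", "TISSUES"]

TISSUES = ("bill", "brain", "liver", "spleen", "testis", "fibroblast")
FAMILY_NAMES = ("kunitz", "crisp", "metalloproteinase", "stonustoxin",
                "latrotoxin", "serine_protease", "lectin", "defensin")
AA20 = "ACDEFGHIKLMNPQRSTVWY"
STOPS = ("TAA", "TAG", "TGA")
SHORT_READ_LEN = 36
LONG_READ_LEN = 180
ENRICHED_TERM = "GO:0008233"  # peptidase activity, planted as enriched
TERM_POOL = tuple(f"GO:{7000000 + i}" for i in range(15))

_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
for aa in _SYNONYMS:
    _SYNONYMS[aa].sort()


@dataclass
class GeneratorConfig:
    """Study-design knobs; defaults are the conditions of the toy study.

    Three toxin families with four planted genes each at 45-70% identity
    to their database protein, six decoy genes, mean venom-gland depths
    of 20 short / 2 long reads per gene, a quarter of planted genes
    broadly expressed (three of six tissues), and a third of planted
    genes covered by a supplied annotation.
    """

    seed: int = 1
    n_contigs: int = 6
    contig_length: int = 20000
    n_families: int = 3
    genes_per_family: int = 4
    target_identity_range: tuple[float, float] = (0.45, 0.70)
    n_decoy_genes: int = 6
    venom_depth_short: float = 20.0
    venom_depth_long: float = 2.0
    broad_expression_fraction: float = 0.25
    n_tissues: int = 6
    intron_fraction: float = 0.25
    annotation_fraction: float = 0.34
    n_background_transcripts: int = 200

    def __post_init__(self):
        lo, hi = self.target_identity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("target_identity_range must satisfy 0 < lo <= hi <= 1")
        for name in ("n_contigs", "contig_length", "n_families",
                     "genes_per_family", "n_decoy_genes", "n_tissues"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.genes_per_family > self.n_contigs:
            raise ValueError(
                "genes_per_family must not exceed n_contigs "
                "(one gene per family per contig keeps loci of a family apart)"
            )
        if self.n_families > len(FAMILY_NAMES):
            raise ValueError(f"at most {len(FAMILY_NAMES)} families supported")
        if self.n_tissues > len(TISSUES):
            raise ValueError(f"at most {len(TISSUES)} tissues supported")


@dataclass
class TruthRow:
    gene_id: str
    locus: GenomicInterval
    family: str
    identity_to_db: float
    expressed_tissues: frozenset[str]
    expected_status: str
    peptide: str
    n_short: int
    n_long: int
    annotated: bool
    is_decoy: bool = False


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    @property
    def planted(self) -> list[TruthRow]:
        return [r for r in self.rows if not r.is_decoy]

    @property
    def decoys(self) -> list[TruthRow]:
        return [r for r in self.rows if r.is_decoy]

    def match_locus(self, contig: str, start: int, end: int) -> TruthRow | None:
        """Truth row whose locus overlaps the query interval, if any."""
        for r in self.rows:
            if (r.locus.contig == contig and r.locus.start < end
                    and start < r.locus.end):
                return r
        return None

    def write_tsv(self, path) -> None:
        cols = ("gene_id", "contig", "start", "end", "strand", "family",
                "identity_to_db", "tissues", "n_short", "n_long", "annotated",
                "is_decoy", "expected_status", "peptide")
        with open(path, "w") as fh:
            fh.write("# " + "\t".join(cols) + "\n")
            for r in self.rows:
                fh.write("\t".join(str(x) for x in (
                    r.gene_id, r.locus.contig, r.locus.start, r.locus.end,
                    r.locus.strand, r.family, f"{r.identity_to_db:.4f}",
                    ",".join(sorted(r.expressed_tissues)) or ".",
                    r.n_short, r.n_long, int(r.annotated), int(r.is_decoy),
                    r.expected_status, r.peptide)) + "\n")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(AA20), size=length - 1))
    return "M" + body


def mutate_protein(p: str, target_identity: float, rng) -> str:
    """Substitute random positions until identity hits the target +-2%.

    Replacements are BLOSUM-plausible (positive BLOSUM62 score against
    the original residue where possible), positions are sampled without
    replacement, and the initial methionine is preserved. Length never
    changes.
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target identity must be in (0, 1]")
    if target_identity < 0.05:
        raise ValueError("target identity below 5% is unreachable")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_sub = round((1.0 - target_identity) * len(p))
    n_sub = min(n_sub, len(p) - 1)
    positions = rng.choice(np.arange(1, len(p)), size=n_sub, replace=False)
    out = list(p)
    for pos in sorted(positions):
        orig = out[pos]
        oi = _B62_INDEX.get(orig)
        plausible = [aa for aa in AA20
                     if aa != orig and oi is not None
                     and _B62[oi, _B62_INDEX[aa]] > 0]
        pool = plausible or [aa for aa in AA20 if aa != orig]
        out[pos] = str(rng.choice(pool))
    mutant = "".join(out)
    achieved = sum(a == b for a, b in zip(p, mutant)) / len(p)
    if abs(achieved - target_identity) > 0.02 + 0.5 / len(p):
        raise RuntimeError("mutation failed to reach target identity")
    return mutant


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform choice over synonymous codons for every residue."""
    return "".join(str(rng.choice(_SYNONYMS[aa])) for aa in protein)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass
class _Locus:
    gene_id: str
    family: str | None
    protein: str
    identity: float
    gene_seq: str          # genomic sequence of the locus, forward orientation
    rel_exons: list[tuple[int, int]]  # exon coords within gene_seq (+ orientation)
    strand: str
    contig_index: int
    # filled at placement time:
    interval: GenomicInterval | None = None
    exons: list[GenomicInterval] = field(default_factory=list)
    cdna: str = ""


def _build_locus(rng, gene_id, family, protein, identity, intron_fraction,
                 contig_index) -> _Locus:
    cds = reverse_translate(protein, rng) + str(rng.choice(list(STOPS)))
    rel_exons = [(0, len(cds))]
    gene_seq = cds
    if rng.random() < intron_fraction and len(protein) >= 20:
        cut_codon = int(rng.integers(int(0.3 * len(protein)),
                                     int(0.7 * len(protein))))
        cut = 3 * cut_codon
        intron = "GT" + _random_dna(rng, int(rng.integers(120, 240))) + "AG"
        gene_seq = cds[:cut] + intron + cds[cut:]
        rel_exons = [(0, cut), (cut + len(intron), len(gene_seq))]
    strand = "+" if rng.random() < 0.5 else "-"
    return _Locus(gene_id=gene_id, family=family, protein=protein,
                  identity=identity, gene_seq=gene_seq, rel_exons=rel_exons,
                  strand=strand, contig_index=contig_index, cdna=cds)


def generate(config: GeneratorConfig, outdir) -> TruthTable:
    """Write the full toy study into ``outdir`` and return its truth table.

    Files: genome.fasta, toxin_db.fasta, annotation.gff3,
    read_alignments.tsv, est_<tissue>.fasta (one per surveyed tissue),
    go_foreground.tsv, go_background.tsv, family_alignment.fasta,
    truth.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # toxin database: one base protein per family
    families = FAMILY_NAMES[: config.n_families]
    db_records = []
    base_proteins: dict[str, str] = {}
    for i, fam in enumerate(families):
        length = int(rng.integers(70, 110))
        prot = _random_protein(rng, length)
        base_proteins[fam] = prot
        db_records.append(
            SequenceRecord(f"tox{i + 1:02d}", prot, f"family={fam}")
        )

    # planted toxin genes: gene g of each family goes to contig g, so loci
    # of one family never share a contig (keeps chaining unambiguous)
    lo, hi = config.target_identity_range
    loci: list[_Locus] = []
    for fi, fam in enumerate(families):
        for g in range(config.genes_per_family):
            target = float(rng.uniform(lo, hi))
            mutant = mutate_protein(base_proteins[fam], target, rng)
            identity = sum(a == b for a, b in
                           zip(base_proteins[fam], mutant)) / len(mutant)
            loci.append(_build_locus(
                rng, f"{fam}_g{g + 1}", fam, mutant, identity,
                config.intron_fraction, contig_index=g))

    for d in range(config.n_decoy_genes):
        length = int(rng.integers(60, 100))
        prot = _random_protein(rng, length)
        loci.append(_build_locus(
            rng, f"decoy_{d + 1}", None, prot, 0.0, config.intron_fraction,
            contig_index=d % config.n_contigs))

    # lay the loci onto contigs with random spacers
    contig_names = [f"contig{c + 1}" for c in range(config.n_contigs)]
    contig_parts: list[list[str]] = [[] for _ in contig_names]
    contig_pos = [0] * config.n_contigs
    for locus in loci:
        c = locus.contig_index
        spacer = int(rng.integers(400, 900))
        contig_parts[c].append(_random_dna(rng, spacer))
        contig_pos[c] += spacer
        start = contig_pos[c]
        inserted = (locus.gene_seq if locus.strand == "+"
                    else reverse_complement(locus.gene_seq))
        contig_parts[c].append(inserted)
        glen = len(inserted)
        locus.interval = GenomicInterval(contig_names[c], start, start + glen,
                                         locus.strand)
        for s, e in locus.rel_exons:
            if locus.strand == "+":
                iv = GenomicInterval(contig_names[c], start + s, start + e, "+")
            else:
                iv = GenomicInterval(contig_names[c], start + glen - e,
                                     start + glen - s, "-")
            locus.exons.append(iv)
        locus.exons.sort(key=lambda iv: iv.start)
        contig_pos[c] += glen
    genome_records = []
    for c, name in enumerate(contig_names):
        tail = max(0, config.contig_length - contig_pos[c])
        contig_parts[c].append(_random_dna(rng, tail))
        seq = "".join(contig_parts[c])
        if len(seq) > config.contig_length:
            raise ValueError(
                "loci do not fit: increase contig_length or n_contigs"
            )
        genome_records.append(SequenceRecord(name, seq))

    # venom-gland read alignments over every expressed locus
    alignments: list[ReadAlignment] = []
    counter = 0
    contig_len = {r.id: len(r.residues) for r in genome_records}
    counts: dict[str, tuple[int, int]] = {}
    for locus in loci:
        n_short = int(rng.poisson(config.venom_depth_short))
        n_long = int(rng.poisson(config.venom_depth_long))
        counts[locus.gene_id] = (n_short, n_long)
        exon_lens = np.array([len(e) for e in locus.exons], dtype=float)
        probs = exon_lens / exon_lens.sum()
        for n_reads, platform, rlen in ((n_short, "short", SHORT_READ_LEN),
                                        (n_long, "long", LONG_READ_LEN)):
            for _ in range(n_reads):
                counter += 1
                e = locus.exons[int(rng.choice(len(locus.exons), p=probs))]
                pos = int(rng.integers(e.start, e.end))
                L = contig_len[e.contig]
                start = max(0, min(pos, L - rlen))
                alignments.append(ReadAlignment(
                    read_id=f"r{counter:06d}", platform=platform,
                    interval=GenomicInterval(e.contig, start,
                                             min(L, start + rlen), "+")))

    # tissue ESTs: broadly-expressed planted genes hit three tissues;
    # every tissue also carries one unrelated housekeeping EST
    tissues = TISSUES[: config.n_tissues]
    planted = [l for l in loci if l.family is not None]
    n_broad = int(round(config.broad_expression_fraction * len(planted)))
    broad_idx = sorted(rng.choice(len(planted), size=n_broad, replace=False)) \
        if n_broad else []
    tissue_sets: dict[str, list[str]] = {}
    for bi in broad_idx:
        chosen = sorted(rng.choice(len(tissues), size=min(3, len(tissues)),
                                   replace=False))
        tissue_sets[planted[bi].gene_id] = [tissues[t] for t in chosen]
    est_by_tissue: dict[str, list[SequenceRecord]] = {t: [] for t in tissues}
    for t in tissues:
        est_by_tissue[t].append(
            SequenceRecord(f"est_hk_{t}", _random_dna(rng, 400)))
    for locus in planted:
        for t in tissue_sets.get(locus.gene_id, ()):
            est_by_tissue[t].append(
                SequenceRecord(f"est_{locus.gene_id}_{t}", locus.cdna))

    # annotation covers a deterministic subset of planted genes
    annotated_models = []
    annotated_ids = set()
    for i, locus in enumerate(planted):
        if config.annotation_fraction > 0 and \
                i % max(1, round(1 / config.annotation_fraction)) == 0:
            annotated_ids.add(locus.gene_id)
            annotated_models.append(GeneModel(
                id=locus.gene_id, contig=locus.interval.contig,
                strand=locus.strand, exons=list(locus.exons),
                peptide=locus.protein, source="supplied", complete=True))

    # GO maps: venom-expressed transcripts (planted + decoys) form the
    # foreground; ENRICHED_TERM marks every planted toxin gene and is rare
    # in the rest of the background
    fg_map: dict[str, set[str]] = {}
    bg_map: dict[str, set[str]] = {}
    for locus in loci:
        terms = set(rng.choice(TERM_POOL,
                               size=int(rng.integers(1, 4)), replace=False))
        if locus.family is not None:
            terms.add(ENRICHED_TERM)
        fg_map[locus.gene_id] = terms
        bg_map[locus.gene_id] = terms
    for b in range(config.n_background_transcripts):
        terms = set(rng.choice(TERM_POOL,
                               size=int(rng.integers(1, 4)), replace=False))
        if rng.random() < 0.03:
            terms.add(ENRICHED_TERM)
        bg_map[f"bgt{b + 1:04d}"] = terms

    # truth statuses by the cascade's own rules
    truth = TruthTable()
    for locus in loci:
        n_short, n_long = counts[locus.gene_id]
        tset = frozenset(tissue_sets.get(locus.gene_id, ()))
        if locus.family is None:
            status = "not_a_candidate"
        elif not (n_short >= 10 or n_long >= 1):
            status = "rejected_no_read_support"
        elif len(tset) >= 3:
            status = "rejected_broad_expression"
        elif len(tset) == 0:
            status = "probable"
        else:
            status = "putative"
        truth.rows.append(TruthRow(
            gene_id=locus.gene_id, locus=locus.interval,
            family=locus.family or ".", identity_to_db=locus.identity,
            expressed_tissues=tset, expected_status=status,
            peptide=locus.protein, n_short=n_short, n_long=n_long,
            annotated=locus.gene_id in annotated_ids,
            is_decoy=locus.family is None))

    # ----- write everything -----
    write_fasta(genome_records, outdir / "genome.fasta")
    write_fasta(db_records, outdir / "toxin_db.fasta")
    write_gff(annotated_models, outdir / "annotation.gff3")
    write_read_alignments(alignments, outdir / "read_alignments.tsv")
    for t in tissues:
        write_fasta(est_by_tissue[t], outdir / f"est_{t}.fasta")
    for name, mapping in (("go_foreground.tsv", fg_map),
                          ("go_background.tsv", bg_map)):
        with open(outdir / name, "w") as fh:
            fh.write("# transcript_id\tterm_id\n")
            for tid in sorted(mapping):
                for term in sorted(mapping[tid]):
                    fh.write(f"{tid}\t{term}\n")
    fam0 = families[0] if families else None
    if fam0 is not None:
        rows = [SequenceRecord(db_records[0].id, base_proteins[fam0])]
        rows += [SequenceRecord(l.gene_id, l.protein)
                 for l in planted if l.family == fam0]
        if len(rows) >= 2:
            write_fasta(rows, outdir / "family_alignment.fasta")
    truth.write_tsv(outdir / "truth.tsv")
    return truth
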