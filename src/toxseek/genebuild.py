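"""HSP chaining, the enhanced genebuild, and homology-projected gene models.

Chains are score-maximizing colinear subsets of HSPs within one
(query, contig, strand) group, extracted greedily by descending total bit
score so that every HSP belongs to exactly one chain. Chains overlapping
an existing annotation are attached to that gene; the rest become novel
loci and are turned into gene models by projecting the HSP intervals onto
the genome and extending to the nearest in-frame start and stop codons —
a documented stand-in for ab initio prediction, which is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats_io import GeneModel, GenomicInterval, SequenceRecord
from .homology import HSP, reverse_complement

__all__ = [
    "HspChain",
    "PredictionRegion",
    "chain_hsps",
    "build_enhanced_genebuild",
    "extract_prediction_region",
    "project_gene_model",
    "choose_model",
]

# aa overlap allowed between consecutive members: X-drop extension can
# overrun a splice junction by up to ~xdrop score units on each flanking
# end, so genuine adjacent-exon HSPs often overlap 10-15 aa in the query
QUERY_OVERLAP_TOLERANCE = 20
CHAIN_EVALUE_MAX = 1e-5       # a chain's best member must clear this

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class HspChain:
    """A colinear group of HSPs interpreted as one candidate locus."""

    query_id: str
    members: list[HSP]
    chain_id: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError("chain has no members")
        contigs = {h.interval.contig for h in self.members}
        strands = {h.interval.strand for h in self.members}
        queries = {h.query_id for h in self.members}
        if len(contigs) > 1 or len(strands) > 1 or len(queries) > 1:
            raise ValueError("chain members must share contig, strand and query")
        self.members.sort(key=lambda h: (h.interval.start, h.interval.end))
        if not self.chain_id:
            s = self.span
            self.chain_id = f"{self.query_id}|{s.contig}:{s.start}-{s.end}{s.strand}"

    @property
    def span(self) -> GenomicInterval:
        m = self.members
        return GenomicInterval(
            m[0].interval.contig,
            min(h.interval.start for h in m),
            max(h.interval.end for h in m),
            m[0].interval.strand,
        )

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.members)

    @property
    def total_bitscore(self) -> float:
        return sum(h.bitscore for h in self.members)


@dataclass(frozen=True)
class PredictionRegion:
    """Genomic window handed to gene prediction around a chain."""

    interval: GenomicInterval
    chain_id: str
    expanded: bool = False


def compatible(prev: HSP, nxt: HSP, max_gap: int) -> bool:
    """Can ``nxt`` follow ``prev`` in a chain?

    Both genomic starts and ends must increase, the genomic gap must not
    exceed ``max_gap``, and the query must advance in the orientation the
    strand dictates (forward on '+', reverse on '-') with at most
    QUERY_OVERLAP_TOLERANCE aa of overlap.
    """
    a, b = prev.interval, nxt.interval
    if not (b.start > a.start and b.end > a.end):
        return False
    if b.start - a.end > max_gap:
        return False
    if a.strand == "+":
        return (
            nxt.query_start >= prev.query_start
            and nxt.query_end >= prev.query_end
            and prev.query_end - nxt.query_start <= QUERY_OVERLAP_TOLERANCE
        )
    return (
        nxt.query_start <= prev.query_start
        and nxt.query_end <= prev.query_end
        and nxt.query_end - prev.query_start <= QUERY_OVERLAP_TOLERANCE
    )


def _best_chain(group: list[HSP], max_gap: int) -> list[int]:
    """Indices of the max-total-bitscore colinear chain (DP over pairs)."""
    order = sorted(
        range(len(group)),
        key=lambda i: (group[i].interval.start, group[i].interval.end),
    )
    score = [group[i].bitscore for i in order]
    back = [-1] * len(order)
    for x in range(len(order)):
        hx = group[order[x]]
        for y in range(x):
            hy = group[order[y]]
            if compatible(hy, hx, max_gap):
                cand = score[y] + group[order[x]].bitscore
                if cand > score[x]:
                    score[x] = cand
                    back[x] = y
    best = max(range(len(order)), key=lambda x: score[x])
    path = []
    while best != -1:
        path.append(order[best])
        best = back[best]
    return path[::-1]


def chain_hsps(hsps: list[HSP], max_gap: int = 40000,
               e_max: float = CHAIN_EVALUE_MAX) -> list[HspChain]:
    """Partition HSPs into colinear chains, best-scoring first.

    Within each (query, contig, strand) group the top chain is found by
    dynamic programming, its members are removed, and the process repeats
    until every HSP is assigned. Chains whose best member E-value exceeds
    ``e_max`` are discarded — the inclusion rule is chain-level, so weak
    HSPs may ride along in a chain anchored by a strong one.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    groups: dict[tuple, list[HSP]] = {}
    for h in hsps:
        groups.setdefault(
            (h.query_id, h.interval.contig, h.interval.strand), []
        ).append(h)
    chains: list[HspChain] = []
    for key in sorted(groups):
        remaining = list(groups[key])
        while remaining:
            idx = _best_chain(remaining, max_gap)
            members = [remaining[i] for i in idx]
            for i in sorted(idx, reverse=True):
                remaining.pop(i)
            chain = HspChain(query_id=key[0], members=members)
            if chain.best_evalue <= e_max:
                chains.append(chain)
    chains.sort(key=lambda c: (c.span.contig, c.span.start, c.chain_id))
    return chains


def build_enhanced_genebuild(
    chains: list[HspChain], annotation: list[GeneModel]
) -> tuple[list[HspChain], dict[str, list[HspChain]]]:
    """Split chains into novel loci and attachments to annotated genes.

    A chain whose span overlaps any supplied gene's exon hull by >= 1 bp
    (either strand) is attached to that gene — the gene is tagged with the
    toxin-database match rather than predicted afresh. All other chains
    are returned as novel loci. A chain overlapping several genes is
    attached to each.
    """
    attached: dict[str, list[HspChain]] = {}
    novel: list[HspChain] = []
    hulls = [(g.id, g.span) for g in annotation if g.exons]
    for chain in chains:
        span = chain.span
        hit = False
        for gid, hull in hulls:
            if span.contig == hull.contig and span.start < hull.end and hull.start < span.end:
                attached.setdefault(gid, []).append(chain)
                hit = True
        if not hit:
            novel.append(chain)
    return novel, attached


def extract_prediction_region(
    chain: HspChain,
    contig_length: int,
    flank: int = 10000,
    max_flank: int = 100000,
    expand: bool = False,
) -> PredictionRegion:
    """Window around a chain handed to gene prediction.

    Small contigs are taken whole; on large sequences the chain span is
    padded by ``flank`` (or ``max_flank`` when ``expand`` is set, the
    retry used when a first prediction came back incomplete), clipped to
    the contig.
    """
    if flank > max_flank:
        raise ValueError("flank exceeds max_flank")
    span = chain.span
    if span.end > contig_length:
        raise ValueError(f"chain span {span} outside contig of length {contig_length}")
    pad = max_flank if expand else flank
    if contig_length <= len(span) + 2 * pad:
        iv = GenomicInterval(span.contig, 0, contig_length, span.strand)
    else:
        iv = GenomicInterval(
            span.contig,
            max(0, span.start - pad),
            min(contig_length, span.end + pad),
            span.strand,
        )
    return PredictionRegion(interval=iv, chain_id=chain.chain_id, expanded=expand)


def _codon_trim(start: int, end: int, frame_offset: int) -> tuple[int, int]:
    """Clip an interval to codon boundaries of the frame with the given
    nucleotide offset (0..2)."""
    s = start + ((frame_offset - start) % 3)
    e = s + 3 * max(0, (end - s) // 3)
    return s, e


def _translate_codons(seq: str) -> str:
    from Bio.Seq import Seq

    sub = seq[: len(seq) - len(seq) % 3]
    return str(Seq(sub).translate()) if sub else ""


def project_gene_model(
    chain: HspChain,
    genome: dict[str, str] | list[SequenceRecord],
    region: PredictionRegion | None = None,
    model_id: str | None = None,
) -> GeneModel:
    """Build a gene model from a chain by projecting its HSPs.

    Exons are the member HSP intervals trimmed to codon boundaries in
    each HSP's frame; the terminal exons are then extended codon by codon
    to the nearest in-frame stop (3') and to the nearest upstream
    in-frame ATG found before a stop (5'). Extension never leaves the
    prediction region. Minus-strand chains are handled by reflection.
    A model is emitted even when extension fails or a member contains an
    internal stop; it is then flagged ``complete=False``.
    """
    if isinstance(genome, list):
        genome = {r.id: r.residues for r in genome}
    span = chain.span
    seq = genome[span.contig]
    L = len(seq)
    if span.end > L:
        raise ValueError(f"chain {chain.chain_id} outside contig {span.contig}")
    strand = span.strand
    if region is not None:
        rs, re_ = region.interval.start, region.interval.end
    else:
        rs, re_ = 0, L

    if strand == "+":
        work = seq
        w_rs, w_re = rs, re_
        exons_fwd = [(h.interval.start, h.interval.end, abs(h.frame) - 1,
                      h.query_start, h.query_end) for h in chain.members]
    else:
        # reflect everything onto the reverse complement and treat as '+'
        work = reverse_complement(seq)
        w_rs, w_re = L - re_, L - rs
        exons_fwd = [(L - h.interval.end, L - h.interval.start,
                      abs(h.frame) - 1, h.query_start, h.query_end)
                     for h in chain.members]
    exons_fwd.sort()

    # consecutive members may overlap in query coordinates (X-drop
    # extension runs a few codons past a splice junction); trim the
    # overlap off the 3' end of the upstream member so junction-derived
    # residues are not duplicated
    clipped = []
    for i, (s, e, off, qs, qe) in enumerate(exons_fwd):
        if i + 1 < len(exons_fwd):
            overlap = qe - exons_fwd[i + 1][3]
            if overlap > 0:
                e = max(s, e - 3 * overlap)
        clipped.append((s, e, off))

    # trim to codon boundaries; drop empties; merge overlaps
    trimmed: list[list[int]] = []
    for s, e, off in clipped:
        s2, e2 = _codon_trim(s, e, off % 3)
        if e2 <= s2:
            continue
        if trimmed and s2 <= trimmed[-1][1]:
            # keep the established frame of the earlier exon on overlap
            trimmed[-1][1] = max(trimmed[-1][1], e2)
        else:
            trimmed.append([s2, e2])
    if not trimmed:
        raise ValueError(f"chain {chain.chain_id}: no codon-aligned exon material")

    # 5' extension to an in-frame ATG (walking upstream, stop codon aborts)
    start_found = work[trimmed[0][0]:trimmed[0][0] + 3] == "ATG"
    pos = trimmed[0][0]
    while not start_found and pos - 3 >= w_rs:
        pos -= 3
        codon = work[pos:pos + 3]
        if codon in _STOPS:
            break
        if codon == "ATG":
            trimmed[0][0] = pos
            start_found = True

    # 3' extension to the nearest in-frame stop (the stop codon is included)
    stop_found = False
    pos = trimmed[-1][1]
    while pos + 3 <= w_re:
        codon = work[pos:pos + 3]
        pos += 3
        if codon in _STOPS:
            trimmed[-1][1] = pos
            stop_found = True
            break

    peptide_parts = []
    internal_stop = False
    for i, (s, e) in enumerate(trimmed):
        aa = _translate_codons(work[s:e])
        if i == len(trimmed) - 1 and aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            internal_stop = True
        peptide_parts.append(aa)
    peptide = "".join(peptide_parts)

    if strand == "+":
        exons = [GenomicInterval(span.contig, s, e, "+") for s, e in trimmed]
    else:
        exons = [GenomicInterval(span.contig, L - e, L - s, "-")
                 for s, e in reversed(trimmed)]

    return GeneModel(
        id=model_id or f"proj_{chain.chain_id}",
        contig=span.contig,
        strand=strand,
        exons=exons,
        peptide=peptide or "X",
        source="projected",
        complete=start_found and stop_found and not internal_stop,
    )


def choose_model(projected: GeneModel, supplied: GeneModel, long_reads) -> GeneModel:
    """Pick between a projected model and a supplied annotation.

    The supplied model wins unless strictly more long-platform (454-like)
    reads overlap the projected exons than the supplied exons; ties keep
    the supplied model.
    """

    def n_overlapping(model: GeneModel) -> int:
        count = 0
        for r in long_reads:
            if r.platform != "long":
                continue
            if any(r.interval.overlaps(e) for e in model.exons):
                count += 1
        return count

    return projected if n_overlapping(projected) > n_overlapping(supplied) else supplied
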