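"""The candidate validation cascade.

A candidate gene model survives only if (1) it is not a redundant copy of
a longer candidate, (2) the venom gland expresses it — at least 10
short-platform reads or at least 1 long-platform read over its exons,
(3) at least one toxin-database HSP hits an exon, and (4) it is not
broadly expressed: EST hits in three or more of the surveyed non-venom
tissues reject it. Survivors expressed in no non-venom tissue are
classified ``probable``; the rest are ``putative``.

The rejection steps are conjunctive, so the accepted set is independent
of their order; the order fixed here only determines which rejection
label a multiply-failing candidate receives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import GeneModel, ReadAlignment, SequenceRecord
from .genebuild import HspChain
from .homology import ScoringScheme, translated_search

__all__ = [
    "ReadSupport",
    "TissueProfile",
    "CandidateRecord",
    "count_read_support",
    "passes_read_support",
    "exon_hsp_screen",
    "tissue_expression_profile",
    "remove_redundancy",
    "classify",
    "STATUSES",
]

STATUSES = (
    "rejected_no_read_support",
    "rejected_broad_expression",
    "rejected_no_exon_hsp",
    "redundant",
    "putative",
    "probable",
)


@dataclass
class ReadSupport:
    gene_id: str
    short_count: int = 0
    long_count: int = 0


@dataclass
class TissueProfile:
    gene_id: str
    tissues_with_hits: frozenset[str] = frozenset()
    n_tissues_surveyed: int = 0


@dataclass
class CandidateRecord:
    """A gene model plus every piece of evidence the cascade consumes."""

    model: GeneModel
    support: ReadSupport | None = None
    profile: TissueProfile | None = None
    exon_hsp_ok: bool | None = None
    redundant_with: str | None = None
    family: str | None = None
    best_family_identity: float | None = None
    signal_peptide: bool | None = None  # annotation only, never an exclusion
    status: str | None = None


def count_read_support(model: GeneModel, alignments: list[ReadAlignment]) -> ReadSupport:
    """Exact per-platform counts of reads overlapping any exon.

    Overlap is >= 1 bp and strand-agnostic; a read spanning several exons
    counts once.
    """
    short = long_ = 0
    for r in alignments:
        if any(r.interval.overlaps(e) for e in model.exons):
            if r.platform == "short":
                short += 1
            else:
                long_ += 1
    return ReadSupport(gene_id=model.id, short_count=short, long_count=long_)


def passes_read_support(s: ReadSupport, short_min: int = 10, long_min: int = 1) -> bool:
    """Venom-gland expression rule: >= short_min short reads OR >= long_min
    long reads."""
    if short_min < 0 or long_min < 0:
        raise ValueError("thresholds must be non-negative")
    return s.short_count >= short_min or s.long_count >= long_min


def exon_hsp_screen(model: GeneModel, chain: HspChain) -> bool:
    """True iff at least one member HSP overlaps at least one exon by >= 1 bp."""
    if not chain.members:
        raise ValueError("chain has no members")
    return any(
        h.interval.overlaps(e) for h in chain.members for e in model.exons
    )


def tissue_expression_profile(
    peptide: str,
    est_by_tissue: dict[str, list[SequenceRecord]],
    min_identity: float = 95.0,
    min_read_coverage: float = 0.90,
    max_evalue: float = 1e-4,
    scheme: ScoringScheme | None = None,
    gene_id: str = "",
) -> TissueProfile:
    """Which non-venom tissues express this peptide?

    The peptide is searched against every EST of every tissue with the
    translated six-frame engine; a tissue counts iff some EST has a hit
    with E <= max_evalue, percent identity >= min_identity and an aligned
    fraction of the EST >= min_read_coverage — the codified version of a
    manual "close to 100% match spanning the entire read" check.
    """
    if len(peptide) < 10:
        raise ValueError("peptide shorter than 10 aa")
    scheme = scheme or ScoringScheme()
    query = SequenceRecord(gene_id or "peptide", peptide.replace("*", "X"))
    hits: set[str] = set()
    for tissue, ests in est_by_tissue.items():
        for est in ests:
            if len(est.residues) < 3:
                continue
            for h in translated_search(query, [est], scheme=scheme,
                                       min_evalue=max_evalue):
                coverage = len(h.interval) / len(est.residues)
                if h.percent_identity >= min_identity and coverage >= min_read_coverage:
                    hits.add(tissue)
                    break
            if tissue in hits:
                break
    return TissueProfile(
        gene_id=gene_id,
        tissues_with_hits=frozenset(hits),
        n_tissues_surveyed=len(est_by_tissue),
    )


_aligner = None


def _protein_aligner():
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _aligner = a
    return _aligner


def peptide_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Local-alignment percent identity and coverage of the shorter peptide.

    Identity is over aligned columns; coverage is the aligned length of
    the shorter sequence divided by its full length.
    """
    a = a.replace("*", "X") or "X"
    b = b.replace("*", "X") or "X"
    aligner = _protein_aligner()
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0
    ident = aligned_a = aligned_b = 0
    for (as_, ae), (bs, be) in zip(*aln.aligned):
        aligned_a += ae - as_
        aligned_b += be - bs
        ident += sum(a[i] == b[bs + (i - as_)] for i in range(as_, ae))
    cols = max(aligned_a, aligned_b)
    if cols == 0:
        return 0.0, 0.0
    shorter = min(len(a), len(b))
    cov = min(aligned_a, aligned_b) / shorter
    return 100.0 * ident / cols, cov


def remove_redundancy(
    candidates: list[CandidateRecord],
    min_identity: float = 97.0,
    min_cov: float = 0.90,
) -> list[CandidateRecord]:
    """Mark near-identical candidates (typically split-assembly copies).

    Candidates are visited by descending peptide length; one is redundant
    iff its peptide aligns to an already-kept candidate's at
    >= min_identity percent identity over >= min_cov of the shorter
    peptide. The longest copy is the kept representative.
    """
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-len(candidates[i].model.peptide), candidates[i].model.id),
    )
    kept: list[int] = []
    for i in order:
        cand = candidates[i]
        cand.redundant_with = None
        for j in kept:
            ident, cov = peptide_identity_coverage(
                cand.model.peptide, candidates[j].model.peptide
            )
            if ident >= min_identity and cov >= min_cov:
                cand.redundant_with = candidates[j].model.id
                break
        if cand.redundant_with is None:
            kept.append(i)
    return candidates


def classify(
    candidates: list[CandidateRecord],
    short_min: int = 10,
    long_min: int = 1,
    tissue_max: int = 3,
) -> list[CandidateRecord]:
    """Assign the final status to every candidate.

    Cascade order: redundant -> no read support -> no exon HSP ->
    broad expression (>= tissue_max tissues) -> probable (0 tissues) /
    putative. Deterministic and idempotent given the evidence fields.
    """
    for cand in candidates:
        gid = cand.model.id
        if cand.support is None or cand.profile is None or cand.exon_hsp_ok is None:
            raise ValueError(f"candidate {gid}: missing evidence")
        if cand.redundant_with is not None:
            cand.status = "redundant"
        elif not passes_read_support(cand.support, short_min, long_min):
            cand.status = "rejected_no_read_support"
        elif not cand.exon_hsp_ok:
            cand.status = "rejected_no_exon_hsp"
        elif len(cand.profile.tissues_with_hits) >= tissue_max:
            cand.status = "rejected_broad_expression"
        elif len(cand.profile.tissues_with_hits) == 0:
            cand.status = "probable"
        else:
            cand.status = "putative"
    return candidates
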