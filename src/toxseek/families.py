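"""Toxin-family assignment and motif / domain-order checks.

Candidates are assigned to a family by their best protein-protein hit
against the toxin database (headers carry ``family=NAME``); homology is
defined at E < 1e-4, matching the discovery threshold used for family
classification. The zinc-binding motif scan (HEXXHXXGXXH for PIII
metalloproteinases) and the domain-order subsequence check are supplied
for the downstream structural sanity checks; domain tables themselves
are inputs, not computed here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .filters import _protein_aligner
from .formats_io import SequenceRecord
from .homology import AA_ALPHABET, ScoringScheme

__all__ = [
    "FamilyAssignment",
    "MotifPattern",
    "DomainAnnotation",
    "ZINC_BINDING_MOTIF",
    "PIII_DOMAIN_ORDER",
    "assign_family",
    "motif_scan",
    "domain_order_check",
    "family_from_description",
]

ZINC_BINDING_MOTIF = "HEXXHXXGXXH"
PIII_DOMAIN_ORDER = ["preprosequence", "metalloproteinase", "disintegrin",
                     "cysteine-rich"]


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    family: str
    best_hit_id: str
    percent_identity: float
    evalue: float


@dataclass(frozen=True)
class MotifPattern:
    """Amino-acid pattern where X matches anything."""

    pattern: str

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern) - (AA_ALPHABET | {"X"})
        if bad:
            raise ValueError(f"invalid motif symbols: {sorted(bad)}")


@dataclass(frozen=True)
class DomainAnnotation:
    gene_id: str
    domains: tuple  # ordered (name, start, end) in peptide coordinates


_FAMILY_RE = re.compile(r"family=(\S+)")


def family_from_description(description: str) -> str:
    m = _FAMILY_RE.search(description)
    return m.group(1) if m else "unknown"


def assign_family(
    peptide: SequenceRecord,
    toxin_db: list[SequenceRecord],
    max_evalue: float = 1e-4,
    scheme: ScoringScheme | None = None,
) -> FamilyAssignment | None:
    """Best toxin-database hit for a candidate peptide, or None.

    Protein-protein local alignment (BLOSUM62, 11/1 gaps); the raw score
    is converted to a bit score and E-value with the same Karlin-Altschul
    machinery as the translated search, with n the total database length.
    The best hit is the lowest E-value, ties broken by higher bit score
    then lexicographically smaller hit id; no assignment unless
    E < max_evalue (strict).
    """
    if not toxin_db:
        raise ValueError("empty toxin database")
    scheme = scheme or ScoringScheme()
    q = peptide.residues.replace("*", "X")
    n_total = sum(len(r.residues) for r in toxin_db)
    aligner = _protein_aligner()
    best = None
    for rec in toxin_db:
        s = rec.residues.replace("*", "X")
        try:
            aln = aligner.align(q, s)[0]
        except (IndexError, ValueError):
            continue
        raw = aln.score
        ev = scheme.evalue(raw, len(q), n_total)
        ident = cols = 0
        for (qs, qe), (ss, _se) in zip(*aln.aligned):
            cols += qe - qs
            ident += sum(q[i] == s[ss + (i - qs)] for i in range(qs, qe))
        pid = 100.0 * ident / cols if cols else 0.0
        bit = scheme.bitscore(raw)
        key = (ev, -bit, rec.id)
        if best is None or key < best[0]:
            best = (key, rec, pid, ev)
    if best is None or best[3] >= max_evalue:
        return None
    _key, rec, pid, ev = best
    return FamilyAssignment(
        gene_id=peptide.id,
        family=family_from_description(rec.description),
        best_hit_id=rec.id,
        percent_identity=pid,
        evalue=ev,
    )


def motif_scan(peptide: str, pattern: MotifPattern | str) -> list[int]:
    """All offsets (overlapping included) where the pattern matches.

    X in the pattern is a wildcard; every other symbol must match
    exactly.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    p = pattern.pattern
    hits = []
    for i in range(len(peptide) - len(p) + 1):
        if all(pc == "X" or pc == peptide[i + j] for j, pc in enumerate(p)):
            hits.append(i)
    return hits


def domain_order_check(annot: DomainAnnotation, required_order: list[str]) -> bool:
    """True iff required_order is a subsequence of the domain-name order."""
    if not required_order:
        raise ValueError("required_order must be non-empty")
    names = [d[0] for d in sorted(annot.domains, key=lambda d: d[1])]
    it = iter(names)
    return all(req in it for req in required_order)
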