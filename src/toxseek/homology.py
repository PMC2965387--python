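"""Translated (six-frame) protein-to-genome local search.

This is a deliberately simple TBLASTN-style engine so the pipeline can run
hermetically at toy scale: 3-mer neighborhood-word seeding under the
two-hit rule, ungapped X-drop extension under BLOSUM62, Karlin-Altschul
conversion of raw scores to bit scores and E-values. Precomputed BLAST tabular output can be ingested
instead (see formats_io.read_blast_tabular) when fidelity to a real search
matters. E-value, not bit score, is the selection variable throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .formats_io import FormatError, GenomicInterval, SequenceRecord

__all__ = [
    "HSP",
    "ScoringScheme",
    "six_frame_translate",
    "translated_search",
    "reverse_complement",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHA = _BLOSUM62.alphabet
_B62_INDEX = {c: i for i, c in enumerate(_B62_ALPHA)}
_B62 = np.asarray(_BLOSUM62)


def _score(a: str, b: str) -> float:
    ia = _B62_INDEX.get(a, _B62_INDEX["X"])
    ib = _B62_INDEX.get(b, _B62_INDEX["X"])
    return _B62[ia, ib]


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters plus Karlin-Altschul constants.

    Defaults are the standard gapped BLOSUM62 statistics
    (lambda = 0.267, K = 0.041); bit score b = (lambda*S - ln K)/ln 2 and
    E = m*n*2^-b with m the query length and n the searched length.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self):
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and k must be positive")

    def bitscore(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.k)) / math.log(2)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bitscore(raw))


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class HSP:
    """One local alignment between a protein query and a genomic segment.

    Query coordinates are 0-based half-open in amino acids; the genomic
    interval is in nucleotides on the forward strand with a strand flag.
    For ungapped HSPs len(interval) == 3 * (query_end - query_start).
    """

    query_id: str
    query_start: int
    query_end: int
    interval: GenomicInterval
    frame: int
    percent_identity: float
    evalue: float
    bitscore: float
    raw_score: float | None = None

    def __post_init__(self):
        if self.frame not in (-3, -2, -1, 1, 2, 3):
            raise FormatError(f"invalid frame {self.frame}")
        if (self.frame > 0) != (self.interval.strand == "+"):
            raise FormatError("frame sign does not match strand")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translate all six reading frames of ``dna``.

    Frames +1..+3 read the forward strand starting at offsets 0..2;
    frames -1..-3 read the reverse complement the same way. Codons
    containing N translate to X and stops are rendered '*'. Trailing
    partial codons are dropped.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(dna) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols: {sorted(bad)}")
    rc = reverse_complement(dna)
    frames: dict[int, str] = {}
    for f in (1, 2, 3):
        for sign, seq in ((1, dna), (-1, rc)):
            sub = seq[f - 1:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sign * f] = str(Seq(sub).translate()) if sub else ""
    return frames


_STD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STD_IDX = np.array([_B62_INDEX[a] for a in _STD_AA])
_S20 = _B62[np.ix_(_STD_IDX, _STD_IDX)]  # 20x20 scores, standard alphabet
_neighborhood_cache: dict[tuple[str, int], tuple[str, ...]] = {}


def neighborhood_words(word: str, threshold: int = 11) -> tuple[str, ...]:
    """All 3-mers over the 20 standard residues scoring >= threshold
    against ``word`` under BLOSUM62 (BLAST-style seed neighborhood)."""
    key = (word, threshold)
    hit = _neighborhood_cache.get(key)
    if hit is not None:
        return hit
    try:
        ia, ib, ic = (_STD_AA.index(c) for c in word)
    except ValueError:
        # seed word contains a nonstandard symbol: match exactly only
        _neighborhood_cache[key] = (word,)
        return (word,)
    scores = (_S20[ia][:, None, None] + _S20[ib][None, :, None]
              + _S20[ic][None, None, :])
    idx = np.argwhere(scores >= threshold)
    words = tuple(_STD_AA[i] + _STD_AA[j] + _STD_AA[k] for i, j, k in idx)
    _neighborhood_cache[key] = words
    return words


def _extend_ungapped(query: str, subject: str, qpos: int, spos: int,
                     word: int, xdrop: float):
    """X-drop extension of an exact word seed along one diagonal.

    Returns (qstart, qend, raw_score) with coordinates half-open in the
    query; the subject extent follows on the same diagonal.
    """
    score = sum(_score(query[qpos + i], subject[spos + i]) for i in range(word))
    # right extension
    best, best_q = score, qpos + word
    cur = score
    qi, si = qpos + word, spos + word
    while qi < len(query) and si < len(subject):
        cur += _score(query[qi], subject[si])
        qi += 1
        si += 1
        if cur > best:
            best, best_q = cur, qi
        elif best - cur > xdrop:
            break
    qend = best_q
    # left extension
    cur = best
    best2, best_q2 = best, qpos
    qi, si = qpos, spos
    while qi > 0 and si > 0:
        qi -= 1
        si -= 1
        cur += _score(query[qi], subject[si])
        if cur > best2:
            best2, best_q2 = cur, qi
        elif best2 - cur > xdrop:
            break
    return best_q2, qend, best2


def _frame_to_genome(frame: int, aa_start: int, aa_end: int, contig_len: int):
    """Map a half-open aa extent in one frame translation to a forward-
    strand nucleotide interval."""
    off = abs(frame) - 1
    a = off + 3 * aa_start
    b = off + 3 * aa_end
    if frame > 0:
        return a, b
    return contig_len - b, contig_len - a


def translated_search(
    protein: SequenceRecord,
    genome: list[SequenceRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_evalue: float = 1e-5,
    word_size: int = 3,
    xdrop: float = 20.0,
    word_threshold: int = 11,
    two_hit_window: int = 40,
) -> list[HSP]:
    """Search a protein against all six frames of every contig.

    Seeding is BLAST-style: 3-mer neighborhood words (every subject word
    scoring >= ``word_threshold`` against a query word) under the
    two-hit rule — extension fires only when two non-overlapping word
    hits share a diagonal within ``two_hit_window`` residues, which
    suppresses lone chance seeds. Ungapped X-drop extension under
    BLOSUM62 starts at the second hit. Only HSPs with E <=
    ``min_evalue`` are returned, with protein coordinates mapped back to
    nucleotide intervals on the correct strand.
    """
    q = protein.residues.upper()
    if len(q) < 10:
        raise ValueError(f"protein {protein.id} shorter than 10 aa")
    bad = set(q) - AA_ALPHABET
    if bad:
        raise ValueError(
            f"protein {protein.id} has non-amino-acid symbols: {sorted(bad)}"
        )
    if not genome:
        return []
    n_total = sum(len(c.residues) for c in genome)
    hsps: list[HSP] = []
    for contig in genome:
        frames = six_frame_translate(contig.residues)
        for frame in (1, 2, 3, -1, -2, -3):
            pep = frames[frame]
            if len(pep) < word_size:
                continue
            index: dict[str, list[int]] = {}
            for j in range(len(pep) - word_size + 1):
                index.setdefault(pep[j:j + word_size], []).append(j)
            seeds_by_diag: dict[int, list[int]] = {}
            for i in range(len(q) - word_size + 1):
                for w in neighborhood_words(q[i:i + word_size], word_threshold):
                    for j in index.get(w, ()):
                        seeds_by_diag.setdefault(j - i, []).append(i)
            found: dict[int, list[tuple[int, int]]] = {}  # diagonal -> q extents
            for diag in sorted(seeds_by_diag):
                positions = sorted(set(seeds_by_diag[diag]))
                for pi, i in enumerate(positions):
                    # two-hit rule: a non-overlapping partner seed must
                    # precede this one on the diagonal within the window
                    partnered = False
                    for p in reversed(positions[:pi]):
                        if i - p > two_hit_window:
                            break
                        if i - p >= word_size:
                            partnered = True
                            break
                    if not partnered:
                        continue
                    if any(s <= i < e for s, e in found.get(diag, ())):
                        continue
                    j = i + diag
                    qs, qe, raw = _extend_ungapped(q, pep, i, j, word_size, xdrop)
                    found.setdefault(diag, []).append((qs, qe))
                    ev = scheme.evalue(raw, len(q), n_total)
                    if ev > min_evalue:
                        continue
                    ss, se = qs + diag, qe + diag
                    ident = sum(q[a] == pep[a + diag] for a in range(qs, qe))
                    g_start, g_end = _frame_to_genome(frame, ss, se, len(contig.residues))
                    hsps.append(
                        HSP(
                            query_id=protein.id,
                            query_start=qs,
                            query_end=qe,
                            interval=GenomicInterval(
                                contig.id, g_start, g_end,
                                "+" if frame > 0 else "-",
                            ),
                            frame=frame,
                            percent_identity=100.0 * ident / (qe - qs),
                            evalue=ev,
                            bitscore=scheme.bitscore(raw),
                            raw_score=raw,
                        )
                    )
    # deduplicate identical extents reached from different seeds
    uniq: dict[tuple, HSP] = {}
    for h in hsps:
        key = (h.query_id, h.interval.contig, h.frame, h.query_start, h.query_end,
               h.interval.start, h.interval.end)
        if key not in uniq:
            uniq[key] = h
    out = sorted(
        uniq.values(),
        key=lambda h: (h.evalue, -h.bitscore, h.interval.contig, h.interval.start),
    )
    return out
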