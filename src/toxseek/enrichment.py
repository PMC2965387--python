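"""Hypergeometric GO-term enrichment.

For a foreground of venom-expressed transcripts against a background
transcript universe, each term's over-representation is scored with the
upper tail of the hypergeometric distribution, P(X >= k) for X ~
Hypergeometric(N, K, n). The tail is computed in log space with lgamma,
exact to well below 1e-12 for any population up to 1e6. No
multiple-testing correction is applied at the fixed cutoff (default
1e-5); Bonferroni can be switched on for exploratory use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TermCounts",
    "EnrichmentResult",
    "hypergeom_log_pmf",
    "hypergeom_upper_tail",
    "go_enrichment",
]


@dataclass(frozen=True)
class TermCounts:
    """k of n foreground and K of N background transcripts carry a term."""

    term: str
    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"{self.term}: need 0 <= k <= min(n, K)")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"{self.term}: need K <= N and n <= N")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    counts: TermCounts
    pvalue: float
    enriched: bool


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_log_pmf(i: int, K: int, n: int, N: int) -> float:
    """log P(X = i) for X ~ Hypergeometric(N, K, n)."""
    if i < max(0, n + K - N) or i > min(n, K):
        return -math.inf
    return _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space."""
    TermCounts("_", k, n, K, N)  # validate
    if k <= max(0, n + K - N):
        return 1.0
    terms = [math.exp(hypergeom_log_pmf(i, K, n, N))
             for i in range(k, min(n, K) + 1)]
    return min(1.0, math.fsum(terms))


def go_enrichment(
    fg: dict[str, set[str]],
    bg: dict[str, set[str]],
    cutoff: float = 1e-5,
    bonferroni: bool = False,
) -> list[EnrichmentResult]:
    """Test every background term for enrichment in the foreground.

    ``fg`` and ``bg`` map transcript id -> set of term ids; the
    foreground transcripts must be a subset of the background. Results
    come back sorted by ascending p-value (ties by term id).
    """
    if not fg:
        raise ValueError("empty foreground")
    missing = sorted(set(fg) - set(bg))
    if missing:
        raise ValueError(f"foreground transcript absent from background: {missing[0]}")
    N, n = len(bg), len(fg)
    bg_count: dict[str, int] = {}
    for terms in bg.values():
        for t in terms:
            bg_count[t] = bg_count.get(t, 0) + 1
    fg_count: dict[str, int] = {}
    for tid, terms in fg.items():
        for t in terms:
            fg_count[t] = fg_count.get(t, 0) + 1
    n_tests = len(bg_count)
    effective_cutoff = cutoff / n_tests if bonferroni else cutoff
    results = []
    for term in sorted(bg_count):
        counts = TermCounts(term=term, k=fg_count.get(term, 0), n=n,
                            K=bg_count[term], N=N)
        p = hypergeom_upper_tail(counts.k, counts.K, counts.n, counts.N)
        results.append(
            EnrichmentResult(term=term, counts=counts, pvalue=p,
                             enriched=p <= effective_cutoff)
        )
    results.sort(key=lambda r: (r.pvalue, r.term))
    return results
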