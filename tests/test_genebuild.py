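"""Chaining, genebuild merging, prediction regions and model projection."""

import numpy as np
import pytest

from toxseek.formats_io import GeneModel, GenomicInterval, ReadAlignment, \
    SequenceRecord
from toxseek.genebuild import (
    HspChain,
    build_enhanced_genebuild,
    chain_hsps,
    choose_model,
    compatible,
    extract_prediction_region,
    project_gene_model,
)
from toxseek.homology import HSP, reverse_complement, translated_search
from toxseek.synth import reverse_translate, _random_protein


def mk_hsp(qs, qe, s, e, strand="+", bit=50.0, ev=1e-9, query="q", contig="c"):
    return HSP(query, qs, qe, GenomicInterval(contig, s, e, strand),
               1 if strand == "+" else -1, 90.0, ev, bit)


def brute_force_best(hsps, max_gap):
    """Exhaustive max-total-bitscore colinear subset (test oracle)."""
    n = len(hsps)
    best = 0.0
    for mask in range(1, 2 ** n):
        subset = [hsps[i] for i in range(n) if mask >> i & 1]
        subset.sort(key=lambda h: (h.interval.start, h.interval.end))
        if all(compatible(a, b, max_gap) for a, b in zip(subset, subset[1:])):
            best = max(best, sum(h.bitscore for h in subset))
    return best


class TestChaining:
    def test_singleton(self):
        h = mk_hsp(0, 50, 100, 250)
        (chain,) = chain_hsps([h], max_gap=1000)
        assert chain.members == [h] and chain.total_bitscore == 50.0

    def test_two_colinear_merge(self):
        a = mk_hsp(0, 50, 100, 250, bit=40)
        b = mk_hsp(50, 100, 1250, 1400, bit=45)
        (chain,) = chain_hsps([a, b], max_gap=2000)
        assert chain.total_bitscore == 85.0
        assert brute_force_best([a, b], 2000) == 85.0

    def test_opposite_strands_stay_separate(self):
        a = mk_hsp(0, 50, 100, 250, "+")
        b = mk_hsp(0, 50, 100, 250, "-")
        chains = chain_hsps([a, b], max_gap=1000)
        assert len(chains) == 2

    def test_partition_every_hsp_once(self):
        rng = np.random.default_rng(11)
        hsps = []
        for _ in range(20):
            s = int(rng.integers(0, 5000))
            qs = int(rng.integers(0, 80))
            hsps.append(mk_hsp(qs, qs + 20, s, s + 60,
                               bit=float(rng.integers(20, 90))))
        chains = chain_hsps(hsps, max_gap=500)
        seen = [id(h) for c in chains for h in c.members]
        assert sorted(seen) == sorted(id(h) for h in hsps)

    def test_weak_chain_discarded(self):
        weak = mk_hsp(0, 50, 100, 250, ev=1e-3)
        assert chain_hsps([weak], max_gap=100) == []

    def test_nonpositive_max_gap_is_error(self):
        with pytest.raises(ValueError):
            chain_hsps([mk_hsp(0, 10, 0, 30)], max_gap=0)

    def test_gap_exceeding_max_splits(self):
        a = mk_hsp(0, 50, 100, 250, bit=40)
        b = mk_hsp(50, 100, 5250, 5400, bit=45)
        chains = chain_hsps([a, b], max_gap=1000)
        assert len(chains) == 2


class TestEnhancedGenebuild:
    def _gene(self, start, end, gid="g1"):
        return GeneModel(id=gid, contig="c", strand="+",
                         exons=[GenomicInterval("c", start, end, "+")],
                         peptide="MK")

    def test_overlapping_chain_attached(self):
        chain = HspChain("q", [mk_hsp(0, 50, 1000, 2000)])
        novel, attached = build_enhanced_genebuild([chain],
                                                   [self._gene(1500, 3000)])
        assert novel == [] and attached == {"g1": [chain]}

    def test_chain_on_bare_contig_is_novel(self):
        chain = HspChain("q", [mk_hsp(0, 50, 1000, 2000, contig="other")])
        novel, attached = build_enhanced_genebuild([chain],
                                                   [self._gene(1500, 3000)])
        assert novel == [chain] and attached == {}

    def test_abutting_half_open_boundary_is_novel(self):
        chain = HspChain("q", [mk_hsp(0, 50, 1000, 1500)])
        novel, attached = build_enhanced_genebuild([chain],
                                                   [self._gene(1500, 3000)])
        assert novel == [chain] and attached == {}


class TestPredictionRegion:
    def test_small_contig_taken_whole(self):
        chain = HspChain("q", [mk_hsp(0, 300, 5000, 6000)])
        r = extract_prediction_region(chain, 8000, flank=10000)
        assert (r.interval.start, r.interval.end) == (0, 8000)

    def test_flank_on_large_sequence(self):
        chain = HspChain("q", [mk_hsp(0, 300, 500000, 501000)])
        r = extract_prediction_region(chain, 1_000_000)
        assert (r.interval.start, r.interval.end) == (490000, 511000)
        assert not r.expanded

    def test_expanded_retry(self):
        chain = HspChain("q", [mk_hsp(0, 300, 500000, 501000)])
        r = extract_prediction_region(chain, 1_000_000, expand=True)
        assert (r.interval.start, r.interval.end) == (400000, 601000)
        assert r.expanded

    def test_span_outside_contig_is_error(self):
        chain = HspChain("q", [mk_hsp(0, 300, 5000, 6000)])
        with pytest.raises(ValueError):
            extract_prediction_region(chain, 5500)


def _plant_gene(seed=0, prot_len=40, strand="+", no_internal_met=False):
    """Single-exon ATG..stop gene in a random contig, plus its chain."""
    rng = np.random.default_rng(seed)
    prot = _random_protein(rng, prot_len)
    if no_internal_met:
        # nearest-upstream-ATG extension would stop at an internal Met
        prot = prot[0] + prot[1:].replace("M", "L")
    cds = reverse_translate(prot, rng) + "TAA"
    left = "".join(rng.choice(list("ACGT"), size=200))
    right = "".join(rng.choice(list("ACGT"), size=200))
    insert = cds if strand == "+" else reverse_complement(cds)
    contig = SequenceRecord("c1", left + insert + right)
    query = SequenceRecord("q", prot)
    hits = translated_search(query, [contig])
    (chain,) = chain_hsps(hits, max_gap=1000)
    return prot, contig, chain


class TestProjection:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exact_single_exon_recovered(self, strand):
        prot, contig, chain = _plant_gene(seed=2, strand=strand)
        model = project_gene_model(chain, [contig])
        assert model.complete
        assert model.peptide == prot
        assert model.strand == strand

    def test_five_prime_extension_recovers_missing_codons(self):
        prot, contig, chain = _plant_gene(seed=4, no_internal_met=True)
        # truncate the chain's only member by 10 codons at the 5' end
        h = chain.members[0]
        trimmed = HSP(h.query_id, h.query_start + 10, h.query_end,
                      GenomicInterval(h.interval.contig,
                                      h.interval.start + 30, h.interval.end,
                                      h.interval.strand),
                      h.frame, h.percent_identity, h.evalue, h.bitscore)
        model = project_gene_model(HspChain("q", [trimmed]), [contig])
        assert model.complete
        assert model.peptide == prot

    def test_contig_edge_without_atg_incomplete(self):
        rng = np.random.default_rng(6)
        prot = _random_protein(rng, 40)[1:]  # drop the Met
        cds = reverse_translate("M" + prot, rng)[3:] + "TAA"  # no ATG at start
        contig = SequenceRecord("c1", cds + "".join(
            rng.choice(list("ACGT"), size=100)))
        h = mk_hsp(1, 39, 0, 114, contig="c1")
        model = project_gene_model(HspChain("q", [h]), [contig])
        assert not model.complete

    def test_internal_stop_flags_incomplete(self):
        rng = np.random.default_rng(8)
        prot = _random_protein(rng, 40)
        cds = reverse_translate(prot, rng)
        cds = cds[:60] + "TGA" + cds[63:] + "TAA"  # poison codon 21
        contig = SequenceRecord("c1", "".join(rng.choice(list("ACGT"), 90))
                                + cds + "".join(rng.choice(list("ACGT"), 90)))
        h = mk_hsp(0, 40, 90, 90 + 120, contig="c1")
        model = project_gene_model(HspChain("q", [h]), [contig])
        assert not model.complete
        assert "*" in model.peptide or model.peptide


class TestChooseModel:
    def _model(self, gid, start, end):
        return GeneModel(id=gid, contig="c", strand="+",
                         exons=[GenomicInterval("c", start, end, "+")],
                         peptide="MK")

    def _reads(self, n_proj, n_sup):
        reads = []
        for i in range(n_proj):
            reads.append(ReadAlignment(f"p{i}", "long",
                                       GenomicInterval("c", 100, 150)))
        for i in range(n_sup):
            reads.append(ReadAlignment(f"s{i}", "long",
                                       GenomicInterval("c", 1000, 1050)))
        return reads

    def test_tie_keeps_supplied(self):
        proj, sup = self._model("p", 90, 200), self._model("s", 950, 1100)
        assert choose_model(proj, sup, self._reads(5, 5)) is sup

    def test_strict_majority_switches_to_projected(self):
        proj, sup = self._model("p", 90, 200), self._model("s", 950, 1100)
        assert choose_model(proj, sup, self._reads(6, 5)) is proj

    def test_no_long_reads_keeps_supplied(self):
        proj, sup = self._model("p", 90, 200), self._model("s", 950, 1100)
        assert choose_model(proj, sup, []) is sup


def test_chain_top_score_matches_enumeration_small():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(2, 7))
        hsps = []
        for _ in range(n):
            s = int(rng.integers(0, 3000))
            qs = int(rng.integers(0, 60))
            hsps.append(mk_hsp(qs, qs + int(rng.integers(5, 30)),
                               s, s + int(rng.integers(30, 120)),
                               bit=float(rng.integers(20, 90))))
        chains = chain_hsps(hsps, max_gap=800)
        top = max(c.total_bitscore for c in chains)
        assert top == pytest.approx(brute_force_best(hsps, 800))
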