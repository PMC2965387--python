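# Methods

## The discovery model

toxseek assumes venom genes can be found by homology alone: venom
toxins across very distant lineages are repeatedly recruited from the
same protein scaffolds, so a curated toxin-protein database searched
against a genome marks candidate loci even when no close relative is
annotated. Candidates are then *validated by expression*: a real venom
gene should be transcribed in the venom gland (deep short-read coverage
or any long read), and should not be broadly expressed across ordinary
tissues. Tissue breadth, not homology with a housekeeping gene, is the
rejection signal — many toxins evolved from, and still resemble,
ordinary proteins, so rejecting on non-venom homology would discard true
positives.

## Translated search

The built-in engine is a teaching-grade TBLASTN equivalent kept simple
enough to audit:

* **Seeding.** 3-mer neighborhood words: a query word seeds at every
  subject position whose word scores ≥ 11 under BLOSUM62 (exact words
  alone lose short, low-identity exons — at 50 % identity a 19-codon
  exon has a ~10 % chance of containing no conserved 3-mer). The
  two-hit rule (two non-overlapping hits on one diagonal within 40
  residues, extension from the second) suppresses lone chance seeds,
  which otherwise glue stretches of translated intron onto real HSPs.
* **Extension.** Ungapped, X-drop 20, trimmed back to the best-scoring
  extent. No gapped pass and no low-complexity (seg) masking: the
  synthetic data contain neither indels nor low-complexity tracts, and
  real runs would ingest genuine BLAST output instead (the
  `--use-precomputed` path accepts 12/13-column tabular hits).
* **Statistics.** Karlin–Altschul with the standard gapped BLOSUM62
  constants λ = 0.267, K = 0.041: b = (λS − ln K)/ln 2 and
  E = m·n·2⁻ᵇ with m the query length and n the total searched length.
  E-value, never bit score, is the selection variable.

Raw HSPs are collected at a permissive reporting threshold (E ≤ 1.0,
`hsp_report_evalue`); the 10⁻⁵ inclusion rule is applied at the *chain*
level (best member), so a weak second-exon HSP can ride along in a chain
anchored by a strong one.

## Chaining and gene models

Within each (query, contig, strand) group, chains maximize total bit
score by dynamic programming over pairs with: genomic starts and ends
both increasing, genomic gap ≤ 40 kb (sized to typical intron spans),
and query advancing in the strand's orientation with ≤ 20 aa overlap.
The overlap tolerance is set to 20 aa because X-drop extension routinely
overruns a splice junction by several codons on *each* flanking HSP end
(chance-positive runs in translated intron sequence); with a tolerance
of 10 aa, genuine two-exon chains were regularly split in two. The top
chain is extracted, its members removed, and the process repeats, so
every HSP lands in exactly one chain.

Gene models are built by projection rather than ab initio prediction
(out of scope): member HSP intervals, trimmed to codon boundaries in
their own frame and with query-coordinate overlaps trimmed off the
upstream exon, become exons; the first exon walks upstream codon by
codon to the nearest in-frame ATG (a stop aborts the walk), the last
exon walks downstream to the nearest in-frame stop. Extension never
leaves the prediction window: whole contig if small, otherwise the chain
span ± 10 kb, retried at ± 100 kb when the first model lacks a start or
stop. Minus-strand chains are handled by reflection onto the reverse
complement. A model with a failed extension or an internal stop is still
emitted, flagged `complete=False` — truncated peptides are expected on
fragmented assemblies and are not grounds for exclusion. Where a
supplied annotation overlaps a chain, the supplied model replaces the
projection unless strictly more long-platform reads overlap the
projected exons (ties keep the supplied model: conservative and
deterministic).

## The evidence cascade

Filter order: redundancy → read support → exon–HSP screen → tissue
breadth. The rejections are conjunctive, so the *accepted* set does not
depend on the order; the order only decides which label a
multiply-failing candidate gets, with statuses
`redundant`, `rejected_no_read_support`, `rejected_no_exon_hsp`,
`rejected_broad_expression`, `putative`, `probable`.

* Read support: ≥ 10 short-platform OR ≥ 1 long-platform reads
  overlapping any exon by ≥ 1 bp, strand-agnostic, each read counted
  once per gene.
* Exon–HSP screen: ≥ 1 member HSP overlaps ≥ 1 exon by ≥ 1 bp.
* Tissue filter: a tissue counts as expressing the candidate iff some
  EST has a translated-search hit at E ≤ 10⁻⁴ with ≥ 95 % identity
  covering ≥ 90 % of the EST — a reproducible codification of a manual
  "near-100 % match spanning the whole read" check. Candidates hitting
  ≥ 3 of the surveyed tissues are rejected; the threshold is
  deliberately loose because genuine venom genes are known to leak into
  some non-venom tissues. Zero tissues ⇒ `probable`, one or two ⇒
  `putative`.
* Redundancy: greedy clustering by descending peptide length; a
  candidate is redundant iff it aligns to a kept candidate at ≥ 97 %
  identity over ≥ 90 % of the shorter peptide (split-assembly copies);
  the longest copy represents the cluster.
* Signal-peptide presence, when supplied, is carried as annotation only
  and never used for exclusion.

Family assignment is label propagation from the best protein–protein
hit against the toxin database (BLOSUM62, 11/1 gaps, same
Karlin–Altschul machinery, n = total database length), requiring
E < 10⁻⁴ strictly; ties break by higher bit score, then lexicographic
hit id, making the result invariant to database order.

## Enrichment statistics

GO-term enrichment uses the upper tail P(X ≥ k) of
Hypergeometric(N, K, n), computed term-by-term in log space (lgamma)
and summed with compensated addition; accuracy is ~10⁻¹⁵ absolute,
verified against exact rational enumeration. No multiple-testing
correction is applied at the fixed 10⁻⁵ cutoff, matching the discovery
protocol; a Bonferroni switch exists for exploratory use, off by
default. Terms are tested exactly as supplied — no GO-graph ancestor
propagation.

## Phylogenetics

Distances are p-distances with pairwise deletion: each pair of rows is
compared only over columns where neither has a gap (a pair sharing no
such column is an error). Trees are Saitou–Nei neighbor joining with the
standard Q criterion; ties in Q break to the smallest index pair and
negative estimated branch lengths clamp to zero, so runs are
bit-reproducible. On an additive matrix NJ provably returns the
generating topology with exact branch lengths, which is the basis of the
consistency tests. Bootstrap resamples alignment columns with
replacement (seeded), rebuilds NJ per replicate, and reports per-edge
support as the percentage of replicates containing the bipartition; the
customary "hide < 50" rule is presentation-only. Input alignments are
supplied (aligned FASTA); MSA construction, model-based distance
corrections and rooting are out of scope.

## The synthetic study

`toxseek simulate` emulates the structure of a venom-gland
transcriptome study: a genome of 6 × 20 kb contigs carrying planted
toxin genes — reverse-translated (uniform synonymous codons), mutated
copies of the database proteins at 45–70 % identity (substitutions only,
BLOSUM-positive where possible, initial Met preserved), a quarter of
them with one intron at a codon boundary — plus decoy genes with no
toxin homology; Poisson read counts per gene (mean 20 short / 2 long)
placed uniformly over exons; six tissue EST sets in which 25 % of
planted genes appear in exactly three tissues (full-length cDNA plus one
unrelated housekeeping EST per tissue); a supplied annotation covering
roughly a third of planted genes, to exercise both genebuild branches;
GO maps with one term enriched among venom transcripts by construction;
and a truth table whose expected statuses follow from the generator's
own draws by the cascade rules. Genes of one family are placed on
distinct contigs so chaining at the 40 kb gap default cannot bridge two
loci of the same query. All randomness flows from one seed and outputs
are byte-identical across runs.

What the generator does **not** emulate — sequencing error, indels,
low-complexity sequence, alternative isoforms, paralog clusters beyond
family membership, fragmented assemblies — bounds what a passing suite
shows: the pipeline's logic and statistics are correct on clean data;
sensitivity on real, noisy data is inherited from whichever real search
engine supplies the precomputed hits.

## Problem sizes and numerical choices

Tests and the acceptance script run the full study at the default scale
(12 planted genes + 6 decoys on a 120 kb genome, ~400 reads), 200
chaining groups of ≤ 8 HSPs against exhaustive enumeration, all
hypergeometric parameter sets with N ≤ 12 against exact rational
arithmetic (tolerance 10⁻¹²), 100 random 5–8-taxon trees (branch
lengths to 10⁻⁹), and 1000 random peptides against a regex motif
oracle — each component chosen so its oracle is exact rather than
approximate. Degenerate inputs are defined, not guessed: empty genome ⇒
empty hit list; empty tissue map ⇒ empty profile over zero surveyed
tissues; a chain with no codon-aligned material is a skipped, logged
locus; k = 0 ⇒ p = 1 exactly.

## Known limitations

* The built-in search is ungapped; frameshifts or indels between query
  and genome break an HSP in two and are not repaired.
* Splice sites are not modeled: exon boundaries are HSP boundaries, so
  a projected peptide can gain or lose a few junction residues; the
  EST coverage check absorbs small distortions but large ones could
  cost a tissue hit.
* The 5' extension stops at the *nearest* in-frame ATG, which may be an
  internal Met when the true start lies further upstream.
* One toxin-database protein per family is assumed sufficient to anchor
  its loci; a sparse database lowers recall in the same way it would
  for any homology-based method.
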