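# toxseek

Homology-guided discovery of venom genes in a genome, built for the
setting where no closely related venomous species exists to borrow
annotations from (the motivating case is the platypus, whose venom-gland
transcriptome must be interpreted through homology with toxins of
distant lineages — snakes, shrews, stonefish, spiders, sea anemones).

Given

* genome contigs (FASTA),
* a toxin protein database with family labels in the headers
  (`>id family=kunitz`),
* venom-gland read alignments from a short-read (Illumina-like, 36 nt)
  and a long-read (454-like, ~180 nt) platform,
* EST collections from non-venom tissues, and
* transcript-to-GO maps,

the pipeline produces classified toxin-gene candidates:

1. **Translated search** — every database protein is searched against
   all six reading frames of the genome (TBLASTN-style: 3-mer
   neighborhood-word seeds with the two-hit rule, ungapped X-drop
   extension under BLOSUM62, Karlin–Altschul statistics
   b = (λS − ln K)/ln 2, E = m·n·2⁻ᵇ). Precomputed BLAST tabular output
   can be ingested instead.
2. **HSP chaining** — colinear high-scoring segment pairs are grouped
   per (query, contig, strand) by a score-maximizing dynamic program; a
   chain is kept iff its best member has E ≤ 10⁻⁵.
3. **Enhanced genebuild** — chains overlapping an existing annotation
   attach to that gene; the rest are novel loci. Novel loci are turned
   into gene models by projecting the chain's HSPs onto the genome and
   extending to the nearest in-frame ATG and stop (with a 10 kb
   prediction window, widened to 100 kb when the model comes back
   incomplete). Where a supplied model and a projection overlap, the
   supplied model wins unless strictly more long-platform reads support
   the projection.
4. **Evidence cascade** — a candidate survives iff it has venom-gland
   read support (≥ 10 short reads OR ≥ 1 long read over its exons), at
   least one toxin HSP hits an exon, it is not a redundant copy
   (≥ 97 % identity over ≥ 90 % of the shorter peptide), and it is not
   expressed in ≥ 3 of the surveyed non-venom tissues (EST hit at
   E ≤ 10⁻⁴, ≥ 95 % identity, covering ≥ 90 % of the EST). Survivors
   expressed in **zero** non-venom tissues are `probable` venom genes;
   the rest are `putative`.
5. **Annotation** — toxin family by best database hit (E < 10⁻⁴, ties
   by bit score then id), zinc-binding-motif scan (HEXXHXXGXXH),
   domain-order subsequence checks, hypergeometric GO-term enrichment
   P(X ≥ k), X ~ Hypergeom(N, K, n) at cutoff 10⁻⁵, and
   neighbor-joining trees (p-distance with pairwise deletion,
   column-resampling bootstrap, Newick output).

A seeded generator (`toxseek simulate`) emits a complete toy study —
genome with planted mutated toxin genes and decoys, read alignments,
tissue ESTs, GO maps, and a ground-truth table — so the whole cascade is
testable without any downloads.

## Worked example

```sh
toxseek simulate --seed 1 --outdir demo
toxseek run demo/config.toml
```

prints

```
wrote toy study with 12 planted toxin genes and 6 decoys to demo
candidates=12 putative+probable=9 probable=9
```

At seed 1 the generator plants 3 toxin families × 4 genes (45–70 %
identity to their database proteins, a quarter of them also expressed in
three non-venom tissues) plus 6 decoy genes. The run finds 12 candidate
loci, rejects the 3 broadly expressed ones, and classifies the 9
venom-restricted genes as `probable` — matching the truth table exactly;
no decoy ever becomes a candidate. `demo/results/` then contains
`candidates.tsv` (one row per candidate: coordinates, read counts,
tissues, family, status), `models.gff3`, `peptides.fasta`,
`enrichment.tsv` (at seed 1 exactly one GO term, the one planted as
venom-enriched, passes the 10⁻⁵ cutoff), `tree.nwk` (bootstrapped NJ
tree of the first family), `funnel.json` with the per-filter counts, and
a `run_log.txt` listing every threshold used.

A typical `candidates.tsv` row:

```
kunitz_g1  contig1  612  879  +  1  19  2  .  kunitz  64.4  probable
```

i.e. a single-exon candidate on contig1 with 19 short and 2 long reads,
no non-venom tissue hits, best family hit `kunitz` at 64.4 % identity —
a probable venom gene.

## Layout

```
src/toxseek/
  formats_io.py   FASTA / GFF3 / BLAST-tabular / read-table I/O
  homology.py     six-frame translated search, scoring statistics
  genebuild.py    HSP chaining, enhanced genebuild, model projection
  filters.py      read-support / exon-HSP / tissue / redundancy cascade
  families.py     family assignment, motif scan, domain order
  enrichment.py   hypergeometric GO enrichment
  phylo.py        p-distance, neighbor joining, bootstrap, Newick
  synth.py        seeded toy-study generator with ground truth
  pipeline.py     config-driven orchestration
  cli.py          `toxseek simulate|search|predict|classify|annotate|enrich|tree|run`
```

See `docs/methods.md` for the model, parameter defaults and known
limitations.
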