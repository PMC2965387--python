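"""End-to-end orchestration: search -> chain -> genebuild -> predict ->
evidence -> classify -> annotate -> enrich (-> tree).

Driven by one flat TOML config in which every stage threshold has a named
key with its default (search E <= 1e-5; family homology E < 1e-4; read
support >= 10 short or >= 1 long; tissue rejection at >= 3 of 6; flanks
10 kb / 100 kb; enrichment cutoff 1e-5), so the whole cascade is
auditable from a single file. Emits the candidate report, gene models,
peptides, the enrichment table, a run log with the counts entering and
leaving every filter, and a machine-readable funnel JSON.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import families as fam_mod
from . import filters as flt
from .enrichment import go_enrichment
from .formats_io import (
    GeneModel,
    read_fasta,
    read_blast_tabular,
    read_gff,
    read_read_alignments,
    write_blast_tabular,
    write_fasta,
    write_gff,
    SequenceRecord,
)
from .genebuild import (
    build_enhanced_genebuild,
    chain_hsps,
    choose_model,
    extract_prediction_region,
    project_gene_model,
)
from .homology import ScoringScheme, translated_search
from .phylo import bootstrap_support, read_alignment_fasta, write_newick

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    genome: Path
    toxin_db: Path
    read_alignments: Path
    outdir: Path
    annotation: Path | None = None
    tissues: dict[str, Path] = field(default_factory=dict)
    go_foreground: Path | None = None
    go_background: Path | None = None
    alignment: Path | None = None
    precomputed_hits: Path | None = None
    seed: int = 1
    # thresholds (defaults are the cascade's published values)
    min_evalue: float = 1e-5
    hsp_report_evalue: float = 1.0  # raw HSP collection; chains filter at min_evalue
    family_evalue: float = 1e-4
    short_min: int = 10
    long_min: int = 1
    tissue_max: int = 3
    flank: int = 10000
    max_flank: int = 100000
    max_gap: int = 40000
    enrichment_cutoff: float = 1e-5
    est_min_identity: float = 95.0
    est_min_coverage: float = 0.90
    est_max_evalue: float = 1e-4
    redundancy_identity: float = 97.0
    redundancy_coverage: float = 0.90
    bootstrap_replicates: int = 100

    def __post_init__(self):
        if not (0 < self.min_evalue and 0 < self.family_evalue):
            raise ValueError("E-value thresholds must be positive")
        if self.flank > self.max_flank:
            raise ValueError("flank must not exceed max_flank")
        if self.tissue_max < 1:
            raise ValueError("tissue_max must be >= 1")


_THRESHOLD_KEYS = (
    "min_evalue hsp_report_evalue "
    "family_evalue short_min long_min tissue_max flank max_flank "
    "max_gap enrichment_cutoff est_min_identity est_min_coverage "
    "est_max_evalue redundancy_identity redundancy_coverage "
    "bootstrap_replicates"
).split()


def load_config(path) -> PipelineConfig:
    """Read a pipeline TOML config; relative paths resolve against it."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = path.parent
    inputs = raw.get("inputs", {})

    def p(section, key, required=False):
        val = section.get(key)
        if val is None:
            if required:
                raise PipelineError(f"config: missing input path {key!r}")
            return None
        return base / val

    tissues = {name: base / rel
               for name, rel in inputs.get("tissues", {}).items()}
    thresholds = raw.get("thresholds", {})
    kwargs = {k: thresholds[k] for k in _THRESHOLD_KEYS if k in thresholds}
    outputs = raw.get("outputs", {})
    return PipelineConfig(
        genome=p(inputs, "genome", required=True),
        toxin_db=p(inputs, "toxin_db", required=True),
        read_alignments=p(inputs, "read_alignments", required=True),
        annotation=p(inputs, "annotation"),
        go_foreground=p(inputs, "go_foreground"),
        go_background=p(inputs, "go_background"),
        alignment=p(inputs, "alignment"),
        precomputed_hits=p(inputs, "precomputed_hits"),
        tissues=tissues,
        outdir=base / outputs.get("outdir", "results"),
        seed=int(raw.get("seed", 1)),
        **kwargs,
    )


def _read_go_map(path) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tid, term = line.split("\t")[:2]
            mapping.setdefault(tid, set()).add(term)
    return mapping


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report files; returns the funnel.

    Any stage failure raises PipelineError naming the stage; outputs
    already written are renamed with a .partial suffix.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def log(msg: str):
        log_lines.append(msg)

    stage = "load"
    try:
        for key in ("genome", "toxin_db", "read_alignments"):
            pth = getattr(config, key)
            if pth is None or not Path(pth).exists():
                raise FileNotFoundError(f"missing input: {key}")
        genome = read_fasta(config.genome)
        genome_map = {r.id: r.residues for r in genome}
        contig_len = {r.id: len(r.residues) for r in genome}
        toxin_db = read_fasta(config.toxin_db)
        reads = read_read_alignments(config.read_alignments)
        annotation = (read_gff(config.annotation)
                      if config.annotation and Path(config.annotation).exists()
                      else [])
        est_by_tissue = {}
        for tissue, pth in sorted(config.tissues.items()):
            est_by_tissue[tissue] = read_fasta(pth) if Path(pth).exists() else []
        scheme = ScoringScheme()
        log(f"inputs: {len(genome)} contigs, {len(toxin_db)} toxin proteins, "
            f"{len(reads)} read alignments, {len(annotation)} supplied genes, "
            f"{len(est_by_tissue)} tissues")

        stage = "search"
        if config.precomputed_hits:
            hsps = read_blast_tabular(config.precomputed_hits)
            hsps = [h for h in hsps if h.evalue <= config.hsp_report_evalue]
        else:
            hsps = []
            for prot in toxin_db:
                hsps.extend(translated_search(
                    prot, genome, scheme=scheme,
                    min_evalue=config.hsp_report_evalue))
        write_blast_tabular(hsps, outdir / "hits.tsv")
        written.append(outdir / "hits.tsv")
        log(f"search: {len(hsps)} HSPs at E <= {config.hsp_report_evalue}")

        stage = "chain"
        chains = chain_hsps(hsps, max_gap=config.max_gap,
                            e_max=config.min_evalue)
        log(f"chain: {len(chains)} chains kept with best E <= "
            f"{config.min_evalue} (max_gap={config.max_gap})")

        stage = "genebuild"
        novel, attached = build_enhanced_genebuild(chains, annotation)
        log(f"genebuild: {len(novel)} novel chains, "
            f"{len(attached)} annotated genes with toxin match")

        stage = "predict"
        candidates: list[flt.CandidateRecord] = []
        chain_of: dict[str, object] = {}
        seen_ids: set[str] = set()
        for chain in novel:
            span = chain.span
            region = extract_prediction_region(
                chain, contig_len[span.contig], config.flank, config.max_flank)
            try:
                model = project_gene_model(chain, genome_map, region)
            except ValueError as exc:
                log(f"predict: skipped chain {chain.chain_id}: {exc}")
                continue
            if not model.complete:
                region = extract_prediction_region(
                    chain, contig_len[span.contig], config.flank,
                    config.max_flank, expand=True)
                model = project_gene_model(chain, genome_map, region)
            base_id = f"novel_{span.contig}_{span.start}_{'p' if span.strand == '+' else 'm'}"
            gid = base_id
            k = 2
            while gid in seen_ids:
                gid = f"{base_id}_{k}"
                k += 1
            seen_ids.add(gid)
            model.id = gid
            candidates.append(flt.CandidateRecord(model=model))
            chain_of[gid] = chain
        supplied_by_id = {g.id: g for g in annotation}
        for gid in sorted(attached):
            best_chain = max(attached[gid], key=lambda c: c.total_bitscore)
            supplied = supplied_by_id[gid]
            try:
                projected = project_gene_model(best_chain, genome_map)
            except ValueError:
                projected = supplied
            model = choose_model(projected, supplied, reads)
            model = GeneModel(id=gid, contig=model.contig, strand=model.strand,
                              exons=list(model.exons), peptide=model.peptide,
                              source=model.source, complete=model.complete)
            candidates.append(flt.CandidateRecord(model=model))
            chain_of[gid] = best_chain
        candidates.sort(key=lambda c: (c.model.contig, c.model.span.start,
                                       c.model.id))
        log(f"predict: {len(candidates)} candidate gene models")

        stage = "evidence"
        for cand in candidates:
            cand.support = flt.count_read_support(cand.model, reads)
            cand.exon_hsp_ok = flt.exon_hsp_screen(
                cand.model, chain_of[cand.model.id])
            cand.profile = flt.tissue_expression_profile(
                cand.model.peptide, est_by_tissue,
                min_identity=config.est_min_identity,
                min_read_coverage=config.est_min_coverage,
                max_evalue=config.est_max_evalue,
                scheme=scheme, gene_id=cand.model.id)
        flt.remove_redundancy(candidates,
                              min_identity=config.redundancy_identity,
                              min_cov=config.redundancy_coverage)

        stage = "classify"
        flt.classify(candidates, short_min=config.short_min,
                     long_min=config.long_min, tissue_max=config.tissue_max)
        status_counts = {s: 0 for s in flt.STATUSES}
        for cand in candidates:
            status_counts[cand.status] += 1
        accepted = status_counts["putative"] + status_counts["probable"]
        log(f"classify: {len(candidates)} in -> "
            + ", ".join(f"{k}={v}" for k, v in status_counts.items()))
        log(f"funnel: candidates {len(candidates)} -> read/tissue-supported "
            f"{accepted} putative of which {status_counts['probable']} probable")

        stage = "annotate"
        for cand in candidates:
            fa = fam_mod.assign_family(
                SequenceRecord(cand.model.id, cand.model.peptide or "X"),
                toxin_db, max_evalue=config.family_evalue, scheme=scheme)
            if fa is not None:
                cand.family = fa.family
                cand.best_family_identity = fa.percent_identity
        n_motif = sum(
            1 for c in candidates
            if fam_mod.motif_scan(c.model.peptide, fam_mod.ZINC_BINDING_MOTIF))
        log(f"annotate: {sum(1 for c in candidates if c.family)} candidates "
            f"assigned a family; {n_motif} carry the zinc-binding motif")

        stage = "enrich"
        enrichment_rows = []
        if config.go_foreground and config.go_background:
            fg = _read_go_map(config.go_foreground)
            bg = _read_go_map(config.go_background)
            results = go_enrichment(fg, bg, cutoff=config.enrichment_cutoff)
            enrichment_rows = results
            n_enriched = sum(r.enriched for r in results)
            log(f"enrich: {len(results)} terms tested, {n_enriched} enriched "
                f"at {config.enrichment_cutoff}")

        stage = "tree"
        newick = None
        if config.alignment and Path(config.alignment).exists():
            aln = read_alignment_fasta(config.alignment)
            tree = bootstrap_support(aln, config.bootstrap_replicates,
                                     seed=config.seed)
            newick = write_newick(tree)
            log(f"tree: NJ over {len(aln.names)} taxa, "
                f"{config.bootstrap_replicates} bootstrap replicates")

        stage = "report"
        funnel = {
            "hsps": len(hsps),
            "chains": len(chains),
            "novel_chains": len(novel),
            "attached_genes": len(attached),
            "candidates": len(candidates),
            **status_counts,
            "accepted_putative": accepted,
        }
        cols = ("gene_id contig start end strand n_exons short_reads "
                "long_reads tissues family pct_identity status").split()
        with open(outdir / "candidates.tsv", "w") as fh:
            fh.write("# " + "\t".join(cols) + "\n")
            for c in candidates:
                span = c.model.span
                fh.write("\t".join(str(x) for x in (
                    c.model.id, span.contig, span.start, span.end,
                    c.model.strand, len(c.model.exons), c.support.short_count,
                    c.support.long_count,
                    ",".join(sorted(c.profile.tissues_with_hits)) or ".",
                    c.family or ".",
                    f"{c.best_family_identity:.1f}" if c.best_family_identity
                    is not None else ".",
                    c.status)) + "\n")
        written.append(outdir / "candidates.tsv")
        write_gff([c.model for c in candidates], outdir / "models.gff3")
        written.append(outdir / "models.gff3")
        write_fasta([SequenceRecord(c.model.id, c.model.peptide or "X")
                     for c in candidates], outdir / "peptides.fasta")
        written.append(outdir / "peptides.fasta")
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("# term\tk\tn\tK\tN\tpvalue\tenriched\n")
            for r in enrichment_rows:
                c = r.counts
                fh.write(f"{r.term}\t{c.k}\t{c.n}\t{c.K}\t{c.N}\t"
                         f"{r.pvalue:.6g}\t{int(r.enriched)}\n")
        written.append(outdir / "enrichment.tsv")
        if newick is not None:
            (outdir / "tree.nwk").write_text(newick + "\n")
            written.append(outdir / "tree.nwk")
        with open(outdir / "funnel.json", "w") as fh:
            json.dump(funnel, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(outdir / "funnel.json")
        thresholds = {k: getattr(config, k) for k in _THRESHOLD_KEYS}
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write("# toxseek run log\n")
            for k in sorted(thresholds):
                fh.write(f"threshold {k} = {thresholds[k]}\n")
            for line in log_lines:
                fh.write(line + "\n")
        return funnel
    except Exception as exc:
        for pth in written:
            if pth.exists():
                pth.rename(pth.with_suffix(pth.suffix + ".partial"))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage}: {exc}") from exc
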