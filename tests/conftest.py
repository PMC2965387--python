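"""Shared fixtures: the seed-1 toy study, generated once per session."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from toxseek.cli import write_pipeline_config
from toxseek.pipeline import load_config, run_pipeline
from toxseek.synth import GeneratorConfig, TruthTable, generate


@dataclass
class Study:
    dir: Path
    truth: TruthTable
    funnel: dict
    candidates: list[dict]


def _parse_candidates(path: Path) -> list[dict]:
    rows = []
    header = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            header = line[1:].split()
            continue
        rows.append(dict(zip(header, line.split("\t"))))
    for r in rows:
        for k in ("start", "end", "n_exons", "short_reads", "long_reads"):
            r[k] = int(r[k])
    return rows


@pytest.fixture(scope="session")
def study(tmp_path_factory) -> Study:
    """Default generator conditions (seed 1) run through the full pipeline."""
    d = tmp_path_factory.mktemp("study")
    truth = generate(GeneratorConfig(seed=1), d)
    cfg_path = write_pipeline_config(d, seed=1)
    funnel = run_pipeline(load_config(cfg_path))
    cands = _parse_candidates(d / "results" / "candidates.tsv")
    return Study(dir=d, truth=truth, funnel=funnel, candidates=cands)


def match_truth(study: Study, cand: dict):
    """Truth row overlapping a candidate's locus (or None)."""
    return study.truth.match_locus(cand["contig"], cand["start"], cand["end"])
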