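"""Orchestration: run every evaluation stage from one YAML config,
assemble the metric table, and rank the assemblies.

A run evaluates each configured assembly with whatever inputs it has —
contiguity always; accuracy from a coverage track (or ingested
sequence counts); k-mer spectra where reads are given; completeness and
repeat summaries where status / hit tables are given — then builds the
seven-metric table and produces rank-score and z-score orderings.
Stages with missing optional inputs are skipped with a logged notice.

Also provides the data-type capability lookup: which sequencing
strategies can resolve which analysis goals.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from asmeval import accuracy as acc
from asmeval import content as cnt
from asmeval import contiguity as ctg
from asmeval import kmer_spectra as kms
from asmeval import ranking as rnk
from asmeval.errors import ConfigError
from asmeval.ranking import DEFAULT_METRICS

log = logging.getLogger(__name__)


@dataclass
class AssemblyEntry:
    name: str
    fasta: str
    provenance: list[str] = field(default_factory=list)
    coverage: str | None = None
    busco_table: str | None = None
    repeats: str | None = None
    reads: str | None = None
    # ingested evaluator outputs, carried through unchanged
    fcd_errors: int | None = None
    sequences_before: int | None = None
    sequences_after: int | None = None


@dataclass
class EvaluationConfig:
    assemblies: list[AssemblyEntry]
    cost_model: str | None = None
    metrics: list[str] = field(default_factory=lambda: list(DEFAULT_METRICS))
    output_dir: str = "asmeval_out"
    seed: int = 0
    baseline_assembly: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assemblies:
            raise ConfigError("config lists no assemblies")
        names = [a.name for a in self.assemblies]
        if len(names) != len(set(names)):
            raise ConfigError("assembly names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvaluationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "assemblies" not in data:
            raise ConfigError(f"{path}: expected a mapping with 'assemblies'")
        entries = [AssemblyEntry(**e) for e in data.pop("assemblies")]
        return cls(assemblies=entries, **data)


#: Defaults for every tunable stage parameter.
DEFAULT_PARAMS = {
    "min_len": 1000,          # scaffold length filter, bp
    "min_gap_run": 25,        # Ns to break scaffolds into contigs
    "thresholds": [100_000, 1_000_000, 39_000_000],
    "gene_len": 25_000,       # "gene-sized scaffold" boundary, bp
    "min_cov": 5,             # error-free coverage threshold
    "min_run": 100,           # dropout run length for a breakpoint, bp
    "k": 31,                  # k-mer size
    "max_copy": 10,
    "max_mult": 200,
}


@dataclass
class EvaluationResult:
    contiguity: dict[str, ctg.ContiguityReport]
    accuracy: dict[str, acc.AccuracyReport]
    break_comparisons: list[acc.BreakComparison]
    busco: dict[str, dict]
    repeats: dict[str, cnt.RepeatReport]
    spectra: dict[str, kms.SpectraMatrix]
    metric_table: pd.DataFrame | None
    rank_result: rnk.RankResult | None
    z_result: rnk.ZResult | None
    warnings: list[str] = field(default_factory=list)


def run_evaluation(config: EvaluationConfig) -> EvaluationResult:
    params = {**DEFAULT_PARAMS, **config.params}
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cost_model = (rnk.CostModel.from_yaml(config.cost_model)
                  if config.cost_model else None)

    contiguity: dict[str, ctg.ContiguityReport] = {}
    accuracy: dict[str, acc.AccuracyReport] = {}
    busco: dict[str, dict] = {}
    busco_tables: dict[str, cnt.OrthologStatusTable] = {}
    repeats: dict[str, cnt.RepeatReport] = {}
    spectra: dict[str, kms.SpectraMatrix] = {}
    notes: list[str] = []

    for entry in config.assemblies:
        t0 = time.perf_counter()
        a = ctg.read_assembly(entry.fasta, name=entry.name,
                              provenance=entry.provenance)
        contiguity[entry.name] = ctg.contiguity_report(
            a, thresholds=params["thresholds"], gene_len=params["gene_len"],
            min_len=params["min_len"], min_gap_run=params["min_gap_run"])

        if entry.coverage:
            tracks = acc.read_coverage_tracks(
                entry.coverage, lengths={r.id: r.length for r in a.records})
            accuracy[entry.name] = acc.accuracy_report(
                a, tracks, min_cov=params["min_cov"],
                min_run=params["min_run"], fcd_errors=entry.fcd_errors)
        else:
            notes.append(f"{entry.name}: no coverage track, accuracy skipped")

        if entry.busco_table:
            table = cnt.read_busco_table(entry.busco_table,
                                         assembly_name=entry.name)
            busco_tables[entry.name] = table
            busco[entry.name] = busco_summary_dict(table)

        if entry.repeats:
            hits = cnt.read_repeat_hits(entry.repeats)
            repeats[entry.name] = cnt.repeat_report(
                hits, assembly_size=a.total_size, assembly_name=entry.name)

        if entry.reads:
            reads = kms.read_sequences(entry.reads)
            read_map = kms.count_kmers(reads, k=params["k"])
            asm_map = kms.count_kmers((r.seq for r in a.records),
                                      k=params["k"])
            spectra[entry.name] = kms.spectra_matrix(
                read_map, asm_map, max_copy=params["max_copy"],
                max_mult=params["max_mult"])
        log.info("%s: evaluated in %.1f s", entry.name,
                 time.perf_counter() - t0)

    break_comparisons = _ingested_break_comparisons(config, notes)

    metric_table = build_metric_table(
        config, contiguity, accuracy, busco_tables, cost_model, notes)
    rank_result = z_result = None
    if metric_table is not None:
        rank_result, z_result = rnk.rank_assemblies(metric_table)

    _write_outputs(outdir, contiguity, accuracy, break_comparisons,
                   busco_tables, repeats, spectra, metric_table,
                   rank_result, z_result)
    for n in notes:
        log.warning(n)
    return EvaluationResult(
        contiguity=contiguity, accuracy=accuracy,
        break_comparisons=break_comparisons, busco=busco, repeats=repeats,
        spectra=spectra, metric_table=metric_table,
        rank_result=rank_result, z_result=z_result, warnings=notes)


def busco_summary_dict(table: cnt.OrthologStatusTable) -> dict:
    return {cat: {"count": n, "pct": p}
            for cat, (n, p) in cnt.busco_summary(table).items()}


def _ingested_break_comparisons(config: EvaluationConfig,
                                notes: list[str],
                                ) -> list[acc.BreakComparison]:
    """Break accounting from ingested sequence counts, against the
    configured baseline assembly."""
    have = [e for e in config.assemblies
            if e.sequences_before is not None and e.sequences_after is not None]
    if not have:
        return []
    baseline_name = config.baseline_assembly or have[0].name
    baseline = next((e for e in have if e.name == baseline_name), None)
    if baseline is None:
        notes.append(f"baseline {baseline_name!r} lacks sequence counts; "
                     "break comparison skipped")
        return []
    base_breaks = acc.reapr_breaks(baseline.sequences_before,
                                   baseline.sequences_after)
    return [acc.compare_breaks(e.name, e.sequences_before,
                               e.sequences_after, base_breaks)
            for e in have]


def build_metric_table(config: EvaluationConfig,
                       contiguity: Mapping[str, ctg.ContiguityReport],
                       accuracy: Mapping[str, acc.AccuracyReport],
                       busco_tables: Mapping[str, cnt.OrthologStatusTable],
                       cost_model: rnk.CostModel | None,
                       notes: list[str]) -> pd.DataFrame | None:
    """Assemble the requested metrics for every assembly that has them
    all; ranking needs at least two such assemblies."""
    prov = {e.name: e.provenance for e in config.assemblies}
    rows = {}
    for name, crep in contiguity.items():
        row: dict[str, float] = {}
        row["scaffold_n50"] = crep.scaffold_n50
        row["contig_n50"] = crep.contig_n50
        row["pct_genome_ge_25kb"] = crep.pct_genome_ge_gene_len
        arep = accuracy.get(name)
        if arep is not None:
            row["broken_scaffold_n50"] = arep.broken_n50
            row["summary_score"] = arep.summary_score
            if cost_model is not None:
                cost = rnk.assembly_cost(prov[name], cost_model)
                row["broken_n50_per_1000"] = rnk.value_for_money(
                    arep.broken_n50, cost)
        table = busco_tables.get(name)
        if table is not None:
            row["single_copy_orthologs"] = cnt.busco_summary(table)["single"][0]
        rows[name] = row
    wanted = [m for m in config.metrics]
    complete = {n: r for n, r in rows.items()
                if all(m in r for m in wanted)}
    if len(complete) < 2:
        notes.append(
            f"only {len(complete)} assemblies carry all metrics "
            f"{wanted}; ranking skipped")
        return None
    skipped = sorted(set(rows) - set(complete))
    if skipped:
        notes.append(f"assemblies missing metrics, excluded from ranking: "
                     f"{skipped}")
    return pd.DataFrame.from_dict(
        {n: {m: complete[n][m] for m in wanted} for n in complete},
        orient="index")[wanted]


def _write_outputs(outdir: Path, contiguity, accuracy, break_comparisons,
                   busco_tables, repeats, spectra, metric_table,
                   rank_result, z_result) -> None:
    ctg.write_contiguity_reports(list(contiguity.values()),
                                 outdir / "contiguity.tsv",
                                 outdir / "contiguity.json")
    if accuracy:
        acc.accuracy_table(accuracy.values()).to_csv(
            outdir / "accuracy.tsv", sep="\t", index=False)
    if break_comparisons:
        acc.break_table(break_comparisons).to_csv(
            outdir / "break_comparison.tsv", sep="\t", index=False)
    if busco_tables:
        cnt.busco_table(busco_tables.values()).to_csv(
            outdir / "busco_summary.tsv", sep="\t", index=False)
    if repeats:
        cnt.repeat_table(repeats.values()).to_csv(
            outdir / "repeats.tsv", sep="\t", index=False)
    for name, matrix in spectra.items():
        kms.write_matrix(matrix, outdir / f"spectra_{name}.tsv")
    if metric_table is not None:
        metric_table.to_csv(outdir / "metric_table.tsv", sep="\t")
    if rank_result is not None and z_result is not None:
        rnk.write_ranking(rank_result, z_result, outdir)


def synthetic_metric_table(study, assembly_cost_usd: float = 30_000.0,
                           ) -> pd.DataFrame:
    """Seven-metric table for a synthetic gradient study.

    All study assemblies share one data-type provenance, so a single
    cost applies and the value-for-money column is broken N50 scaled by
    that cost.
    """
    rows = {}
    for asm, tracks, table in zip(study.assemblies, study.tracks,
                                  study.status_tables):
        crep = ctg.contiguity_report(asm)
        arep = acc.accuracy_report(asm, tracks)
        rows[asm.name] = {
            "scaffold_n50": crep.scaffold_n50,
            "broken_scaffold_n50": arep.broken_n50,
            "contig_n50": crep.contig_n50,
            "pct_genome_ge_25kb": crep.pct_genome_ge_gene_len,
            "single_copy_orthologs": cnt.busco_summary(table)["single"][0],
            "summary_score": arep.summary_score,
            "broken_n50_per_1000": rnk.value_for_money(arep.broken_n50,
                                                       assembly_cost_usd),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(DEFAULT_METRICS)]


# ---------------------------------------------------------------------------
# capability lookup: which data-type combinations resolve which goals

CAPABILITY_GOALS = (
    "gene_content",
    "gene_order",
    "repeat_spanning",
    "structural_variants",
    "haplotype_resolution",
)

CAPABILITY_COMBINATIONS = (
    "paired_end",
    "paired_end_lmp",
    "bionano",
    "10x",
)

#: goal -> per-combination capability, columns ordered as
#: CAPABILITY_COMBINATIONS.
CAPABILITY_MATRIX: Mapping[str, tuple[bool, bool, bool, bool]] = {
    "gene_content":          (True,  True,  False, True),
    "gene_order":            (True,  True,  False, True),
    "repeat_spanning":       (False, True,  True,  True),
    "structural_variants":   (False, True,  True,  True),
    "haplotype_resolution":  (False, False, False, True),
}


def advise(goals: Sequence[str]) -> list[str]:
    """Data-type combinations able to resolve every requested goal."""
    for g in goals:
        if g not in CAPABILITY_MATRIX:
            raise ValueError(
                f"unknown goal {g!r}; choose from {sorted(CAPABILITY_MATRIX)}")
    return [
        combo for i, combo in enumerate(CAPABILITY_COMBINATIONS)
        if all(CAPABILITY_MATRIX[g][i] for g in goals)
    ]
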