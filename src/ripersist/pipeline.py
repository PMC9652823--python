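"""End-to-end orchestration of the persistence and benchmarking stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import benchmark as bm
from .annotation import TranscriptModel
from .coverage import CoverageTrack
from .intervals import GenomicInterval
from .longreads import (
    LongReadAlignment,
    ReadAssignment,
    RetentionMatrix,
    TranscriptCatalog,
    assign_reads,
    build_retention_matrix,
    select_target_genes,
)
from .persistence import (
    IntronPersistence,
    PersistenceParams,
    PersistenceRecord,
    intron_persistence,
    persistence_table,
    transcript_persistence_all,
)

logger = logging.getLogger(__name__)


@dataclass
class PersistenceResult:
    assignments: list[ReadAssignment]
    matrices: dict[str, RetentionMatrix]
    records: list[PersistenceRecord]
    by_intron: dict[tuple, IntronPersistence]
    table: pd.DataFrame
    target_genes: set[str] = field(default_factory=set)
    eligible_transcripts: set[str] = field(default_factory=set)
    universe: list[GenomicInterval] = field(default_factory=list)

    @property
    def p_i(self) -> dict[tuple, float]:
        return {k: v.p_i for k, v in self.by_intron.items()}


def run_persistence(
    transcripts: Mapping[str, TranscriptModel],
    alignments: Sequence[LongReadAlignment],
    coverage: CoverageTrack | None = None,
    params: PersistenceParams = PersistenceParams(),
    end_tolerance: int = 50,
    min_median_coverage: float = 2.0,
) -> PersistenceResult:
    """Assign reads, build retention matrices, and compute persistence.

    When a coverage track is given, the gene/transcript selection
    filters apply and persistence is restricted to eligible transcripts
    of target genes; otherwise every transcript with enough assigned
    reads is analyzed.
    """
    catalog = TranscriptCatalog(transcripts)
    assignments, reads = assign_reads(alignments, catalog)

    if coverage is not None:
        target_genes, eligible, _ = select_target_genes(
            transcripts,
            assignments,
            reads,
            coverage,
            min_median_coverage=min_median_coverage,
            min_full_length_reads=params.min_reads_per_transcript,
            end_tolerance=end_tolerance,
        )
        keep_tx = {
            t for t in eligible if transcripts[t].gene_id in target_genes
        }
    else:
        counts: dict[str, int] = {}
        for a in assignments:
            counts[a.transcript_id] = counts.get(a.transcript_id, 0) + 1
        keep_tx = {
            t for t, c in counts.items() if c >= params.min_reads_per_transcript
        }
        target_genes = {transcripts[t].gene_id for t in keep_tx}
        eligible = set(keep_tx)

    matrices: dict[str, RetentionMatrix] = {}
    records: list[PersistenceRecord] = []
    for tx_id in sorted(keep_tx):
        tx = transcripts[tx_id]
        if not tx.introns:
            continue
        assigned = [a for a in assignments if a.transcript_id == tx_id]
        if len(assigned) < params.min_reads_per_transcript:
            continue
        matrix = build_retention_matrix(assigned, reads, tx)
        matrices[tx_id] = matrix
        records.extend(transcript_persistence_all(matrix, params))

    by_intron = intron_persistence(records)
    gene_by_tx = {t: transcripts[t].gene_id for t in transcripts}
    table = persistence_table(records, gene_by_tx, params)
    universe_keys: set[tuple] = set()
    universe: list[GenomicInterval] = []
    for tx_id in sorted(matrices):
        for intron in transcripts[tx_id].introns:
            if intron.key not in universe_keys:
                universe_keys.add(intron.key)
                universe.append(intron)
    universe.sort(key=lambda iv: iv.key)
    if not records:
        logger.warning("no transcript reached the minimum read count")
    return PersistenceResult(
        assignments=assignments,
        matrices=matrices,
        records=records,
        by_intron=by_intron,
        table=table,
        target_genes=target_genes,
        eligible_transcripts=eligible,
        universe=universe,
    )


@dataclass
class BenchmarkResult:
    harmonized: pd.DataFrame
    calls: pd.DataFrame
    truth: pd.DataFrame
    performance: pd.DataFrame
    sweep: pd.DataFrame
    potential_vs_called: pd.DataFrame
    consensus: pd.DataFrame
    kappa: float | None
    binned_performance: pd.DataFrame


def run_benchmark(
    p_i: Mapping[tuple, float],
    universe: Sequence[GenomicInterval],
    call_sets: Sequence[bm.ToolCallSet],
    rules: Mapping[str, bm.CallRule] | None = None,
    persistent_threshold: float = 0.1,
    thresholds: Sequence[float] = bm.DEFAULT_THRESHOLDS,
    min_tools: int = 3,
    window_width: int = 300,
    window_step: int = 100,
    window_max: int = 4300,
    profile: str = "default",
) -> BenchmarkResult:
    """Harmonize caller outputs and produce every performance summary."""
    rules = rules if rules is not None else bm.default_call_rules(profile)
    harmonized = bm.harmonize(universe, call_sets)
    called = bm.apply_call_rules(harmonized, rules)
    calls = bm.call_matrix(called)
    persistent = {k for k, p in p_i.items() if p >= persistent_threshold}
    truth = bm.assign_truth(calls, persistent)
    perf = bm.performance_frame(
        [bm.performance(truth, tool, persistent_threshold) for tool in calls.columns]
    )
    sweep = bm.performance_frame(bm.threshold_sweep(p_i, calls, thresholds))
    pvc = bm.potential_vs_called(p_i, called, thresholds)
    consensus_rows = []
    for category in (bm.TP, bm.FP, bm.FN):
        for k in range(1, len(calls.columns) + 1):
            consensus_rows.append(
                {
                    "category": category,
                    "min_tools": k,
                    "count": bm.consensus_counts(truth, category, k),
                }
            )
    consensus = pd.DataFrame(consensus_rows)
    kappa = bm.fleiss_kappa(calls) if calls.shape[0] >= 2 and calls.shape[1] >= 2 else None
    lengths = {iv.key: len(iv) for iv in universe}
    binned = bm.binned_performance(
        lengths,
        truth,
        window_width=window_width,
        step=window_step,
        max_len=window_max,
        threshold=persistent_threshold,
    )
    return BenchmarkResult(
        harmonized=harmonized,
        calls=calls,
        truth=truth,
        performance=perf,
        sweep=sweep,
        potential_vs_called=pvc,
        consensus=consensus,
        kappa=kappa,
        binned_performance=binned,
    )
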