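"""Long-read processing: intron-chain extraction, best-match transcript
assignment, retention matrices, and target-gene selection.

A spliced long-read alignment is reduced to its chain of skip gaps
(reference-space introns). A read is matched to annotated transcripts
whose intron set it equals exactly ("all_introns") or, failing that,
whose intron set contains it ("skipped_splicing"); among candidates the
transcript whose exonic length is closest to the read's exonic
footprint wins. Per transcript, assigned reads form a reads x introns
retention matrix with states retained / spliced / uncovered.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .coverage import CoverageTrack
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

# retention-matrix states
UNCOVERED, SPLICED, RETAINED = 0, 1, 2
STATE_NAMES = {UNCOVERED: "uncovered", SPLICED: "spliced", RETAINED: "retained"}

ALL_INTRONS = "all_introns"
SKIPPED_SPLICING = "skipped_splicing"
FULL_LENGTH = "full_length"
PARTIAL = "partial"

# CIGAR op codes consuming the reference
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True)
class LongReadAlignment:
    """A spliced long-read alignment reduced to span + intron chain."""

    read_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    intron_chain: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        for iv in self.intron_chain:
            if not self.span.contains(iv):
                raise ValueError(f"chain interval {iv} outside span {self.span}")
        for a, b in zip(self.intron_chain, self.intron_chain[1:]):
            if b.start < a.end:
                raise ValueError("chain intervals overlap or are unsorted")

    @property
    def chain_keys(self) -> frozenset:
        return frozenset(iv.key for iv in self.intron_chain)

    @property
    def exonic_footprint(self) -> int:
        """Aligned span length minus total spliced-gap length."""
        return len(self.span) - sum(len(iv) for iv in self.intron_chain)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    transcript_id: str
    match_class: str  # all_introns | skipped_splicing
    span_class: str  # full_length | partial


@dataclass
class RetentionMatrix:
    """Reads x introns state matrix for one transcript."""

    transcript_id: str
    reads: list[str]
    introns: tuple[GenomicInterval, ...]
    states: np.ndarray  # int8, shape (n_reads, n_introns)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def chain_from_cigar(
    ref_start: int, cigartuples: Sequence[tuple[int, int]]
) -> tuple[int, list[tuple[int, int]]]:
    """Walk a cigartuples list; return (ref_end, skip-gap intervals)."""
    pos = ref_start
    gaps: list[tuple[int, int]] = []
    for op, length in cigartuples:
        if op == 3:  # N: spliced gap
            gaps.append((pos, pos + length))
        if op in _REF_CONSUMING:
            pos += length
    return pos, gaps


def extract_intron_chain(record) -> LongReadAlignment | None:
    """Convert a pysam AlignedSegment into a LongReadAlignment.

    Skip gaps (N) become chain intervals; insertions, deletions, and
    clips do not. Strand comes from the spliced-alignment tag (XS/ts)
    when present, else from alignment orientation. Unmapped, secondary,
    and supplementary records return None.
    """
    if record.is_unmapped or record.is_secondary or record.is_supplementary:
        return None
    start = record.reference_start
    end, gaps = chain_from_cigar(start, record.cigartuples or [])
    strand = _record_strand(record)
    span = GenomicInterval(record.reference_name, start, end, strand)
    chain = tuple(
        GenomicInterval(record.reference_name, s, e, strand) for s, e in gaps
    )
    return LongReadAlignment(record.query_name, record.reference_name, strand, span, chain)


def _record_strand(record) -> str:
    if record.has_tag("XS"):
        tag = record.get_tag("XS")
        if tag in ("+", "-"):
            return tag
    if record.has_tag("ts"):
        # minimap2 transcript-strand tag: relative to the read orientation
        ts = record.get_tag("ts")
        if ts in ("+", "-"):
            fwd = "-" if record.is_reverse else "+"
            return fwd if ts == "+" else ("-" if fwd == "+" else "+")
    return "-" if record.is_reverse else "+"


def read_alignments_sam(path: str) -> list[LongReadAlignment]:
    """Load primary spliced alignments from a SAM/BAM file."""
    import pysam

    out: list[LongReadAlignment] = []
    n_skipped = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for record in fh:
            aln = extract_intron_chain(record)
            if aln is None:
                n_skipped += 1
            else:
                out.append(aln)
    if n_skipped:
        logger.info("skipped %d unmapped/secondary/supplementary records", n_skipped)
    return out


def read_alignments_tsv(source: "str | Iterable[str]") -> list[LongReadAlignment]:
    """Load alignments from the plain-text fixture format.

    Columns: read_id, chrom, strand, span_start, span_end, chain —
    where chain is a comma-separated list of "start-end" pairs or "."
    for an unspliced read.
    """
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    out = []
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("read_id\t"):
            continue
        read_id, chrom, strand, s, e, chain_str = line.split("\t")[:6]
        span = GenomicInterval(chrom, int(s), int(e), strand)
        chain = []
        if chain_str not in (".", ""):
            for pair in chain_str.split(","):
                a, b = pair.split("-")
                chain.append(GenomicInterval(chrom, int(a), int(b), strand))
        out.append(LongReadAlignment(read_id, chrom, strand, span, tuple(chain)))
    return out


def write_alignments_tsv(alignments: Iterable[LongReadAlignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstrand\tspan_start\tspan_end\tchain\n")
        for a in alignments:
            chain = ",".join(f"{iv.start}-{iv.end}" for iv in a.intron_chain) or "."
            fh.write(
                f"{a.read_id}\t{a.chrom}\t{a.strand}\t{a.span.start}\t{a.span.end}\t{chain}\n"
            )


class TranscriptCatalog:
    """Transcripts grouped by (chrom, strand) with an intron->transcript map."""

    def __init__(self, transcripts: Mapping[str, TranscriptModel]) -> None:
        self.transcripts = dict(transcripts)
        self.by_location: dict[tuple[str, str], list[TranscriptModel]] = defaultdict(list)
        self.by_intron: dict[tuple, set[str]] = defaultdict(set)
        for tx in transcripts.values():
            self.by_location[(tx.interval.chrom, tx.interval.strand)].append(tx)
            for intron in tx.introns:
                self.by_intron[intron.key].add(tx.transcript_id)
        for group in self.by_location.values():
            group.sort(key=lambda t: t.transcript_id)


def match_candidate_transcripts(
    read: LongReadAlignment, catalog: TranscriptCatalog
) -> tuple[list[TranscriptModel], str | None]:
    """Exact intron-set matches if any, else subset matches, else none.

    An unspliced read (empty chain) is a subset match to every
    same-chromosome, same-strand transcript.
    """
    pool = catalog.by_location.get((read.chrom, read.strand), [])
    if not pool:
        return [], None
    chain = read.chain_keys
    if chain:
        # transcripts containing every chain intron
        sets = [catalog.by_intron.get(key) for key in chain]
        if any(s is None for s in sets):
            return [], None
        shared = set.intersection(*sets)
        supersets = [
            catalog.transcripts[tx_id]
            for tx_id in sorted(shared)
            if catalog.transcripts[tx_id].interval.strand == read.strand
            and catalog.transcripts[tx_id].interval.chrom == read.chrom
        ]
        exact = [t for t in supersets if t.intron_keys == chain]
        if exact:
            return exact, ALL_INTRONS
        if supersets:
            return supersets, SKIPPED_SPLICING
        return [], None
    return list(pool), SKIPPED_SPLICING


def select_best_transcript(
    read: LongReadAlignment, candidates: Sequence[TranscriptModel]
) -> TranscriptModel:
    """Candidate whose exonic length is closest to the read's exonic
    footprint; ties go to the lexicographically smallest transcript_id."""
    if not candidates:
        raise ValueError("no candidate transcripts")
    footprint = read.exonic_footprint
    return min(
        candidates,
        key=lambda t: (abs(t.exonic_length - footprint), t.transcript_id),
    )


def classify_span(read: LongReadAlignment, transcript: TranscriptModel) -> str:
    if not transcript.introns:
        return FULL_LENGTH
    lo = min(i.start for i in transcript.introns)
    hi = max(i.end for i in transcript.introns)
    if read.span.start <= lo and read.span.end >= hi:
        return FULL_LENGTH
    return PARTIAL


def assign_reads(
    alignments: Sequence[LongReadAlignment], catalog: TranscriptCatalog
) -> tuple[list[ReadAssignment], dict[str, LongReadAlignment]]:
    """Best-match assignment of every read; unmatched reads are dropped."""
    assignments: list[ReadAssignment] = []
    by_read: dict[str, LongReadAlignment] = {}
    n_discarded = 0
    for read in sorted(alignments, key=lambda a: a.read_id):
        if read.read_id in by_read:
            continue  # one primary alignment per read_id
        candidates, match_class = match_candidate_transcripts(read, catalog)
        if not candidates:
            n_discarded += 1
            continue
        best = select_best_transcript(read, candidates)
        assignments.append(
            ReadAssignment(
                read.read_id, best.transcript_id, match_class, classify_span(read, best)
            )
        )
        by_read[read.read_id] = read
    if n_discarded:
        logger.info("discarded %d reads with no transcript match", n_discarded)
    return assignments, by_read


def build_retention_matrix(
    assignments: Sequence[ReadAssignment],
    reads: Mapping[str, LongReadAlignment],
    transcript: TranscriptModel,
) -> RetentionMatrix:
    """Reads x introns state matrix for one transcript.

    spliced: the intron is in the read's chain; retained: the read span
    wholly contains the intron but it is not in the chain; uncovered
    otherwise.
    """
    read_ids = sorted(
        a.read_id for a in assignments if a.transcript_id == transcript.transcript_id
    )
    if not read_ids:
        raise ValueError(f"no reads assigned to {transcript.transcript_id}")
    states = np.zeros((len(read_ids), len(transcript.introns)), dtype=np.int8)
    for r, read_id in enumerate(read_ids):
        read = reads[read_id]
        chain = read.chain_keys
        for c, intron in enumerate(transcript.introns):
            if intron.key in chain:
                states[r, c] = SPLICED
            elif read.span.contains(intron):
                states[r, c] = RETAINED
            else:
                states[r, c] = UNCOVERED
    return RetentionMatrix(transcript.transcript_id, read_ids, transcript.introns, states)


@dataclass
class GeneCoverageSummary:
    gene_id: str
    median_coverage: float
    full_length_reads: dict[str, int]  # transcript_id -> coordinate-matched count


def gene_spans(transcripts: Mapping[str, TranscriptModel]) -> dict[str, GenomicInterval]:
    spans: dict[str, GenomicInterval] = {}
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for tx in transcripts.values():
        by_gene[tx.gene_id].append(tx)
    for gene_id, txs in by_gene.items():
        spans[gene_id] = GenomicInterval(
            txs[0].interval.chrom,
            min(t.interval.start for t in txs),
            max(t.interval.end for t in txs),
            txs[0].interval.strand,
        )
    return spans


def select_target_genes(
    transcripts: Mapping[str, TranscriptModel],
    assignments: Sequence[ReadAssignment],
    reads: Mapping[str, LongReadAlignment],
    coverage: CoverageTrack,
    min_median_coverage: float = 2.0,
    min_full_length_reads: int = 5,
    end_tolerance: int = 50,
) -> tuple[set[str], set[str], list[GeneCoverageSummary]]:
    """Keep genes with adequate short- and long-read support.

    A gene passes when its median gene-wide per-base short-read
    coverage is >= min_median_coverage AND at least one of its
    transcripts has >= min_full_length_reads full-length assigned reads
    whose aligned ends both fall within end_tolerance bases of the
    transcript's annotated ends. Eligible transcripts are those meeting
    the read criterion within passing genes.
    """
    spans = gene_spans(transcripts)
    matched_counts: dict[str, int] = defaultdict(int)
    for a in assignments:
        if a.span_class != FULL_LENGTH:
            continue
        tx = transcripts[a.transcript_id]
        read = reads[a.read_id]
        if (
            abs(read.span.start - tx.interval.start) <= end_tolerance
            and abs(read.span.end - tx.interval.end) <= end_tolerance
        ):
            matched_counts[a.transcript_id] += 1

    summaries: list[GeneCoverageSummary] = []
    target_genes: set[str] = set()
    eligible_transcripts: set[str] = set()
    by_gene: dict[str, list[str]] = defaultdict(list)
    for tx_id, tx in transcripts.items():
        by_gene[tx.gene_id].append(tx_id)

    for gene_id in sorted(by_gene):
        span = spans[gene_id]
        if not coverage.has_chrom(span.chrom):
            logger.warning("no coverage for gene %s; excluded", gene_id)
            continue
        med = coverage.median(span.chrom, span.start, span.end)
        counts = {tx_id: matched_counts.get(tx_id, 0) for tx_id in by_gene[gene_id]}
        summaries.append(GeneCoverageSummary(gene_id, med, counts))
        good_txs = {t for t, c in counts.items() if c >= min_full_length_reads}
        if med >= min_median_coverage and good_txs:
            target_genes.add(gene_id)
            eligible_transcripts.update(good_txs)
    return target_genes, eligible_transcripts, summaries


def assignments_frame(assignments: Sequence[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "transcript_id": a.transcript_id,
                "match_class": a.match_class,
                "span_class": a.span_class,
            }
            for a in assignments
        ],
        columns=["read_id", "transcript_id", "match_class", "span_class"],
    )
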