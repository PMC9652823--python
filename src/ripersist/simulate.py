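"""Synthetic splicing data with known ground truth.

Generates a toy genome + multi-isoform annotation, long reads with
stochastic splicing progression and optional truncation, per-base
coverage tracks, and mock short-read caller outputs with controlled
sensitivity/specificity — everything the pipeline consumes, with no
downloads and full determinism under a seed.

Read model: a *mature* read splices each intron independently with
probability 1 - rho_i; a *pre-mRNA* read has splicing progressed 5'->3'
to a random stopping point, retaining the contiguous 3' run of introns
beyond it. A *partial* read truncates the aligned span uniformly at
random from one end, at an exonic (covered) position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import TranscriptModel
from .benchmark import ScoredInterval, ToolCallSet
from .intervals import GenomicInterval
from .longreads import LongReadAlignment

BASES = np.array(list("ACGT"))

DEFAULT_TOOLS: dict[str, tuple[float, float]] = {
    "IntEREst": (0.9, 0.9),
    "KMA": (0.9, 0.9),
    "iREAD": (0.9, 0.9),
    "superintronic": (0.9, 0.9),
    "IRFinder-S": (0.9, 0.9),
    "MAJIQ": (0.9, 0.9),
    "rMATS": (0.9, 0.9),
    "SUPPA2": (0.9, 0.9),
}


@dataclass
class SimulationConfig:
    n_genes: int = 4
    isoforms_per_gene: int = 2
    introns_per_transcript: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (80, 200)
    intron_length: tuple[int, int] = (100, 400)
    rho_values: tuple[float, ...] = (0.0, 0.25, 0.5)
    pre_mrna_fraction: float = 0.0
    partial_fraction: float = 0.0
    pre_mrna_model: str = "progressive"  # or "random_subset"
    reads_per_transcript: int = 20
    coverage_depth: float = 5.0
    coverage_decay: float = 0.0
    tools: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TOOLS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("pre_mrna_fraction", self.pre_mrna_fraction),
            ("partial_fraction", self.partial_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for rho in self.rho_values:
            if not 0.0 <= rho <= 1.0:
                raise ValueError("retention probabilities must be in [0, 1]")
        if self.introns_per_transcript[0] < 1:
            raise ValueError("need at least one intron per transcript")
        if self.exon_length[0] < 10 or self.intron_length[0] < 10:
            raise ValueError("exon/intron lengths must be >= 10")
        if self.exon_length[0] > self.exon_length[1] or (
            self.intron_length[0] > self.intron_length[1]
        ):
            raise ValueError("length ranges must be (lo, hi) with lo <= hi")


@dataclass
class ReadLabel:
    read_id: str
    transcript_id: str
    maturity: str  # mature | pre_mRNA
    truncated: bool
    retained_keys: frozenset


@dataclass
class GroundTruth:
    rho: dict[tuple, float] = field(default_factory=dict)
    expected_persistent: dict[tuple, bool] = field(default_factory=dict)
    read_labels: dict[str, ReadLabel] = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)].copy()


def generate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, TranscriptModel], GroundTruth]:
    """Build a toy genome and annotation.

    One chromosome holds all genes, laid out left to right with
    intergenic gaps; strands alternate so minus-strand handling is
    exercised. Isoform 1 uses every exon; later isoforms skip one
    internal exon each, so the skipped exon overlaps the skipping
    isoform's merged intron. Canonical GT-AG motifs are planted at every
    intron boundary (on the transcript strand).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = "chrS"
    cursor = 300
    seq_parts: list[tuple[int, np.ndarray]] = []
    transcripts: dict[str, TranscriptModel] = {}
    truth = GroundTruth()

    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:03d}"
        strand = "+" if g % 2 == 0 else "-"
        n_introns = int(
            rng.integers(
                config.introns_per_transcript[0], config.introns_per_transcript[1] + 1
            )
        )
        n_exons = n_introns + 1
        exon_lens = rng.integers(
            config.exon_length[0], config.exon_length[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=n_introns
        )
        exons: list[GenomicInterval] = []
        pos = cursor
        for k in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_introns:
                pos += int(intron_lens[k])
        gene_end = pos
        cursor = gene_end + 500

        isoforms = [exons]
        n_iso = max(1, config.isoforms_per_gene)
        skippable = list(range(1, n_exons - 1))
        for j in range(1, n_iso):
            if not skippable:
                break
            skip = skippable[(j - 1) % len(skippable)]
            isoforms.append([e for k, e in enumerate(exons) if k != skip])
        for j, iso_exons in enumerate(isoforms, start=1):
            tx_id = f"{gene_id}.t{j}"
            transcripts[tx_id] = TranscriptModel.from_exons(tx_id, gene_id, iso_exons)

    # genome sequence: random background, then plant splice motifs
    genome_len = cursor + 300
    seq = _rand_seq(rng, genome_len)
    for tx in transcripts.values():
        for intron in tx.introns:
            if intron.strand == "+":
                seq[intron.start : intron.start + 2] = list("GT")
                seq[intron.end - 2 : intron.end] = list("AG")
            else:
                seq[intron.start : intron.start + 2] = list("CT")
                seq[intron.end - 2 : intron.end] = list("AC")
    genome = {chrom: "".join(seq)}

    # per-intron retention probabilities: cycle rho_values over the
    # deduplicated intron keys in genomic order
    all_keys = sorted({i.key for tx in transcripts.values() for i in tx.introns})
    for n, key in enumerate(all_keys):
        rho = config.rho_values[n % len(config.rho_values)]
        truth.rho[key] = rho
        truth.expected_persistent[key] = rho >= 0.1
    return genome, transcripts, truth


def _transcript_order(tx: TranscriptModel) -> list[int]:
    """Indices of tx.introns in 5'->3' transcript order."""
    n = len(tx.introns)
    return list(range(n)) if tx.interval.strand == "+" else list(range(n - 1, -1, -1))


def simulate_long_reads(
    config: SimulationConfig,
    transcripts: Mapping[str, TranscriptModel],
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list[LongReadAlignment]:
    """Emit one batch of spliced long reads per transcript.

    Labels (source transcript, maturity, truncation, retained introns)
    are recorded into ``truth.read_labels``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    reads: list[LongReadAlignment] = []
    for tx_id in sorted(transcripts):
        tx = transcripts[tx_id]
        order = _transcript_order(tx)
        n = len(tx.introns)
        for k in range(config.reads_per_transcript):
            read_id = f"{tx_id}_read{k:04d}"
            is_pre = rng.random() < config.pre_mrna_fraction
            if is_pre and n > 0:
                if config.pre_mrna_model == "progressive":
                    # splicing progressed 5'->3' to a random stop; the
                    # 3' remainder is still unspliced
                    stop = int(rng.integers(0, n + 1))
                    retained = {order[j] for j in range(stop, n)}
                else:
                    mask = rng.random(n) < 0.5
                    retained = {j for j in range(n) if mask[j]}
                maturity = "pre_mRNA"
            else:
                retained = {
                    j for j in range(n) if rng.random() < truth.rho[tx.introns[j].key]
                }
                maturity = "mature"
            chain = tuple(
                intron for j, intron in enumerate(tx.introns) if j not in retained
            )
            span = tx.interval
            truncated = False
            if config.partial_fraction > 0 and rng.random() < config.partial_fraction:
                span, chain, did = _truncate(rng, span, chain)
                truncated = did
            reads.append(
                LongReadAlignment(read_id, tx.interval.chrom, tx.interval.strand, span, chain)
            )
            truth.read_labels[read_id] = ReadLabel(
                read_id,
                tx_id,
                maturity,
                truncated,
                frozenset(tx.introns[j].key for j in retained),
            )
    return reads


def _truncate(
    rng: np.random.Generator,
    span: GenomicInterval,
    chain: tuple[GenomicInterval, ...],
) -> tuple[GenomicInterval, tuple[GenomicInterval, ...], bool]:
    """Cut the span at a random covered (non-gap) position from one end."""
    segments: list[tuple[int, int]] = []
    pos = span.start
    for gap in chain:
        segments.append((pos, gap.start))
        pos = gap.end
    segments.append((pos, span.end))
    footprint = sum(e - s for s, e in segments)
    if footprint < 3:
        return span, chain, False
    offset = int(rng.integers(1, footprint))  # keep >= 1 base either way
    genomic = None
    acc = 0
    for s, e in segments:
        if offset < acc + (e - s):
            genomic = s + (offset - acc)
            break
        acc += e - s
    assert genomic is not None
    if rng.random() < 0.5:
        new = GenomicInterval(span.chrom, span.start, genomic, span.strand)
        kept = tuple(g for g in chain if g.end <= genomic)
    else:
        new = GenomicInterval(span.chrom, genomic, span.end, span.strand)
        kept = tuple(g for g in chain if g.start >= genomic)
    return new, kept, True


def simulate_coverage(
    transcripts: Mapping[str, TranscriptModel],
    depth: float = 5.0,
    decay_5to3: float = 0.0,
) -> list[tuple[str, int, int, float]]:
    """Flat per-base coverage over gene spans, with an optional linear
    5'->3' decay inside introns; returned as bedGraph segments."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    from .longreads import gene_spans

    spans = gene_spans(transcripts)
    per_chrom: dict[str, dict[int, float]] = {}
    for gene_id in sorted(spans):
        span = spans[gene_id]
        store = per_chrom.setdefault(span.chrom, {})
        for p in range(span.start, span.end):
            store[p] = max(store.get(p, 0.0), depth)
    if decay_5to3 > 0:
        seen = set()
        for tx_id in sorted(transcripts):
            tx = transcripts[tx_id]
            store = per_chrom[tx.interval.chrom]
            for intron in tx.introns:
                if intron.key in seen:
                    continue
                seen.add(intron.key)
                length = len(intron)
                for off in range(length):
                    frac = off / max(length - 1, 1)
                    if intron.strand == "-":
                        frac = 1.0 - frac
                    value = depth * (1.0 - decay_5to3 * frac)
                    store[intron.start + off] = value
    segments: list[tuple[str, int, int, float]] = []
    for chrom in sorted(per_chrom):
        store = per_chrom[chrom]
        positions = sorted(store)
        run_start = None
        run_val = None
        prev = None
        for p in positions:
            v = store[p]
            if run_start is None:
                run_start, run_val, prev = p, v, p
            elif p == prev + 1 and v == run_val:
                prev = p
            else:
                segments.append((chrom, run_start, prev + 1, run_val))
                run_start, run_val, prev = p, v, p
        if run_start is not None:
            segments.append((chrom, run_start, prev + 1, run_val))
    return segments


# score generators per mock tool: (positive draw, negative draw, aux maker)
def _caller_record(
    tool: str,
    intron: GenomicInterval,
    called: bool,
    rng: np.random.Generator,
) -> ScoredInterval:
    u = rng.random()
    aux: dict[str, float] = {}
    if tool == "IntEREst":
        score = 45.0 + 55.0 * u if called else 44.0 * u
    elif tool == "KMA":
        score = 1.0 + 99.0 * u
        aux["unique_counts"] = float(rng.integers(10, 51)) if called else float(
            rng.integers(0, 10)
        )
    elif tool == "iREAD":
        score = 3.0 + 97.0 * u if called else 3.0 + 97.0 * u
        aux["entropy"] = 0.9 + 0.1 * rng.random() if called else 0.89 * rng.random()
        aux["junction_reads"] = float(rng.integers(1, 20)) if called else 0.0
        aux["fragments"] = float(rng.integers(20, 100)) if called else float(
            rng.integers(0, 10)
        )
    elif tool == "superintronic":
        score = 3.0 + 7.0 * u if called else 2.9 * u
    elif tool == "IRFinder-S":
        score = 0.5 + 0.5 * u if called else 0.49 * u
        aux["flags"] = 0.0 if called else float(rng.integers(0, 2))
    elif tool == "MAJIQ":
        score = 0.51 + 0.49 * u if called else 0.5 * u
    elif tool in ("rMATS", "SUPPA2"):
        score = 0.81 + 0.19 * u if called else 0.8 * u
    else:
        raise KeyError(f"unknown mock tool {tool!r}")
    return ScoredInterval(intron, score, aux)


def simulate_caller_outputs(
    persistent: set,
    universe: Sequence[GenomicInterval],
    tools: Mapping[str, tuple[float, float]],
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> dict[str, ToolCallSet]:
    """Mock per-tool scored interval tables.

    A persistent intron is called with probability ``sensitivity``; a
    non-persistent one with probability ``1 - specificity``. Scores and
    aux columns are drawn so the shipped call rule for the tool fires
    exactly on called introns.
    """
    rng = rng if rng is not None else np.random.default_rng(seed + 2)
    out: dict[str, ToolCallSet] = {}
    for tool in sorted(tools):
        sens, spec = tools[tool]
        records = []
        for intron in universe:
            p_call = sens if intron.key in persistent else 1.0 - spec
            called = rng.random() < p_call
            records.append(_caller_record(tool, intron, called, rng))
        out[tool] = ToolCallSet(tool, records)
    return out


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(
    reads: Sequence[LongReadAlignment], genome: Mapping[str, str], path: str
) -> None:
    """Plain-text SAM with skip-gap CIGARs; SEQ omitted ('*')."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(genome):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{len(genome[chrom])}\n")
        for read in reads:
            cigar = []
            pos = read.span.start
            for gap in read.intron_chain:
                cigar.append(f"{gap.start - pos}M{len(gap)}N")
                pos = gap.end
            cigar.append(f"{read.span.end - pos}M")
            fh.write(
                f"{read.read_id}\t0\t{read.chrom}\t{read.span.start + 1}\t60\t"
                f"{''.join(cigar)}\t*\t0\t0\t*\t*\tXS:A:{read.strand}\n"
            )


def write_caller_tsv(call_set: ToolCallSet, path: str) -> None:
    aux_names = sorted({k for rec in call_set.records for k in rec.aux})
    with open(path, "w") as fh:
        header = ["chrom", "start", "end", "strand", "score"] + aux_names
        fh.write("\t".join(header) + "\n")
        for rec in call_set.records:
            iv = rec.interval
            row = [iv.chrom, str(iv.start), str(iv.end), iv.strand, f"{rec.score:.6g}"]
            row += [f"{rec.aux.get(name, 0.0):.6g}" for name in aux_names]
            fh.write("\t".join(row) + "\n")


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\trho\texpected_persistent\n")
        for key in sorted(truth.rho):
            chrom, start, end, strand = key
            fh.write(
                f"{chrom}\t{start}\t{end}\t{strand}\t{truth.rho[key]:g}\t"
                f"{int(truth.expected_persistent[key])}\n"
            )
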