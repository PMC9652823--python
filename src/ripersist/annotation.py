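"""Gene annotation parsing and per-intron feature computation.

Parses GENCODE-dialect GTF into transcript models, derives introns as
the gaps between consecutive exons, and computes the intron properties
used throughout the analysis: length, GC fraction, relative transcript
position, overlap with exons of other transcripts, terminal splice
motif, and spliceosome class (U2/U12).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .intervals import GenomicInterval, IntervalIndex

MOTIF_CANONICAL = ("GT-AG", "GC-AG", "AT-AC")
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GTFParseError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptModel:
    """An annotated isoform: ordered exons plus derived introns."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...]

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def intron_keys(self) -> frozenset:
        return frozenset(i.key for i in self.introns)

    @classmethod
    def from_exons(
        cls, transcript_id: str, gene_id: str, exons: Iterable[GenomicInterval]
    ) -> "TranscriptModel":
        exons = tuple(sorted(exons, key=lambda e: e.start))
        if not exons:
            raise ValueError(f"transcript {transcript_id} has no exons")
        chrom, strand = exons[0].chrom, exons[0].strand
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        introns = tuple(
            GenomicInterval(chrom, a.end, b.start, strand)
            for a, b in zip(exons, exons[1:])
        )
        interval = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
        return cls(transcript_id, gene_id, interval, exons, introns)


@dataclass(frozen=True)
class IntronFeatures:
    length: int
    gc_fraction: float
    relative_position: float
    n_overlapping_exons: int
    pct_bases_overlapped: float
    max_overlap_depth: int
    motif: str
    spliceosome: str


_ATTR_RE = re.compile(r'(\S+) "([^"]*)"')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise GTFParseError(f"line {lineno}: unparseable attribute field: {attr_field!r}")
    return attrs


def parse_annotation(
    source: "str | Iterable[str]",
) -> tuple[dict[str, TranscriptModel], IntervalIndex]:
    """Parse GTF text into transcript models and an exon overlap index.

    Parameters
    ----------
    source
        A path to a GTF file or an iterable of GTF lines. Only ``exon``
        features are consumed; each must carry ``transcript_id`` and
        ``gene_id`` attributes. GTF 1-based closed coordinates are
        converted to the internal 0-based half-open convention.

    Returns
    -------
    transcripts
        Mapping transcript_id -> TranscriptModel, introns derived.
    exon_index
        IntervalIndex over all exons; payload is the source transcript_id.
    """
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    gene_by_tx: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise GTFParseError(f"line {lineno}: expected 9 tab-separated fields")
        chrom, _, feature, start, end, _, strand, _, attr_field = fields[:9]
        if feature != "exon":
            continue
        attrs = _parse_attributes(attr_field, lineno)
        try:
            tx_id = attrs["transcript_id"]
            gene_id = attrs["gene_id"]
        except KeyError as exc:
            raise GTFParseError(f"line {lineno}: missing attribute {exc}") from None
        iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
        exons_by_tx.setdefault(tx_id, []).append(iv)
        gene_by_tx[tx_id] = gene_id

    transcripts: dict[str, TranscriptModel] = {}
    index = IntervalIndex()
    for tx_id, exons in exons_by_tx.items():
        model = TranscriptModel.from_exons(tx_id, gene_by_tx[tx_id], exons)
        transcripts[tx_id] = model
        for exon in model.exons:
            index.add(exon.chrom, exon.start, exon.end, tx_id)
    index.build()
    return transcripts, index


def write_annotation(transcripts: Mapping[str, TranscriptModel], path: str) -> None:
    """Write transcript models back to GTF (exon features only)."""
    with open(path, "w") as fh:
        for tx_id in sorted(transcripts):
            tx = transcripts[tx_id]
            for n, exon in enumerate(tx.exons, start=1):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'exon_number "{n}";'
                )
                fh.write(
                    f"{exon.chrom}\tripersist\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\t{attrs}\n"
                )


def splice_motif(genome, intron: GenomicInterval) -> str:
    """Classify the donor-acceptor dinucleotides of an intron.

    ``genome`` is any mapping from chromosome name to a sliceable
    sequence (pyfaidx.Fasta works). The motif is read 5'->3' on the
    transcript strand; non-canonical pairs return ``"other"``.
    """
    if len(intron) < 4:
        raise ValueError("intron shorter than 4 bases has no donor/acceptor motif")
    chrom_seq = genome[intron.chrom]
    chrom_len = len(chrom_seq)
    if intron.end > chrom_len:
        raise IndexError(
            f"intron end {intron.end} beyond chromosome {intron.chrom} length {chrom_len}"
        )
    seq = str(chrom_seq[intron.start : intron.end])
    if intron.strand == "-":
        seq = reverse_complement(seq)
    motif = f"{seq[:2]}-{seq[-2:]}".upper()
    return motif if motif in MOTIF_CANONICAL else "other"


def gc_fraction(genome, intron: GenomicInterval) -> float:
    """(#G + #C) / length, case-insensitive; ambiguous bases count as non-GC."""
    seq = str(genome[intron.chrom][intron.start : intron.end]).upper()
    if not seq:
        raise ValueError("empty interval")
    return (seq.count("G") + seq.count("C")) / len(seq)


def relative_position(intron_rank: int, n_introns: int) -> float:
    """Relative 5'->3' transcript position of an intron, in [0, 1].

    Rank is 1-based in transcript orientation. A single-intron
    transcript returns 0.5.
    """
    if not 1 <= intron_rank <= n_introns:
        raise ValueError(f"rank {intron_rank} out of range for {n_introns} introns")
    if n_introns == 1:
        return 0.5
    return (intron_rank - 1) / (n_introns - 1)


def exon_overlap_stats(
    intron: GenomicInterval, index: IntervalIndex, own_transcript: str
) -> tuple[int, float, int]:
    """Overlap of an intron with exons from *other* transcripts.

    Returns (number of overlapping foreign exons, percent of intron
    bases covered by at least one, maximum per-base overlap depth).
    """
    hits = [
        (s, e)
        for s, e, tx in index.query(intron.chrom, intron.start, intron.end)
        if tx != own_transcript
    ]
    if not hits:
        return 0, 0.0, 0
    # sweep line over clipped endpoints for union length and max depth
    events: list[tuple[int, int]] = []
    for s, e in hits:
        events.append((max(s, intron.start), 1))
        events.append((min(e, intron.end), -1))
    events.sort()
    depth = 0
    max_depth = 0
    covered = 0
    prev = intron.start
    for pos, delta in events:
        if depth > 0:
            covered += pos - prev
        prev = pos
        depth += delta
        max_depth = max(max_depth, depth)
    pct = 100.0 * covered / len(intron)
    return len(hits), pct, max_depth


def spliceosome_class(
    intron: GenomicInterval, u2: IntervalIndex, u12: IntervalIndex
) -> str:
    """U2/U12 label: overlap with exactly one category gives that label,
    both or neither gives "other"."""
    hit_u2 = bool(u2.query(intron.chrom, intron.start, intron.end))
    hit_u12 = bool(u12.query(intron.chrom, intron.start, intron.end))
    if hit_u2 and not hit_u12:
        return "U2"
    if hit_u12 and not hit_u2:
        return "U12"
    return "other"


def transcript_intron_ranks(tx: TranscriptModel) -> list[int]:
    """1-based 5'->3' rank for each intron in genomic order.

    On the minus strand the transcript's 5' end is the genomic right, so
    ranks count down in genomic order.
    """
    n = len(tx.introns)
    if tx.interval.strand == "-":
        return list(range(n, 0, -1))
    return list(range(1, n + 1))


def intron_feature_table(
    transcripts: Mapping[str, TranscriptModel],
    exon_index: IntervalIndex,
    genome=None,
    u2: IntervalIndex | None = None,
    u12: IntervalIndex | None = None,
) -> pd.DataFrame:
    """Per-intron feature table across all transcripts.

    Sequence-derived columns (gc_fraction, motif) are NaN/"NA" when no
    genome is supplied; spliceosome is "other" when no BED sets are.
    """
    empty = IntervalIndex().build()
    u2 = u2 if u2 is not None else empty
    u12 = u12 if u12 is not None else empty
    rows = []
    for tx_id in sorted(transcripts):
        tx = transcripts[tx_id]
        ranks = transcript_intron_ranks(tx)
        n = len(tx.introns)
        for intron, rank in zip(tx.introns, ranks):
            n_ov, pct, depth = exon_overlap_stats(intron, exon_index, tx_id)
            if genome is not None:
                gc = gc_fraction(genome, intron)
                motif = splice_motif(genome, intron) if len(intron) >= 4 else "other"
            else:
                gc, motif = float("nan"), "NA"
            rows.append(
                {
                    "chrom": intron.chrom,
                    "start": intron.start,
                    "end": intron.end,
                    "strand": intron.strand,
                    "gene_id": tx.gene_id,
                    "transcript_id": tx_id,
                    "rank": rank,
                    "length": len(intron),
                    "gc_fraction": gc,
                    "relative_position": relative_position(rank, n),
                    "n_overlapping_exons": n_ov,
                    "pct_bases_overlapped": pct,
                    "max_overlap_depth": depth,
                    "motif": motif,
                    "spliceosome": spliceosome_class(intron, u2, u12),
                }
            )
    columns = [
        "chrom", "start", "end", "strand", "gene_id", "transcript_id", "rank",
        "length", "gc_fraction", "relative_position", "n_overlapping_exons",
        "pct_bases_overlapped", "max_overlap_depth", "motif", "spliceosome",
    ]
    return pd.DataFrame(rows, columns=columns)
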