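import numpy as np
import pytest

from ripersist.annotation import TranscriptModel
from ripersist.intervals import GenomicInterval
from ripersist.longreads import RETAINED, SPLICED, UNCOVERED, RetentionMatrix

STATE_CODE = {"r": RETAINED, "s": SPLICED, ".": UNCOVERED}


def matrix_from_strings(rows: list[str], transcript_id: str = "tx1") -> RetentionMatrix:
    """Build a RetentionMatrix from compact row strings.

    'r' = retained, 's' = spliced, '.' = uncovered. Intron coordinates
    are synthetic placeholders on one chromosome.
    """
    n_introns = len(rows[0])
    introns = tuple(
        GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 100, "+")
        for i in range(n_introns)
    )
    states = np.array(
        [[STATE_CODE[c] for c in row] for row in rows], dtype=np.int8
    )
    reads = [f"read{k}" for k in range(len(rows))]
    return RetentionMatrix(transcript_id, reads, introns, states)


def random_matrix(rng: np.random.Generator, max_reads: int = 10, max_introns: int = 6):
    """Random retention matrix with every read spanning >= 1 intron."""
    n_reads = int(rng.integers(1, max_reads + 1))
    n_introns = int(rng.integers(1, max_introns + 1))
    while True:
        states = rng.integers(0, 3, size=(n_reads, n_introns)).astype(np.int8)
        if np.all((states != UNCOVERED).sum(axis=1) > 0):
            break
    introns = tuple(
        GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 100, "+")
        for i in range(n_introns)
    )
    reads = [f"read{k}" for k in range(n_reads)]
    return RetentionMatrix("txR", reads, introns, states)


@pytest.fixture
def worked_matrix() -> RetentionMatrix:
    """The 3-intron / 5-read worked example: r1,r2 retain only intron 1,
    r3,r4 splice everything, r5 retains everything."""
    return matrix_from_strings(["rss", "rss", "sss", "sss", "rrr"])


TOY_GTF = """\
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttest\texon\t201\t300\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttest\texon\t401\t500\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttest\texon\t1\t100\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
chr1\ttest\texon\t401\t500\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
chr1\ttest\texon\t2001\t2100\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
chr1\ttest\texon\t2301\t2400\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
"""


@pytest.fixture
def toy_annotation():
    """Two genes; tA2 skips tA1's middle exon, tB1 is minus-strand."""
    from ripersist.annotation import parse_annotation

    return parse_annotation(TOY_GTF.splitlines(keepends=True))


def make_transcript(
    tx_id: str,
    gene_id: str,
    exon_coords: list[tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
) -> TranscriptModel:
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return TranscriptModel.from_exons(tx_id, gene_id, exons)
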