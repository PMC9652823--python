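"""Intron persistence: a noise-aware long-read variant of intron PSI.

For each intron i of a transcript t with at least ``min_reads_per_transcript``
assigned long reads, the per-transcript persistence is

    P_it = d_i * sum_r [ R(r,i) * SF(r,i) * H(r,i) ] / D

where the sum runs over reads spanning i, d_i is the fraction of
assigned reads covering i (information density), R is 1 iff the read
retains i, SF is the read's spliced fraction excluding the target, H is
the scaled Hamming similarity of the read's splicing pattern to other
reads with the same state at i, and D is the number of assigned reads
(default) or of spanning reads (configurable). The gene-level intron
persistence P_i is the maximum P_it across isoforms containing i; an
intron is "persistent" when P_i >= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .longreads import RETAINED, SPLICED, UNCOVERED, RetentionMatrix

ASSIGNED = "assigned"
SPANNING = "spanning"


@dataclass(frozen=True)
class PersistenceParams:
    min_reads_per_transcript: int = 5
    persistent_threshold: float = 0.1
    mean_denominator: str = ASSIGNED
    sf_single_intron_value: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistent_threshold <= 1.0:
            raise ValueError("persistent_threshold must be in [0, 1]")
        if self.min_reads_per_transcript < 1:
            raise ValueError("min_reads_per_transcript must be >= 1")
        if self.mean_denominator not in (ASSIGNED, SPANNING):
            raise ValueError(f"mean_denominator must be '{ASSIGNED}' or '{SPANNING}'")
        if not 0.0 <= self.sf_single_intron_value <= 1.0:
            raise ValueError("sf_single_intron_value must be in [0, 1]")


@dataclass(frozen=True)
class PersistenceRecord:
    intron_key: tuple  # (chrom, start, end, strand)
    transcript_id: str
    d_i: float
    p_it: float
    n_reads: int
    n_spanning: int


@dataclass
class IntronPersistence:
    intron_key: tuple
    p_i: float
    transcripts: dict[str, float] = field(default_factory=dict)  # tx -> P_it

    @property
    def argmax_transcripts(self) -> list[str]:
        best = max(self.transcripts.values())
        return sorted(t for t, p in self.transcripts.items() if p == best)


def information_density(matrix: RetentionMatrix, intron_index: int) -> float:
    """Fraction of assigned reads whose span covers the intron."""
    if matrix.n_reads == 0:
        raise ValueError("empty retention matrix")
    col = matrix.states[:, intron_index]
    return float(np.count_nonzero(col != UNCOVERED)) / matrix.n_reads


def spliced_fraction(
    read_states: np.ndarray, target_index: int, sf_single_intron_value: float = 1.0
) -> float:
    """Fraction of spliced introns in a read, target excluded.

    ``read_states`` is one row of a retention matrix. The target intron
    must be covered by the read. When the read spans only the target
    intron the denominator vanishes and the configured single-intron
    value is returned.
    """
    target = read_states[target_index]
    if target == UNCOVERED:
        raise ValueError("target intron not covered by read")
    spanned = read_states != UNCOVERED
    n_spanned = int(np.count_nonzero(spanned))
    if n_spanned == 1:
        return sf_single_intron_value
    n_spliced = int(np.count_nonzero(read_states == SPLICED))
    r = 1 if target == RETAINED else 0
    return (n_spliced + r - 1) / (n_spanned - 1)


def hamming_similarity(
    matrix: RetentionMatrix, read_index: int, target_index: int
) -> float:
    """Mean per-intron agreement between a read and its comparison set.

    The comparison set holds every read spanning the target intron with
    the same state there as the query (the query itself included). Each
    pair is scored on the introns spanned by both reads.
    """
    states = matrix.states
    query = states[read_index]
    if query[target_index] == UNCOVERED:
        raise ValueError("query read does not span the target intron")
    same_state = states[:, target_index] == query[target_index]
    comparison = np.nonzero(same_state)[0]
    query_spanned = query != UNCOVERED
    total = 0.0
    for other_index in comparison:
        other = states[other_index]
        shared = query_spanned & (other != UNCOVERED)
        n_shared = int(np.count_nonzero(shared))
        assert n_shared > 0, "both reads span the target; shared set is non-empty"
        n_match = int(np.count_nonzero((query == other) & shared))
        total += n_match / n_shared
    return total / len(comparison)


def transcript_persistence(
    matrix: RetentionMatrix,
    intron_index: int,
    params: PersistenceParams = PersistenceParams(),
) -> PersistenceRecord:
    """Per-transcript persistence P_it for one intron."""
    states = matrix.states
    col = states[:, intron_index]
    spanning = np.nonzero(col != UNCOVERED)[0]
    d_i = information_density(matrix, intron_index)
    if params.mean_denominator == ASSIGNED:
        denom = matrix.n_reads
    else:
        denom = max(len(spanning), 1)
    total = 0.0
    for r in spanning:
        if col[r] != RETAINED:
            continue  # R = 0: no contribution
        sf = spliced_fraction(states[r], intron_index, params.sf_single_intron_value)
        h = hamming_similarity(matrix, int(r), intron_index)
        total += sf * h
    p_it = min(max(d_i * total / denom, 0.0), 1.0)
    intron = matrix.introns[intron_index]
    return PersistenceRecord(
        intron_key=intron.key,
        transcript_id=matrix.transcript_id,
        d_i=d_i,
        p_it=p_it,
        n_reads=matrix.n_reads,
        n_spanning=int(len(spanning)),
    )


def transcript_persistence_all(
    matrix: RetentionMatrix, params: PersistenceParams = PersistenceParams()
) -> list[PersistenceRecord]:
    """P_it for every intron of a transcript; empty if the transcript
    has fewer assigned reads than the minimum."""
    if matrix.n_reads < params.min_reads_per_transcript:
        return []
    return [
        transcript_persistence(matrix, i, params)
        for i in range(len(matrix.introns))
    ]


def intron_persistence(records: Iterable[PersistenceRecord]) -> dict[tuple, IntronPersistence]:
    """Collapse per-transcript records to gene-level P_i = max_t P_it."""
    out: dict[tuple, IntronPersistence] = {}
    for rec in records:
        entry = out.get(rec.intron_key)
        if entry is None:
            entry = IntronPersistence(rec.intron_key, rec.p_it, {})
            out[rec.intron_key] = entry
        entry.transcripts[rec.transcript_id] = max(
            rec.p_it, entry.transcripts.get(rec.transcript_id, 0.0)
        )
        entry.p_i = max(entry.p_i, rec.p_it)
    return out


def classify_persistent(p_i: float, threshold: float = 0.1) -> bool:
    """Inclusive threshold: P_i >= threshold."""
    if not 0.0 <= p_i <= 1.0:
        raise ValueError(f"P_i must be in [0, 1], got {p_i}")
    return p_i >= threshold


def persistence_table(
    records: Sequence[PersistenceRecord],
    gene_by_transcript: Mapping[str, str],
    params: PersistenceParams = PersistenceParams(),
) -> pd.DataFrame:
    """Tidy per-intron persistence table.

    One row per intron key; transcript_id is the argmax isoform, d_i and
    counts are taken from the argmax record.
    """
    collapsed = intron_persistence(records)
    best_record: dict[tuple, PersistenceRecord] = {}
    for rec in records:
        cur = best_record.get(rec.intron_key)
        if (
            cur is None
            or rec.p_it > cur.p_it
            or (rec.p_it == cur.p_it and rec.transcript_id < cur.transcript_id)
        ):
            best_record[rec.intron_key] = rec
    rows = []
    for key in sorted(collapsed):
        ip = collapsed[key]
        rec = best_record[key]
        chrom, start, end, strand = key
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "gene_id": gene_by_transcript.get(rec.transcript_id, "NA"),
                "transcript_id": rec.transcript_id,
                "d_i": rec.d_i,
                "P_it_max": rec.p_it,
                "P_i": ip.p_i,
                "n_reads": rec.n_reads,
                "n_spanning": rec.n_spanning,
                "persistent_flag": classify_persistent(ip.p_i, params.persistent_threshold),
            }
        )
    columns = [
        "chrom", "start", "end", "strand", "gene_id", "transcript_id",
        "d_i", "P_it_max", "P_i", "n_reads", "n_spanning", "persistent_flag",
    ]
    return pd.DataFrame(rows, columns=columns)
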