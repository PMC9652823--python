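"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity with plain loops (and exact
rational arithmetic for persistence) so they stay independent of the
package's optimized code paths.
"""

from __future__ import annotations

from fractions import Fraction

UNCOVERED, SPLICED, RETAINED = 0, 1, 2


def oracle_sf(row, target, sf_single=Fraction(1)):
    spanned = [i for i in range(len(row)) if row[i] != UNCOVERED]
    assert row[target] != UNCOVERED
    if len(spanned) == 1:
        return Fraction(sf_single)
    n_spliced = sum(1 for i in spanned if row[i] == SPLICED)
    r = 1 if row[target] == RETAINED else 0
    return Fraction(n_spliced + r - 1, len(spanned) - 1)


def oracle_h(states, read, target):
    assert states[read][target] != UNCOVERED
    spanning = [r for r in range(len(states)) if states[r][target] != UNCOVERED]
    comparison = [r for r in spanning if states[r][target] == states[read][target]]
    query_spanned = [i for i in range(len(states[read])) if states[read][i] != UNCOVERED]
    total = Fraction(0)
    for other in comparison:
        shared = [i for i in query_spanned if states[other][i] != UNCOVERED]
        assert shared
        matches = sum(1 for i in shared if states[other][i] == states[read][i])
        total += Fraction(matches, len(shared))
    return total / len(comparison)


def oracle_p_it(states, target, denominator="assigned", sf_single=Fraction(1)):
    """Exact-rational nested-loop evaluation of per-transcript persistence."""
    n_reads = len(states)
    spanning = [r for r in range(n_reads) if states[r][target] != UNCOVERED]
    d_i = Fraction(len(spanning), n_reads)
    total = Fraction(0)
    for r in spanning:
        if states[r][target] != RETAINED:
            continue
        total += oracle_sf(states[r], target, sf_single) * oracle_h(states, r, target)
    denom = n_reads if denominator == "assigned" else max(len(spanning), 1)
    p = d_i * total / denom
    return min(max(p, Fraction(0)), Fraction(1))


def oracle_exon_overlap(intron_start, intron_end, exons):
    """Per-base sweep: (n overlapping exons, pct bases covered, max depth)."""
    hits = [
        (s, e)
        for s, e in exons
        if s < intron_end and e > intron_start
    ]
    depth = [0] * (intron_end - intron_start)
    for s, e in hits:
        for p in range(max(s, intron_start), min(e, intron_end)):
            depth[p - intron_start] += 1
    covered = sum(1 for d in depth if d > 0)
    pct = 100.0 * covered / len(depth)
    return len(hits), pct, (max(depth) if depth else 0)


def oracle_fleiss(matrix):
    """Textbook Fleiss' kappa over a binary subjects x raters matrix."""
    n_subjects = len(matrix)
    n_raters = len(matrix[0])
    counts = []
    for row in matrix:
        pos = sum(1 for x in row if x)
        counts.append((n_raters - pos, pos))
    p_j = [
        Fraction(sum(c[j] for c in counts), n_subjects * n_raters) for j in (0, 1)
    ]
    p_e = sum(p * p for p in p_j)
    p_subjects = [
        Fraction(sum(c * c for c in row) - n_raters, n_raters * (n_raters - 1))
        for row in counts
    ]
    p_bar = sum(p_subjects) / n_subjects
    if p_e == 1:
        return None
    return float((p_bar - p_e) / (1 - p_e))
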