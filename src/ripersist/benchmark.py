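"""Benchmarking of short-read retained-intron callers against
persistent introns.

Caller outputs are harmonized onto the long-read intron ranges with
length-weighted medians (LWM), turned into boolean calls via per-tool
threshold rules, scored against the persistent-intron set as
TP/FP/FN/TN, and summarized: precision/recall/F1, persistence-threshold
sweeps, Fleiss' kappa agreement, cross-tool consensus counts,
intron-length-binned performance, and 1000-bin coverage/exon-overlap
profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GenomicInterval, IntervalIndex

TP, FP, FN, TN = "TP", "FP", "FN", "TN"


# ---------------------------------------------------------------------------
# length-weighted medians

def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median with even-split midpoint.

    Scores are sorted ascending; the result is the first score whose
    cumulative weight reaches half the total, or the midpoint of the two
    straddling scores when the cumulative weight hits exactly half.
    Reduces to the ordinary median for equal weights.
    """
    if len(values) == 0:
        raise ValueError("no values")
    if len(values) != len(weights):
        raise ValueError("values and weights differ in length")
    order = np.argsort(np.asarray(values, dtype=float), kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half, side="left"))
    if math.isclose(cum[idx], half) and idx + 1 < len(v):
        return float((v[idx] + v[idx + 1]) / 2.0)
    return float(v[idx])


@dataclass(frozen=True)
class ScoredInterval:
    interval: GenomicInterval
    score: float
    aux: Mapping[str, float] = field(default_factory=dict)


@dataclass
class ToolCallSet:
    tool_name: str
    records: list[ScoredInterval]


def length_weighted_median(
    target: GenomicInterval, records: Sequence[ScoredInterval]
) -> float | None:
    """LWM score of the records overlapping the target, or None."""
    vals, weights = [], []
    for rec in records:
        if rec.interval.chrom != target.chrom:
            continue
        ov = target.overlap_length(rec.interval.start, rec.interval.end)
        if ov > 0:
            vals.append(rec.score)
            weights.append(ov)
    if not vals:
        return None
    return weighted_median(vals, weights)


def _harmonize_aux(
    target: GenomicInterval, records: Sequence[ScoredInterval]
) -> dict[str, float]:
    """Aggregate auxiliary columns over overlapping records by LWM."""
    per_field: dict[str, tuple[list[float], list[float]]] = {}
    for rec in records:
        if rec.interval.chrom != target.chrom:
            continue
        ov = target.overlap_length(rec.interval.start, rec.interval.end)
        if ov <= 0:
            continue
        for name, value in rec.aux.items():
            vals, weights = per_field.setdefault(name, ([], []))
            vals.append(float(value))
            weights.append(ov)
    return {name: weighted_median(v, w) for name, (v, w) in per_field.items()}


def harmonize(
    universe: Sequence[GenomicInterval], call_sets: Sequence[ToolCallSet]
) -> pd.DataFrame:
    """Harmonized call table: one row per (intron, tool).

    Columns: intron key parts, tool, lwm (NaN when no record overlaps),
    plus harmonized aux columns prefixed ``aux_``.
    """
    rows = []
    for cs in call_sets:
        index = IntervalIndex()
        for i, rec in enumerate(cs.records):
            index.add(rec.interval.chrom, rec.interval.start, rec.interval.end, i)
        index.build()
        for intron in universe:
            hits = [
                cs.records[i]
                for _, _, i in index.query(intron.chrom, intron.start, intron.end)
            ]
            lwm = length_weighted_median(intron, hits)
            row = {
                "chrom": intron.chrom,
                "start": intron.start,
                "end": intron.end,
                "strand": intron.strand,
                "tool": cs.tool_name,
                "lwm": np.nan if lwm is None else lwm,
            }
            for name, value in _harmonize_aux(intron, hits).items():
                row[f"aux_{name}"] = value
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-tool calling rules

_OPS = {
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
    "<=": lambda a, b: a <= b,
    "<": lambda a, b: a < b,
    "==": lambda a, b: a == b,
}


@dataclass(frozen=True)
class CallRule:
    """Conjunction of threshold comparisons over LWM and aux fields.

    Each condition is (field, op, value) with op in >=, >, <=, <, ==;
    field "lwm" refers to the harmonized score, anything else to an aux
    column. op "falsy" requires the field to be absent/zero (used for
    flag columns).
    """

    tool_name: str
    conditions: tuple[tuple[str, str, float], ...]

    def __call__(self, lwm: float | None, aux: Mapping[str, float]) -> bool:
        if lwm is None or (isinstance(lwm, float) and math.isnan(lwm)):
            return False
        for name, op, value in self.conditions:
            if name == "lwm":
                operand = lwm
            else:
                if op == "falsy":
                    operand = aux.get(name, 0.0)
                    if operand is None or (
                        isinstance(operand, float) and math.isnan(operand)
                    ):
                        operand = 0.0
                    if operand:
                        return False
                    continue
                if name not in aux or (
                    isinstance(aux[name], float) and math.isnan(aux[name])
                ):
                    raise KeyError(
                        f"rule for {self.tool_name} references missing aux field {name!r}"
                    )
                operand = aux[name]
            if op == "falsy":
                if operand:
                    return False
                continue
            if not _OPS[op](operand, value):
                return False
        return True


# iREAD's expression/fragment floors differ by sequencing depth; they
# are profiles, not per-sample constants.
IREAD_PROFILES = {
    "default": {"fpkm": 3.0, "fragments": 20.0},
    "low_coverage": {"fpkm": 1.0, "fragments": 10.0},
}


def default_call_rules(profile: str = "default") -> dict[str, CallRule]:
    """The shipped per-tool calling rules on harmonized scores."""
    ip = IREAD_PROFILES[profile]
    rules = [
        CallRule("IntEREst", (("lwm", ">=", 45.0),)),
        CallRule("KMA", (("unique_counts", ">=", 10.0),)),
        CallRule(
            "iREAD",
            (
                ("entropy", ">=", 0.9),
                ("junction_reads", ">=", 1.0),
                ("lwm", ">=", ip["fpkm"]),
                ("fragments", ">=", ip["fragments"]),
            ),
        ),
        CallRule("superintronic", (("lwm", ">=", 3.0),)),
        CallRule("IRFinder-S", (("lwm", ">=", 0.5), ("flags", "falsy", 0.0))),
        CallRule("MAJIQ", (("lwm", ">", 0.5),)),
        CallRule("rMATS", (("lwm", ">", 0.8),)),
        CallRule("SUPPA2", (("lwm", ">", 0.8),)),
    ]
    return {r.tool_name: r for r in rules}


def apply_call_rule(row: Mapping, rule: CallRule) -> bool:
    """Evaluate a rule on one harmonized-table row."""
    aux = {
        k[len("aux_"):]: v for k, v in row.items() if isinstance(k, str) and k.startswith("aux_")
    }
    lwm = row.get("lwm")
    return rule(lwm, aux)


def apply_call_rules(
    harmonized: pd.DataFrame, rules: Mapping[str, CallRule]
) -> pd.DataFrame:
    """Add a boolean ``called`` column to the harmonized table."""
    out = harmonized.copy()
    called = []
    for _, row in out.iterrows():
        rule = rules.get(row["tool"])
        if rule is None:
            raise KeyError(
                f"no call rule for tool {row['tool']!r}; known: {sorted(rules)}"
            )
        called.append(apply_call_rule(row.to_dict(), rule))
    out["called"] = called
    return out


# ---------------------------------------------------------------------------
# truth categories and performance

def call_matrix(harmonized_called: pd.DataFrame) -> pd.DataFrame:
    """Pivot to introns x tools boolean call matrix."""
    df = harmonized_called.copy()
    df["intron_key"] = list(zip(df["chrom"], df["start"], df["end"], df["strand"]))
    mat = df.pivot_table(
        index="intron_key", columns="tool", values="called", aggfunc="first"
    ).fillna(False).astype(bool)
    mat.columns.name = None
    return mat.sort_index()


def assign_truth(
    calls: pd.DataFrame, persistent: set, universe: "Iterable[tuple] | None" = None
) -> pd.DataFrame:
    """Introns x tools truth-category table.

    ``calls`` is an introns x tools boolean matrix indexed by intron
    key; ``persistent`` is the set of persistent intron keys. Introns
    outside ``universe`` (when given) are excluded.
    """
    if universe is not None:
        universe = set(universe)
        calls = calls.loc[[k for k in calls.index if k in universe]]
    out = pd.DataFrame(index=calls.index, columns=calls.columns, dtype=object)
    for key in calls.index:
        is_persistent = key in persistent
        for tool in calls.columns:
            called = bool(calls.at[key, tool])
            if is_persistent:
                out.at[key, tool] = TP if called else FN
            else:
                out.at[key, tool] = FP if called else TN
    return out


@dataclass(frozen=True)
class PerformanceSummary:
    tool_name: str
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None


def performance(
    truth: pd.DataFrame, tool: str, threshold: float = 0.1
) -> PerformanceSummary:
    """Precision/recall/F1 for one tool's truth-category column.

    Metrics with zero denominators are reported as None, never as 0.
    """
    col = truth[tool]
    tp = int((col == TP).sum())
    fp = int((col == FP).sum())
    fn = int((col == FN).sum())
    tn = int((col == TN).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return PerformanceSummary(tool, threshold, tp, fp, fn, tn, precision, recall, f1)


def performance_frame(summaries: Iterable[PerformanceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tool": s.tool_name,
                "threshold": s.threshold,
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
                "tn": s.tn,
                "precision": np.nan if s.precision is None else s.precision,
                "recall": np.nan if s.recall is None else s.recall,
                "f1": np.nan if s.f1 is None else s.f1,
            }
            for s in summaries
        ],
        columns=["tool", "threshold", "tp", "fp", "fn", "tn", "precision", "recall", "f1"],
    )


DEFAULT_THRESHOLDS = tuple(round(0.1 * k, 1) for k in range(1, 10))


def threshold_sweep(
    p_i: Mapping[tuple, float],
    calls: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[PerformanceSummary]:
    """Performance of every tool at each persistence threshold."""
    summaries = []
    for threshold in thresholds:
        persistent = {k for k, p in p_i.items() if p >= threshold}
        truth = assign_truth(calls, persistent)
        for tool in calls.columns:
            summaries.append(performance(truth, tool, threshold))
    return summaries


def potential_vs_called(
    p_i: Mapping[tuple, float],
    harmonized_called: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Paired performance of 'potential' RIs (LWM present) vs rule-passing calls."""
    called = call_matrix(harmonized_called)
    potential_df = harmonized_called.copy()
    potential_df["called"] = potential_df["lwm"].notna()
    potential = call_matrix(potential_df)
    frames = []
    for label, mat in (("potential", potential), ("called", called)):
        df = performance_frame(threshold_sweep(p_i, mat, thresholds))
        df.insert(0, "call_set", label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# agreement and consensus

def fleiss_kappa(calls: "pd.DataFrame | np.ndarray") -> float | None:
    """Fleiss' kappa for binary called/not-called ratings.

    Rows are subjects (introns), columns raters (tools). Returns None
    when expected agreement is 1 (all ratings in one category).
    """
    mat = np.asarray(calls, dtype=bool)
    n_subjects, n_raters = mat.shape
    if n_subjects < 2 or n_raters < 2:
        raise ValueError("need >= 2 introns and >= 2 tools")
    pos = mat.sum(axis=1)
    counts = np.column_stack([n_raters - pos, pos]).astype(float)
    p_j = counts.sum(axis=0) / (n_subjects * n_raters)
    p_e = float(np.sum(p_j**2))
    p_i = (np.sum(counts**2, axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = float(np.mean(p_i))
    if math.isclose(p_e, 1.0):
        return None
    return (p_bar - p_e) / (1.0 - p_e)


def consensus_counts(truth: pd.DataFrame, category: str, min_tools: int) -> int:
    """Number of introns in the given truth category for >= min_tools tools."""
    if category not in (TP, FP, FN):
        raise ValueError(f"category must be one of TP/FP/FN, got {category!r}")
    per_intron = (truth == category).sum(axis=1)
    return int((per_intron >= min_tools).sum())


def consensus_members(truth: pd.DataFrame, category: str, min_tools: int) -> list:
    per_intron = (truth == category).sum(axis=1)
    return sorted(per_intron.index[per_intron >= min_tools])


# ---------------------------------------------------------------------------
# binned summaries

def length_windows(
    window_width: int = 300, step: int = 100, min_len: int = 0, max_len: int = 4300
) -> list[tuple[int, int]]:
    """Sliding windows [s, s+width) with s stepping from min_len while
    the window stays within max_len. Defaults yield 41 windows."""
    if window_width <= 0 or step <= 0:
        raise ValueError("window width and step must be positive")
    return [
        (s, s + window_width)
        for s in range(min_len, max_len - window_width + 1, step)
    ]


def binned_performance(
    intron_lengths: Mapping[tuple, int],
    truth: pd.DataFrame,
    window_width: int = 300,
    step: int = 100,
    min_len: int = 0,
    max_len: int = 4300,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-tool performance within sliding intron-length windows.

    An intron contributes to every window containing its length.
    """
    windows = length_windows(window_width, step, min_len, max_len)
    rows = []
    for lo, hi in windows:
        keys = [k for k in truth.index if lo <= intron_lengths[k] < hi]
        sub = truth.loc[keys]
        for tool in truth.columns:
            if len(sub) == 0:
                s = PerformanceSummary(tool, threshold, 0, 0, 0, 0, None, None, None)
            else:
                s = performance(sub, tool, threshold)
            rows.append(
                {
                    "window_start": lo,
                    "window_end": hi,
                    "tool": tool,
                    "n_introns": len(keys),
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                    "tn": s.tn,
                    "precision": np.nan if s.precision is None else s.precision,
                    "recall": np.nan if s.recall is None else s.recall,
                    "f1": np.nan if s.f1 is None else s.f1,
                }
            )
    return pd.DataFrame(rows)


def binned_intron_profile(
    introns: Sequence[GenomicInterval],
    coverage: CoverageTrack,
    exon_index: IntervalIndex,
    n_bins: int = 1000,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """1000-bin normalized coverage and exon-overlap profile.

    Each intron is rescaled to ``n_bins`` equal bins on the positive
    strand (5'->3' on +; minus-strand introns are NOT flipped). Per
    bin: log10(median across introns of the bin's mean per-base
    coverage + pseudocount) and the fraction of introns whose bin
    overlaps at least one annotated exon. Bins shorter than one base
    are handled by proportional overlap weighting.
    """
    if not introns:
        raise ValueError("no introns in group")
    cov = np.zeros((len(introns), n_bins))
    exon_hit = np.zeros((len(introns), n_bins), dtype=bool)
    for j, intron in enumerate(introns):
        length = len(intron)
        edges = intron.start + np.arange(n_bins + 1) * (length / n_bins)
        for b in range(n_bins):
            a, z = edges[b], edges[b + 1]
            cov[j, b] = coverage.integral(intron.chrom, a, z) / (z - a)
            lo, hi = int(math.floor(a)), int(math.ceil(z))
            exon_hit[j, b] = bool(exon_index.query(intron.chrom, lo, max(hi, lo + 1)))
    med = np.median(cov, axis=0)
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "log10_median_coverage": np.log10(med + pseudocount),
            "fraction_exon_overlap": exon_hit.mean(axis=0),
        }
    )


def loess_smooth(x: Sequence[float], y: Sequence[float], span: float = 0.5) -> np.ndarray:
    """Optional LOESS presentation helper (acceptance paths never use it)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    out = lowess(np.asarray(y, float), np.asarray(x, float), frac=span, return_sorted=False)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# caller-output IO

def read_tool_tsv(path: str, tool_name: str) -> ToolCallSet:
    """Read a per-tool scored interval table.

    Expected columns: chrom, start, end, score, then any aux columns.
    An optional ``strand`` column is honoured; absent, '+' is assumed.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    aux_cols = [c for c in df.columns if c not in required and c != "strand"]
    records = []
    for _, row in df.iterrows():
        strand = row["strand"] if "strand" in df.columns else "+"
        iv = GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]), strand)
        aux = {c: float(row[c]) for c in aux_cols}
        records.append(ScoredInterval(iv, float(row["score"]), aux))
    return ToolCallSet(tool_name, records)
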