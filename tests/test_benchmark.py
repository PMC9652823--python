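import numpy as np
import pandas as pd
import pytest

from oracles import oracle_fleiss
from ripersist import benchmark as bm
from ripersist.benchmark import (
    CallRule,
    ScoredInterval,
    ToolCallSet,
    apply_call_rule,
    assign_truth,
    binned_intron_profile,
    binned_performance,
    call_matrix,
    consensus_counts,
    default_call_rules,
    fleiss_kappa,
    harmonize,
    length_weighted_median,
    length_windows,
    performance,
    potential_vs_called,
    threshold_sweep,
    weighted_median,
)
from ripersist.coverage import CoverageTrack
from ripersist.intervals import GenomicInterval, IntervalIndex


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestWeightedMedian:
    def test_single_value(self):
        assert weighted_median([7.0], [100.0]) == 7.0

    def test_equal_weights_reduce_to_plain_median(self):
        assert weighted_median([9, 1, 5], [1, 1, 1]) == 5.0

    def test_even_split_takes_midpoint(self):
        assert weighted_median([1, 3], [1, 1]) == 2.0

    def test_dominant_low_weight(self):
        assert weighted_median([2, 10], [80, 20]) == 2.0

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(1, 10))
            v = rng.random(n).tolist()
            w = (rng.random(n) + 0.1).tolist()
            ref = weighted_median(v, w)
            perm = rng.permutation(n)
            assert weighted_median(
                [v[i] for i in perm], [w[i] for i in perm]
            ) == pytest.approx(ref)

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            weighted_median([1, 2], [1, 0])


class TestLengthWeightedMedian:
    def test_full_cover_single_record(self):
        recs = [ScoredInterval(iv(0, 100), 7.0)]
        assert length_weighted_median(iv(0, 100), recs) == 7.0

    def test_equal_overlaps_plain_median(self):
        recs = [
            ScoredInterval(iv(0, 10), 1.0),
            ScoredInterval(iv(10, 20), 5.0),
            ScoredInterval(iv(20, 30), 9.0),
        ]
        assert length_weighted_median(iv(0, 30), recs) == 5.0

    def test_worked_80_20(self):
        recs = [
            ScoredInterval(iv(0, 80), 2.0),
            ScoredInterval(iv(80, 100), 10.0),
        ]
        assert length_weighted_median(iv(0, 100), recs) == 2.0

    def test_no_overlap_absent(self):
        recs = [ScoredInterval(iv(500, 600), 3.0)]
        assert length_weighted_median(iv(0, 100), recs) is None

    def test_zero_length_overlap_excluded(self):
        recs = [ScoredInterval(iv(100, 200), 3.0)]
        assert length_weighted_median(iv(0, 100), recs) is None


class TestCallRules:
    def test_irfinder_called_without_flags(self):
        rule = default_call_rules()["IRFinder-S"]
        assert rule(0.6, {"flags": 0.0}) is True

    def test_irfinder_flag_blocks(self):
        rule = default_call_rules()["IRFinder-S"]
        assert rule(0.6, {"flags": 1.0}) is False

    def test_interest_threshold(self):
        rule = default_call_rules()["IntEREst"]
        assert rule(44.9, {}) is False
        assert rule(45.0, {}) is True

    def test_missing_lwm_is_not_called(self):
        rule = default_call_rules()["MAJIQ"]
        assert rule(None, {}) is False
        assert rule(float("nan"), {}) is False

    def test_missing_aux_field_is_configuration_error(self):
        rule = default_call_rules()["KMA"]
        with pytest.raises(KeyError, match="unique_counts"):
            rule(5.0, {})

    def test_iread_profiles(self):
        strict = default_call_rules("default")["iREAD"]
        relaxed = default_call_rules("low_coverage")["iREAD"]
        aux = {"entropy": 0.95, "junction_reads": 2.0, "fragments": 12.0}
        assert strict(2.0, aux) is False  # fragments < 20, fpkm < 3
        assert relaxed(2.0, aux) is True

    def test_apply_on_row(self):
        rule = default_call_rules()["KMA"]
        row = {"lwm": 5.0, "aux_unique_counts": 12.0}
        assert apply_call_rule(row, rule) is True


def _calls_df(universe, tool_flags):
    """Build a harmonized+called frame from {tool: {key: bool}}."""
    rows = []
    for tool, flags in tool_flags.items():
        for intron in universe:
            rows.append(
                {
                    "chrom": intron.chrom,
                    "start": intron.start,
                    "end": intron.end,
                    "strand": intron.strand,
                    "tool": tool,
                    "lwm": 1.0,
                    "called": flags[intron.key],
                }
            )
    return pd.DataFrame(rows)


class TestTruthAndPerformance:
    universe = [iv(0, 100), iv(200, 300), iv(400, 500), iv(600, 700)]

    def test_categories(self):
        persistent = {self.universe[0].key, self.universe[1].key}
        flags = {
            self.universe[0].key: True,   # TP
            self.universe[1].key: False,  # FN
            self.universe[2].key: True,   # FP
            self.universe[3].key: False,  # TN
        }
        calls = call_matrix(_calls_df(self.universe, {"toolX": flags}))
        truth = assign_truth(calls, persistent)
        col = truth["toolX"]
        assert col[self.universe[0].key] == "TP"
        assert col[self.universe[1].key] == "FN"
        assert col[self.universe[2].key] == "FP"
        assert col[self.universe[3].key] == "TN"

    def test_universe_restriction(self):
        flags = {k.key: True for k in self.universe}
        calls = call_matrix(_calls_df(self.universe, {"t": flags}))
        truth = assign_truth(calls, set(), universe=[self.universe[0].key])
        assert len(truth) == 1

    def test_performance_balanced(self):
        df = pd.DataFrame({"t": ["TP", "TP", "FP", "FP", "FN", "FN"]})
        s = performance(df, "t")
        assert (s.precision, s.recall, s.f1) == (0.5, 0.5, 0.5)

    def test_performance_missing_metrics(self):
        df = pd.DataFrame({"t": ["FN"] * 5})
        s = performance(df, "t")
        assert s.precision is None
        assert s.recall == 0.0
        assert s.f1 is None

    def test_performance_harmonic_mean(self):
        df = pd.DataFrame({"t": ["TP"] * 6 + ["FP"] * 2 + ["FN"] * 3})
        s = performance(df, "t")
        assert s.precision == pytest.approx(0.75)
        assert s.recall == pytest.approx(2 / 3)
        assert s.f1 == pytest.approx(12 / 17)

    def test_counts_partition_universe(self):
        rng = np.random.default_rng(5)
        persistent = {u.key for u in self.universe if rng.random() < 0.5}
        flags = {u.key: bool(rng.random() < 0.5) for u in self.universe}
        calls = call_matrix(_calls_df(self.universe, {"t": flags}))
        truth = assign_truth(calls, persistent)
        s = performance(truth, "t")
        assert s.tp + s.fp + s.fn + s.tn == len(self.universe)


class TestThresholdSweep:
    def test_default_thresholds_give_nine_rows_per_tool(self):
        universe = [iv(0, 100), iv(200, 300)]
        p_i = {universe[0].key: 0.55, universe[1].key: 0.0}
        flags = {universe[0].key: True, universe[1].key: False}
        calls = call_matrix(_calls_df(universe, {"a": flags, "b": flags}))
        summaries = threshold_sweep(p_i, calls)
        assert len(summaries) == 18
        assert sorted({s.threshold for s in summaries}) == [
            pytest.approx(0.1 * k) for k in range(1, 10)
        ]

    def test_persistent_set_shrinks_with_threshold(self):
        rng = np.random.default_rng(8)
        p_i = {iv(k * 10, k * 10 + 5).key: float(rng.random()) for k in range(30)}
        sizes = [
            sum(1 for p in p_i.values() if p >= t) for t in bm.DEFAULT_THRESHOLDS
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_tp_plus_fn_constant_across_tools(self):
        universe = [iv(k * 10, k * 10 + 5) for k in range(20)]
        rng = np.random.default_rng(9)
        p_i = {u.key: float(rng.random()) for u in universe}
        tool_flags = {
            t: {u.key: bool(rng.random() < 0.5) for u in universe}
            for t in ("a", "b", "c")
        }
        calls = call_matrix(_calls_df(universe, tool_flags))
        for threshold in (0.1, 0.5):
            truth = assign_truth(calls, {k for k, p in p_i.items() if p >= threshold})
            totals = {
                t: performance(truth, t).tp + performance(truth, t).fn
                for t in calls.columns
            }
            assert len(set(totals.values())) == 1

    def test_potential_vs_called_identical_when_rule_always_true(self):
        universe = [iv(0, 100), iv(200, 300)]
        p_i = {universe[0].key: 0.5, universe[1].key: 0.0}
        df = _calls_df(universe, {"a": {u.key: True for u in universe}})
        paired = potential_vs_called(p_i, df, thresholds=(0.1,))
        pot = paired[paired.call_set == "potential"].drop(columns="call_set")
        cal = paired[paired.call_set == "called"].drop(columns="call_set")
        pd.testing.assert_frame_equal(pot.reset_index(drop=True), cal.reset_index(drop=True))


class TestFleissKappa:
    def test_perfect_agreement(self):
        mat = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0]], dtype=bool)
        assert fleiss_kappa(mat) == pytest.approx(1.0)

    def test_coin_flips_near_zero(self):
        rng = np.random.default_rng(42)
        mat = rng.random((1000, 8)) < 0.5
        kappa = fleiss_kappa(mat)
        assert abs(kappa) < 0.05

    def test_hand_matrix(self):
        # counts per subject (neg, pos): (1,2) (2,1) (0,3) (3,0)
        mat = [[1, 1, 0], [1, 0, 0], [1, 1, 1], [0, 0, 0]]
        assert fleiss_kappa(np.array(mat, dtype=bool)) == pytest.approx(1 / 3)
        assert oracle_fleiss(mat) == pytest.approx(1 / 3)

    def test_all_one_category_undefined(self):
        mat = np.ones((5, 4), dtype=bool)
        assert fleiss_kappa(mat) is None

    def test_matches_direct_formula_on_random_matrices(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 100:
            mat = (rng.random((10, 4)) < rng.random()).astype(bool)
            expected = oracle_fleiss(mat.tolist())
            if expected is None:
                continue
            assert fleiss_kappa(mat) == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(23)
        mat = (rng.random((50, 6)) < 0.3).astype(int)
        counts, _ = aggregate_raters(mat)
        assert fleiss_kappa(mat.astype(bool)) == pytest.approx(sm_fleiss(counts))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.ones((1, 3), dtype=bool))


class TestConsensus:
    def _truth(self):
        index = [("chr1", k, k + 5, "+") for k in range(0, 40, 10)]
        data = {
            "a": ["TP", "FP", "FN", "TN"],
            "b": ["TP", "FP", "TN", "TN"],
            "c": ["TP", "TN", "TN", "TN"],
        }
        return pd.DataFrame(data, index=index)

    def test_threshold_counts(self):
        truth = self._truth()
        assert consensus_counts(truth, "TP", 3) == 1
        assert consensus_counts(truth, "FP", 2) == 1
        assert consensus_counts(truth, "FP", 3) == 0
        assert consensus_counts(truth, "FN", 1) == 1

    def test_min_tools_above_raters_is_zero(self):
        assert consensus_counts(self._truth(), "TP", 9) == 0

    def test_non_increasing_in_k(self):
        truth = self._truth()
        for cat in ("TP", "FP", "FN"):
            counts = [consensus_counts(truth, cat, k) for k in range(1, 5)]
            assert counts == sorted(counts, reverse=True)

    def test_invalid_category(self):
        with pytest.raises(ValueError):
            consensus_counts(self._truth(), "TN", 1)


class TestBinnedPerformance:
    def test_default_window_count_is_41(self):
        assert len(length_windows()) == 41

    def test_window_count_closed_form(self):
        for width, step, mx in ((300, 100, 4300), (200, 50, 1000), (100, 100, 500)):
            assert len(length_windows(width, step, 0, mx)) == (mx - width) // step + 1

    def test_intron_assigned_to_every_containing_window(self):
        key = ("chr1", 0, 250, "+")
        truth = pd.DataFrame({"t": ["TP"]}, index=[key])
        df = binned_performance({key: 250}, truth)
        present = df[df.n_introns > 0]
        assert set(present.window_start) == {0, 100, 200}

    def test_empty_window_metrics_missing(self):
        key = ("chr1", 0, 5000, "+")
        truth = pd.DataFrame({"t": ["TP"]}, index=[key])
        df = binned_performance({key: 5000}, truth)
        assert df.n_introns.eq(0).all()
        assert df.precision.isna().all()


class TestBinnedProfile:
    def _flat_track(self, value, end=10_000):
        track = CoverageTrack()
        track.add("chr1", 0, end, value)
        return track.build()

    def test_uniform_coverage(self):
        track = self._flat_track(4.0)
        introns = [iv(0, 1000), iv(2000, 3500)]
        prof = binned_intron_profile(introns, track, IntervalIndex().build(), n_bins=100)
        assert np.allclose(prof.log10_median_coverage, np.log10(5.0))
        assert (prof.fraction_exon_overlap == 0).all()

    def test_decreasing_coverage_gives_decreasing_bins(self):
        track = CoverageTrack()
        for p in range(1000):
            track.add("chr1", p, p + 1, 1000 - p)
        track.build()
        prof = binned_intron_profile([iv(0, 1000)], track, IntervalIndex().build(), n_bins=50)
        diffs = np.diff(prof.log10_median_coverage.to_numpy())
        assert (diffs < 0).all()

    def test_exon_overlap_fraction_by_half(self):
        track = self._flat_track(1.0)
        exons = IntervalIndex()
        exons.add("chr1", 0, 500, "tx")  # first half of intron 1 only
        exons.build()
        introns = [iv(0, 1000), iv(2000, 3000)]
        prof = binned_intron_profile(introns, track, exons, n_bins=10)
        assert np.allclose(prof.fraction_exon_overlap[:5], 0.5)
        assert np.allclose(prof.fraction_exon_overlap[5:], 0.0)

    def test_intron_shorter_than_bins_uses_fractional_weighting(self):
        track = self._flat_track(3.0)
        prof = binned_intron_profile([iv(0, 10)], track, IntervalIndex().build(), n_bins=100)
        assert np.allclose(prof.log10_median_coverage, np.log10(4.0))


class TestHarmonize:
    def test_lwm_and_called_columns(self):
        universe = [iv(0, 100), iv(200, 300)]
        cs = ToolCallSet(
            "superintronic",
            [ScoredInterval(iv(0, 80), 4.0), ScoredInterval(iv(80, 100), 1.0)],
        )
        harmonized = harmonize(universe, [cs])
        called = bm.apply_call_rules(harmonized, default_call_rules())
        row0 = called[(called.start == 0)].iloc[0]
        assert row0["lwm"] == 4.0
        assert bool(row0["called"]) is True
        row1 = called[(called.start == 200)].iloc[0]
        assert np.isnan(row1["lwm"])
        assert bool(row1["called"]) is False

    def test_unknown_tool_raises(self):
        universe = [iv(0, 100)]
        cs = ToolCallSet("mystery", [ScoredInterval(iv(0, 100), 1.0)])
        harmonized = harmonize(universe, [cs])
        with pytest.raises(KeyError, match="mystery"):
            bm.apply_call_rules(harmonized, default_call_rules())
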