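"""Scoring, binomial threshold selection, coverage, and summary tables."""

import numpy as np
import pytest
from scipy.stats import binom

from conftest import make_lineage

from ampligauge.calibrate import (
    BIN_LOWER,
    DEFAULT_FPR_GRID,
    N_BINS,
    UNATTAINABLE,
    ConfidenceHistogram,
    Outcome,
    ThresholdRequest,
    ThresholdTable,
    ThresholdEntry,
    bin_confidences,
    bin_index,
    coverage,
    fpr,
    fpr_coverage_curve,
    median_threshold,
    pick_threshold,
    score_prediction,
    write_summary,
)
from ampligauge.errors import CalibrationError
from ampligauge.lko import LkoConfig, LkoRun, LkoRecord
from ampligauge.nbc import ClassificationResult
from ampligauge.taxonomy import Rank, SynonymMap


def _pred(qid="q", entries=(), **kw):
    return ClassificationResult(query_id=qid, entries=tuple(entries), **kw)


def _full_pred(qid, genus_conf=100, family_conf=100, skip=(), confs=None):
    lin = make_lineage("G1")
    confs = confs or {}
    entries = []
    for rank, name in lin.entries:
        if rank in skip:
            continue
        conf = confs.get(rank, family_conf if rank is Rank.FAMILY else genus_conf if rank is Rank.GENUS else 100)
        entries.append((rank, name, conf))
    return _pred(qid, entries)


class TestScorePrediction:
    def test_matching_family_is_tp(self):
        pred = _full_pred("q")
        ref = make_lineage("G1")
        assert score_prediction(pred, ref, Rank.FAMILY) is Outcome.TP

    def test_rank_only_in_prediction_is_fp(self):
        pred = _full_pred("q")
        ref = make_lineage("G9", gap_order_family=True)  # ref lacks family
        assert score_prediction(pred, ref, Rank.FAMILY) is Outcome.FP

    def test_rank_absent_from_prediction_is_neither(self):
        pred = _full_pred("q", skip=(Rank.FAMILY,))
        ref = make_lineage("G1")
        assert score_prediction(pred, ref, Rank.FAMILY) is Outcome.NEITHER

    def test_name_mismatch_is_fp(self):
        pred = _full_pred("q")
        ref = make_lineage("G1", family="F9")
        assert score_prediction(pred, ref, Rank.FAMILY) is Outcome.FP

    def test_synonyms_make_tp(self):
        pred = _full_pred("q")
        ref = make_lineage("G1", family="F1_alias")
        syn = SynonymMap([("F1", "F1_alias")])
        assert score_prediction(pred, ref, Rank.FAMILY, syn) is Outcome.TP


class TestFpr:
    @pytest.mark.parametrize(
        "tp,fp,expected", [(19, 1, 0.05), (10, 0, 0.0), (0, 0, None)]
    )
    def test_hand_arithmetic(self, tp, fp, expected):
        assert fpr(tp, fp) == expected


class TestBins:
    @pytest.mark.parametrize("conf,idx", [(0, 0), (4, 0), (5, 1), (97, 19), (99, 19), (100, 20)])
    def test_bin_boundaries(self, conf, idx):
        assert bin_index(conf) == idx

    def test_out_of_range_confidence_is_error(self):
        with pytest.raises(CalibrationError):
            bin_index(101)

    def test_histograms_from_run(self):
        ref = make_lineage("G1")
        records = [
            LkoRecord(0, "a", ref, _full_pred("a", confs={Rank.FAMILY: 97}), (), ()),
            LkoRecord(0, "b", ref, _full_pred("b", confs={Rank.FAMILY: 97}), (), ()),
            LkoRecord(0, "c", ref, _full_pred("c", confs={Rank.FAMILY: 97}), (), ()),
        ]
        run = LkoRun(LkoConfig(repeats=1), records, (0,))
        (hist,) = bin_confidences(run, Rank.FAMILY)
        assert hist.tp[19] == 3 and hist.tp.sum() == 3 and hist.fp.sum() == 0

    def test_empty_run_gives_zero_histogram(self):
        run = LkoRun(LkoConfig(repeats=1), [], (0,))
        (hist,) = bin_confidences(run, Rank.GENUS)
        assert hist.tp.sum() == 0 and hist.fp.sum() == 0


def brute_force_threshold(hist, e, alpha=0.05):
    """Independent oracle: evaluate all 21 bins with scipy.stats.binom,
    then replay the downward scan over the full table."""
    probs = binom.cdf(hist.tp, hist.tp + hist.fp, 1.0 - e)
    for i in range(N_BINS - 1, -1, -1):
        if hist.tp[i] + hist.fp[i] == 0:
            continue
        if probs[i] <= alpha:
            return UNATTAINABLE if i == N_BINS - 1 else BIN_LOWER[i + 1]
    return 0


class TestPickThreshold:
    def test_all_pure_tp_gives_zero_threshold(self):
        hist = ConfidenceHistogram(rank=Rank.GENUS)
        hist.tp[:] = 50
        assert pick_threshold(hist, ThresholdRequest(e=0.05)) == 0

    def test_failing_interval_below_100_picks_100(self):
        hist = ConfidenceHistogram(rank=Rank.GENUS)
        hist.tp[20], hist.fp[20] = 100, 0
        hist.tp[19], hist.fp[19] = 50, 50
        # P(X<=50 | n=100, p=0.95) is astronomically small
        assert binom.cdf(50, 100, 0.95) < 1e-20
        assert pick_threshold(hist, ThresholdRequest(e=0.05)) == 100

    def test_failing_100_bin_is_unattainable(self):
        hist = ConfidenceHistogram(rank=Rank.GENUS)
        hist.tp[20], hist.fp[20] = 0, 20
        # P(X<=0 | n=20, p=0.95) = 0.05**20 <= alpha
        assert binom.cdf(0, 20, 0.95) == pytest.approx(0.05**20)
        assert pick_threshold(hist, ThresholdRequest(e=0.05)) == UNATTAINABLE

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            hist = ConfidenceHistogram(rank=Rank.GENUS)
            hist.tp[:] = rng.integers(0, 40, N_BINS)
            hist.fp[:] = rng.integers(0, 10, N_BINS)
            hist.tp[rng.random(N_BINS) < 0.3] = 0
            hist.fp[rng.random(N_BINS) < 0.3] = 0
            for e in DEFAULT_FPR_GRID:
                req = ThresholdRequest(e=e)
                assert pick_threshold(hist, req) == brute_force_threshold(hist, e)


class TestMedianThreshold:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ([90, 95, 95], 95),
            ([90, 95], 95),  # even count rounds to the larger bin
            ([UNATTAINABLE] * 5, UNATTAINABLE),
            ([0, 0, UNATTAINABLE], 0),
        ],
    )
    def test_median_rules(self, cts, expected):
        assert median_threshold(cts) == expected

    def test_empty_list_is_error(self):
        with pytest.raises(CalibrationError):
            median_threshold([])


class TestCoverage:
    def test_plain_coverage(self):
        results = [
            _full_pred(f"q{i}", confs={Rank.GENUS: 90 if i < 50 else 10})
            for i in range(100)
        ]
        rep = coverage(results, Rank.GENUS, 50)
        assert (rep.n, rep.s, rep.value) == (50, 100, 0.50)
        assert rep.gap_excluded == 0

    def test_gap_correction_shrinks_denominator(self):
        # 10 of 100 sequences classified into a phylum with no child taxa
        full = [_full_pred(f"q{i}") for i in range(90)]
        gapped = [
            _pred(
                f"g{i}",
                [(Rank.DOMAIN, "domain__Bacteria", 100), (Rank.PHYLUM, "phylum__P9", 100)],
            )
            for i in range(10)
        ]
        rep = coverage(full + gapped, Rank.CLASS, 0)
        assert rep.s == 100 and rep.gap_excluded == 10
        assert rep.value == pytest.approx(90 / 90)

    def test_rank_consistency_excludes_from_numerator(self):
        res = _full_pred("q", confs={Rank.CLASS: 52, Rank.PHYLUM: 55})
        rep = coverage(
            [res], Rank.CLASS, 50, thresholds_above={Rank.PHYLUM: 60}
        )
        assert rep.n == 0 and rep.inconsistent_excluded == 1

    def test_unattainable_threshold_passes_nothing(self):
        rep = coverage([_full_pred("q")], Rank.GENUS, UNATTAINABLE)
        assert rep.n == 0 and rep.value == 0.0

    def test_coverage_non_increasing_in_threshold(self):
        rng = np.random.default_rng(7)
        results = [
            _full_pred(f"q{i}", confs={Rank.GENUS: int(rng.integers(0, 101))})
            for i in range(60)
        ]
        values = [coverage(results, Rank.GENUS, ct).value for ct in BIN_LOWER]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_empty_denominator_is_error(self):
        with pytest.raises(CalibrationError):
            coverage([], Rank.GENUS, 0)


class TestSummary:
    def _run(self):
        ref = make_lineage("G1")
        records = [
            LkoRecord(0, "a", ref, _full_pred("a", confs={Rank.GENUS: 100}), (), ()),
            LkoRecord(0, "b", ref, _full_pred("b", confs={Rank.GENUS: 97}), (), ()),
            LkoRecord(0, "c", make_lineage("G2"), _full_pred("c", confs={Rank.GENUS: 97}), (), ()),
        ]
        return LkoRun(LkoConfig(repeats=1), records, (0,))

    def test_empty_run_writes_header_only(self, tmp_path):
        run = LkoRun(LkoConfig(repeats=1), [], (0,))
        path = tmp_path / "summary.tsv"
        frame = write_summary(run, path=path)
        assert frame.empty
        assert path.read_text().count("\n") == 1

    def test_cumulative_columns_are_suffix_sums(self):
        frame = write_summary(self._run())
        genus = frame[frame["rank"] == "genus"].reset_index(drop=True)
        itp = genus["Interval_TP"].to_numpy()
        assert np.allclose(
            genus["Cumulative_TP"].to_numpy(), np.cumsum(itp[::-1])[::-1]
        )

    def test_interval_precision_complements_fpr(self):
        frame = write_summary(self._run())
        seen = frame[(frame["rank"] == "genus") & (frame["Interval_FPR"] != "")]
        for _, row in seen.iterrows():
            assert row["Interval_precision"] == pytest.approx(
                100 - row["Interval_FPR"]
            )


class TestCurve:
    def _table(self, cts, e_grid):
        entries = {
            (Rank.GENUS, e): ThresholdEntry(Rank.GENUS, e, ct, False, (ct,))
            for e, ct in zip(e_grid, cts)
        }
        return ThresholdTable(entries=entries, alpha=0.05, e_grid=tuple(e_grid))

    def test_single_e_grid_gives_single_point(self):
        table = self._table([95], [0.05])
        results = [_full_pred("q", confs={Rank.GENUS: 100})]
        covs = {(Rank.GENUS, 0.05): coverage(results, Rank.GENUS, 95)}
        curve = fpr_coverage_curve(table, covs, ranks=[Rank.GENUS])
        assert len(curve) == 1

    def test_truncates_after_threshold_zero(self):
        e_grid = [0.01, 0.05, 0.10, 0.20]
        table = self._table([95, 0, 0, 0], e_grid)
        results = [_full_pred("q", confs={Rank.GENUS: 50})]
        covs = {
            (Rank.GENUS, e): coverage(results, Rank.GENUS, table.ct(Rank.GENUS, e))
            for e in e_grid
        }
        curve = fpr_coverage_curve(table, covs, ranks=[Rank.GENUS])
        assert list(curve["desired_fpr"]) == [0.01, 0.05]

    def test_unattainable_threshold_reports_zero_coverage(self):
        table = self._table([UNATTAINABLE], [0.01])
        curve = fpr_coverage_curve(table, {}, ranks=[Rank.GENUS])
        assert curve.iloc[0]["coverage"] == 0.0
        assert curve.iloc[0]["confidence_threshold"] == "unattainable"

    def test_coverage_monotone_in_desired_fpr(self):
        # thresholds non-increasing in e force coverage non-decreasing
        e_grid = [0.01, 0.05, 0.10, 0.30]
        cts = [100, 95, 80, 50]
        table = self._table(cts, e_grid)
        rng = np.random.default_rng(3)
        results = [
            _full_pred(f"q{i}", confs={Rank.GENUS: int(rng.integers(0, 101))})
            for i in range(80)
        ]
        covs = {
            (Rank.GENUS, e): coverage(results, Rank.GENUS, ct)
            for e, ct in zip(e_grid, cts)
        }
        curve = fpr_coverage_curve(table, covs, ranks=[Rank.GENUS])
        vals = list(curve["coverage"])
        assert all(a <= b for a, b in zip(vals, vals[1:]))
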