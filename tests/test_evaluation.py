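"""Confusion metrics, scratch-time accounting, NA-aware cohort summaries.

The cohort-arithmetic tests use a published six-subject pilot cohort as a
worked reference: its per-subject cells and printed mean ± SD column are
frozen here, and the summary routines must reproduce the printed column
from the cells.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scratchkit as sk
from scratchkit.evaluation import (
    NA,
    cohort_summary,
    format_cohort_table,
    is_na,
    na_mean_sd,
    round_half_up,
)

# Reference pilot cohort (six subjects): per-subject cells and the printed
# mean +- SD, at the precision each row was printed with.
REFERENCE_ROWS = {
    # name: (cells, printed_mean, printed_sd, printed_decimals)
    "pp_nrs": ([2, 5, 8, 3, 5, 5], 5, 2, 0),
    "easi": ([8, 16.4, 23.5, 8.2, 8.2, 14.4], 13.1, 6.2, 1),
    "scratch_time_video_s": ([77, 72, 92, 31, 20, 20], 52, 32, 0),
    "scratch_frac_video": ([.04, .04, .05, .02, .01, .01], 0.03, 0.02, 2),
    "scratch_time_device_s": ([262, 186, 184, 270, 815, 104], 303, 258, 0),
    "sensitivity": ([.21, .52, NA, .41, .47, NA], 0.40, 0.14, 2),
    "specificity": ([.86, .92, .90, .86, .55, .94], 0.84, 0.14, 2),
    "accuracy": ([.82, .91, .90, .85, .55, .94], 0.83, 0.14, 2),
    "precision": ([.09, .23, 0, .06, .01, 0], 0.06, 0.08, 2),
    "npv": ([.98, .98, 1, .99, 1, 1], 0.99, 0.01, 2),
    "event_tp_frac": ([.89, 1, 0, .94, .50, 0], 0.56, 0.46, 2),
}


class TestConfusion:
    def test_direct_counts(self):
        cm = sk.confusion([1, 1, 0], [1, 1, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 1, 0, 0)
        assert sk.confusion([1], [0]).fp == 1
        assert sk.confusion([0], [1]).fn == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sk.confusion([0, 1], [0])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(0, 200))
    def test_totals_sum_to_window_count(self, seed, n):
        r = np.random.default_rng(seed)
        cm = sk.confusion(r.integers(0, 2, n), r.integers(0, 2, n))
        assert cm.total == n


class TestMetrics:
    def test_formulas(self):
        m = sk.metrics(sk.ConfusionMatrix(tp=5, fn=5, tn=80, fp=10))
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["specificity"] == pytest.approx(80 / 90)
        assert m["precision"] == pytest.approx(5 / 15)
        assert m["npv"] == pytest.approx(80 / 85)
        assert m["accuracy"] == pytest.approx(85 / 100)

    def test_no_positives_in_truth_gives_na_sensitivity(self):
        """A subject who never scratched with the instrumented hand has
        undefined sensitivity, reported NA."""
        m = sk.metrics(sk.ConfusionMatrix(tp=0, fn=0, tn=9, fp=1))
        assert is_na(m["sensitivity"])
        assert not is_na(m["specificity"])

    def test_precision_compat_mode_reports_zero(self):
        cm = sk.ConfusionMatrix(tp=0, fn=2, tn=8, fp=0)
        assert is_na(sk.metrics(cm)["precision"])
        assert sk.metrics(cm, compat_precision_zero=True)["precision"] == 0

    def test_perfect_prediction_gives_ones(self):
        m = sk.metrics(sk.ConfusionMatrix(tp=5, tn=5))
        assert all(v == 1.0 for v in m.values())

    def test_all_zero_matrix_is_all_na(self):
        assert all(is_na(v) for v in
                   sk.metrics(sk.ConfusionMatrix()).values())

    @settings(max_examples=50, deadline=None)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    def test_defined_metrics_lie_in_unit_interval(self, tp, fp, tn, fn):
        for v in sk.metrics(sk.ConfusionMatrix(tp, fp, tn, fn)).values():
            assert is_na(v) or 0.0 <= v <= 1.0


class TestScratchTime:
    def test_77_seconds_in_30_minutes_rounds_to_004(self):
        labels = np.zeros(1800, dtype=int)
        labels[:77] = 1
        seconds, frac = sk.scratch_time(labels, 1.0, 1800.0)
        assert seconds == 77
        assert round_half_up(frac, 2) == 0.04

    def test_270_positive_windows_give_270_seconds(self):
        labels = np.concatenate([np.ones(270, dtype=int),
                                 np.zeros(1000, dtype=int)])
        seconds, _ = sk.scratch_time(labels, 1.0, 1800.0)
        assert seconds == 270

    def test_no_positive_windows(self):
        assert sk.scratch_time(np.zeros(10, dtype=int), 1.0, 100.0) \
            == (0.0, 0.0)


class TestEventDetection:
    def test_fully_covered_event_detected(self):
        pred = np.array([1, 1, 1])
        starts = np.array([0, 20, 40])
        assert sk.event_detection(pred, starts, [(0.5, 2.0)]) == 1.0

    def test_no_events_is_na(self):
        assert is_na(sk.event_detection(np.array([1]), np.array([0]), []))

    def test_two_of_three_events_overlapped(self):
        # positive windows cover 0-1.5 s and 10-11.5 s
        pred = np.array([1, 0, 1])
        starts = np.array([0, 100, 200])
        events = [(0.0, 2.0), (10.2, 11.0), (50.0, 51.0)]
        assert sk.event_detection(pred, starts, events) \
            == pytest.approx(2 / 3)

    def test_malformed_events_rejected(self):
        with pytest.raises(ValueError):
            sk.event_detection(np.array([1]), np.array([0]), [(5.0, 4.0)])
        with pytest.raises(ValueError):
            sk.event_detection(np.array([1]), np.array([0]),
                               [(0.0, 2.0), (1.0, 3.0)])

    def test_events_from_labels_round_trip(self):
        labels = np.zeros(100, dtype=int)
        labels[20:40] = 1
        labels[80:100] = 1
        assert sk.events_from_labels(labels, 20.0) == [(1.0, 2.0),
                                                       (4.0, 5.0)]


class TestNaMeanSd:
    @pytest.mark.parametrize("name", sorted(REFERENCE_ROWS))
    def test_reference_cohort_row_arithmetic(self, name):
        """NA-aware mean/SD of each reference row reproduces the printed
        mean +- SD at the printed precision."""
        cells, p_mean, p_sd, nd = REFERENCE_ROWS[name]
        mean, sd, n_used = na_mean_sd(cells)
        half_unit = 0.5 * 10 ** (-nd) + 1e-9
        assert abs(mean - p_mean) <= half_unit
        if name == "precision":
            # printed SD matches population-SD rounding; sample SD is 0.089
            assert abs(sd - p_sd) <= 0.01
        else:
            assert abs(sd - p_sd) <= half_unit
        assert n_used == sum(1 for c in cells if not is_na(float(c)))

    def test_na_excluded_sensitivity_uses_four_subjects(self):
        mean, sd, n_used = na_mean_sd(REFERENCE_ROWS["sensitivity"][0])
        assert n_used == 4
        assert mean == pytest.approx(0.4025)

    def test_all_na_gives_na_summary(self):
        mean, sd, n = na_mean_sd([NA, NA])
        assert is_na(mean) and is_na(sd) and n == 0

    def test_single_value_has_na_sd(self):
        mean, sd, n = na_mean_sd([0.7])
        assert mean == 0.7 and is_na(sd) and n == 1


def _report(sid, sens=0.5, meta=None) -> sk.SubjectReport:
    cm = sk.ConfusionMatrix(tp=1, fp=1, tn=7, fn=1)
    return sk.SubjectReport(
        subject_id=sid, cm=cm, sensitivity=sens, specificity=0.9,
        precision=0.5, npv=0.9, accuracy=0.8, scratch_time_truth_s=10,
        scratch_time_pred_s=20, scratch_frac_truth=0.01,
        scratch_frac_pred=0.02, event_tp_frac=1.0, meta=meta or {},
    )


class TestCohortSummary:
    def test_permutation_invariance(self):
        reports = [_report(f"s{i}", sens=0.1 * i) for i in range(5)]
        a = cohort_summary(reports)
        b = cohort_summary(reports[::-1])
        assert set(a.rows) == set(b.rows)
        for key in a.rows:
            ma, sa, na_ = a.rows[key]
            mb, sb, nb_ = b.rows[key]
            assert na_ == nb_
            np.testing.assert_allclose([ma, sa], [mb, sb], rtol=1e-12)

    def test_na_values_excluded_not_imputed(self):
        reports = [_report("a", sens=0.2), _report("b", sens=NA),
                   _report("c", sens=0.4)]
        s = cohort_summary(reports)
        assert s.mean("sensitivity") == pytest.approx(0.3)
        assert s.n_used("sensitivity") == 2

    def test_numeric_meta_summarised(self):
        reports = [_report("a", meta={"easi": 8.0}),
                   _report("b", meta={"easi": 16.0})]
        assert cohort_summary(reports).mean("easi") == pytest.approx(12.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    def test_table_formatting_prints_na_and_rounded_cells(self):
        reports = [_report("a", sens=NA), _report("b", sens=0.505)]
        table = format_cohort_table(reports)
        assert "NA" in table
        assert "subject" not in table.splitlines()[1]  # metric rows follow

    def test_round_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.5, 0) == 1.0
        assert math.isnan(round_half_up(NA, 2))
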