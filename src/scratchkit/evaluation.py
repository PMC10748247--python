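"""Window-level and event-level evaluation of scratch predictions.

Window-level: a confusion matrix over per-window labels (class 1 =
scratch) yields sensitivity, specificity, precision, NPV, and accuracy.
Ratios with a zero denominator are NA — a subject who never scratched with
the instrumented hand has no defined sensitivity. A compatibility mode
reports precision 0 instead of NA when there are no positive predictions,
matching how some published summaries print such cells.

Scratch time: windows stride at 1 s, so each positive window contributes
one second; the session fraction is seconds over session length.

Event-level: a ground-truth scratch event (a time interval) counts as
detected if at least one positive predicted window overlaps it; the
detected fraction is the event-level recall ("% true positives detected").

Cohort summaries are NA-aware: means and sample standard deviations
(n-1 denominator) are taken over the subjects whose value is defined; NA
values are excluded, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

NA = float("nan")


def is_na(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (Python's round is half-even)."""
    if is_na(x):
        return NA
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Count agreement between predicted and true window labels."""
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {pred.shape} predictions vs {truth.shape} "
            "truth labels"
        )
    for arr, name in ((pred, "pred"), (truth, "truth")):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else NA


def metrics(cm: ConfusionMatrix, compat_precision_zero: bool = False,
            ) -> dict[str, float]:
    """Confusion-derived rates; undefined ratios are NA.

    ``compat_precision_zero`` reports precision as 0 (not NA) when there
    are no positive predictions, for parity with summaries that print 0 in
    that cell.
    """
    out = {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "precision": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
    }
    if compat_precision_zero and cm.tp + cm.fp == 0 and cm.total > 0:
        out["precision"] = 0.0
    return out


def scratch_time(
    window_labels: np.ndarray, stride_s: float = 1.0,
    session_s: float = 0.0,
) -> tuple[float, float]:
    """Total scratch seconds and session fraction from window labels.

    Each positive window contributes ``stride_s`` seconds (windows stride
    at 1 s, so integer second totals). The fraction is raw; round for
    display with :func:`round_half_up`.
    """
    if session_s <= 0:
        raise ValueError("session_s must be positive")
    labels = np.asarray(window_labels, dtype=np.int64)
    seconds = float(labels.sum() * stride_s)
    return seconds, seconds / session_s


def _validate_events(events: list[tuple[float, float]]) -> list:
    evs = sorted((float(s), float(e)) for s, e in events)
    for s, e in evs:
        if not e > s:
            raise ValueError(f"malformed event ({s}, {e}): end must exceed "
                             "start")
    for (s0, e0), (s1, e1) in zip(evs, evs[1:]):
        if s1 < e0:
            raise ValueError("events must be non-overlapping")
    return evs


def events_from_labels(
    labels: np.ndarray, fs: float,
) -> list[tuple[float, float]]:
    """Contiguous runs of 1 in a per-sample track, as [start_s, end_s)."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        return []
    padded = np.concatenate([[0], labels, [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def event_detection(
    pred_labels: np.ndarray,
    starts: np.ndarray,
    truth_events: list[tuple[float, float]],
    window_len: int = 30,
    sample_rate_hz: float = 20.0,
) -> float:
    """Fraction of truth scratch events overlapped by a positive window.

    A window starting at sample ``s`` spans
    ``[s/fs, (s + window_len)/fs)`` seconds; an event is detected if at
    least one positive window overlaps it in time. NA when there are no
    events.
    """
    evs = _validate_events(truth_events)
    if not evs:
        return NA
    pred_labels = np.asarray(pred_labels, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    if pred_labels.shape != starts.shape:
        raise ValueError("pred_labels and starts must align")
    pos = starts[pred_labels == 1]
    w_lo = pos / sample_rate_hz
    w_hi = (pos + window_len) / sample_rate_hz
    detected = sum(
        1 for ev_s, ev_e in evs
        if np.any((w_lo < ev_e) & (w_hi > ev_s))
    )
    return detected / len(evs)


@dataclass
class SubjectReport:
    """Per-subject evaluation row (the unit the cohort summary averages)."""

    subject_id: str
    cm: ConfusionMatrix
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    scratch_time_truth_s: float
    scratch_time_pred_s: float
    scratch_frac_truth: float
    scratch_frac_pred: float
    event_tp_frac: float
    meta: dict = field(default_factory=dict)

    METRIC_FIELDS = (
        "sensitivity", "specificity", "precision", "npv", "accuracy",
        "scratch_time_truth_s", "scratch_time_pred_s",
        "scratch_frac_truth", "scratch_frac_pred", "event_tp_frac",
    )

    def metric_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in self.METRIC_FIELDS}
        for k, v in self.meta.items():
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                d[str(k)] = float(v)
        return d

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id,
               "tp": self.cm.tp, "fp": self.cm.fp,
               "tn": self.cm.tn, "fn": self.cm.fn}
        row.update(self.metric_dict())
        return row


def subject_report(
    subject_id: str,
    pred_labels: np.ndarray,
    truth_labels: np.ndarray,
    starts: np.ndarray,
    session_s: float,
    truth_events: list[tuple[float, float]] | None = None,
    stride_s: float = 1.0,
    window_len: int = 30,
    sample_rate_hz: float = 20.0,
    meta: dict | None = None,
    compat_precision_zero: bool = False,
) -> SubjectReport:
    """Assemble the full per-subject row from window labels and events."""
    cm = confusion(pred_labels, truth_labels)
    m = metrics(cm, compat_precision_zero=compat_precision_zero)
    pred_s, pred_frac = scratch_time(pred_labels, stride_s, session_s)
    truth_s, truth_frac = scratch_time(truth_labels, stride_s, session_s)
    ev_frac = NA
    if truth_events is not None:
        ev_frac = event_detection(pred_labels, starts, truth_events,
                                  window_len, sample_rate_hz)
    return SubjectReport(
        subject_id=subject_id, cm=cm,
        scratch_time_truth_s=truth_s, scratch_time_pred_s=pred_s,
        scratch_frac_truth=truth_frac, scratch_frac_pred=pred_frac,
        event_tp_frac=ev_frac, meta=meta or {}, **m,
    )


def na_mean_sd(values) -> tuple[float, float, int]:
    """NA-excluded mean and sample SD (n-1) with the count actually used.

    Mean is NA when every value is NA; SD is NA when fewer than two values
    are defined.
    """
    vals = [float(v) for v in values if v is not None and not is_na(float(v))]
    n = len(vals)
    if n == 0:
        return NA, NA, 0
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else NA
    return mean, sd, n


@dataclass
class CohortSummary:
    """Per-metric NA-aware mean ± SD rows over a cohort of subjects."""

    rows: dict[str, tuple[float, float, int]]
    n_subjects: int

    def mean(self, metric: str) -> float:
        return self.rows[metric][0]

    def sd(self, metric: str) -> float:
        return self.rows[metric][1]

    def n_used(self, metric: str) -> int:
        return self.rows[metric][2]


def cohort_summary(reports: list[SubjectReport]) -> CohortSummary:
    """Summarise subject reports metric by metric (NA-excluded).

    Permutation-invariant in the subjects; numeric metadata (e.g. severity
    scores carried on the reports) is summarised alongside the computed
    metrics.
    """
    if not reports:
        raise ValueError("need at least one subject report")
    keys: list[str] = []
    for r in reports:
        for k in r.metric_dict():
            if k not in keys:
                keys.append(k)
    rows = {
        k: na_mean_sd(r.metric_dict().get(k, NA) for r in reports)
        for k in keys
    }
    return CohortSummary(rows=rows, n_subjects=len(reports))


def _fmt(x: float, ndigits: int) -> str:
    if is_na(x):
        return "NA"
    r = round_half_up(x, ndigits)
    return f"{r:.{ndigits}f}" if ndigits > 0 else f"{int(r)}"


def format_cohort_table(
    reports: list[SubjectReport], summary: CohortSummary | None = None,
) -> str:
    """Human-readable cohort table: one metric per row, one subject per
    column, plus a mean ± SD column. Fractions print at 2 decimals,
    second totals as integers."""
    summary = summary or cohort_summary(reports)
    names = [r.subject_id for r in reports]
    lines = ["Metric\t" + "\t".join(names) + "\tMean"]
    for key in summary.rows:
        nd = 0 if key.endswith("_s") else 2
        cells = [_fmt(r.metric_dict().get(key, NA), nd) for r in reports]
        mean, sd, _ = summary.rows[key]
        lines.append(
            f"{key}\t" + "\t".join(cells)
            + f"\t{_fmt(mean, nd)} ± {_fmt(sd, nd)}"
        )
    return "\n".join(lines)
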