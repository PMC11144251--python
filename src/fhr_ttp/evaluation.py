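"""Progressive evaluation of FHR recordings: approaches, thresholds, TTP.

A trained classifier produces one compromise probability per window of a
test recording. Three evaluation approaches turn those per-window
probabilities into a single record-level decision:

* **Approach 1** -- fixed 15-min sliding windows at a 5-min stride; the
  record is positive if any window crosses the decision threshold.
* **Approach 2** -- cumulative windows growing from 15 min in 5-min steps;
  the decision threshold decreases linearly with the window index
  (an affine schedule fitted from per-length calibrations).
* **Approach 3** -- a single whole-segment evaluation.

The time to predict (TTP) is the time from the start of the recording to
the end of the first positive window; for Approach 3 it is identically the
evaluation length. Decision thresholds are calibrated per test fold by
descending a 0.001 grid until the record-level false positive rate reaches
each target operating point (5/10/15/20% FPR). Windows whose signal loss
exceeds a chosen threshold can be gated: their probability is forced to 0
so they can never trigger a positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .io_ctg import CTGRecord, Label
from .preprocess import (
    ProcessedFHR,
    WindowSegment,
    augment_training_windows,
    cumulative_windows,
    select_last_segment,
    sliding_windows,
)

__all__ = [
    "PredictionTrace",
    "ThresholdSchedule",
    "EvaluationResult",
    "decide_record",
    "search_threshold",
    "fit_threshold_gradients",
    "gate_by_signal_loss",
    "filter_training_by_signal_loss",
    "pooled_tpr",
    "mean_ttp",
    "mcnemar_test",
    "run_cross_validation",
    "CalibrationError",
    "FPR_TARGETS",
    "APPROACHES",
]

FPR_TARGETS = (0.05, 0.10, 0.15, 0.20)
APPROACHES = ("A1", "A2", "A3")
GRID_STEP = 0.001


class CalibrationError(RuntimeError):
    """Raised when no threshold on the search grid reaches the target FPR."""


@dataclass
class PredictionTrace:
    """Per-window probabilities of one record under one approach."""

    record_id: str
    approach: str  # "A1" | "A2" | "A3"
    window_probs: np.ndarray
    window_end_min: np.ndarray
    true_label: int
    gated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.window_probs = np.asarray(self.window_probs, dtype=float)
        self.window_end_min = np.asarray(self.window_end_min, dtype=float)
        if self.window_probs.size != self.window_end_min.size:
            raise ValueError("window_probs and window_end_min differ in length")
        if self.window_probs.size == 0:
            raise ValueError("a trace needs at least one window")
        if np.any(np.diff(self.window_end_min) <= 0):
            raise ValueError("window end times must be strictly increasing")
        if self.gated is None:
            self.gated = np.zeros(self.window_probs.size, dtype=bool)
        else:
            self.gated = np.asarray(self.gated, dtype=bool)


@dataclass
class ThresholdSchedule:
    """Decision threshold per window index.

    Constant for Approaches 1 and 3; for Approach 2 the effective threshold
    at window ``w`` (1-based) is ``base_threshold - |gradient| * w`` so
    longer cumulative windows face a lower bar, matching the observed decay
    of calibrated thresholds with window length.
    """

    fpr_target: float
    base_threshold: float
    gradient_per_window: float = 0.0

    def effective(self, window_index: np.ndarray | int) -> np.ndarray | float:
        w = np.asarray(window_index)
        return self.base_threshold - abs(self.gradient_per_window) * w


@dataclass
class EvaluationResult:
    """Pooled operating-point metrics plus per-record traces."""

    approach: str
    tpr_at_fpr: dict[float, float]
    tpr_std: dict[float, float]
    ttp_at_fpr: dict[float, float]
    ttp_std: dict[float, float]
    achieved_fpr: dict[float, float]
    decisions: dict[float, np.ndarray]  # record-level, pooled over folds
    labels: np.ndarray
    record_ids: list[str]
    traces: list[PredictionTrace] = field(default_factory=list)


def decide_record(
    trace: PredictionTrace, schedule: ThresholdSchedule
) -> tuple[int, float | None]:
    """Record-level decision and time-to-predict.

    A window is positive when its probability meets the (possibly
    window-indexed) threshold and it is not gated; the record is positive
    when any window is. TTP is the end time of the first positive window
    (the earliest instant at which the decision is computable); ``None``
    for negative records.
    """
    w = np.arange(1, trace.window_probs.size + 1)
    thr = schedule.effective(w)
    hits = (trace.window_probs >= thr) & ~trace.gated
    if not hits.any():
        return 0, None
    first = int(np.argmax(hits))
    return 1, float(trace.window_end_min[first])


def search_threshold(
    traces: Sequence[PredictionTrace],
    fpr_target: float,
    approach: str = "A1",
    gradient: float = 0.0,
    search_start: float | None = None,
    step: float = GRID_STEP,
) -> ThresholdSchedule:
    """Descend the threshold grid until the record-level FPR reaches target.

    Returns the first (largest) grid threshold whose induced false positive
    rate over the normal records of ``traces`` is >= ``fpr_target``. For
    Approach 2 a fitted per-window ``gradient`` is applied and the descent
    starts at 1.5 to widen the search space; Approaches 1 and 3 use a
    constant threshold descending from 1.0.
    """
    labels = np.array([t.true_label for t in traces])
    n_neg = int(np.sum(labels == 0))
    if n_neg == 0:
        raise ValueError("calibration requires normal records")
    if search_start is None:
        search_start = 1.5 if approach == "A2" else 1.0
    # A record fires at base b iff some non-gated window has
    # prob >= b - |g| w, i.e. iff b <= max_w(prob + |g| w) =: s. The grid
    # descent from search_start therefore stops at the largest grid point
    # <= the k-th largest s among normal records, k = ceil(target * n_neg).
    g = abs(gradient)
    scores = np.full(len(traces), -np.inf)
    for i, t in enumerate(traces):
        if t.true_label != 0:
            continue
        w = np.arange(1, t.window_probs.size + 1)
        lifted = np.where(t.gated, -np.inf, t.window_probs + g * w)
        scores[i] = lifted.max()
    neg_scores = np.sort(scores[labels == 0])[::-1]
    k = int(np.ceil(fpr_target * n_neg - 1e-9))
    if k == 0:  # target 0%: the descent stops immediately, zero false positives
        return ThresholdSchedule(fpr_target, search_start, gradient)
    s_k = neg_scores[k - 1]
    if not np.isfinite(s_k) or s_k < 0.0:
        raise CalibrationError(
            f"target FPR {fpr_target:.0%} unreachable on the calibration set"
        )
    m = max(0, int(np.ceil((search_start - s_k) / step - 1e-9)))
    base = search_start - m * step
    return ThresholdSchedule(fpr_target, base, gradient)


def fit_threshold_gradients(
    thresholds_by_length: np.ndarray, fprs: Sequence[float] = FPR_TARGETS
) -> dict[float, float]:
    """OLS slope of calibrated threshold vs window index, per operating point.

    ``thresholds_by_length`` has one row per FPR target and one column per
    window length (15, 20, ... min -> window index 1, 2, ...). Calibrated
    thresholds decrease as windows grow, so slopes are expected <= 0.
    """
    thr = np.atleast_2d(np.asarray(thresholds_by_length, dtype=float))
    if thr.shape[1] < 2:
        raise ValueError("need thresholds for at least two window lengths")
    w = np.arange(1, thr.shape[1] + 1)
    out = {}
    for fpr, row in zip(fprs, thr):
        slope, _ = np.polyfit(w, row, 1)
        out[float(fpr)] = float(slope)
    return out


def gate_by_signal_loss(
    trace: PredictionTrace,
    segments: Sequence[WindowSegment],
    loss_threshold_pct: float,
) -> PredictionTrace:
    """Force windows whose signal loss exceeds the threshold to probability 0.

    A window with loss exactly at the threshold is kept (meeting the
    threshold is inclusive). Gated windows can never trigger a positive, so
    a fully gated record is predicted normal regardless of model output.
    """
    if len(segments) != trace.window_probs.size:
        raise ValueError("segments and trace windows are misaligned")
    losses = np.array([seg.signal_loss_pct for seg in segments])
    gated = losses > loss_threshold_pct
    probs = np.where(gated, 0.0, trace.window_probs)
    return PredictionTrace(
        record_id=trace.record_id,
        approach=trace.approach,
        window_probs=probs,
        window_end_min=trace.window_end_min,
        true_label=trace.true_label,
        gated=gated | trace.gated,
    )


def filter_training_by_signal_loss(
    segments: Sequence[WindowSegment], loss_threshold_pct: float
) -> list[WindowSegment]:
    """Keep training segments whose signal loss is within the threshold."""
    return [s for s in segments if s.signal_loss_pct <= loss_threshold_pct]


def pooled_tpr(decisions: np.ndarray, labels: np.ndarray) -> float:
    """TP / (TP + FN) over pooled compromised records."""
    decisions = np.asarray(decisions)
    labels = np.asarray(labels)
    pos = labels == 1
    if not pos.any():
        raise ValueError("no compromised records in the pool")
    return float(decisions[pos].sum() / pos.sum())


def pooled_fpr(decisions: np.ndarray, labels: np.ndarray) -> float:
    neg = np.asarray(labels) == 0
    if not neg.any():
        raise ValueError("no normal records in the pool")
    return float(np.asarray(decisions)[neg].sum() / neg.sum())


def mean_ttp(
    decisions: np.ndarray, ttps: Sequence[float | None]
) -> float:
    """Mean TTP over all positively predicted records (false positives too)."""
    vals = [t for d, t in zip(np.asarray(decisions), ttps) if d == 1]
    if not vals:
        raise ValueError("no positive predictions; TTP undefined")
    return float(np.mean(vals))


def mcnemar_test(
    decisions_a: np.ndarray,
    decisions_b: np.ndarray,
    labels: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Paired comparison of two methods on the compromised records.

    Builds the 2x2 table of (method A correct / incorrect) x (method B
    correct / incorrect) restricted to compromised records (a TPR
    comparison), then applies McNemar's test: the exact binomial form when
    the discordant count is below 25, otherwise the chi-square statistic
    with continuity correction.
    """
    a = np.asarray(decisions_a)
    b = np.asarray(decisions_b)
    y = np.asarray(labels)
    if not (a.size == b.size == y.size):
        raise ValueError("decision and label vectors differ in length")
    pos = y == 1
    ca, cb = a[pos] == 1, b[pos] == 1  # correct iff a compromised case is flagged
    table = np.array(
        [
            [np.sum(ca & cb), np.sum(ca & ~cb)],
            [np.sum(~ca & cb), np.sum(~ca & ~cb)],
        ],
        dtype=int,
    )
    n_disc = table[0, 1] + table[1, 0]
    if n_disc == 0:
        return table, 1.0
    k = int(min(table[0, 1], table[1, 0]))
    if n_disc < 25:
        p = min(1.0, 2.0 * float(sps.binom.cdf(k, n_disc, 0.5)))
        # both tails coincide at k == n - k; do not double-count the centre
        if 2 * k == n_disc:
            p = 1.0
    else:
        chi2 = (abs(table[0, 1] - table[1, 0]) - 1) ** 2 / n_disc
        p = float(sps.chi2.sf(chi2, df=1))
    return table, p


# ---------------------------------------------------------------------------
# Cross-validated orchestration
# ---------------------------------------------------------------------------


def _windows_for_approach(proc: ProcessedFHR, approach: str) -> list[WindowSegment]:
    if approach == "A1":
        return sliding_windows(proc)
    if approach == "A2":
        return cumulative_windows(proc)
    if approach == "A3":
        d = proc.duration_min
        return [
            WindowSegment(
                parent_id=proc.record_id,
                start_min=0.0,
                end_min=d,
                samples=proc.samples,
                window_index=1,
                rate=proc.out_rate,
            )
        ]
    raise ValueError(f"unknown approach {approach!r} (expected A1, A2 or A3)")


def _trace(
    proc: ProcessedFHR,
    approach: str,
    label: int,
    predict: Callable[[list[WindowSegment]], np.ndarray],
    loss_threshold_pct: float,
) -> PredictionTrace:
    segs = _windows_for_approach(proc, approach)
    trace = PredictionTrace(
        record_id=proc.record_id,
        approach=approach,
        window_probs=predict(segs),
        window_end_min=np.array([s.end_min for s in segs]),
        true_label=label,
    )
    if loss_threshold_pct < 100.0:
        trace = gate_by_signal_loss(trace, segs, loss_threshold_pct)
    return trace


def _per_length_thresholds(
    traces_a2: Sequence[PredictionTrace], fprs: Sequence[float]
) -> np.ndarray:
    """Calibrate a scalar threshold per cumulative-window length.

    Each window length is treated as a single-window evaluation, giving the
    threshold-vs-length curve from which the Approach-2 gradient is fitted.
    """
    n_w = min(t.window_probs.size for t in traces_a2)
    out = np.empty((len(fprs), n_w))
    for j in range(n_w):
        singles = [
            PredictionTrace(
                record_id=t.record_id,
                approach="A3",
                window_probs=t.window_probs[j : j + 1],
                window_end_min=t.window_end_min[j : j + 1],
                true_label=t.true_label,
                gated=t.gated[j : j + 1],
            )
            for t in traces_a2
        ]
        for i, fpr in enumerate(fprs):
            out[i, j] = search_threshold(singles, fpr, approach="A1").base_threshold
    return out


def run_cross_validation(
    records: list[CTGRecord],
    model_factory: Callable[[int], object],
    train_fn: Callable[[object, list[WindowSegment], np.ndarray, int], object],
    predict_fn: Callable[[object, list[WindowSegment]], np.ndarray],
    approach: str | Sequence[str] = "A2",
    fprs: Sequence[float] = FPR_TARGETS,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    loss_threshold_pct: float = 100.0,
    segment_min: float = 60.0,
    augment_window_min: float = 30.0,
) -> EvaluationResult | dict[str, EvaluationResult]:
    """Repeated stratified k-fold evaluation.

    Per repeat and fold: train on augmented 30-min windows of the training
    folds (intermediate-pH records excluded from training only; segments
    over the signal-loss threshold removed), predict per-window
    probabilities on the test fold, calibrate thresholds on that fold's own
    probabilities at each FPR target, decide, and pool decisions across
    folds. TPR/TTP are computed per repeat and summarised as mean +- std
    across repeats. For Approach 2 the per-window threshold gradient is
    fitted from per-length calibrations on the same fold.

    ``approach`` may be a single approach or a sequence; the trained fold
    models are shared across approaches, and a dict of results is returned
    when a sequence is given.
    """
    single = isinstance(approach, str)
    approaches: tuple[str, ...] = (approach,) if single else tuple(approach)
    labeled = [r for r in records if r.ph is not None]
    y = np.array([1 if r.label.is_compromised else 0 for r in labeled])
    if y.sum() < folds:
        raise ValueError("need at least one compromised record per fold")
    processed = [select_last_segment(r, minutes=segment_min) for r in labeled]
    intermediate = np.array([r.label is Label.INTERMEDIATE for r in labeled])

    per_repeat_tpr = {a: {f: [] for f in fprs} for a in approaches}
    per_repeat_ttp = {a: {f: [] for f in fprs} for a in approaches}
    achieved = {a: {f: [] for f in fprs} for a in approaches}
    pooled_decisions = {a: None for a in approaches}
    all_traces = {a: [] for a in approaches}

    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        rep_decisions = {
            a: {f: np.zeros(len(labeled), dtype=int) for f in fprs} for a in approaches
        }
        rep_ttps = {
            a: {f: [None] * len(labeled) for f in fprs} for a in approaches
        }
        for fold_i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            train_idx = [i for i in train_idx if not intermediate[i]]
            segs: list[WindowSegment] = []
            seg_labels: list[int] = []
            for i in train_idx:
                ws = augment_training_windows(
                    processed[i], window_min=augment_window_min
                )
                for s in ws:
                    if s.signal_loss_pct <= loss_threshold_pct:
                        segs.append(s)
                        seg_labels.append(y[i])
            fold_seed = seed * 1000 + rep * 10 + fold_i
            model = model_factory(fold_seed)
            model = train_fn(model, segs, np.array(seg_labels), fold_seed)

            for a in approaches:
                fold_traces = [
                    _trace(
                        processed[i],
                        a,
                        int(y[i]),
                        lambda ws: predict_fn(model, ws),
                        loss_threshold_pct,
                    )
                    for i in test_idx
                ]
                all_traces[a].extend(fold_traces)

                gradients = {f: 0.0 for f in fprs}
                if a == "A2":
                    thr_by_len = _per_length_thresholds(fold_traces, fprs)
                    gradients = fit_threshold_gradients(thr_by_len, fprs)
                for f in fprs:
                    schedule = search_threshold(
                        fold_traces, f, approach=a, gradient=gradients[f]
                    )
                    for t, i in zip(fold_traces, test_idx):
                        d, ttp = decide_record(t, schedule)
                        rep_decisions[a][f][i] = d
                        rep_ttps[a][f][i] = ttp

        for a in approaches:
            for f in fprs:
                per_repeat_tpr[a][f].append(pooled_tpr(rep_decisions[a][f], y))
                per_repeat_ttp[a][f].append(mean_ttp(rep_decisions[a][f], rep_ttps[a][f]))
                achieved[a][f].append(pooled_fpr(rep_decisions[a][f], y))
            if rep == 0:
                pooled_decisions[a] = rep_decisions[a]

    results = {
        a: EvaluationResult(
            approach=a,
            tpr_at_fpr={f: float(np.mean(v)) for f, v in per_repeat_tpr[a].items()},
            tpr_std={f: float(np.std(v)) for f, v in per_repeat_tpr[a].items()},
            ttp_at_fpr={f: float(np.mean(v)) for f, v in per_repeat_ttp[a].items()},
            ttp_std={f: float(np.std(v)) for f, v in per_repeat_ttp[a].items()},
            achieved_fpr={f: float(np.mean(v)) for f, v in achieved[a].items()},
            decisions=pooled_decisions[a],
            labels=y,
            record_ids=[r.record_id for r in labeled],
            traces=all_traces[a],
        )
        for a in approaches
    }
    return results[approaches[0]] if single else results
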