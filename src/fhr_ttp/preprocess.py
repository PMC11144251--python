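"""FHR cleaning, gap handling, downsampling, segment selection and windowing.

The cleaning chain for a raw 4 Hz FHR trace is:

1. ``remove_artifacts`` -- zero out physiologically implausible samples
   (outside 50-200 bpm) and abrupt jumps (>25 bpm from the previously
   retained nonzero sample).
2. ``interpolate_gaps`` -- linearly fill zero-runs shorter than 15 s that
   are flanked by valid samples; longer gaps stay zero.
3. ``downsample`` -- average 4 Hz blocks down to 0.25 Hz, averaging only the
   nonzero samples of each block so gaps stay zero-coded.
4. ``select_last_segment`` -- keep the final 60 minutes for analysis.

Signal loss is the percentage of zero-coded samples in a segment; all
windowing (sliding, cumulative, training augmentation) operates on the
0.25 Hz processed signal while the MCNN quality vector is computed on the
raw 4 Hz signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_ctg import CTGRecord, Label

__all__ = [
    "ProcessedFHR",
    "WindowSegment",
    "QualityVector",
    "remove_artifacts",
    "interpolate_gaps",
    "downsample",
    "preprocess_fhr",
    "select_last_segment",
    "signal_loss_pct",
    "sliding_windows",
    "cumulative_windows",
    "augment_training_windows",
    "quality_vector",
    "window_count",
    "signal_loss_summary",
]

MAX_BPM = 200.0
MIN_BPM = 50.0
MAX_JUMP_BPM = 25.0
MAX_GAP_S = 15.0
RAW_RATE_HZ = 4.0
OUT_RATE_HZ = 0.25
SEGMENT_MIN = 60.0


@dataclass
class ProcessedFHR:
    """Cleaned, downsampled FHR segment with zero-coded gaps."""

    record_id: str
    samples: np.ndarray
    out_rate: float = OUT_RATE_HZ
    raw_fhr_4hz: np.ndarray | None = None  # cleaned 4 Hz signal over same span
    uc: np.ndarray | None = None  # UC downsampled to out_rate over same span

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_min(self) -> float:
        return self.samples.size / self.out_rate / 60.0

    @property
    def signal_loss_pct(self) -> float:
        return signal_loss_pct(self.samples)

    @property
    def gap_mask(self) -> np.ndarray:
        return self.samples == 0.0


@dataclass
class WindowSegment:
    """A contiguous sub-segment handed to a classifier.

    ``window_index`` numbers windows in temporal order starting at 1;
    windows cover the half-open interval [start_min, end_min).
    """

    parent_id: str
    start_min: float
    end_min: float
    samples: np.ndarray
    window_index: int
    rate: float = OUT_RATE_HZ
    label: Label | None = None
    uc: np.ndarray | None = None
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def signal_loss_pct(self) -> float:
        return signal_loss_pct(self.samples)


@dataclass
class QualityVector:
    """Per-window valid-sample fraction of the raw 4 Hz FHR (MCNN input)."""

    values: np.ndarray
    window_min: float = 15.0
    step_min: float = 5.0


def remove_artifacts(fhr: np.ndarray) -> np.ndarray:
    """Zero out-of-range samples and abrupt jumps.

    Samples >200 bpm or <50 bpm become 0. Then, scanning left to right and
    skipping zeros, a sample differing by more than 25 bpm from the previous
    retained nonzero sample is zeroed (the earlier accepted value is kept).
    """
    x = np.asarray(fhr, dtype=float).copy()
    x[(x > MAX_BPM) | (x < MIN_BPM)] = 0.0
    prev = None
    for i in range(x.size):
        if x[i] == 0.0:
            continue
        if prev is not None and abs(x[i] - prev) > MAX_JUMP_BPM:
            x[i] = 0.0
        else:
            prev = x[i]
    return x


def interpolate_gaps(
    fhr: np.ndarray, max_gap_s: float = MAX_GAP_S, rate: float = RAW_RATE_HZ
) -> np.ndarray:
    """Linearly fill interior zero-runs strictly shorter than ``max_gap_s``.

    A gap must be flanked by nonzero samples on both sides; leading and
    trailing zero-runs are left untouched, as are gaps of 15 s or longer.
    """
    x = np.asarray(fhr, dtype=float).copy()
    max_len = int(round(max_gap_s * rate))  # gap < max_len samples is filled
    n = x.size
    i = 0
    while i < n:
        if x[i] != 0.0:
            i += 1
            continue
        j = i
        while j < n and x[j] == 0.0:
            j += 1
        gap = j - i
        if i > 0 and j < n and gap < max_len:
            left, right = x[i - 1], x[j]
            x[i:j] = left + (right - left) * np.arange(1, gap + 1) / (gap + 1)
        i = j
    return x


def downsample(fhr: np.ndarray, factor: int = 16) -> np.ndarray:
    """Block-average 4 Hz samples down to 0.25 Hz (factor 16 by default).

    Each output value is the mean of the *nonzero* samples in its block so a
    partially missing block keeps a physiological value; an all-zero block
    stays 0, preserving the gap coding. Samples that do not fill a complete
    block are dropped from the front (the analysis keeps the *last* part of
    the record).
    """
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    x = np.asarray(fhr, dtype=float)
    n_blocks = x.size // factor
    x = x[x.size - n_blocks * factor :]
    blocks = x.reshape(n_blocks, factor)
    nonzero = blocks != 0.0
    counts = nonzero.sum(axis=1)
    sums = np.where(nonzero, blocks, 0.0).sum(axis=1)
    out = np.zeros(n_blocks)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out


def signal_loss_pct(samples: np.ndarray) -> float:
    """Percentage of zero-coded samples in a segment."""
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("signal_loss_pct of an empty segment is undefined")
    return 100.0 * float(np.count_nonzero(samples == 0.0)) / samples.size


def preprocess_fhr(fhr_raw: np.ndarray, rate: float = RAW_RATE_HZ) -> np.ndarray:
    """Full cleaning chain at 4 Hz followed by downsampling to 0.25 Hz."""
    factor = int(round(rate / OUT_RATE_HZ))
    return downsample(interpolate_gaps(remove_artifacts(fhr_raw), rate=rate), factor)


def select_last_segment(record: CTGRecord, minutes: float = SEGMENT_MIN) -> ProcessedFHR:
    """Run the cleaning chain and keep the last ``minutes`` of the record.

    Also retains the matching span of the cleaned 4 Hz signal (for the
    quality vector and the raw-rate features) and of the block-averaged UC
    trace (for the multimodal baseline).
    """
    cleaned_4hz = interpolate_gaps(
        remove_artifacts(record.fhr_raw), rate=record.sample_rate
    )
    factor = int(round(record.sample_rate / OUT_RATE_HZ))
    processed = downsample(cleaned_4hz, factor)
    n_out = int(round(minutes * 60 * OUT_RATE_HZ))
    if processed.size < n_out:
        raise ValueError(
            f"record {record.record_id!r}: {processed.size / OUT_RATE_HZ / 60:.1f} min "
            f"after preprocessing, need {minutes:g} min"
        )
    n_raw = int(round(minutes * 60 * record.sample_rate))
    uc_ds = downsample(np.where(record.uc_raw == 0, 0, record.uc_raw), factor)
    return ProcessedFHR(
        record_id=record.record_id,
        samples=processed[-n_out:],
        raw_fhr_4hz=cleaned_4hz[-n_raw:],
        uc=uc_ds[-n_out:],
    )


def window_count(duration_min: float, window_min: float, step_min: float) -> int:
    """Closed form floor((D - W)/S) + 1 (0 when the window does not fit)."""
    if window_min > duration_min:
        return 0
    return int(np.floor((duration_min - window_min) / step_min + 1e-9)) + 1


def _slice(fhr: ProcessedFHR, start_min: float, end_min: float, index: int) -> WindowSegment:
    a = int(round(start_min * 60 * fhr.out_rate))
    b = int(round(end_min * 60 * fhr.out_rate))
    return WindowSegment(
        parent_id=fhr.record_id,
        start_min=start_min,
        end_min=end_min,
        samples=fhr.samples[a:b],
        window_index=index,
        rate=fhr.out_rate,
        uc=None if fhr.uc is None else fhr.uc[a:b],
    )


def sliding_windows(
    fhr: ProcessedFHR, window_min: float = 15.0, step_min: float = 5.0
) -> list[WindowSegment]:
    """Fixed-length sliding windows (progressive evaluation, Approach 1)."""
    n = window_count(fhr.duration_min, window_min, step_min)
    return [
        _slice(fhr, w * step_min, w * step_min + window_min, w + 1) for w in range(n)
    ]


def cumulative_windows(
    fhr: ProcessedFHR, initial_min: float = 15.0, step_min: float = 5.0
) -> list[WindowSegment]:
    """Growing windows anchored at the recording start (Approach 2)."""
    n = window_count(fhr.duration_min, initial_min, step_min)
    return [_slice(fhr, 0.0, initial_min + w * step_min, w + 1) for w in range(n)]


def augment_training_windows(
    fhr: ProcessedFHR,
    window_min: float = 30.0,
    step_min: float = 5.0,
    label: Label | None = None,
) -> list[WindowSegment]:
    """Overlapping fixed windows for training-set augmentation.

    A 60-min record yields seven 30-min windows at a 5-min stride, each
    inheriting the parent record's label.
    """
    segments = sliding_windows(fhr, window_min, step_min)
    for seg in segments:
        seg.label = label
    return segments


def quality_vector(
    raw_fhr_4hz: np.ndarray,
    duration_min: float | None = None,
    window_min: float = 15.0,
    step_min: float = 5.0,
    rate: float = RAW_RATE_HZ,
) -> QualityVector:
    """Per-window fraction of valid (nonzero) raw 4 Hz samples.

    A 60-min signal yields a quality vector of length 10; 45 and 30 min give
    7 and 4.
    """
    x = np.asarray(raw_fhr_4hz, dtype=float)
    if duration_min is None:
        duration_min = x.size / rate / 60.0
    n = window_count(duration_min, window_min, step_min)
    if n == 0:
        raise ValueError(f"signal of {duration_min:g} min is shorter than one window")
    w = int(round(window_min * 60 * rate))
    s = int(round(step_min * 60 * rate))
    values = np.array(
        [np.count_nonzero(x[k * s : k * s + w]) / w for k in range(n)]
    )
    return QualityVector(values=values, window_min=window_min, step_min=step_min)


def signal_loss_summary(
    records: list[CTGRecord],
    loss_band_pct: float = 20.0,
    minutes: float = SEGMENT_MIN,
) -> dict:
    """Cohort-level signal-loss distribution by outcome class.

    Mirrors the accession-level summary: counts per class and the fraction of
    each class whose last-``minutes`` processed segment has signal loss below
    ``loss_band_pct``. Records without pH or shorter than ``minutes`` are
    reported but excluded from the class fractions.
    """
    n_comp = n_norm = 0
    comp_below = norm_below = 0
    skipped = 0
    for rec in records:
        if rec.ph is None:
            skipped += 1
            continue
        try:
            proc = select_last_segment(rec, minutes=minutes)
        except ValueError:
            skipped += 1
            continue
        loss = proc.signal_loss_pct
        if rec.label.is_compromised:
            n_comp += 1
            comp_below += loss < loss_band_pct
        else:
            n_norm += 1
            norm_below += loss < loss_band_pct
    return {
        "n_records": len(records),
        "n_compromised": n_comp,
        "n_normal": n_norm,
        "n_skipped": skipped,
        "loss_band_pct": loss_band_pct,
        "pct_normal_below_band": 100.0 * norm_below / n_norm if n_norm else float("nan"),
        "pct_compromised_below_band": 100.0 * comp_below / n_comp if n_comp else float("nan"),
    }
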