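"""Classical FHR features and a logistic-regression classifier over them.

Four features summarise a raw 4 Hz cleaned FHR segment (zeros code gaps):

* ``dc_prsa``  -- deceleration capacity from phase-rectified signal
  averaging: windows around decreasing anchor points are averaged and
  summarised by a 4-point Haar contrast. Quantifies the downward trend.
* ``beta0``    -- the mean of a smooth baseline estimate (running median
  followed by a low-pass), a scalar FHR baseline in bpm.
* ``mad_dtrd`` -- median absolute deviation of the signal from that
  baseline; an average deceleration-depth summary.
* ``hurst``    -- the Hurst exponent from order-1 detrended fluctuation
  analysis, an FHR variability measure in (0, 1).

Gap samples are excluded from every estimator: anchors must have a fully
valid window, medians and means run over valid samples only, and DFA is
computed on the concatenated valid samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps
from sklearn.linear_model import LogisticRegression

from .preprocess import WindowSegment

__all__ = [
    "FeatureVector",
    "PRSAConfig",
    "dc_prsa",
    "baseline_estimate",
    "beta0",
    "mad_dtrd",
    "hurst_exponent",
    "compute_features",
    "FeatureClassifier",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("dc_prsa", "mad_dtrd", "beta0", "hurst")


@dataclass
class PRSAConfig:
    """Phase-rectified signal averaging parameters.

    ``anchor_lag_T`` samples on each side define the decreasing-anchor test
    (mean of the T samples from the anchor on is below the mean of the T
    samples before it); ``half_window_L`` samples of context on each side
    are averaged across anchors. Defaults: T=1, L=60 (15 s at 4 Hz).
    """

    anchor_lag_T: int = 1
    half_window_L: int = 60

    def __post_init__(self) -> None:
        if self.anchor_lag_T < 1 or self.half_window_L < 2:
            raise ValueError("PRSA requires T >= 1 and L >= 2")


@dataclass
class FeatureVector:
    dc_prsa: float
    mad_dtrd: float
    beta0: float
    hurst: float
    valid: dict[str, bool] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.dc_prsa, self.mad_dtrd, self.beta0, self.hurst])


def dc_prsa(x: np.ndarray, cfg: PRSAConfig | None = None) -> tuple[float, bool]:
    """Deceleration capacity of phase-rectified signal averaging.

    Anchors are indices ``i`` with ``mean(x[i:i+T]) < mean(x[i-T:i])`` whose
    whole ``[i-L, i+L)`` window is valid (nonzero). Aligned windows are
    averaged into the PRSA curve ``X(k)``, ``k in [-L, L)``, and
    ``DC = (X(0) + X(1) - X(-1) - X(-2)) / 4``.

    Returns ``(value, valid_flag)``; a segment with no eligible anchor is
    flagged invalid rather than raising.
    """
    cfg = cfg or PRSAConfig()
    x = np.asarray(x, dtype=float)
    T, L = cfg.anchor_lag_T, cfg.half_window_L
    n = x.size
    if n < 2 * L + 1:
        return float("nan"), False
    valid = x != 0.0
    # candidate anchors need a fully valid surrounding window
    csum = np.concatenate([[0], np.cumsum(valid)])
    win_ok = np.zeros(n, dtype=bool)
    i = np.arange(L, n - L + 1)
    win_ok[i] = (csum[i + L] - csum[i - L]) == 2 * L
    xs = np.concatenate([[0.0], np.cumsum(x)])
    fwd = np.full(n, np.nan)
    bwd = np.full(n, np.nan)
    j = np.arange(T, n - T + 1)
    fwd[j] = (xs[j + T] - xs[j]) / T
    bwd[j] = (xs[j] - xs[j - T]) / T
    with np.errstate(invalid="ignore"):
        anchors = np.where(win_ok & (fwd < bwd))[0]
    if anchors.size == 0:
        return float("nan"), False
    offsets = np.arange(-L, L)
    prsa = x[anchors[:, None] + offsets[None, :]].mean(axis=0)
    centre = L  # prsa[centre + k] == X(k)
    dc = (prsa[centre] + prsa[centre + 1] - prsa[centre - 1] - prsa[centre - 2]) / 4.0
    return float(dc), True


def baseline_estimate(
    x: np.ndarray,
    rate: float = 4.0,
    median_window_s: float = 120.0,
    lowpass_hz: float = 0.01,
    min_valid_frac: float = 0.25,
) -> tuple[np.ndarray, bool]:
    """Smooth baseline trace: running median then a low-pass, gaps bridged.

    Interior gaps are linearly bridged before filtering so the baseline does
    not dip toward zero; the returned trace covers every sample but is only
    meaningful where the input was valid. Invalid (all-gap or <25% valid)
    segments are flagged.
    """
    x = np.asarray(x, dtype=float)
    valid = x != 0.0
    if valid.sum() < max(3, min_valid_frac * x.size):
        return np.full_like(x, np.nan), False
    idx = np.arange(x.size)
    bridged = np.interp(idx, idx[valid], x[valid])
    w = int(round(median_window_s * rate))
    w = min(w if w % 2 == 1 else w + 1, 2 * (x.size // 2) - 1)
    med = ndimage.median_filter(bridged, size=max(w, 3), mode="nearest")
    nyq = rate / 2
    if 0 < lowpass_hz < nyq:
        b, a = sps.butter(2, lowpass_hz / nyq)
        med = sps.filtfilt(b, a, med, method="gust")
    return med, True


def beta0(x: np.ndarray, rate: float = 4.0) -> tuple[float, bool]:
    """Scalar FHR baseline: mean of the baseline trace over valid samples."""
    x = np.asarray(x, dtype=float)
    base, ok = baseline_estimate(x, rate=rate)
    if not ok:
        return float("nan"), False
    return float(base[x != 0.0].mean()), True


def mad_dtrd(x: np.ndarray, rate: float = 4.0) -> tuple[float, bool]:
    """Median absolute deviation of FHR from its baseline (deceleration depth)."""
    x = np.asarray(x, dtype=float)
    base, ok = baseline_estimate(x, rate=rate)
    if not ok:
        return float("nan"), False
    valid = x != 0.0
    return float(np.median(np.abs(x[valid] - base[valid]))), True


def hurst_exponent(
    x: np.ndarray, min_scale: int = 4, max_scale_frac: float = 0.25,
    min_samples: int = 256,
) -> tuple[float, bool]:
    """Hurst exponent by order-1 detrended fluctuation analysis.

    Valid (nonzero) samples are concatenated, mean-centred and integrated
    into a profile; the RMS of linearly detrended non-overlapping segments
    is computed at dyadic scales from ``min_scale`` to ``max_scale_frac * N``
    and the slope of log F(s) vs log s is the estimate. White noise gives
    H ~= 0.5, persistent fractional noise H > 0.5. Estimates outside (0, 1)
    or from fewer than ``min_samples`` valid points are flagged invalid.
    """
    x = np.asarray(x, dtype=float)
    v = x[x != 0.0]
    n = v.size
    if n < min_samples:
        return float("nan"), False
    profile = np.cumsum(v - v.mean())
    scales, flucts = [], []
    s = min_scale
    while s <= int(n * max_scale_frac):
        n_seg = n // s
        seg = profile[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s)
        # order-1 detrend per segment via least squares
        tm = t - t.mean()
        slope = seg @ tm / (tm @ tm)
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * tm
        flucts.append(np.sqrt((resid**2).mean()))
        scales.append(s)
        s *= 2
    if len(scales) < 3:
        return float("nan"), False
    h = float(np.polyfit(np.log(scales), np.log(flucts), 1)[0])
    return h, 0.0 < h < 1.0


def compute_features(
    x: np.ndarray, rate: float = 4.0, prsa: PRSAConfig | None = None
) -> FeatureVector:
    """All four features of one raw-rate segment, with validity flags."""
    dc, dc_ok = dc_prsa(x, prsa)
    mad, mad_ok = mad_dtrd(x, rate=rate)
    b0, b0_ok = beta0(x, rate=rate)
    h, h_ok = hurst_exponent(x)
    return FeatureVector(
        dc_prsa=dc, mad_dtrd=mad, beta0=b0, hurst=h,
        valid={"dc_prsa": dc_ok, "mad_dtrd": mad_ok, "beta0": b0_ok, "hurst": h_ok},
    )


class FeatureClassifier:
    """L2-regularised logistic regression over a chosen feature subset.

    Invalid features are imputed with training-set medians (kept for test
    time); a test window whose features are all invalid is scored 0, i.e.
    treated as normal, mirroring the signal-loss gating convention.
    """

    def __init__(self, feature_names: tuple[str, ...] = FEATURE_NAMES, C: float = 1.0):
        unknown = set(feature_names) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        self.feature_names = tuple(feature_names)
        self._cols = [FEATURE_NAMES.index(f) for f in self.feature_names]
        self._model = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)
        self._medians: np.ndarray | None = None
        self._scale_mean: np.ndarray | None = None
        self._scale_std: np.ndarray | None = None

    def _matrix(self, fvs: list[FeatureVector]) -> np.ndarray:
        X = np.array([fv.as_array()[self._cols] for fv in fvs])
        mask = np.array(
            [[fv.valid.get(f, False) for f in self.feature_names] for fv in fvs]
        )
        X[~mask] = np.nan
        return X

    def fit(self, fvs: list[FeatureVector], labels: np.ndarray) -> "FeatureClassifier":
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        X = self._matrix(fvs)
        self._medians = np.nanmedian(X, axis=0)
        self._medians = np.where(np.isnan(self._medians), 0.0, self._medians)
        X = np.where(np.isnan(X), self._medians, X)
        self._scale_mean = X.mean(axis=0)
        self._scale_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self._model.fit((X - self._scale_mean) / self._scale_std, y)
        return self

    @property
    def coef_(self) -> np.ndarray:
        return self._model.coef_

    @property
    def intercept_(self) -> np.ndarray:
        return self._model.intercept_

    def predict_proba_features(self, fvs: list[FeatureVector]) -> np.ndarray:
        if self._medians is None:
            raise RuntimeError("classifier is not fitted")
        X = self._matrix(fvs)
        all_invalid = np.isnan(X).all(axis=1)
        X = np.where(np.isnan(X), self._medians, X)
        p = self._model.predict_proba(
            (X - self._scale_mean) / self._scale_std
        )[:, 1]
        p[all_invalid] = 0.0
        return p

    def predict_window(self, window: WindowSegment, rate: float | None = None) -> float:
        """Compromise probability for one raw-rate window segment."""
        fv = compute_features(window.samples, rate=rate or window.rate)
        return float(self.predict_proba_features([fv])[0])
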