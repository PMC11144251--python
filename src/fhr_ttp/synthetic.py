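"""Synthetic intrapartum CTG cohort generator.

Emulates the statistical structure the pipeline assumes about real labour
recordings: 4 Hz FHR with a 120-160 bpm baseline, band-limited short-term
variability, contraction-coupled (late) decelerations whose frequency and
depth differ by outcome class, sensor-dropout gaps coded as zeros, occasional
non-physiological outliers, a paired smooth-bump UC trace, and a
class-conditional umbilical-artery pH so the labeling rules reproduce the
intended classes. It is a signal-level emulator, not a cardiovascular model:
the pH is drawn, not derived from the waveform, and the generated classes are
the ground truth that classifiers are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy import stats

from .io_ctg import CTGRecord, write_meta_sidecar, write_record

__all__ = ["SynthConfig", "generate_cohort", "generate_record", "planted_effect_check",
           "expected_signal_loss_pct"]

RATE_HZ = 4.0


@dataclass
class SynthConfig:
    """Cohort-level generator settings.

    Depth/probability of decelerations carry the planted class effect:
    compromised records get frequent deep contraction-locked dips, normal
    records rare shallow ones.
    """

    n_records: int = 100
    compromised_fraction: float = 0.2
    duration_min: float = 60.0
    baseline_bpm: tuple[float, float] = (120.0, 160.0)
    variability_bpm: float = 5.0
    contraction_period_s: tuple[float, float] = (180.0, 300.0)
    decel_depth_bpm: tuple[float, float] = (20.0, 60.0)
    decel_depth_bpm_normal: tuple[float, float] = (10.0, 30.0)
    decel_prob_per_contraction: float = 0.8
    decel_prob_per_contraction_normal: float = 0.1
    decel_lag_s: float = 30.0
    decel_width_s: float = 45.0
    dropout_mean_gap_s: float = 20.0
    dropout_rate_per_min: float = 0.3
    outlier_rate_per_min: float = 0.2
    ph_normal: tuple[float, float] = (7.25, 0.07)  # truncated normal, lower 7.05
    ph_compromised: tuple[float, float] = (6.85, 7.05)  # uniform
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.baseline_bpm,
            self.contraction_period_s,
            self.decel_depth_bpm,
            self.decel_depth_bpm_normal,
            self.ph_compromised,
        ):
            if lo > hi:
                raise ValueError(f"range ({lo}, {hi}) is not ordered")
        for p in (
            self.compromised_fraction,
            self.decel_prob_per_contraction,
            self.decel_prob_per_contraction_normal,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        n_comp = int(round(self.n_records * self.compromised_fraction))
        if not 0 < n_comp < self.n_records:
            raise ValueError(
                "compromised_fraction must yield at least one record of each class"
            )


def expected_signal_loss_pct(cfg: SynthConfig) -> float:
    """Stationary gap fraction of the two-state dropout process, in percent."""
    if cfg.dropout_rate_per_min <= 0 or cfg.dropout_mean_gap_s <= 0:
        return 0.0
    p_enter = cfg.dropout_rate_per_min / (60.0 * RATE_HZ)
    p_exit = 1.0 / (cfg.dropout_mean_gap_s * RATE_HZ)
    return 100.0 * p_enter / (p_enter + p_exit)


def _bandlimited_noise(n: int, std: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise low-passed below ~0.5 Hz: beat-to-beat FHR variability."""
    if std <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n + 256)
    b, a = sps.butter(2, 0.5 / (RATE_HZ / 2))
    coloured = sps.lfilter(b, a, white)[256:]
    sd = coloured.std()
    return coloured * (std / sd) if sd > 0 else np.zeros(n)


def _uc_trace(
    n: int, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Periodic raised-cosine contraction bumps with jitter; returns peaks too."""
    uc = np.zeros(n)
    peaks: list[int] = []
    t = rng.uniform(30.0, 90.0) * RATE_HZ  # first peak somewhere early
    while t < n:
        peaks.append(int(t))
        half = int(rng.uniform(30.0, 50.0) * RATE_HZ)  # contraction half-width
        amp = rng.uniform(40.0, 80.0)
        a, b = max(0, int(t) - half), min(n, int(t) + half)
        k = np.arange(a, b)
        uc[a:b] += amp * 0.5 * (1 + np.cos(np.pi * (k - t) / half))
        period = rng.uniform(*cfg.contraction_period_s)
        t += (period + rng.normal(0, 10.0)) * RATE_HZ
    uc += np.abs(rng.normal(0, 2.0, n)) + 5.0
    return uc, peaks


def generate_record(
    record_id: str, compromised: bool, cfg: SynthConfig, rng: np.random.Generator
) -> CTGRecord:
    """Generate one labelled CTG record at 4 Hz."""
    n = int(round(cfg.duration_min * 60 * RATE_HZ))
    baseline = rng.uniform(*cfg.baseline_bpm)
    fhr = baseline + _bandlimited_noise(n, cfg.variability_bpm, rng)

    uc, peaks = _uc_trace(n, cfg, rng)

    # contraction-locked decelerations (late: lagged after the UC peak)
    p_decel = (
        cfg.decel_prob_per_contraction
        if compromised
        else cfg.decel_prob_per_contraction_normal
    )
    depth_range = cfg.decel_depth_bpm if compromised else cfg.decel_depth_bpm_normal
    width = cfg.decel_width_s * RATE_HZ
    for pk in peaks:
        if rng.uniform() >= p_decel:
            continue
        centre = pk + (cfg.decel_lag_s + rng.normal(0, 5.0)) * RATE_HZ
        depth = rng.uniform(*depth_range)
        k = np.arange(n)
        fhr -= depth * np.exp(-0.5 * ((k - centre) / (width / 2.355)) ** 2)

    # non-physiological outliers (isolated spikes outside 50-200 bpm)
    n_outliers = rng.poisson(cfg.outlier_rate_per_min * cfg.duration_min)
    for _ in range(n_outliers):
        i = rng.integers(0, n)
        fhr[i] = rng.uniform(205.0, 230.0) if rng.uniform() < 0.5 else rng.uniform(25.0, 45.0)

    # two-state (valid/gap) geometric dropout
    if cfg.dropout_rate_per_min > 0 and cfg.dropout_mean_gap_s > 0:
        p_enter = cfg.dropout_rate_per_min / (60.0 * RATE_HZ)
        p_exit = 1.0 / (cfg.dropout_mean_gap_s * RATE_HZ)
        u = rng.uniform(size=n)
        gap = np.zeros(n, dtype=bool)
        state = False
        for i in range(n):
            state = (u[i] < p_enter) if not state else (u[i] >= p_exit)
            gap[i] = state
        fhr[gap] = 0.0
        uc[gap] = np.where(rng.uniform(size=int(gap.sum())) < 0.5, 0.0, uc[gap])

    if compromised:
        # floor-round so rounding can never lift a compromised pH onto the cut
        ph = float(np.floor(rng.uniform(*cfg.ph_compromised) * 1000.0) / 1000.0)
        return CTGRecord(
            record_id=record_id,
            fhr_raw=fhr,
            uc_raw=np.clip(uc, 0.0, None),
            sample_rate=RATE_HZ,
            ph=ph,
        )
    else:
        mean, sd = cfg.ph_normal
        a = (7.05 - mean) / sd  # truncate below the compromise cut
        ph = float(stats.truncnorm.rvs(a, (7.59 - mean) / sd, loc=mean, scale=sd,
                                       random_state=rng))
    return CTGRecord(
        record_id=record_id,
        fhr_raw=fhr,
        uc_raw=np.clip(uc, 0.0, None),
        sample_rate=RATE_HZ,
        ph=round(ph, 3),
    )


def generate_cohort(cfg: SynthConfig) -> list[CTGRecord]:
    """Generate a labelled cohort; deterministic for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_comp = int(round(cfg.n_records * cfg.compromised_fraction))
    flags = np.array([True] * n_comp + [False] * (cfg.n_records - n_comp))
    rng.shuffle(flags)
    return [
        generate_record(f"synth{i:04d}", bool(flag), cfg, rng)
        for i, flag in enumerate(flags)
    ]


def write_cohort(records: list[CTGRecord], directory: str | Path,
                 dialect: str = "csv") -> None:
    """Write a cohort plus ``meta.csv`` in the requested dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".csv" if dialect == "csv" else ".hea"
    for rec in records:
        write_record(rec, directory / f"{rec.record_id}{ext}", dialect=dialect)
    write_meta_sidecar(records, directory / "meta.csv")


def planted_effect_check(records: list[CTGRecord]) -> dict:
    """Per-class deceleration summaries: the generator's separability contract.

    Compromised records must show deeper decelerations (higher median absolute
    deviation from baseline, more negative deceleration capacity) than normal
    ones; classifiers downstream rely on that planted signal.
    """
    from .features import compute_features  # deferred: features imports nothing back
    from .preprocess import OUT_RATE_HZ, preprocess_fhr

    rows = {"compromised": {"mad_dtrd": [], "dc_prsa": []},
            "normal": {"mad_dtrd": [], "dc_prsa": []}}
    for rec in records:
        if rec.ph is None:
            continue
        # features at the cleaned 0.25 Hz rate, where one PRSA step spans 4 s
        # and deceleration-scale structure is visible
        clean = preprocess_fhr(rec.fhr_raw, rate=rec.sample_rate)
        fv = compute_features(clean, rate=OUT_RATE_HZ)
        cls = "compromised" if rec.label.is_compromised else "normal"
        if fv.valid["mad_dtrd"]:
            rows[cls]["mad_dtrd"].append(fv.mad_dtrd)
        if fv.valid["dc_prsa"]:
            rows[cls]["dc_prsa"].append(fv.dc_prsa)
    return {
        cls: {name: float(np.mean(vals)) if vals else float("nan")
              for name, vals in feats.items()}
        for cls, feats in rows.items()
    }
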