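"""Input-length-invariant FHR classifier (FHR-LINet) and the multimodal
CNN baseline (MCNN).

FHR-LINet takes a 0.25 Hz FHR segment of any length (above the largest
kernel) and outputs a compromise probability. Its topology is: input batch
normalisation -> three parallel 1-D convolutions with kernel sizes 5/15/25
(inception-style multiscale front end, 160 filters each, ReLU) ->
channel-wise concatenation -> max pooling (size 2) -> two further
convolutions (128 filters, kernels 7 and 9, ReLU) -> global average pooling
over time -> dense 64 (ReLU) -> dropout -> a single sigmoid unit. Global
average pooling removes every dependence of the parameter set on the input
length, so one set of weights evaluates 15-, 30-, 45- or 60-minute windows
without retraining.

The MCNN baseline processes fixed-length FHR and UC traces through two
convolutional branches (five conv(40 filters, kernel 9) + batch-norm + ReLU
+ max-pool stages each), multiplies the FHR branch output elementwise by a
learned projection of a per-window signal-quality vector, concatenates with
the UC branch, and classifies through two dense layers and a sigmoid unit.
Its dense layers fix the input length at configuration time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocess import WindowSegment, window_count

__all__ = [
    "LINetConfig",
    "MCNNConfig",
    "TrainConfig",
    "FHRLINet",
    "MCNN",
    "build_fhr_linet",
    "build_mcnn",
    "class_weights",
    "train_model",
    "predict_segments",
]


@dataclass
class LINetConfig:
    """FHR-LINet hyper-parameters (defaults follow the published topology)."""

    branch_kernels: tuple[int, int, int] = (5, 15, 25)
    branch_filters: int = 160
    pool_size: int = 2
    post_kernels: tuple[int, int] = (7, 9)
    post_filters: int = 128
    dense_units: int = 64
    dropout_rate: float = 0.3
    dilation: int = 1  # exposed but 1 (undilated) by default

    def __post_init__(self) -> None:
        for k in (*self.branch_kernels, *self.post_kernels):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernel sizes must be odd and >= 1")
        if self.branch_filters < 1 or self.post_filters < 1:
            raise ValueError("filter counts must be >= 1")

    @classmethod
    def small(cls) -> "LINetConfig":
        """Width-reduced variant (same topology) for desk-scale experiments."""
        return cls(branch_filters=24, post_filters=24, dense_units=16)

    @property
    def min_input_len(self) -> int:
        return max(self.branch_kernels)


@dataclass
class MCNNConfig:
    """MCNN hyper-parameters for a fixed evaluation length.

    ``quality_len`` is tied to the duration: floor((D - 15)/5) + 1, i.e. 10
    for 60 min, 7 for 45, 4 for 30.
    """

    duration_min: float = 60.0
    conv_kernel: int = 9
    conv_filters: int = 40
    conv_blocks_per_branch: int = 5
    fc_units: int = 10
    dropout_rate: float = 0.3
    rate_hz: float = 0.25

    @property
    def input_len(self) -> int:
        return int(round(self.duration_min * 60 * self.rate_hz))

    @property
    def quality_len(self) -> int:
        return window_count(self.duration_min, 15.0, 5.0)

    @classmethod
    def small(cls, duration_min: float = 60.0) -> "MCNNConfig":
        return cls(duration_min=duration_min, conv_filters=12)


@dataclass
class TrainConfig:
    """Optimisation settings (defaults follow the published protocol)."""

    epochs: int = 65
    batch_size: int = 32
    learning_rate: float = 1e-4
    folds: int = 5
    repeats: int = 5
    seed: int = 0
    exclude_intermediate_from_training: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.folds < 2:
            raise ValueError("need epochs >= 1 and folds >= 2")


class FHRLINet:
    """Input-length-invariant CNN; one weight set for any segment length."""

    def __init__(self, cfg: LINetConfig | None = None, seed: int = 0):
        self.cfg = cfg = cfg or LINetConfig()
        rng = np.random.default_rng(seed)
        self.bn_in = nn.BatchNorm(1)
        self.branches = [
            nn.Conv1D(1, cfg.branch_filters, k, rng) for k in cfg.branch_kernels
        ]
        self.branch_relu = [nn.ReLU() for _ in cfg.branch_kernels]
        cat = cfg.branch_filters * len(cfg.branch_kernels)
        self.pool = nn.MaxPool1D(cfg.pool_size)
        self.post = nn.Sequential(
            [
                nn.Conv1D(cat, cfg.post_filters, cfg.post_kernels[0], rng),
                nn.ReLU(),
                nn.Conv1D(cfg.post_filters, cfg.post_filters, cfg.post_kernels[1], rng),
                nn.ReLU(),
                nn.GlobalAvgPool1D(),
                nn.Dense(cfg.post_filters, cfg.dense_units, rng),
                nn.ReLU(),
                nn.Dropout(cfg.dropout_rate, rng),
                nn.Dense(cfg.dense_units, 1, rng),
            ]
        )

    def params(self) -> list[nn.Param]:
        out = self.bn_in.params()
        for br in self.branches:
            out += br.params()
        return out + self.post.params()

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch ``(N, T, 1)``; T may differ between calls."""
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] < self.cfg.min_input_len:
            raise ValueError(
                f"input length {x.shape[1]} below the minimum "
                f"{self.cfg.min_input_len} (largest kernel)"
            )
        h = self.bn_in.forward(x, training)
        outs = [
            relu.forward(conv.forward(h, training), training)
            for conv, relu in zip(self.branches, self.branch_relu)
        ]
        cat = np.concatenate(outs, axis=2)
        return self.post.forward(self.pool.forward(cat, training), training)

    def backward(self, dlogits: np.ndarray) -> None:
        dcat = self.pool.backward(self.post.backward(dlogits))
        f = self.cfg.branch_filters
        dh = np.zeros_like(self._dh_template)
        for i, (conv, relu) in enumerate(zip(self.branches, self.branch_relu)):
            dh += conv.backward(relu.backward(dcat[:, :, i * f : (i + 1) * f]))
        self.bn_in.backward(dh)

    def train_forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 2:
            x = x[:, :, None]
        self._dh_template = x
        return self.forward(x, training=True)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(np.asarray(x), training=False)).ravel()


class _ConvBranch(nn.Sequential):
    """Five conv+BN+ReLU+pool stages, dropout, then a dense projection."""

    def __init__(self, cfg: MCNNConfig, out_len: int, rng: np.random.Generator):
        layers: list[nn.Layer] = []
        c_in, t = 1, cfg.input_len
        for _ in range(cfg.conv_blocks_per_branch):
            layers += [
                nn.Conv1D(c_in, cfg.conv_filters, cfg.conv_kernel, rng),
                nn.BatchNorm(cfg.conv_filters),
                nn.ReLU(),
                nn.MaxPool1D(2),
            ]
            c_in, t = cfg.conv_filters, t // 2
        layers += [
            nn.Dropout(cfg.dropout_rate, rng),
            nn.Flatten(),
            nn.Dense(t * c_in, out_len, rng),
        ]
        super().__init__(layers)


class MCNN:
    """Multimodal CNN: FHR and UC branches plus a signal-quality gate."""

    def __init__(self, cfg: MCNNConfig | None = None, seed: int = 0):
        self.cfg = cfg = cfg or MCNNConfig()
        rng = np.random.default_rng(seed)
        q = cfg.quality_len
        self.fhr_branch = _ConvBranch(cfg, q, rng)
        self.uc_branch = _ConvBranch(cfg, q, rng)
        self.quality_branch = nn.Dense(q, q, rng)
        self.head = nn.Sequential(
            [
                nn.Dense(2 * q, cfg.fc_units, rng),
                nn.ReLU(),
                nn.Dropout(cfg.dropout_rate, rng),
                nn.Dense(cfg.fc_units, cfg.fc_units, rng),
                nn.ReLU(),
                nn.Dropout(cfg.dropout_rate, rng),
                nn.Dense(cfg.fc_units, 1, rng),
            ]
        )

    def params(self) -> list[nn.Param]:
        return (
            self.fhr_branch.params()
            + self.uc_branch.params()
            + self.quality_branch.params()
            + self.head.params()
        )

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _check(self, fhr: np.ndarray) -> None:
        if fhr.shape[1] != self.cfg.input_len:
            raise ValueError(
                f"MCNN configured for length {self.cfg.input_len}, "
                f"got {fhr.shape[1]}"
            )

    def forward(
        self,
        fhr: np.ndarray,
        uc: np.ndarray,
        quality: np.ndarray,
        training: bool = False,
    ) -> np.ndarray:
        if fhr.ndim == 2:
            fhr = fhr[:, :, None]
        if uc.ndim == 2:
            uc = uc[:, :, None]
        self._check(fhr)
        f = self.fhr_branch.forward(fhr, training)
        u = self.uc_branch.forward(uc, training)
        g = self.quality_branch.forward(quality, training)
        if training:
            self._f, self._g = f, g
        merged = np.concatenate([f * g, u], axis=1)
        return self.head.forward(merged, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dmerged = self.head.backward(dlogits)
        q = self.cfg.quality_len
        dprod, du = dmerged[:, :q], dmerged[:, q:]
        self.fhr_branch.backward(dprod * self._g)
        self.quality_branch.backward(dprod * self._f)
        self.uc_branch.backward(du)

    def predict_proba(
        self, fhr: np.ndarray, uc: np.ndarray, quality: np.ndarray
    ) -> np.ndarray:
        return nn.sigmoid(self.forward(fhr, uc, quality, training=False)).ravel()


def build_fhr_linet(cfg: LINetConfig | None = None, seed: int = 0) -> FHRLINet:
    return FHRLINet(cfg, seed=seed)


def build_mcnn(cfg: MCNNConfig | None = None, seed: int = 0) -> MCNN:
    return MCNN(cfg, seed=seed)


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Balanced inverse-frequency weights: w_c = n_total / (2 n_c)."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty label list")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return {int(c): y.size / (2.0 * n) for c, n in zip(classes, counts)}


def _segments_to_array(segments: list[WindowSegment]) -> np.ndarray:
    lengths = {seg.samples.size for seg in segments}
    if len(lengths) != 1:
        raise ValueError("training segments must share one length")
    return np.stack([seg.samples for seg in segments])[:, :, None]


def train_model(
    model: FHRLINet,
    segments: list[WindowSegment],
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> FHRLINet:
    """Train with weighted binary cross-entropy and Adam.

    All segments must share one length (the augmentation windows do);
    shuffling, dropout and initialisation are all driven by fixed seeds, so
    two runs from the same seeds produce identical weights.
    """
    cfg = cfg or TrainConfig()
    X = _segments_to_array(segments)
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("segments and labels differ in length")
    cw = class_weights(y)
    w = np.where(y > 0.5, cw[1], cw[0])
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            z = model.train_forward(X[idx])
            loss, dz = nn.weighted_bce_from_logits(z, y[idx], w[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss {loss}")
            model.backward(dz)
            opt.step()
    return model


def train_mcnn(
    model: MCNN,
    fhr: np.ndarray,
    uc: np.ndarray,
    quality: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> MCNN:
    """Train the MCNN on fixed-length (FHR, UC, quality) triples."""
    cfg = cfg or TrainConfig()
    y = np.asarray(labels, dtype=float)
    cw = class_weights(y)
    w = np.where(y > 0.5, cw[1], cw[0])
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = y.size
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            z = model.forward(fhr[idx], uc[idx], quality[idx], training=True)
            loss, dz = nn.weighted_bce_from_logits(z, y[idx], w[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss {loss}")
            model.backward(dz)
            opt.step()
    return model


def predict_segments(model: FHRLINet, segments: list[WindowSegment]) -> np.ndarray:
    """One compromise probability per segment; segments may differ in length."""
    probs = np.empty(len(segments))
    by_len: dict[int, list[int]] = {}
    for i, seg in enumerate(segments):
        by_len.setdefault(seg.samples.size, []).append(i)
    for idx in by_len.values():
        batch = np.stack([segments[i].samples for i in idx])[:, :, None]
        probs[idx] = model.predict_proba(batch)
    return probs
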