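"""The CNN-LSTM window classifier and a deterministic spectral baseline.

Architecture (input: one 30-sample x 13-channel processed window):

    Conv1D(32) -> dropout -> ReLU
    Conv1D(64) -> dropout -> ReLU
    MaxPool1D(2)
    LSTM(16)            (final hidden state)
    Dense(64) -> ReLU
    Dense(output_units) -> softmax

``output_units`` is 2 by default (non-scratch / scratch). The 3-class
variant separates rubbing (class 2) during training and collapses it onto
scratch at prediction time, reflecting that rubbing relieves itch the same
way and is counted as scratching.

Unstated hyperparameters (kernel size, dropout rate, pool size, optimizer,
learning rate, epochs, batch size) are fixed, documented defaults exposed
through :class:`ModelConfig`. Per-channel normalisation statistics are
estimated on the training windows only and stored with the model; they are
never recomputed from evaluation data.

The rule-based baseline needs no training: a window is called scratch if
any filtered stretch channel carries enough 3-8 Hz band power, or if the
accelerometer does while at least three fingers are in the bent state —
the same physical signatures the network is meant to learn. It serves as
an independent sanity check on the network, not as its substitute.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from scratchkit import nn
from scratchkit.dsp import band_power
from scratchkit.windowing import WindowSet

#: 3-class label vocabulary for the optional rub-aware variant.
CLASS_NON_SCRATCH, CLASS_SCRATCH, CLASS_RUB = 0, 1, 2


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters."""

    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel_size: int = 3
    dropout_rate: float = 0.2
    pool_size: int = 2
    lstm_units: int = 16
    dense_units: int = 64
    output_units: int = 2
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    window_len: int = 30
    n_channels: int = 13

    def __post_init__(self) -> None:
        for name in ("conv1_filters", "conv2_filters", "kernel_size",
                     "pool_size", "lstm_units", "dense_units", "epochs",
                     "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.output_units not in (2, 3):
            raise ValueError("output_units must be 2 or 3")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def build_model(cfg: ModelConfig | None = None) -> nn.Sequential:
    """Construct the untrained layer stack for 30 x 13 windows.

    The pooling stage follows the 64-filter convolution (pooling itself has
    no filters); dropout precedes each ReLU. Weight initialisation is
    seeded from ``cfg.seed``.
    """
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(cfg.seed)
    return nn.Sequential([
        nn.Conv1D(cfg.n_channels, cfg.conv1_filters, cfg.kernel_size, rng),
        nn.Dropout(cfg.dropout_rate),
        nn.ReLU(),
        nn.Conv1D(cfg.conv1_filters, cfg.conv2_filters, cfg.kernel_size,
                  rng),
        nn.Dropout(cfg.dropout_rate),
        nn.ReLU(),
        nn.MaxPool1D(cfg.pool_size),
        nn.LSTM(cfg.conv2_filters, cfg.lstm_units, rng),
        nn.Dense(cfg.lstm_units, cfg.dense_units, rng),
        nn.ReLU(),
        nn.Dense(cfg.dense_units, cfg.output_units, rng),
    ])


@dataclass
class TrainedModel:
    """A fitted classifier: weights + normalisation statistics + history."""

    net: nn.Sequential
    config: ModelConfig
    norm_mean: np.ndarray  # (13,) per-channel mean from training windows
    norm_sd: np.ndarray    # (13,) per-channel sd from training windows
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.norm_mean = np.asarray(self.norm_mean, dtype=float)
        self.norm_sd = np.asarray(self.norm_sd, dtype=float)
        if self.norm_mean.shape != (self.config.n_channels,):
            raise ValueError("norm_mean must have one entry per channel")
        if self.norm_sd.shape != (self.config.n_channels,):
            raise ValueError("norm_sd must have one entry per channel")

    def _normalize(self, windows: np.ndarray) -> np.ndarray:
        return (windows - self.norm_mean) / self.norm_sd

    def predict_proba(self, window_set: WindowSet) -> np.ndarray:
        """Class probabilities ``(W, output_units)`` (softmax rows)."""
        w = np.asarray(window_set.windows, dtype=float)
        if w.shape[1:] != (self.config.window_len, self.config.n_channels):
            raise ValueError(
                f"windows must be (W, {self.config.window_len}, "
                f"{self.config.n_channels}), got {w.shape}"
            )
        if w.shape[0] == 0:
            return np.empty((0, self.config.output_units))
        logits = self.net.forward(self._normalize(w), train=False)
        return nn.softmax(logits)

    def save(self, path: str | Path) -> None:
        """Persist to a directory: JSON config/stats + .npz weight arrays."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": "scratchkit-model-v1",
            "config": asdict(self.config),
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
            "history": self.history,
        }
        (path / "model.json").write_text(
            json.dumps(meta, indent=2), encoding="utf-8"
        )
        np.savez(path / "weights.npz", **self.net.state_arrays())


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text(encoding="utf-8"))
    if meta.get("format") != "scratchkit-model-v1":
        raise ValueError(f"{path}: not a scratchkit model directory")
    cfg = ModelConfig(**meta["config"])
    net = build_model(cfg)
    with np.load(path / "weights.npz") as z:
        net.load_state(dict(z))
    return TrainedModel(
        net=net, config=cfg,
        norm_mean=np.array(meta["norm_mean"]),
        norm_sd=np.array(meta["norm_sd"]),
        history=meta.get("history", {}),
    )


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def train(
    model: nn.Sequential,
    train_set: WindowSet,
    cfg: ModelConfig | None = None,
    class_labels: np.ndarray | None = None,
) -> TrainedModel:
    """Fit the classifier on a window set.

    Normalisation statistics (per-channel mean and sd) are computed from
    the training windows only and stored on the returned model. Training is
    seeded end to end: the same seed, data, and configuration reproduce the
    same final weights and loss on a single thread.

    ``class_labels`` supplies 3-class targets (0 non-scratch, 1 scratch,
    2 rub) for the ``output_units=3`` variant; by default the window set's
    binary labels are used. A training set containing a single class is an
    error.
    """
    cfg = cfg or ModelConfig()
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    y = train_set.labels if class_labels is None \
        else np.asarray(class_labels, dtype=np.int64)
    if y.shape != (len(train_set),):
        raise ValueError("class_labels must have one entry per window")
    if y.max() >= cfg.output_units:
        raise ValueError(
            f"label {y.max()} out of range for output_units="
            f"{cfg.output_units}"
        )
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least two classes")

    x = np.asarray(train_set.windows, dtype=float)
    mean = x.mean(axis=(0, 1))
    sd = x.std(axis=(0, 1))
    sd = np.where(sd < 1e-8, 1.0, sd)
    xn = (x - mean) / sd
    onehot = _one_hot(y, cfg.output_units)

    rng = np.random.default_rng(cfg.seed + 1)  # distinct from init stream
    opt = nn.Adam(model, lr=cfg.learning_rate)
    n = xn.shape[0]
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = model.forward(xn[idx], train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, onehot[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        pred = model.forward(xn, train=False).argmax(axis=1)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(float((pred == y).mean()))

    return TrainedModel(net=model, config=cfg, norm_mean=mean, norm_sd=sd,
                        history=history)


def predict(m: TrainedModel, window_set: WindowSet) -> np.ndarray:
    """Binary per-window labels; the 3-class rub output collapses to 1."""
    if len(window_set) == 0:
        return np.empty(0, dtype=np.int64)
    classes = m.predict_proba(window_set).argmax(axis=1)
    return (classes >= CLASS_SCRATCH).astype(np.int64)


@dataclass
class RuleBaselineConfig:
    """Thresholds for the training-free spectral detector.

    Band powers are integrated periodogram power inside the scratch band.
    The defaults give about a decade of margin each way under the default
    synthetic signal scales (20 mΩ stretch oscillations over ~1 mΩ noise;
    0.5 g accelerometer oscillations over ~0.02 g noise).
    """

    band_hz: tuple[float, float] = (3.0, 8.0)
    stretch_power_mohm2: float = 20.0
    accel_power_g2: float = 0.01
    min_bent_fingers: int = 3
    bent_duty_frac: float = 1.0 / 3.0
    sample_rate_hz: float = 20.0


def rule_baseline(
    window_set: WindowSet, cfg: RuleBaselineConfig | None = None,
) -> np.ndarray:
    """Deterministic per-window scratch calls from band power + bend states.

    A window is scratch (1) if any filtered stretch channel's band power in
    the scratch band exceeds ``stretch_power_mohm2`` (finger-dominant
    signature), or if any filtered accelerometer axis exceeds
    ``accel_power_g2`` while at least ``min_bent_fingers`` fingers count as
    bent (arm-dominant signature). A finger counts as bent when its bend
    channel is 1 for at least ``bent_duty_frac`` of the window: the slow
    path's high-pass de-means long curls, so within-window duty — not an
    every-sample requirement — is the robust statistic.
    """
    cfg = cfg or RuleBaselineConfig()
    out = np.zeros(len(window_set), dtype=np.int64)
    for i, win in enumerate(window_set.windows):  # win: (T, 13)
        stretch_p = max(
            band_power(win[:, ch], cfg.sample_rate_hz, cfg.band_hz)
            for ch in range(5)
        )
        accel_p = max(
            band_power(win[:, ch], cfg.sample_rate_hz, cfg.band_hz)
            for ch in range(5, 8)
        )
        duty = win[:, 8:13].mean(axis=0)
        bent = int((duty >= cfg.bent_duty_frac).sum())
        finger_like = stretch_p > cfg.stretch_power_mohm2
        arm_like = (accel_p > cfg.accel_power_g2
                    and bent >= cfg.min_bent_fingers)
        out[i] = int(finger_like or arm_like)
    return out
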