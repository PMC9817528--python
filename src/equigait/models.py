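"""Sequence classifiers for gait recognition and their training harness.

Four architectures are supported, all mapping an ``(ni, T)`` segment to a
5-class probability vector:

* ``lstm`` — one LSTM layer (200 units by default), last hidden state;
* ``bilstm`` — bidirectional LSTM, 400 units total (200 per direction),
  concatenated final states of the two directions;
* ``gru`` — one GRU layer (200 units);
* ``cnn1d`` — four dilated 1-D convolutions (kernel 3, dilations 12/8/4/1,
  channels ni→16→32→64→128), globally averaged over time.

Each feeds a 128-unit linear layer (ReLU) and a 5-class softmax head.
Training uses Adam, cross-entropy, batch size 64, up to 20 epochs, and
early stopping on validation loss (patience 3, best checkpoint restored).
Inputs are z-scored per channel with training-set statistics, since raw
m/s² and deg/s scales differ by an order of magnitude.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .dataset import Segment
from .gaits import Gait

N_CLASSES = 5

ARCHS = ("lstm", "bilstm", "gru", "cnn1d")

CNN_DILATIONS = (12, 8, 4, 1)
CNN_OUT_CHANNELS = (16, 32, 64, 128)


class ConfigError(ValueError):
    """Invalid model or training configuration."""


class ShapeError(ValueError):
    """Input channel count does not match the model."""


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``units`` is the total recurrent width: 200 for lstm/gru, 400 for
    bilstm (200 per direction). The ``small`` profile (units 64, epochs 10
    in :class:`TrainConfig`) is for fast desk-scale experiments.
    """

    arch: str = "bilstm"
    units: int = 400
    ni: int = 6
    n_classes: int = N_CLASSES
    head_units: int = 128

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ConfigError(f"unsupported architecture {self.arch!r}")
        if self.n_classes != N_CLASSES:
            raise ConfigError("the gait classifier has exactly 5 classes")
        if self.ni not in (3, 6, 7):
            raise ConfigError(f"ni must be one of 3, 6, 7, got {self.ni}")
        if self.arch == "bilstm" and self.units % 2:
            raise ConfigError("bilstm units must be even (split over directions)")


def small_config(arch: str = "bilstm", ni: int = 6) -> "ModelConfig":
    """The reduced profile: 64 recurrent units (128 total for bilstm)."""
    units = 128 if arch == "bilstm" else 64
    return ModelConfig(arch=arch, units=units, ni=ni)


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    lr: float = 1e-3
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")


class SequenceClassifier:
    """A built network: layers, normalisation statistics and forward/backward."""

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.norm_mu = np.zeros(cfg.ni, dtype=_nn.DTYPE)
        self.norm_sd = np.ones(cfg.ni, dtype=_nn.DTYPE)
        ni = cfg.ni
        if cfg.arch == "lstm":
            self.rnn = _nn.LSTMCellSeq(rng, ni, cfg.units)
            feat = cfg.units
            self.layers = [self.rnn]
        elif cfg.arch == "gru":
            self.rnn = _nn.GRUCellSeq(rng, ni, cfg.units)
            feat = cfg.units
            self.layers = [self.rnn]
        elif cfg.arch == "bilstm":
            half = cfg.units // 2
            self.rnn_f = _nn.LSTMCellSeq(rng, ni, half)
            self.rnn_b = _nn.LSTMCellSeq(rng, ni, half)
            feat = cfg.units
            self.layers = [self.rnn_f, self.rnn_b]
        else:  # cnn1d
            chans = (ni,) + CNN_OUT_CHANNELS
            self.convs = [
                _nn.DilatedConv1d(rng, chans[i], chans[i + 1], CNN_DILATIONS[i])
                for i in range(4)
            ]
            self.conv_relus = [_nn.ReLU() for _ in range(4)]
            feat = CNN_OUT_CHANNELS[-1]
            self.layers = list(self.convs) + list(self.conv_relus)
        self.head1 = _nn.Dense(rng, feat, cfg.head_units)
        self.head_relu = _nn.ReLU()
        self.head2 = _nn.Dense(rng, cfg.head_units, cfg.n_classes)
        self.layers += [self.head1, self.head_relu, self.head2]
        self._param_layers = [lay for lay in self.layers if lay.params]

    # -- forward / backward ------------------------------------------------

    def _normalise(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mu[None, :, None]) / self.norm_sd[None, :, None]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch ``x`` of shape (B, ni, T)."""
        if x.ndim != 3 or x.shape[1] != self.cfg.ni:
            raise ShapeError(
                f"expected (B, {self.cfg.ni}, T) input, got {x.shape}"
            )
        x = self._normalise(x.astype(_nn.DTYPE))
        arch = self.cfg.arch
        if arch in ("lstm", "gru"):
            hs = self.rnn.forward(np.ascontiguousarray(x.transpose(0, 2, 1)))
            self._T = hs.shape[1]
            feat = hs[:, -1]
        elif arch == "bilstm":
            xt = np.ascontiguousarray(x.transpose(0, 2, 1))
            hs_f = self.rnn_f.forward(xt)
            hs_b = self.rnn_b.forward(np.ascontiguousarray(xt[:, ::-1]))
            self._T = hs_f.shape[1]
            feat = np.concatenate([hs_f[:, -1], hs_b[:, -1]], axis=1)
        else:
            h = x
            for conv, relu in zip(self.convs, self.conv_relus):
                h = relu.forward(conv.forward(h))
            self._T = h.shape[2]
            feat = h.mean(axis=2)
        return self.head2.forward(self.head_relu.forward(self.head1.forward(feat)))

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head1.backward(
            self.head_relu.backward(self.head2.backward(dlogits))
        )
        B = dfeat.shape[0]
        arch = self.cfg.arch
        if arch in ("lstm", "gru"):
            dhs = np.zeros((B, self._T, self.cfg.units), dtype=_nn.DTYPE)
            dhs[:, -1] = dfeat
            self.rnn.backward(dhs)
        elif arch == "bilstm":
            half = self.cfg.units // 2
            dhs = np.zeros((B, self._T, half), dtype=_nn.DTYPE)
            dhs[:, -1] = dfeat[:, :half]
            self.rnn_f.backward(dhs)
            dhs = np.zeros((B, self._T, half), dtype=_nn.DTYPE)
            dhs[:, -1] = dfeat[:, half:]
            self.rnn_b.backward(dhs)
        else:
            dh = np.repeat(
                (dfeat / self._T)[:, :, None], self._T, axis=2
            ).astype(_nn.DTYPE)
            for conv, relu in zip(reversed(self.convs), reversed(self.conv_relus)):
                dh = conv.backward(relu.backward(dh))

    def zero_grad(self) -> None:
        for lay in self._param_layers:
            lay.zero_grad()

    # -- persistence -------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for lay in self._param_layers for p in lay.params.values()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for lay in self._param_layers:
            for k in lay.params:
                lay.params[k] = next(it).copy()

    def save(self, path: str | Path) -> None:
        arrays = {
            f"w{i}": w for i, w in enumerate(self.get_weights())
        }
        np.savez(
            path,
            arch=self.cfg.arch,
            units=self.cfg.units,
            ni=self.cfg.ni,
            norm_mu=self.norm_mu,
            norm_sd=self.norm_sd,
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SequenceClassifier":
        data = np.load(path, allow_pickle=False)
        cfg = ModelConfig(
            arch=str(data["arch"]), units=int(data["units"]), ni=int(data["ni"])
        )
        model = cls(cfg)
        n = len([k for k in data.files if k.startswith("w")])
        model.set_weights([data[f"w{i}"] for i in range(n)])
        model.norm_mu = data["norm_mu"]
        model.norm_sd = data["norm_sd"]
        return model


def build_model(cfg: ModelConfig, seed: int = 0) -> SequenceClassifier:
    """Construct (and seed-initialise) a classifier from its configuration."""
    return SequenceClassifier(cfg, seed=seed)


def segments_to_arrays(segments: Sequence[Segment]) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into ``X (n, C, T)`` and integer labels ``y (n,)``."""
    X = np.stack([s.x for s in segments]).astype(_nn.DTYPE)
    y = np.array([int(s.y) for s in segments], dtype=np.int64)
    return X, y


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        X, y = data
        return np.asarray(X, dtype=_nn.DTYPE), np.asarray(y, dtype=np.int64)
    return segments_to_arrays(data)


def train_model(
    model: SequenceClassifier,
    train,
    val,
    cfg: TrainConfig,
) -> tuple[SequenceClassifier, list[dict]]:
    """Train in place; return the model (best-val-loss weights) and history.

    ``train``/``val`` are either segment lists or ``(X, y)`` tuples. The
    per-channel z-scoring statistics are computed from the training set and
    stored on the model so prediction applies the same transform.
    """
    X_tr, y_tr = _as_arrays(train)
    if len(X_tr) == 0:
        raise ConfigError("empty training set")
    X_va, y_va = _as_arrays(val)
    if len(X_va) == 0:
        raise ConfigError("early stopping needs a nonempty validation set")

    mu = X_tr.mean(axis=(0, 2))
    sd = X_tr.std(axis=(0, 2))
    sd[sd < 1e-8] = 1.0
    model.norm_mu = mu.astype(_nn.DTYPE)
    model.norm_sd = sd.astype(_nn.DTYPE)

    rng = np.random.default_rng(cfg.seed)
    opt = _nn.Adam(model._param_layers, lr=cfg.lr)
    history: list[dict] = []
    best_loss = np.inf
    best_weights = model.get_weights()
    strikes = 0
    n = len(X_tr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(X_tr[idx])
            loss, dlogits = _nn.cross_entropy(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            total += loss * len(idx)
        val_logits = _forward_batched(model, X_va)
        val_loss, _ = _nn.cross_entropy(val_logits, y_va)
        val_acc = float((val_logits.argmax(axis=1) == y_va).mean())
        history.append(
            {
                "epoch": epoch,
                "train_loss": total / n,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = model.get_weights()
            strikes = 0
        else:
            strikes += 1
            if strikes >= cfg.patience:
                break
    model.set_weights(best_weights)
    return model, history


def _forward_batched(
    model: SequenceClassifier, X: np.ndarray, batch: int = 256
) -> np.ndarray:
    outs = [model.forward(X[i : i + batch]) for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)


def predict_proba(model: SequenceClassifier, segments) -> np.ndarray:
    """Class-probability vectors, one simplex 5-vector per segment, in order."""
    if isinstance(segments, np.ndarray):
        X = segments.astype(_nn.DTYPE)
    else:
        X, _ = segments_to_arrays(segments)
    logits = _forward_batched(model, X)
    return _nn.softmax(logits.astype(np.float64))


def predict_gaits(model: SequenceClassifier, segments) -> list[Gait]:
    return [Gait(int(i)) for i in predict_proba(model, segments).argmax(axis=1)]
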