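"""Dilated causal temporal convolutional network for early-warning prediction.

The network stacks temporal blocks of one-dimensional dilated causal
convolutions (64 filters, kernel size 4).  Block ``i``'s first convolution has
dilation ``2**(i-1)``; the second has dilation 1.  Each convolution is
followed by a ReLU, a one-dimensional spatial dropout (training only) and a
parameter-free channel normalization.  The block stack is followed by global
average pooling over time, a bias-free dense projection to two classes, and a
softmax.  Every linear map is bias-free, which makes the logits positively
homogeneous in the input and underpins the exact equivalence between z-rule
relevance propagation and Gradient x Input used by the explanation module.

The receptive field of the stack is ``1 + sum_i (k-1) * (2**(i-1) + 1)``
(31 time steps for kernel size 4 and three blocks).

All tensors are ``(batch, time, channels)`` float64 arrays; the implementation
is pure NumPy, with explicit forward/backward passes so the explanation module
can read per-layer weights and activations directly.
"""
from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
import zlib
from typing import Sequence

import numpy as np
import pandas as pd

from .ehr import HOUR, AdmissionTimeline, HourlyMatrix, bin_hourly
from .parameters import parameter_names

STANDARD_HORIZONS = (0, 3, 6, 12, 24)


def receptive_field(kernel_size: int, n_blocks: int) -> int:
    """Closed-form receptive field of the temporal block stack.

    ``1 + sum_{i=1..n} (k - 1) * (2**(i-1) + 1)``: each block contributes one
    convolution with dilation ``2**(i-1)`` and one with dilation 1, each
    spanning ``(k-1) * d`` steps beyond the current one.
    """
    if kernel_size < 1 or n_blocks < 1:
        raise ValueError("kernel_size and n_blocks must be positive")
    if kernel_size == 1:
        warnings.warn("kernel_size 1 yields a degenerate receptive field of 1")
    k = kernel_size
    return 1 + sum((k - 1) * (2 ** (i - 1) + 1) for i in range(1, n_blocks + 1))


@dataclasses.dataclass
class TCNConfig:
    n_blocks: int = 3
    filters: int = 64
    kernel_size: int = 4
    dropout_rate: float = 0.10
    n_classes: int = 2
    use_bias: bool = False
    n_features: int = 33
    window_hours: int = 24

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.kernel_size < 2:
            raise ValueError("need n_blocks >= 1 and kernel_size >= 2")
        if self.use_bias:
            raise ValueError(
                "bias terms are not supported: the explanation module's "
                "conservation and gradient equivalences require a bias-free network"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 200
    learning_rate: float = 1e-3
    max_epochs: int = 60
    patience: int = 5
    #: epochs trained before early stopping may trigger (guards against
    #: stopping on the initial plateau before optimization takes off)
    min_epochs: int = 0
    seed: int = 0
    oversample_positives: bool = False
    #: multiply the learning rate by this factor when the validation loss has
    #: not improved for patience//2 epochs (1.0 disables the schedule)
    lr_decay: float = 1.0
    #: decoupled (AdamW-style) weight decay per step; 0 disables
    weight_decay: float = 0.0
    #: number of independently initialized networks whose predicted
    #: probabilities are averaged (small-cohort variance reduction; 1 = the
    #: plain single-model setup)
    n_ensemble: int = 1
    #: std of Gaussian noise added to training inputs (augmentation against
    #: small-sample overfitting; inputs are standardized, so 0.1-0.3 is mild)
    input_noise: float = 0.0
    #: probability of dropping an entire input channel per training sample
    #: (bagging over parameter subsets; discourages reliance on spurious
    #: channels when training cohorts are small)
    input_channel_dropout: float = 0.0
    #: early-stopping monitor: "loss" (validation cross-entropy) or "auroc"
    #: (validation discrimination; appropriate when the end metric is ranking)
    monitor: str = "loss"
    #: per-step decay for Polyak (exponential moving) averaging of weights;
    #: 0 disables.  The averaged network is used for validation monitoring
    #: and returned; averaging weights keeps the network bias-free.
    ema_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate <= 0 or self.max_epochs < 0:
            raise ValueError("invalid training configuration")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# convolution primitives (shared with the explanation module)
# ---------------------------------------------------------------------------

def causal_conv(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Causal dilated 1-D convolution.

    ``x`` is ``(B, T, C_in)``, ``w`` is ``(k, C_in, C_out)``; output position
    ``t`` sees inputs ``t, t-d, ..., t-(k-1)d`` (zero-padded on the left), so
    no output depends on any later input.
    """
    k = w.shape[0]
    B, T, _ = x.shape
    pad = (k - 1) * dilation
    xp = np.concatenate([np.zeros((B, pad, x.shape[2])), x], axis=1)
    out = np.zeros((B, T, w.shape[2]))
    for j in range(k):
        out += xp[:, j * dilation : j * dilation + T, :] @ w[j]
    return out


def causal_conv_input_grad(g: np.ndarray, w: np.ndarray, dilation: int, T: int) -> np.ndarray:
    """Adjoint of :func:`causal_conv` with respect to its input."""
    k = w.shape[0]
    B = g.shape[0]
    pad = (k - 1) * dilation
    gx = np.zeros((B, T + pad, w.shape[1]))
    for j in range(k):
        gx[:, j * dilation : j * dilation + T, :] += g @ w[j].T
    return gx[:, pad:, :]


def causal_conv_weight_grad(x: np.ndarray, g: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """Adjoint of :func:`causal_conv` with respect to its weights."""
    B, T, C_in = x.shape
    pad = (k - 1) * dilation
    xp = np.concatenate([np.zeros((B, pad, C_in)), x], axis=1)
    gw = np.empty((k, C_in, g.shape[2]))
    gflat = g.reshape(-1, g.shape[2])
    for j in range(k):
        seg = xp[:, j * dilation : j * dilation + T, :].reshape(-1, C_in)
        gw[j] = seg.T @ gflat
    return gw


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class CausalConv1d:
    kind = "conv"

    def __init__(self, w: np.ndarray, dilation: int):
        self.w = w
        self.dilation = int(dilation)
        self.gw = np.zeros_like(w)
        self.input: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        self.input = x
        return causal_conv(x, self.w, self.dilation)

    def backward(self, g):
        self.gw = causal_conv_weight_grad(self.input, g, self.w.shape[0], self.dilation)
        return causal_conv_input_grad(g, self.w, self.dilation, self.input.shape[1])


class ReLU:
    kind = "relu"

    def forward(self, x, training=False, rng=None):
        self.mask = x > 0
        return x * self.mask

    def backward(self, g):
        return g * self.mask


class SpatialDropout:
    """Drops whole channels; identity at inference."""

    kind = "dropout"

    def __init__(self, rate: float):
        self.rate = float(rate)
        self.mask: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0:
            self.mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        keep = (rng.random((x.shape[0], 1, x.shape[2])) >= self.rate) / (1.0 - self.rate)
        self.mask = keep
        return x * keep

    def backward(self, g):
        return g if self.mask is None else g * self.mask


class ChannelNorm:
    """Parameter-free per-channel RMS normalization.

    During training each batch is divided by its per-channel RMS (computed over
    batch and time) and a running RMS is tracked; at inference the running RMS
    is a recorded constant scaling, so the layer is an exact bias-free diagonal
    linear map.  The scale is treated as detached in the backward pass.
    """

    kind = "norm"

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-6):
        self.running = np.ones(channels)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.scale: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        if training:
            s = np.sqrt(np.mean(x**2, axis=(0, 1))) + self.eps
            self.running = (1.0 - self.momentum) * self.running + self.momentum * s
            self._train_input = x
        else:
            s = self.running
            self._train_input = None
        self.scale = s
        return x / s

    def backward(self, g):
        if self._train_input is None:
            return g / self.scale
        # training mode: differentiate through the batch RMS statistic
        x, s = self._train_input, self.scale
        n = x.shape[0] * x.shape[1]
        inner = np.sum(g * x, axis=(0, 1))  # per channel
        return g / s - x * (inner / (n * s**3))


class GlobalAvgPool:
    kind = "pool"

    def forward(self, x, training=False, rng=None):
        self.T = x.shape[1]
        self.input = x
        return x.mean(axis=1)

    def backward(self, g):
        return np.repeat(g[:, None, :], self.T, axis=1) / self.T


class Dense:
    kind = "dense"

    def __init__(self, w: np.ndarray):
        self.w = w
        self.gw = np.zeros_like(w)
        self.input: np.ndarray | None = None

    def forward(self, x, training=False, rng=None):
        self.input = x
        return x @ self.w

    def backward(self, g):
        self.gw = self.input.T @ g
        return g @ self.w.T


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class TCN:
    """The full prediction network: temporal blocks -> GAP -> dense -> softmax."""

    def __init__(self, config: TCNConfig, conv_stack: list, dense: Dense):
        self.config = config
        self.conv_stack = conv_stack
        self.gap = GlobalAvgPool()
        self.dense = dense

    # -- forward -----------------------------------------------------------
    def features(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Per-time-step features (B, T, filters) from the temporal block stack."""
        h = x
        for layer in self.conv_stack:
            h = layer.forward(h, training=training, rng=rng)
        return h

    def logits(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Pre-softmax class scores (B, n_classes)."""
        h = self.features(x, training=training, rng=rng)
        pooled = self.gap.forward(h, training=training)
        return self.dense.forward(pooled, training=training)

    def logits_last_step(self, x: np.ndarray) -> np.ndarray:
        """Class scores read off the final time step only (no pooling); used by
        the receptive-field perturbation probe."""
        h = self.features(x, training=False)
        return h[:, -1, :] @ self.dense.w

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(np.asarray(x, dtype=float)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Probability of the positive class (class index 1)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.window_hours or x.shape[2] != self.config.n_features:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match the model's configured "
                f"({self.config.window_hours}, {self.config.n_features}) window"
            )
        return self.predict_proba(x)[:, 1]

    # -- gradients ---------------------------------------------------------
    def backward_from_logits(self, g: np.ndarray) -> np.ndarray:
        """Backpropagate a logit-space gradient to the input of the stack."""
        g = self.dense.backward(g)
        g = self.gap.backward(g)
        for layer in reversed(self.conv_stack):
            g = layer.backward(g)
        return g

    def gradient(self, x: np.ndarray, class_c: int = 1) -> np.ndarray:
        """d logit_c / d input for a single (T, F) input, at inference."""
        x = np.asarray(x, dtype=float)[None]
        self.logits(x, training=False)
        seed = np.zeros((1, self.config.n_classes))
        seed[0, class_c] = 1.0
        return self.backward_from_logits(seed)[0]

    # -- parameter plumbing -------------------------------------------------
    def trainable_layers(self) -> list:
        return [l for l in self.conv_stack if isinstance(l, CausalConv1d)] + [self.dense]

    def get_weights(self) -> list[np.ndarray]:
        ws = [l.w.copy() for l in self.trainable_layers()]
        ws += [l.running.copy() for l in self.conv_stack if isinstance(l, ChannelNorm)]
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        trainable = self.trainable_layers()
        norms = [l for l in self.conv_stack if isinstance(l, ChannelNorm)]
        for layer, w in zip(trainable, ws[: len(trainable)]):
            layer.w = w.copy()
        for layer, r in zip(norms, ws[len(trainable) :]):
            layer.running = r.copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def build_network(config: TCNConfig | None = None, seed: int = 0) -> TCN:
    """Assemble the network with He-normal initialized, bias-free weights."""
    config = TCNConfig() if config is None else config
    rng = np.random.default_rng(seed)
    k, f = config.kernel_size, config.filters

    def he_conv(c_in: int, c_out: int) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(2.0 / (k * c_in)), size=(k, c_in, c_out))

    layers: list = []
    c_in = config.n_features
    for block in range(1, config.n_blocks + 1):
        for dilation in (2 ** (block - 1), 1):
            layers.append(CausalConv1d(he_conv(c_in, f), dilation))
            layers.append(ReLU())
            layers.append(SpatialDropout(config.dropout_rate))
            layers.append(ChannelNorm(f))
            c_in = f
    dense = Dense(rng.normal(0.0, np.sqrt(2.0 / f), size=(f, config.n_classes)))
    return TCN(config, layers, dense)


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PredictionSample:
    admission_id: str
    patient_id: str
    horizon_hours: int
    prediction_time: pd.Timestamp
    label: int
    matrix: HourlyMatrix


def make_samples(
    timelines: Sequence[AdmissionTimeline],
    labels: pd.DataFrame,
    illness: str,
    horizon: int,
    parameters: Sequence[str] | None = None,
    seed: int = 0,
    window_hours: int = 24,
) -> list[PredictionSample]:
    """Build one observation-window sample per admission at the given horizon.

    Positives are anchored ``horizon`` hours before onset (skipped when that
    leaves less than a full window of history); negatives are anchored at a
    seeded uniform-random time in ``[admit + window, discharge]``.
    """
    if horizon not in STANDARD_HORIZONS:
        warnings.warn(f"horizon {horizon} h is outside the standard set {STANDARD_HORIZONS}")
    parameters = parameter_names() if parameters is None else list(parameters)
    lab = labels[labels["illness"] == illness].set_index("admission_id")
    samples = []
    for tl in timelines:
        if tl.admission_id not in lab.index:
            continue
        row = lab.loc[tl.admission_id]
        positive = bool(row["positive"])
        earliest = tl.admit_time + window_hours * HOUR
        if positive:
            pred = pd.Timestamp(row["onset_time"]) - horizon * HOUR
            if pred < earliest:
                continue
        else:
            span_h = (tl.discharge_time - earliest) / HOUR
            if span_h < 0:
                continue
            u = np.random.default_rng(
                [seed, zlib.crc32(tl.admission_id.encode()) & 0x7FFFFFFF]
            ).uniform()
            pred = earliest + round(u * span_h * 60.0) / 60.0 * HOUR
        samples.append(
            PredictionSample(
                admission_id=tl.admission_id,
                patient_id=tl.patient_id,
                horizon_hours=horizon,
                prediction_time=pred,
                label=int(positive),
                matrix=bin_hourly(tl, pred, window_hours, parameters),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8,
                 weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


def _ranking_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC (ties count one half) for the early-stopping monitor."""
    from scipy.stats import rankdata

    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(y)), y].mean())


def train(
    network: TCN,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: TrainConfig | None = None,
) -> dict:
    """Train with cross-entropy + Adam; early-stop on validation loss.

    Returns a history dict with per-epoch train/validation losses.  The
    network is left holding the best-validation weights.  Deterministic for a
    fixed seed and data.
    """
    config = TrainConfig() if config is None else config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "val_loss": []}
    if config.max_epochs == 0:
        return history

    monitor_val = X_val is not None and y_val is not None and len(np.unique(y_val)) == 2
    trainables = network.trainable_layers()
    opt = Adam([l.w for l in trainables], config.learning_rate,
               weight_decay=config.weight_decay)
    best_loss, best_weights, since_best = np.inf, network.get_weights(), 0
    use_ema = config.ema_decay > 0
    ema = [l.w.copy() for l in trainables] if use_ema else None

    base_idx = np.arange(len(y))
    if config.oversample_positives:
        pos = base_idx[y == 1]
        neg = base_idx[y == 0]
        if len(pos) and len(neg) > len(pos):
            extra = rng.choice(pos, size=len(neg) - len(pos), replace=True)
            base_idx = np.concatenate([base_idx, extra])

    for epoch in range(config.max_epochs):
        order = rng.permutation(base_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = X[batch], y[batch]
            if config.input_channel_dropout > 0:
                keep = rng.random((len(xb), 1, xb.shape[2])) >= config.input_channel_dropout
                xb = xb * keep / (1.0 - config.input_channel_dropout)
            if config.input_noise > 0:
                xb = xb + config.input_noise * rng.standard_normal(xb.shape)
            logits = network.logits(xb, training=True, rng=rng)
            epoch_loss += cross_entropy(logits, yb)
            n_batches += 1
            p = softmax(logits)
            p[np.arange(len(yb)), yb] -= 1.0
            network.backward_from_logits(p / len(yb))
            opt.step([l.w for l in trainables], [l.gw for l in trainables])
            if use_ema:
                for e, layer in zip(ema, trainables):
                    e *= config.ema_decay
                    e += (1.0 - config.ema_decay) * layer.w
        train_loss = epoch_loss / max(n_batches, 1)
        history["train_loss"].append(train_loss)
        if use_ema:  # monitor and snapshot the averaged network
            live = [layer.w for layer in trainables]
            for layer, e in zip(trainables, ema):
                layer.w = e
        if monitor_val:
            val_logits = network.logits(X_val)
            val_loss = cross_entropy(val_logits, np.asarray(y_val, dtype=int))
            if config.monitor == "auroc":
                # negated so that "lower is better" holds for both monitors
                monitored = -_ranking_auroc(val_logits[:, 1] - val_logits[:, 0], y_val)
            else:
                monitored = val_loss
        else:
            val_loss = train_loss
            monitored = train_loss
        history["val_loss"].append(val_loss)
        if monitored < best_loss - 1e-6:
            best_loss, best_weights, since_best = monitored, network.get_weights(), 0
            stop = False
        else:
            since_best += 1
            if config.lr_decay < 1.0 and since_best and since_best % max(config.patience // 2, 1) == 0:
                opt.lr *= config.lr_decay
            stop = since_best >= config.patience and epoch + 1 >= config.min_epochs
        if use_ema:  # restore the live weights for further training
            for layer, w in zip(trainables, live):
                layer.w = w
        if stop:
            break
    network.set_weights(best_weights)
    return history


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(network: TCN, preprocessor, path) -> None:
    """Write weights (npz) plus a JSON sidecar with config and preprocessing state."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = network.get_weights()
    np.savez(path / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
    sidecar = {
        "config": network.config.to_dict(),
        "preprocessor": json.loads(preprocessor.to_json()) if preprocessor else None,
    }
    (path / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> tuple[TCN, "object"]:
    from .ehr import Preprocessor

    path = pathlib.Path(path)
    sidecar = json.loads((path / "model.json").read_text())
    config = TCNConfig(**sidecar["config"])
    network = build_network(config, seed=0)
    with np.load(path / "weights.npz") as data:
        weights = [data[f"w{i}"] for i in range(len(data.files))]
    network.set_weights(weights)
    preproc = None
    if sidecar["preprocessor"] is not None:
        preproc = Preprocessor.from_json(json.dumps(sidecar["preprocessor"]))
    return network, preproc
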