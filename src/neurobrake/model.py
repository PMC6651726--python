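"""Three-layer perceptron classifier: sigmoid hidden layer, 2-unit
softmax output, trained on mean cross-entropy.

Training is full-batch gradient descent with a "bold driver" adaptive
step — grow the rate by 5% after an improving step, halve and retry
after a worsening one — which keeps runs deterministic for a fixed
seed.  Early stopping monitors validation cross-entropy with a
configurable patience and restores the best-validation weights.

Class index convention everywhere: 0 = normal driving, 1 = braking
intention.  Ties in the output probabilities break toward the lower
index (normal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import DatasetTable


@dataclass
class NetworkConfig:
    n_input: int
    n_hidden: int = 50
    n_output: int = 2
    max_iterations: int = 200
    patience: int = 10
    learning_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_input <= 0 or self.n_hidden <= 0:
            raise ValueError("layer sizes must be positive")
        if self.n_output != 2:
            raise ValueError("this classifier is two-class (n_output = 2)")


@dataclass
class Standardizer:
    """Per-feature z-scoring with constants fit on training data only."""

    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=np.float64)
        self.mean = x.mean(axis=0)
        sd = x.std(axis=0)
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.scale


@dataclass
class Network:
    """MLP parameters plus training history."""

    config: NetworkConfig
    w_hidden: np.ndarray  # (n_hidden, n_input)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray  # (2, n_hidden)
    b_out: np.ndarray  # (2,)
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})


def init_network(config: NetworkConfig) -> Network:
    """Seeded symmetric-uniform initialization scaled by fan-in."""
    rng = np.random.default_rng(config.seed)
    s1 = 1.0 / np.sqrt(config.n_input)
    s2 = 1.0 / np.sqrt(config.n_hidden)
    return Network(
        config=config,
        w_hidden=rng.uniform(-s1, s1, size=(config.n_hidden, config.n_input)),
        b_hidden=np.zeros(config.n_hidden),
        w_out=rng.uniform(-s2, s2, size=(config.n_output, config.n_hidden)),
        b_out=np.zeros(config.n_output),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    z = np.asarray(z, dtype=np.float64)
    zs = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(zs)
    return ez / ez.sum(axis=-1, keepdims=True)


def forward(net: Network, x: np.ndarray) -> np.ndarray:
    """Class probabilities for one sample (D,) or a batch (n, D)."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    xb = x[None, :] if single else x
    if xb.shape[1] != net.config.n_input:
        raise ValueError(
            f"expected {net.config.n_input} features, got {xb.shape[1]}"
        )
    hidden = _sigmoid(xb @ net.w_hidden.T + net.b_hidden)
    probs = softmax(hidden @ net.w_out.T + net.b_out)
    return probs[0] if single else probs


def _loss_and_grads(net, x, onehot):
    n = x.shape[0]
    hidden = _sigmoid(x @ net.w_hidden.T + net.b_hidden)
    probs = softmax(hidden @ net.w_out.T + net.b_out)
    loss = -np.mean(np.sum(onehot * np.log(np.clip(probs, 1e-300, None)), axis=1))
    delta_out = (probs - onehot) / n  # (n, 2)
    g_w_out = delta_out.T @ hidden
    g_b_out = delta_out.sum(axis=0)
    delta_hid = (delta_out @ net.w_out) * hidden * (1.0 - hidden)
    g_w_hidden = delta_hid.T @ x
    g_b_hidden = delta_hid.sum(axis=0)
    return loss, (g_w_hidden, g_b_hidden, g_w_out, g_b_out)


def cross_entropy(net: Network, x: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy of the network on (x, y)."""
    probs = forward(net, x)
    p = np.clip(probs[np.arange(len(y)), y], 1e-300, None)
    return float(-np.mean(np.log(p)))


def train(
    net: Network,
    train_table: DatasetTable | tuple[np.ndarray, np.ndarray],
    val_table: DatasetTable | tuple[np.ndarray, np.ndarray] | None = None,
) -> Network:
    """Train in place by full-batch adaptive gradient descent.

    Features are assumed standardized.  Records per-iteration train
    (and validation) cross-entropy in ``net.history``; the recorded
    train losses are those of *accepted* steps and are non-increasing.
    With validation data, stops after ``patience`` iterations without
    improvement and restores the best-validation weights.

    Raises
    ------
    ValueError
        If the training set does not contain both classes.
    """
    def unpack(t):
        if isinstance(t, DatasetTable):
            return t.features, t.labels
        return np.asarray(t[0], dtype=np.float64), np.asarray(t[1])

    x, y = unpack(train_table)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    onehot = np.zeros((len(y), net.config.n_output))
    onehot[np.arange(len(y)), y] = 1.0
    val = None
    if val_table is not None:
        val = unpack(val_table)

    lr = net.config.learning_rate
    params = [net.w_hidden, net.b_hidden, net.w_out, net.b_out]
    loss, grads = _loss_and_grads(net, x, onehot)
    best_val = np.inf
    best_params = None
    stall = 0
    for _ in range(net.config.max_iterations):
        # bold-driver: try a step, halve and retry while it worsens
        accepted = False
        for _attempt in range(30):
            trial = [p - lr * g for p, g in zip(params, grads)]
            net.w_hidden, net.b_hidden, net.w_out, net.b_out = trial
            new_loss, new_grads = _loss_and_grads(net, x, onehot)
            if new_loss <= loss:
                params, loss, grads = trial, new_loss, new_grads
                lr *= 1.05
                accepted = True
                break
            net.w_hidden, net.b_hidden, net.w_out, net.b_out = params
            lr *= 0.5
        if not accepted:
            break
        net.history["train_loss"].append(loss)
        if val is not None:
            vloss = cross_entropy(net, *val)
            net.history["val_loss"].append(vloss)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best_params = [p.copy() for p in params]
                stall = 0
            else:
                stall += 1
                if stall > net.config.patience:
                    break
    if best_params is not None:
        net.w_hidden, net.b_hidden, net.w_out, net.b_out = best_params
    return net


def predict(
    net: Network, table: DatasetTable | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, braking-class probabilities) for a dataset or matrix.

    Labels are the argmax of the softmax output; an exact 0.5/0.5 tie
    resolves to class 0 (normal).
    """
    x = table.features if isinstance(table, DatasetTable) else np.asarray(table)
    probs = forward(net, x)
    return probs.argmax(axis=1), probs[:, 1]


def save_checkpoint(
    path,
    net: Network,
    standardizer: Standardizer,
    feature_meta: dict,
) -> None:
    """Persist weights + standardization constants + feature layout."""
    np.savez(
        path,
        w_hidden=net.w_hidden,
        b_hidden=net.b_hidden,
        w_out=net.w_out,
        b_out=net.b_out,
        std_mean=standardizer.mean,
        std_scale=standardizer.scale,
        config=json.dumps(
            {
                "n_input": net.config.n_input,
                "n_hidden": net.config.n_hidden,
                "n_output": net.config.n_output,
                "seed": net.config.seed,
            }
        ),
        feature_meta=json.dumps(feature_meta),
    )


def load_checkpoint(path) -> tuple[Network, Standardizer, dict]:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        net = Network(
            config=NetworkConfig(
                n_input=cfg["n_input"],
                n_hidden=cfg["n_hidden"],
                seed=cfg.get("seed", 0),
            ),
            w_hidden=data["w_hidden"],
            b_hidden=data["b_hidden"],
            w_out=data["w_out"],
            b_out=data["b_out"],
        )
        std = Standardizer(mean=data["std_mean"], scale=data["std_scale"])
        meta = json.loads(str(data["feature_meta"]))
    return net, std, meta
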