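"""Feedforward-network Hurst estimator (M3) on the first 32 sample-ACVF lags.

The network approximates the conditional expectation E[H | γ̂(0..31)]: a
dense stack 32 → 64 → 64 → 32 → 1 with Swish-1 activations on the hidden
layers and a sigmoid on the output unit, so predictions land in (0, 1) — the
admissible Hurst range — by construction. The sigmoid sits inside the
trained graph, so the mean-squared-error loss is computed on the (0, 1)
scale that the targets live on. Training uses Adam (step 1e-3, moment
decays 0.9/0.999, epsilon 1e-8), mini-batches of 64, and early stopping on
validation MSE with the best-epoch weights restored. Inputs are raw ACVF
values with no standardization; the lag-0 entry then encodes the variance
scale, and the trained model assumes D = 1 scaled inputs.

The implementation is self-contained NumPy: the network is small (8385
parameters in the default configuration) and the forward/backward pass and
Adam updates are a page of array code, which keeps training exactly
reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .acvf import ACVFVector
from .estimators import HurstEstimate

__all__ = [
    "swish",
    "sigmoid",
    "FNNArchitecture",
    "TrainingConfig",
    "FNNModel",
    "build_model",
    "train",
    "estimate_m3",
]


def sigmoid(x):
    """Logistic function σ(x) = 1/(1 + e^{−x}), numerically stable."""
    return expit(x)


def swish(x, beta: float = 1.0):
    """Swish-β activation x·σ(βx); β = 1 is the hidden-layer activation."""
    return x * expit(beta * x)


def _swish_grad(x):
    """d/dx [x σ(x)] = σ(x)(1 + x(1 − σ(x)))."""
    s = expit(x)
    return s * (1.0 + x * (1.0 - s))


@dataclass(frozen=True)
class FNNArchitecture:
    input_size: int = 32
    hidden_sizes: tuple[int, ...] = (64, 64, 32)

    def __post_init__(self) -> None:
        if self.input_size < 1 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("layer sizes must be positive")
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_size, *self.hidden_sizes, 1)

    def parameter_count(self) -> int:
        sizes = self.layer_sizes
        return sum(fi * fo + fo for fi, fo in zip(sizes[:-1], sizes[1:]))


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    max_epochs: int = 50
    early_stop_patience: int = 3
    early_stop_min_delta: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


class FNNModel:
    """A dense feedforward regressor with Swish-1 hidden and sigmoid output."""

    def __init__(
        self,
        architecture: FNNArchitecture,
        weights: list[np.ndarray],
        biases: list[np.ndarray],
        training_meta: dict | None = None,
    ) -> None:
        sizes = architecture.layer_sizes
        if len(weights) != len(sizes) - 1 or len(biases) != len(sizes) - 1:
            raise ValueError("one weight matrix and bias vector per layer required")
        for i, (w, b) in enumerate(zip(weights, biases)):
            if w.shape != (sizes[i], sizes[i + 1]) or b.shape != (sizes[i + 1],):
                raise ValueError(
                    f"layer {i}: expected weights {(sizes[i], sizes[i+1])} and "
                    f"biases {(sizes[i+1],)}, got {w.shape} and {b.shape}"
                )
        self.architecture = architecture
        self.weights = weights
        self.biases = biases
        self.training_meta = training_meta or {}

    def parameter_count(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Forward pass keeping pre-activations for backprop."""
        zs, activations = [], [x]
        a = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            zs.append(z)
            a = expit(z) if i == n_layers - 1 else swish(z)
            activations.append(a)
        return zs, activations

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predict Ĥ ∈ (0, 1) for a batch of ACVF inputs, shape (m, input_size)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.architecture.input_size:
            raise ValueError(
                f"expected input of shape (m, {self.architecture.input_size}); got {x.shape}"
            )
        _, activations = self._forward(x)
        return activations[-1][:, 0]

    def copy_weights(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    # -- serialization: self-describing JSON archive (text, lossless floats) --

    def save(self, path) -> None:
        payload = {
            "format_version": 1,
            "architecture": {
                "input_size": self.architecture.input_size,
                "hidden_sizes": list(self.architecture.hidden_sizes),
                "hidden_activation": "swish-1",
                "output_activation": "sigmoid",
            },
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FNNModel":
        with open(path) as fh:
            payload = json.load(fh)
        arch = FNNArchitecture(
            input_size=payload["architecture"]["input_size"],
            hidden_sizes=tuple(payload["architecture"]["hidden_sizes"]),
        )
        weights = [np.asarray(w, dtype=float) for w in payload["weights"]]
        biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
        return cls(arch, weights, biases, payload.get("training_meta", {}))


def build_model(arch: FNNArchitecture | None = None, seed: int = 0) -> FNNModel:
    """Seeded Glorot-uniform initialization of the dense stack; zero biases."""
    arch = arch or FNNArchitecture()
    rng = np.random.default_rng(seed)
    sizes = arch.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return FNNModel(arch, weights, biases, {"init_seed": seed, "trained": False})


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    d = pred - target
    return float(d @ d / d.size)


def train(
    model: FNNModel,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig | None = None,
) -> FNNModel:
    """Train with Adam + MSE and validation-based early stopping.

    ``train_set`` / ``val_set`` are (inputs, targets) pairs with inputs of
    shape (m, input_size) and targets H ∈ (0, 1). Training stops when the
    validation MSE has not improved by ``early_stop_min_delta`` for
    ``early_stop_patience`` consecutive epochs (or at ``max_epochs``) and
    returns a new model carrying the best-validation-epoch weights. Fully
    reproducible from ``config.seed`` on one platform.
    """
    config = config or TrainingConfig()
    x_train, y_train = (np.asarray(a, dtype=float) for a in train_set)
    x_val, y_val = (np.asarray(a, dtype=float) for a in val_set)
    for name, (x, y) in (("train", (x_train, y_train)), ("validation", (x_val, y_val))):
        if x.size == 0 or y.size == 0:
            raise ValueError(f"{name} set is empty")
        if x.ndim != 2 or x.shape[1] != model.architecture.input_size:
            raise ValueError(f"{name} inputs must have shape (m, {model.architecture.input_size})")
        if x.shape[0] != y.shape[0]:
            raise ValueError(f"{name} inputs and targets disagree in length")
        if np.any((y <= 0.0) | (y >= 1.0)):
            raise ValueError(f"{name} targets must lie strictly in (0, 1)")

    work = FNNModel(model.architecture, *model.copy_weights(), dict(model.training_meta))
    rng = np.random.default_rng(config.seed)
    n = x_train.shape[0]
    n_layers = len(work.weights)

    # Adam state, one slot per parameter array (weights then biases per layer)
    m_state = [np.zeros_like(w) for w in work.weights] + [np.zeros_like(b) for b in work.biases]
    v_state = [np.zeros_like(a) for a in m_state]
    step = 0

    best_val = np.inf
    best_weights = work.copy_weights()
    best_epoch = 0
    stall = 0
    history: list[dict] = []

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start: start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            m_batch = xb.shape[0]

            zs, activations = work._forward(xb)
            pred = activations[-1][:, 0]
            batch_loss = _mse(pred, yb)
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
            epoch_loss += batch_loss * m_batch

            # output layer: dMSE/dz = 2(ŷ−y)/m · σ'(z) with σ' = ŷ(1−ŷ)
            delta = (2.0 / m_batch) * (pred - yb) * pred * (1.0 - pred)
            delta = delta[:, None]
            grads_w = [None] * n_layers
            grads_b = [None] * n_layers
            for layer in range(n_layers - 1, -1, -1):
                grads_w[layer] = activations[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ work.weights[layer].T) * _swish_grad(zs[layer - 1])

            step += 1
            params = work.weights + work.biases
            grads = grads_w + grads_b
            bc1 = 1.0 - config.beta1 ** step
            bc2 = 1.0 - config.beta2 ** step
            for p, g, m_s, v_s in zip(params, grads, m_state, v_state):
                m_s *= config.beta1
                m_s += (1.0 - config.beta1) * g
                v_s *= config.beta2
                v_s += (1.0 - config.beta2) * g * g
                p -= config.learning_rate * (m_s / bc1) / (np.sqrt(v_s / bc2) + config.adam_eps)

        train_mse = epoch_loss / n
        val_mse = _mse(work.predict(x_val), y_val)
        history.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse})

        if best_val - val_mse > config.early_stop_min_delta:
            best_val = val_mse
            best_weights = work.copy_weights()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stop_patience:
                break

    weights, biases = best_weights
    meta = {
        "init_seed": model.training_meta.get("init_seed"),
        "trained": True,
        "seed": config.seed,
        "epochs_run": history[-1]["epoch"],
        "best_epoch": best_epoch,
        "best_val_mse": best_val,
        "final_train_mse": history[-1]["train_mse"],
        "history": history,
    }
    return FNNModel(model.architecture, weights, biases, meta)


def estimate_m3(acvf: ACVFVector | np.ndarray, model: FNNModel) -> HurstEstimate:
    """Network estimate from a single ACVF vector of exactly ``input_size`` lags.

    Always valid: the sigmoid output lies in (0, 1) for any input. Use
    `acvf.restrict_lags` first to zero-pad or zero out lags as needed.
    """
    values = acvf.values if isinstance(acvf, ACVFVector) else np.asarray(acvf, dtype=float)
    if values.shape != (model.architecture.input_size,):
        raise ValueError(
            f"M3 requires exactly {model.architecture.input_size} ACVF lags; "
            f"got shape {values.shape}"
        )
    h = float(model.predict(values[None, :])[0])
    return HurstEstimate(hurst_hat=h, method="M3", valid=True)
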