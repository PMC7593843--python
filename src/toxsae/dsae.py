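"""Deep sparse autoencoder on additive SNP dosages, implemented in numpy.

The network mirrors a small symmetric ("specular") architecture:
J -> 40 -> 30 -> 20 -> 30 -> 40 -> J, with hyperbolic-tangent hidden layers,
a sigmoidal 20-node code (so an L1 activity penalty on the code is bounded
and nonnegative) and a linear output.  The loss is the mean per-sample
squared Euclidean reconstruction error plus lambda times the mean L1 norm
of the code activations, minimised with Adam (default learning rate 0.001)
for a fixed number of epochs.

Inputs follow a fixed scaling convention: dosages in [0, 2] are divided by
2, never standardised against the data, so train and test columns are on
the same scale by construction.

The parameter count is tiny (7,243 weights for J = 43), so training is a
few hundred full-batch gradient steps; everything is seeded and runs
deterministically on a single thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkSpec",
    "TrainedModel",
    "scale_dosages",
    "build_network",
    "train_dsae",
    "forward",
    "reconstruction_error_matrix",
    "save_model",
    "load_model",
]

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training hyperparameters of the autoencoder."""

    input_width: int
    encoder_widths: tuple[int, ...] = (40, 30, 20)
    decoder_widths: tuple[int, ...] = (30, 40)
    encoder_activations: tuple[str, ...] = ("tanh", "tanh", "sigmoid")
    decoder_activations: tuple[str, ...] = ("tanh", "tanh", "linear")
    sparsity_weight: float = 1e-4
    epochs: int = 400
    learning_rate: float = 0.001
    batch_size: int | None = None  # None = full batch

    def __post_init__(self) -> None:
        if self.input_width < 1:
            raise ValueError("input_width must be >= 1")
        if any(w < 1 for w in self.encoder_widths + self.decoder_widths):
            raise ValueError("layer widths must be positive")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be >= 0")
        if self.decoder_widths != tuple(reversed(self.encoder_widths[:-1])):
            raise ValueError("decoder widths must mirror the encoder")
        acts = self.encoder_activations + self.decoder_activations
        if len(self.encoder_activations) != len(self.encoder_widths):
            raise ValueError("one encoder activation per encoder layer")
        if len(self.decoder_activations) != len(self.decoder_widths) + 1:
            raise ValueError("decoder activations must include the output layer")
        for a in acts:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")

    @property
    def layer_widths(self) -> tuple[int, ...]:
        return (
            (self.input_width,)
            + self.encoder_widths
            + self.decoder_widths
            + (self.input_width,)
        )

    @property
    def activations(self) -> tuple[str, ...]:
        return self.encoder_activations + self.decoder_activations

    @property
    def code_layer(self) -> int:
        """Index (1-based over layers) of the innermost code layer."""
        return len(self.encoder_widths)

    @property
    def n_parameters(self) -> int:
        ws = self.layer_widths
        return sum(ws[i] * ws[i + 1] + ws[i + 1] for i in range(len(ws) - 1))


@dataclass
class TrainedModel:
    """Per-layer parameters plus the spec and the training loss trace."""

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        ws = self.spec.layer_widths
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape != (ws[i], ws[i + 1]) or b.shape != (ws[i + 1],):
                raise ValueError(f"layer {i}: parameter shape mismatch")


def scale_dosages(X: np.ndarray) -> np.ndarray:
    """Map additive dosages [0, 2] to the network's [0, 1] input scale."""
    return np.asarray(X, dtype=float) / 2.0


def build_network(spec: NetworkSpec, seed: int = 0) -> TrainedModel:
    """Glorot-uniform initial weights, zero biases; reproducible per seed."""
    rng = np.random.default_rng(seed)
    ws = spec.layer_widths
    weights, biases = [], []
    for fan_in, fan_out in zip(ws[:-1], ws[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return TrainedModel(spec=spec, weights=weights, biases=biases)


def forward(model: TrainedModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer; last element is the reconstruction."""
    acts = [np.asarray(X, dtype=float)]
    for W, b, name in zip(model.weights, model.biases, model.spec.activations):
        f, _ = _ACTIVATIONS[name]
        acts.append(f(acts[-1] @ W + b))
    return acts


def _loss_and_grads(
    model: TrainedModel, X: np.ndarray
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    spec = model.spec
    acts = forward(model, X)
    n = X.shape[0]
    code = acts[spec.code_layer]
    resid = acts[-1] - X
    loss = float((resid**2).sum() / n + spec.sparsity_weight * np.abs(code).sum() / n)

    grad_w = [np.empty_like(W) for W in model.weights]
    grad_b = [np.empty_like(b) for b in model.biases]
    # gradient w.r.t. the output activation (linear output layer)
    g = 2.0 * resid / n
    for layer in range(len(model.weights) - 1, -1, -1):
        name = spec.activations[layer]
        _, dgrad = _ACTIVATIONS[name]
        delta = g * dgrad(acts[layer + 1])
        grad_w[layer] = acts[layer].T @ delta
        grad_b[layer] = delta.sum(axis=0)
        if layer > 0:
            g = delta @ model.weights[layer].T
            if layer == spec.code_layer:
                # L1 activity penalty acts on the code activations
                g = g + spec.sparsity_weight * np.sign(acts[layer]) / n
    return loss, grad_w, grad_b


def train_dsae(
    model: TrainedModel,
    X_train: np.ndarray,
    seed: int = 0,
    record_trace: bool = True,
) -> TrainedModel:
    """Train in place with Adam; returns the model with its loss trace.

    ``X_train`` rows must already be on the input scale (see
    :func:`scale_dosages`).  Raises on non-finite loss.
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X_train must be a non-empty 2-D array")
    if X.shape[1] != model.spec.input_width:
        raise ValueError("X_train width does not match the network input")
    spec = model.spec
    rng = np.random.default_rng(seed)
    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    trace: list[float] = []
    bs = spec.batch_size or X.shape[0]
    for _ in range(spec.epochs):
        if spec.batch_size is None:
            batches = [X]
        else:
            order = rng.permutation(X.shape[0])
            batches = [X[order[s : s + bs]] for s in range(0, X.shape[0], bs)]
        epoch_loss = 0.0
        for batch in batches:
            loss, grad_w, grad_b = _loss_and_grads(model, batch)
            if not np.isfinite(loss):
                raise RuntimeError("training diverged: non-finite loss")
            epoch_loss += loss * batch.shape[0]
            t += 1
            grads = grad_w + grad_b
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g**2
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                p -= spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
        if record_trace:
            trace.append(epoch_loss / X.shape[0])
    model.loss_trace = trace
    return model


def reconstruction_error_matrix(model: TrainedModel, X_test: np.ndarray) -> np.ndarray:
    """Per-sample, per-feature squared residual (x - x_hat)^2."""
    X = np.asarray(X_test, dtype=float)
    if X.shape[1] != model.spec.input_width:
        raise ValueError("X_test width does not match the network input")
    xhat = forward(model, X)[-1]
    return (X - xhat) ** 2


# --- portable serialisation ---------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """JSON container: spec fields plus per-layer shape-annotated arrays."""
    payload = {
        "spec": {
            "input_width": model.spec.input_width,
            "encoder_widths": list(model.spec.encoder_widths),
            "decoder_widths": list(model.spec.decoder_widths),
            "encoder_activations": list(model.spec.encoder_activations),
            "decoder_activations": list(model.spec.decoder_activations),
            "sparsity_weight": model.spec.sparsity_weight,
            "epochs": model.spec.epochs,
            "learning_rate": model.spec.learning_rate,
            "batch_size": model.spec.batch_size,
        },
        "layers": [
            {"shape": list(W.shape), "weights": W.tolist(), "bias": b.tolist()}
            for W, b in zip(model.weights, model.biases)
        ],
        "loss_trace": model.loss_trace,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    s = payload["spec"]
    spec = NetworkSpec(
        input_width=s["input_width"],
        encoder_widths=tuple(s["encoder_widths"]),
        decoder_widths=tuple(s["decoder_widths"]),
        encoder_activations=tuple(s["encoder_activations"]),
        decoder_activations=tuple(s["decoder_activations"]),
        sparsity_weight=s["sparsity_weight"],
        epochs=s["epochs"],
        learning_rate=s["learning_rate"],
        batch_size=s["batch_size"],
    )
    weights = [np.array(l["weights"]) for l in payload["layers"]]
    biases = [np.array(l["bias"]) for l in payload["layers"]]
    model = TrainedModel(spec=spec, weights=weights, biases=biases)
    model.loss_trace = list(payload.get("loss_trace", []))
    return model
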