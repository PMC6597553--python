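"""Fully-connected multilayer perceptron searched by the Trader optimizer.

The default architecture is 8-3-2-1: eight pair-descriptor inputs, two
hidden layers of three and two neurons, one output neuron whose logistic
activation is read as an interaction probability.  All synapse weights and
biases live in one flat vector (8*3 + 3*2 + 2*1 = 32 synapses plus 6 biases
= 38 variables), which is the optimizer's search space.  The training
objective is the root-mean-square error between network outputs and the
0/1 interaction labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .trader import ObjectiveFunction

__all__ = [
    "MLPSpec",
    "parameter_count",
    "decode",
    "encode",
    "forward",
    "forward_batch",
    "rmse_objective",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class MLPSpec:
    """Architecture: layer sizes, activation, and the classification
    threshold applied to the output score (boundary maps to positive)."""

    layer_sizes: tuple = (8, 3, 2, 1)
    activation: str = "logistic"  # or "tanh"
    threshold: float = 0.5

    def __post_init__(self):
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least an input and an output layer")
        if any(int(s) < 1 for s in self.layer_sizes):
            raise ValueError(f"layer sizes must be >= 1, got {self.layer_sizes}")
        if self.activation not in ("logistic", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))

    @property
    def synapse_count(self) -> int:
        s = self.layer_sizes
        return sum(s[i] * s[i + 1] for i in range(len(s) - 1))

    @property
    def bias_count(self) -> int:
        return sum(self.layer_sizes[1:])

    @property
    def parameter_count(self) -> int:
        return self.synapse_count + self.bias_count


def parameter_count(spec: MLPSpec) -> int:
    """Total number of trainable variables (synapses + biases)."""
    return spec.parameter_count


def decode(spec: MLPSpec, flat: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a flat weight vector into per-layer ``(W, b)`` views.

    Layout, layer by layer: the ``(n_in, n_out)`` weight matrix flattened
    row-major, then that layer's ``n_out`` biases.  The returned arrays are
    views into ``flat`` — ``encode(decode(v)) == v`` bit-exactly.
    """
    flat = np.asarray(flat, dtype=float)
    if flat.shape != (spec.parameter_count,):
        raise ValueError(
            f"weight vector has length {flat.size}, spec needs {spec.parameter_count}"
        )
    layers = []
    pos = 0
    s = spec.layer_sizes
    for n_in, n_out in zip(s[:-1], s[1:]):
        W = flat[pos : pos + n_in * n_out].reshape(n_in, n_out)
        pos += n_in * n_out
        b = flat[pos : pos + n_out]
        pos += n_out
        layers.append((W, b))
    return layers


def encode(spec: MLPSpec, layers) -> np.ndarray:
    """Inverse of :func:`decode`: flatten per-layer ``(W, b)`` pairs."""
    parts = []
    for W, b in layers:
        parts.append(np.asarray(W, dtype=float).ravel())
        parts.append(np.asarray(b, dtype=float).ravel())
    flat = np.concatenate(parts)
    if flat.shape != (spec.parameter_count,):
        raise ValueError("layer shapes do not match the spec")
    return flat


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    return expit(z) if kind == "logistic" else np.tanh(z)


def forward_batch(spec: MLPSpec, weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Feed-forward scores for a ``(S, n_in)`` input matrix; returns ``(S,)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.layer_sizes[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, spec expects {spec.layer_sizes[0]}"
        )
    a = X
    for W, b in decode(spec, weights):
        a = _activate(a @ W + b, spec.activation)
    return a[:, 0]


def forward(spec: MLPSpec, weights: np.ndarray, x: np.ndarray) -> float:
    """Feed-forward value for a single input vector."""
    return float(forward_batch(spec, weights, np.asarray(x, dtype=float)[None, :])[0])


def rmse_objective(
    spec: MLPSpec,
    features: np.ndarray,
    labels: np.ndarray,
    bounds: tuple[float, float] = (-10.0, 10.0),
) -> ObjectiveFunction:
    """Build the training objective ``sqrt(mean((prediction - label)^2))``
    over a fixed dataset, as a function of the flat weight vector."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training dataset")
    if y.shape != (X.shape[0],):
        raise ValueError("labels must be one per feature row")

    def evaluate(w: np.ndarray) -> float:
        p = forward_batch(spec, w, X)
        return float(np.sqrt(np.mean((p - y) ** 2)))

    return ObjectiveFunction(evaluate, spec.parameter_count, bounds)


def predict(spec: MLPSpec, weights: np.ndarray, x: np.ndarray) -> tuple[int, float]:
    """Return ``(label, score)``: label 1 iff the forward score reaches the
    spec's threshold (the boundary counts as positive)."""
    score = forward(spec, weights, x)
    return (1 if score >= spec.threshold else 0, score)


def save_model(path, spec: MLPSpec, weights: np.ndarray, meta: dict | None = None) -> None:
    """Serialize spec + flat weights (+ optional training metadata) as JSON;
    floats are written with full round-trip precision."""
    payload = {
        "layer_sizes": list(spec.layer_sizes),
        "activation": spec.activation,
        "threshold": spec.threshold,
        "weights": [float(w).hex() for w in np.asarray(weights, dtype=float)],
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path) -> tuple[MLPSpec, np.ndarray, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    spec = MLPSpec(
        tuple(payload["layer_sizes"]), payload["activation"], payload["threshold"]
    )
    weights = np.array([float.fromhex(w) for w in payload["weights"]])
    if weights.shape != (spec.parameter_count,):
        raise ValueError("model file weight count does not match its architecture")
    return spec, weights, payload.get("meta", {})
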