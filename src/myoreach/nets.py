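"""Minimal feed-forward networks with hand-written backpropagation.

The policy stack needs only small MLPs, so this module implements them
directly in numpy (float64): tanh hidden layers, linear output, Xavier
initialization, explicit forward caches and backward passes, a flat
parameter view for checkpointing and finite-difference gradient checks,
and an Adam optimizer. Gradient correctness is enforced by tests that
compare every analytic gradient against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "flatten_params", "unflatten_params"]


class MLP:
    """Multi-layer perceptron: tanh hidden activations, linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = list(sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Forward pass; ``cache`` (if a list) collects layer inputs for
        backward and doubles as the hidden-activation record."""
        h = np.asarray(x, dtype=float)
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            if cache is not None:
                cache.append(h)
            h = h @ W + b
            if i < n_layers - 1:
                h = np.tanh(h)
        return h

    def hidden_activations(self, x: np.ndarray) -> list[np.ndarray]:
        """Post-tanh activations of each hidden layer (for geometry analysis)."""
        h = np.asarray(x, dtype=float)
        acts = []
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.tanh(h)
                acts.append(h)
        return acts

    def backward(self, cache: list, grad_out: np.ndarray,
                 grads: dict | None = None) -> np.ndarray:
        """Backpropagate ``grad_out`` through the cached forward pass.

        Accumulates parameter gradients into ``grads`` (keys ``W{i}``,
        ``b{i}``) and returns the gradient with respect to the input.
        """
        if grads is None:
            grads = self.zero_grads()
        g = np.asarray(grad_out, dtype=float)
        n_layers = len(self.W)
        for i in range(n_layers - 1, -1, -1):
            h_in = cache[i]
            if i < n_layers - 1:
                # cache[i+1] is input of the next layer = tanh output here
                post = cache[i + 1] if i + 1 < n_layers else None
                g = g * (1.0 - post**2)
            grads[f"W{i}"] += h_in.T @ g
            grads[f"b{i}"] += g.sum(axis=0)
            g = g @ self.W[i].T
        return g

    # -- parameter bookkeeping ---------------------------------------------

    def zero_grads(self) -> dict:
        return {
            **{f"W{i}": np.zeros_like(W) for i, W in enumerate(self.W)},
            **{f"b{i}": np.zeros_like(b) for i, b in enumerate(self.b)},
        }

    def params(self) -> dict:
        return {
            **{f"W{i}": W for i, W in enumerate(self.W)},
            **{f"b{i}": b for i, b in enumerate(self.b)},
        }

    def set_params(self, params: dict) -> None:
        for i in range(len(self.W)):
            self.W[i] = np.asarray(params[f"W{i}"], dtype=float)
            self.b[i] = np.asarray(params[f"b{i}"], dtype=float)


def flatten_params(param_dicts: list[dict]) -> np.ndarray:
    """Concatenate a list of parameter dicts into one flat vector."""
    chunks = []
    for d in param_dicts:
        for k in sorted(d):
            chunks.append(np.ravel(d[k]))
    return np.concatenate(chunks) if chunks else np.array([])


def unflatten_params(flat: np.ndarray, templates: list[dict]) -> list[dict]:
    """Inverse of :func:`flatten_params` given shape templates."""
    out = []
    pos = 0
    for d in templates:
        new = {}
        for k in sorted(d):
            n = d[k].size
            new[k] = flat[pos : pos + n].reshape(d[k].shape)
            pos += n
        out.append(new)
    if pos != flat.size:
        raise ValueError("flat vector length mismatch")
    return out


class Adam:
    """Adam optimizer over a list of parameter dicts."""

    def __init__(self, param_dicts: list[dict], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in d.items()} for d in param_dicts]
        self.v = [{k: np.zeros_like(v) for k, v in d.items()} for d in param_dicts]

    def step(self, param_dicts: list[dict], grad_dicts: list[dict]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for params, grads, m, v in zip(param_dicts, grad_dicts, self.m, self.v):
            for k in params:
                g = grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                params[k] -= self.lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)
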