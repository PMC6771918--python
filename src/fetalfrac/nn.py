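"""Feed-forward regression network trained by Rprop+ (resilient backprop
with weight backtracking).

The network is deliberately small: standardized PC scores feed two logistic
hidden layers and a linear output unit, and the loss is the plain sum of
squared errors.  Rprop adapts a per-weight step size from the *sign* of the
gradient only, which makes full-batch training on a few hundred samples both
fast and insensitive to the loss scale; the "+" variant undoes the previous
step whenever the partial derivative changes sign (weight backtracking).

Canonical Riedmiller-Braun constants are the defaults: eta+ = 1.2,
eta- = 0.5, Delta0 = 0.1, Delta_max = 50, Delta_min = 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RpropConfig:
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-6
    grad_tol: float = 1e-5
    max_epochs: int = 20_000


@dataclass
class FitResult:
    converged: bool
    failed: bool  # non-finite loss or weights
    epochs: int
    sse: float
    sse_trace: list[float] = field(default_factory=list)


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class RpropNetwork:
    """Two-hidden-layer logistic network with a linear output."""

    def __init__(self, n_in: int, hidden_sizes: tuple[int, int] = (16, 8),
                 seed: int = 0):
        self.n_in = n_in
        self.hidden_sizes = tuple(hidden_sizes)
        rng = np.random.default_rng(seed)
        sizes = [n_in, *self.hidden_sizes, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-limit, limit, size=fan_out))

    # -- forward / backward ------------------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _logistic(a @ W + b)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    def _loss_and_grads(self, X, y):
        activations = [np.asarray(X, dtype=float)]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            activations.append(_logistic(activations[-1] @ W + b))
        pred = (activations[-1] @ self.weights[-1] + self.biases[-1]).ravel()
        resid = pred - y
        sse = float(resid @ resid)
        gW = [np.empty_like(W) for W in self.weights]
        gb = [np.empty_like(b) for b in self.biases]
        delta = 2.0 * resid[:, None]  # d SSE / d output
        gW[-1] = activations[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        for layer in range(len(self.weights) - 2, -1, -1):
            a = activations[layer + 1]
            delta = (delta @ self.weights[layer + 1].T) * a * (1.0 - a)
            gW[layer] = activations[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
        return sse, gW, gb

    # -- Rprop+ ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            config: RpropConfig | None = None) -> FitResult:
        """Full-batch Rprop+ minimization of the SSE.

        Stops when ``max |dSSE/dw| < grad_tol`` (converged) or after
        ``max_epochs``; a non-finite loss or weight marks the fit as failed.
        """
        cfg = config or RpropConfig()
        y = np.asarray(y, dtype=float).ravel()
        params = self.weights + self.biases
        deltas = [np.full_like(p, cfg.delta0) for p in params]
        prev_g = [np.zeros_like(p) for p in params]
        prev_step = [np.zeros_like(p) for p in params]
        trace: list[float] = []
        sse = np.inf
        for epoch in range(1, cfg.max_epochs + 1):
            sse, gW, gb = self._loss_and_grads(X, y)
            grads = gW + gb
            trace.append(sse)
            if not np.isfinite(sse) or any(not np.isfinite(p).all() for p in params):
                return FitResult(False, True, epoch, sse, trace)
            gmax = max(np.max(np.abs(g)) for g in grads)
            if gmax < cfg.grad_tol:
                return FitResult(True, False, epoch, sse, trace)
            for p, g, d, pg, ps in zip(params, grads, deltas, prev_g, prev_step):
                sign = g * pg
                grow = sign > 0
                shrink = sign < 0
                d[grow] = np.minimum(d[grow] * cfg.eta_plus, cfg.delta_max)
                d[shrink] = np.maximum(d[shrink] * cfg.eta_minus, cfg.delta_min)
                # backtrack: revert the previous step where the sign flipped
                p[shrink] -= ps[shrink]
                g = g.copy()
                g[shrink] = 0.0
                step = -np.sign(g) * d
                step[shrink] = 0.0
                p += step
                ps[...] = step
                pg[...] = g
        return FitResult(False, False, cfg.max_epochs, sse, trace)

    # -- (de)serialization -------------------------------------------------

    def state(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_state(cls, n_in: int, hidden_sizes: tuple[int, int],
                   state: dict[str, np.ndarray]) -> "RpropNetwork":
        net = cls(n_in, hidden_sizes, seed=0)
        net.weights = [np.asarray(state[f"W{i}"], dtype=float)
                       for i in range(len(net.weights))]
        net.biases = [np.asarray(state[f"b{i}"], dtype=float)
                      for i in range(len(net.biases))]
        return net
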