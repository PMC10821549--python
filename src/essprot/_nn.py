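"""Minimal numpy building blocks for the two-branch classifier.

Dense, batch-normalization and ReLU layers with explicit forward/backward
passes, an Adam optimizer, and a two-branch network whose branch outputs are
concatenated before a small fully connected head ending in one logit. Sized
for desk-scale problems (hundreds to low thousands of samples); everything
is full-batch and deterministic given the seeding generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "BatchNorm", "ReLU", "Adam", "TwoBranchNet", "bce_with_logits"]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, appropriate for the ReLU nonlinearity that follows
        self.W = rng.normal(0.0, np.sqrt(2.0 / max(n_in, 1)), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def state(self) -> dict:
        return {"W": self.W.tolist(), "b": self.b.tolist()}

    def load(self, s: dict) -> None:
        self.W = np.asarray(s["W"], dtype=float)
        self.b = np.asarray(s["b"], dtype=float)


class BatchNorm:
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return self.gamma * xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = g.shape[0]
        self.dgamma = (g * xhat).sum(axis=0)
        self.dbeta = g.sum(axis=0)
        gx = g * self.gamma
        return inv_std / n * (n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def state(self) -> dict:
        return {
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "running_mean": self.running_mean.tolist(),
            "running_var": self.running_var.tolist(),
        }

    def load(self, s: dict) -> None:
        self.gamma = np.asarray(s["gamma"], dtype=float)
        self.beta = np.asarray(s["beta"], dtype=float)
        self.running_mean = np.asarray(s["running_mean"], dtype=float)
        self.running_var = np.asarray(s["running_var"], dtype=float)


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask

    params: list = []
    grads: list = []

    def state(self) -> dict:
        return {}

    def load(self, s: dict) -> None:
        pass


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _branch(n_in: int, widths: tuple[int, ...], rng: np.random.Generator) -> list:
    layers: list = []
    prev = n_in
    for w in widths:
        layers += [Dense(prev, w, rng), BatchNorm(w), ReLU()]
        prev = w
    return layers


class TwoBranchNet:
    """Branch per input block (FC + BatchNorm + ReLU stacks), concatenated
    into a fully connected head that emits a single logit."""

    def __init__(
        self,
        n_community: int,
        n_subcellular: int,
        community_hidden: tuple[int, ...] = (32, 16),
        subcellular_hidden: tuple[int, ...] = (256, 64, 16),
        head_hidden: tuple[int, ...] = (16,),
        rng: np.random.Generator | None = None,
    ):
        if n_community <= 0 and n_subcellular <= 0:
            raise ValueError("at least one branch must have positive input width")
        rng = rng or np.random.default_rng(0)
        self.n_community = n_community
        self.n_subcellular = n_subcellular
        self.com_layers = _branch(n_community, community_hidden, rng) if n_community > 0 else []
        self.sub_layers = _branch(n_subcellular, subcellular_hidden, rng) if n_subcellular > 0 else []
        head_in = (community_hidden[-1] if n_community > 0 else 0) + (
            subcellular_hidden[-1] if n_subcellular > 0 else 0
        )
        self.branch_output_widths = (
            community_hidden[-1] if n_community > 0 else 0,
            subcellular_hidden[-1] if n_subcellular > 0 else 0,
        )
        self.head_layers: list = []
        prev = head_in
        for w in head_hidden:
            self.head_layers += [Dense(prev, w, rng), ReLU()]
            prev = w
        self.head_layers.append(Dense(prev, 1, rng))
        self._hidden = (tuple(community_hidden), tuple(subcellular_hidden), tuple(head_hidden))

    def _all_layers(self) -> list:
        return self.com_layers + self.sub_layers + self.head_layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self._all_layers() for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._all_layers() for g in layer.grads]

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        Xc = X[:, : self.n_community]
        Xs = X[:, self.n_community : self.n_community + self.n_subcellular]
        parts = []
        if self.com_layers:
            h = Xc
            for layer in self.com_layers:
                h = layer.forward(h, training)
            parts.append(h)
        if self.sub_layers:
            h = Xs
            for layer in self.sub_layers:
                h = layer.forward(h, training)
            parts.append(h)
        h = np.concatenate(parts, axis=1)
        self._concat_split = parts[0].shape[1] if len(parts) == 2 else None
        for layer in self.head_layers:
            h = layer.forward(h, training)
        return h.ravel()

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits.reshape(-1, 1)
        for layer in reversed(self.head_layers):
            g = layer.backward(g)
        if self.com_layers and self.sub_layers:
            gc, gs = g[:, : self._concat_split], g[:, self._concat_split :]
        elif self.com_layers:
            gc, gs = g, None
        else:
            gc, gs = None, g
        if gc is not None:
            for layer in reversed(self.com_layers):
                gc = layer.backward(gc)
        if gs is not None:
            for layer in reversed(self.sub_layers):
                gs = layer.backward(gs)

    def state(self) -> dict:
        return {
            "n_community": self.n_community,
            "n_subcellular": self.n_subcellular,
            "hidden": [list(h) for h in self._hidden],
            "layers": [layer.state() for layer in self._all_layers()],
        }

    @classmethod
    def from_state(cls, s: dict) -> "TwoBranchNet":
        com_h, sub_h, head_h = (tuple(h) for h in s["hidden"])
        net = cls(
            n_community=s["n_community"],
            n_subcellular=s["n_subcellular"],
            community_hidden=com_h,
            subcellular_hidden=sub_h,
            head_hidden=head_h,
            rng=np.random.default_rng(0),
        )
        for layer, st in zip(net._all_layers(), s["layers"]):
            layer.load(st)
        return net


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross entropy and its gradient wrt the logits."""
    # log(1 + e^z) computed stably
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    p = 1.0 / (1.0 + np.exp(-logits))
    return loss, (p - y) / logits.size
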