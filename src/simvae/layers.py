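"""Neural-network building blocks on top of the autodiff engine.

Parameters live in ordered dicts (name -> Tensor) so whole sub-networks can
be frozen, checksummed, serialized, and updated as units.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = ["Linear", "Embedding", "GRUCell", "Adam", "Module"]


class Module:
    """Base: a named parameter registry with freeze/serialize helpers."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register(self, prefix: str, sub: "Module") -> "Module":
        for name, t in sub._params.items():
            self._params[f"{prefix}.{name}"] = t
        return sub

    def parameters(self) -> dict[str, Tensor]:
        return dict(self._params)

    def zero_grad(self) -> None:
        for t in self._params.values():
            t.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self._params) ^ set(state)
        if missing:
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for k, t in self._params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = arr.copy()

    def checksum(self) -> float:
        """Order-stable sum over all parameter values (freeze audit)."""
        return float(sum(v.data.sum() for _, v in sorted(self._params.items())))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        super().__init__()
        self.W = self.add_param("W", _glorot(rng, n_in, n_out))
        self.b = self.add_param("b", np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, n_tokens: int, dim: int):
        super().__init__()
        self.W = self.add_param("W", rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def __call__(self, idx) -> Tensor:
        return self.W.take_rows(idx)


class GRUCell(Module):
    """Single gated-recurrent-unit step.

    r = sigmoid(x Wxr + h Whr + br);  u = sigmoid(x Wxu + h Whu + bu)
    n = tanh(x Wxn + bxn + r * (h Whn + bhn));  h' = (1-u) * n + u * h
    """

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        super().__init__()
        for gate in ("r", "u", "n"):
            self.add_param(f"Wx{gate}", _glorot(rng, n_in, n_hidden))
            self.add_param(f"Wh{gate}", _glorot(rng, n_hidden, n_hidden))
            self.add_param(f"b{gate}", np.zeros(n_hidden))
        self.add_param("bhn", np.zeros(n_hidden))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        p = self._params
        r = (x @ p["Wxr"] + h @ p["Whr"] + p["br"]).sigmoid()
        u = (x @ p["Wxu"] + h @ p["Whu"] + p["bu"]).sigmoid()
        n = (x @ p["Wxn"] + p["bn"] + r * (h @ p["Whn"] + p["bhn"])).tanh()
        return (1.0 - u) * n + u * h

    def step_masked(self, x: Tensor, h: Tensor, mask: np.ndarray) -> Tensor:
        """Advance only rows where mask==1 (padding keeps the old state)."""
        m = mask.reshape(-1, 1).astype(np.float64)
        return Tensor(m) * self(x, h) + Tensor(1.0 - m) * h


class Adam:
    """Adam optimizer over a named parameter dict (deterministic order)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dict(sorted(params.items()))
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in self.params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()
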