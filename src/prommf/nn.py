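"""Layers, initialisation, Adam and the binary cross-entropy objective.

Built on :mod:`prommf._tensor`. Modules hold their parameters in a flat
``params`` dict so optimizers, checkpointing and the zero-ablation tests can
address every weight by name.
"""

from __future__ import annotations

import math

import numpy as np

from ._tensor import Tensor

__all__ = ["Linear", "Module", "Adam", "bce_with_logits", "kaiming_uniform"]


def kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """He-style uniform init, the convention for ReLU networks."""
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    """Affine map ``x W^T + b`` for 1-d or 2-d (rows = instances) input."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(kaiming_uniform(rng, in_dim, (out_dim, in_dim)), requires_grad=True)
        bound = 1.0 / math.sqrt(in_dim)
        self.bias = Tensor(rng.uniform(-bound, bound, size=out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ _transpose(self.weight) + self.bias


def _transpose(t: Tensor) -> Tensor:
    """Transpose a 2-d tensor (gradient flows through the reshape of axes)."""
    out = Tensor(t.data.T)
    out.requires_grad = t.requires_grad
    if out.requires_grad:
        out._parents = (t,)

        def backward(g):
            t._accumulate(np.asarray(g).T)

        out._backward = backward
    return out


class Module:
    """Base class: a named parameter dict plus a train/eval flag."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}
        self.training = True
        self._children: list["Module"] = []

    def add_linear(self, name: str, in_dim: int, out_dim: int, rng: np.random.Generator) -> Linear:
        layer = Linear(in_dim, out_dim, rng)
        self.params[f"{name}.weight"] = layer.weight
        self.params[f"{name}.bias"] = layer.bias
        return layer

    def add_module(self, name: str, module: "Module") -> "Module":
        """Adopt a child module, merging its parameters under a name prefix."""
        self._children.append(module)
        for k, p in module.params.items():
            self.params[f"{name}.{k}"] = p
        return module

    def train(self) -> "Module":
        self.training = True
        for c in self._children:
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self._children:
            c.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=np.float64).copy()


class Adam:
    """Adam with L2 weight decay folded into the gradient.

    Matches the common framework convention where ``weight_decay`` adds
    ``wd * theta`` to the raw gradient before the moment updates.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logit: Tensor, target: float) -> Tensor:
    """Binary cross-entropy from the logit: log(1+e^z) - y*z, stable."""
    return logit.logaddexp0() - logit * float(target)
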