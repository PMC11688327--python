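"""Lightweight module system over the autodiff tensors.

Modules hold parameters as :class:`~somnostage.autodiff.Tensor` attributes and
submodules as attributes or plain lists.  ``state_dict`` flattens the tree into
a name -> array map for checkpointing.  Stochastic layers (dropout, the
CrossNorm exchange) draw from a generator installed with :meth:`Module.apply_rng`
so a training run is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from somnostage.autodiff import Tensor, layer_norm


class Module:
    def __init__(self):
        self.training = False
        self.rng: np.random.Generator | None = None

    # -- tree traversal -------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def apply_rng(self, rng: np.random.Generator):
        """Install a shared random generator on every module (dropout, CrossNorm)."""
        for m in self.modules():
            m.rng = rng
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = sorted(set(own) - set(state))
            extra = sorted(set(state) - set(own))
            raise ValueError(f"state dict mismatch; missing={missing}, unexpected={extra}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    """Affine map over the last axis, initialized ~N(0, 1/fan_in)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        std = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.normal(0.0, std, size=(in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("training-mode dropout requires apply_rng() first")
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias, eps=self.eps)
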