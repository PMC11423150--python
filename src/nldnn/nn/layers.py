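"""Neural-network modules on top of the :mod:`nldnn.nn.tensor` engine.

Follows the familiar module pattern: each layer owns named parameter tensors,
``parameters()`` walks the tree, and ``train()``/``eval()`` toggle dropout and
batch-norm behaviour.  Initialization is deterministic given the
``numpy.random.Generator`` handed to the constructor.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate, stack

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "Dropout",
    "MaxPool1d",
    "BiGRU",
    "Sequential",
]


class Module:
    """Base class: parameter registry plus train/eval mode propagation."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def weights(self) -> list[Tensor]:
        """Weight matrices/kernels only (biases and norm shifts excluded)."""
        return [p for name, p in self.named_parameters() if "bias" not in name
                and not name.endswith(".beta")]

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            out[name] = buf.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for name, _ in self.named_buffers():
            self._set_buffer(name, state[name].copy())

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for attr in getattr(self, "_buffers", []):
            out.append((prefix + attr, getattr(self, attr)))
        for cname, child in self._children.items():
            out.extend(child.named_buffers(prefix + cname + "."))
        return out

    def _set_buffer(self, dotted: str, value: np.ndarray):
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            obj = obj._children[part]
        object.__setattr__(obj, parts[-1], value)

    def param_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padded 1-D convolution over (N, C, L) inputs."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.weight = Tensor(
            _kaiming(rng, (c_out, c_in, kernel), c_in * kernel), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel batch normalization for (N, C, L) inputs."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._buffers = ("running_mean", "running_var")

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.reshape(-1)
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MaxPool1d(Module):
    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        return x.maxpool1d(self.k)


class _GRUCellParams(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        scale_x = np.sqrt(1.0 / n_in)
        scale_h = np.sqrt(1.0 / n_hidden)
        self.w_x = Tensor(rng.normal(0, scale_x, (n_in, 3 * n_hidden)), requires_grad=True)
        self.w_h = Tensor(rng.normal(0, scale_h, (n_hidden, 3 * n_hidden)), requires_grad=True)
        self.bias = Tensor(np.zeros(3 * n_hidden), requires_grad=True)
        self.n_hidden = n_hidden


class BiGRU(Module):
    """Bidirectional gated recurrent unit over (N, T, C) feature sequences.

    Returns the concatenated forward/backward hidden states, shape
    (N, T, 2*hidden).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _GRUCellParams(n_in, n_hidden, rng)
        self.bwd = _GRUCellParams(n_in, n_hidden, rng)
        self.n_hidden = n_hidden

    @staticmethod
    def _run(cell: _GRUCellParams, x: Tensor, reverse: bool) -> list[Tensor]:
        n, t, c = x.shape
        H = cell.n_hidden
        # all input projections in one matmul, then a recurrence over steps
        gx_all = (x.reshape(n * t, c) @ cell.w_x + cell.bias).reshape(n, t, 3 * H)
        order = range(t - 1, -1, -1) if reverse else range(t)
        h = Tensor(np.zeros((n, H)))
        outs: list[Tensor | None] = [None] * t
        for i in order:
            gx = gx_all[:, i, :]
            gh = h @ cell.w_h
            z = (gx[:, 0:H] + gh[:, 0:H]).sigmoid()
            r = (gx[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
            n_ = (gx[:, 2 * H : 3 * H] + r * gh[:, 2 * H : 3 * H]).tanh()
            one = Tensor(np.ones_like(z.data))
            h = (one - z) * n_ + z * h
            outs[i] = h
        return outs

    def __call__(self, x: Tensor) -> Tensor:
        fwd_out = self._run(self.fwd, x, reverse=False)
        bwd_out = self._run(self.bwd, x, reverse=True)
        per_step = [concatenate([f, b], axis=1) for f, b in zip(fwd_out, bwd_out)]
        return stack(per_step, axis=1)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)

    def __call__(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x
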