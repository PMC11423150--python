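"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-based engine sized for 1-D sequence models: dense/convolutional
layers, pooling, recurrent cells and the usual pointwise nonlinearities.  All
heavy lifting is delegated to numpy matmuls (convolutions run through im2col),
so desk-scale networks train in seconds on one CPU.

Gradients accumulate into ``Tensor.grad`` after calling :meth:`Tensor.backward`
on a scalar.  Only float64 is used; determinism is inherited from the caller's
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(stack_.pop())
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node.requires_grad and node._backward is None:
                    node._accum(g)
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            if node.requires_grad and not node._parents:
                node._accum(g)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            return ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape)))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            return (
                (a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape)),
            )

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            return (
                (a, _unbroadcast(g / b.data, a.shape)),
                (b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape)),
            )

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            return ((a, g * e * np.power(a.data, e - 1.0)),)

        return Tensor._make(np.power(a.data, e), (a,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return ((a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape)))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        a = self
        orig = a.shape
        out = Tensor._make(
            a.data.reshape(*shape), (a,), lambda g: ((a, g.reshape(orig)),)
        )
        return out

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: ((a, g.transpose(inv)),)
        )

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return ((a, full),)

        return Tensor._make(a.data[idx], (a,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                return ((a, np.broadcast_to(g, a.shape).copy()),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g2, a.shape).copy()),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.max(a.data, axis=axis, keepdims=keepdims)

        def backward(g):
            full = np.zeros_like(a.data)
            g2 = g if not keepdims else np.squeeze(g, axis=axis)
            grid = np.indices(idx.shape)
            sel = list(grid)
            sel.insert(axis if axis >= 0 else a.ndim + axis, idx)
            np.add.at(full, tuple(sel), g2)
            return ((a, full),)

        return Tensor._make(out_data, (a,), backward)

    # ------------------------------------------------------------- nonlinears
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: ((a, g * mask),))

    def elu(self, alpha: float = 1.0):
        a = self
        pos = a.data > 0
        expm = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
        out = np.where(pos, a.data, expm)

        def backward(g):
            return ((a, g * np.where(pos, 1.0, expm + alpha)),)

        return Tensor._make(out, (a,), backward)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(s, (a,), lambda g: ((a, g * s * (1.0 - s)),))

    def tanh(self):
        a = self
        t = np.tanh(a.data)
        return Tensor._make(t, (a,), lambda g: ((a, g * (1.0 - t * t)),))

    def exp(self):
        a = self
        e = np.exp(a.data)
        return Tensor._make(e, (a,), lambda g: ((a, g * e),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def clamp(self, lo: float, hi: float):
        a = self
        mask = (a.data > lo) & (a.data < hi)
        return Tensor._make(np.clip(a.data, lo, hi), (a,), lambda g: ((a, g * mask),))

    # ------------------------------------------------------------ conv / pool
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Same-padding 1-D convolution (cross-correlation).

        self: (N, C, L); weight: (O, C, K); bias: (O,).  Output (N, O, L).
        """
        x, w = self, weight
        N, C, L = x.shape
        O, Cw, K = w.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        pl = (K - 1) // 2
        pr = K - 1 - pl
        xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
        # im2col: (N, L, C*K)
        s = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(N, L, C, K), strides=(s[0], s[2], s[1], s[2])
        ).reshape(N, L, C * K)
        wmat = w.data.reshape(O, C * K)
        out = cols @ wmat.T  # (N, L, O)
        if bias is not None:
            out = out + bias.data[None, None, :]
        out = out.transpose(0, 2, 1)
        cols_c = cols  # view into xp; safe, xp local

        def backward(g):
            gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, L, O)
            gw = (
                gt.reshape(N * L, O).T @ cols_c.reshape(N * L, C * K)
            ).reshape(O, C, K)
            # input gradient = correlation of g with the k-flipped kernels
            gp = np.pad(g, ((0, 0), (0, 0), (pr, pl)))
            sg = gp.strides
            gcols = np.lib.stride_tricks.as_strided(
                gp, shape=(N, L, O, K), strides=(sg[0], sg[2], sg[1], sg[2])
            ).reshape(N, L, O * K)
            w_flip = np.ascontiguousarray(w.data[:, :, ::-1].transpose(1, 0, 2))
            gx = (gcols @ w_flip.reshape(C, O * K).T).transpose(0, 2, 1)
            grads = [(x, gx), (w, gw)]
            if bias is not None:
                grads.append((bias, gt.sum(axis=(0, 1))))
            return tuple(grads)

        parents = (x, w) if bias is None else (x, w, bias)
        return Tensor._make(out, parents, backward)

    def maxpool1d(self, k: int):
        """Non-overlapping max pooling; trailing remainder positions dropped."""
        a = self
        N, C, L = a.shape
        Lo = L // k
        trimmed = a.data[:, :, : Lo * k].reshape(N, C, Lo, k)
        idx = np.argmax(trimmed, axis=3)
        out = np.max(trimmed, axis=3)

        def backward(g):
            gfull = np.zeros((N, C, Lo, k))
            n_i, c_i, l_i = np.indices(idx.shape)
            gfull[n_i, c_i, l_i, idx] = g
            gx = np.zeros_like(a.data)
            gx[:, :, : Lo * k] = gfull.reshape(N, C, Lo * k)
            return ((a, gx),)

        return Tensor._make(out, (a,), backward)

    def avgpool_to(self, bins: int):
        """Adaptive average pooling along the last axis to `bins` positions."""
        a = self
        N, C, L = a.shape
        edges = [(int(np.floor(i * L / bins)), int(np.ceil((i + 1) * L / bins)))
                 for i in range(bins)]
        out = np.stack(
            [a.data[:, :, lo:hi].mean(axis=2) for lo, hi in edges], axis=2
        )

        def backward(g):
            gx = np.zeros_like(a.data)
            for i, (lo, hi) in enumerate(edges):
                gx[:, :, lo:hi] += g[:, :, i : i + 1] / (hi - lo)
            return ((a, gx),)

        return Tensor._make(out, (a,), backward)

    def upsample_to(self, length: int):
        """Nearest-neighbour upsampling of the last axis to `length`."""
        a = self
        N, C, L = a.shape
        idx = np.floor(np.arange(length) * L / length).astype(np.intp)

        def backward(g):
            gx = np.zeros_like(a.data)
            np.add.at(gx.transpose(2, 0, 1), idx, g.transpose(2, 0, 1))
            return ((a, gx),)

        return Tensor._make(a.data[:, :, idx], (a,), backward)


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            grads.append((t, g[tuple(sl)]))
        return tuple(grads)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def stack(tensors: list[Tensor], axis: int) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concatenate(expanded, axis)
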