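"""Minimal reverse-mode autodiff over NumPy arrays, with the layers needed by
the classifier families: linear, 1-D convolution, embeddings and (weight-
droppable) LSTM stacks, plus an Adam optimizer and an averaging (ASGD-style)
wrapper.

Deliberately small: float64 throughout, 2-D matmul only, no broadcasting
beyond bias addition. Everything is deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers --------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def matmul(self, other: "Tensor") -> "Tensor":
        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ grad)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * mask)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(self.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        inverse = np.argsort(axes)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.transpose(*inverse))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        index = [slice(None)] * self.data.ndim
        index[axis] = slice(start, start + length)
        index = tuple(index)

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[index] = grad
                self._accumulate(full)

        return self._make(self.data[index], (self,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(grad):
            if not self.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int) -> "Tensor":
        out_data = self.data.max(axis=axis)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(
                    full, argmax, np.expand_dims(grad, axis), axis=axis
                )
                self._accumulate(full)

        return self._make(out_data, (self,), backward)

    # -- backprop ---------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, start, size in zip(tensors, offsets, sizes):
            if t.requires_grad:
                index = [slice(None)] * grad.ndim
                index[axis] = slice(start, start + size)
                t._accumulate(grad[tuple(index)])

    out = Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add backward."""
    indices = np.asarray(indices)

    def backward(grad):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, indices.reshape(-1), grad.reshape(-1, grad.shape[-1]))
            weight._accumulate(full)

    return Tensor._make(weight.data[indices], (weight,), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution. x: (B, Cin, L); w: (Cout, Cin, K); b: (Cout,).
    Output (B, Cout, L-K+1)."""
    K = w.data.shape[2]
    windows = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)
    out_data = np.einsum("bclk,ock->bol", windows, w.data) + b.data[None, :, None]

    def backward(grad):
        if w.requires_grad:
            w._accumulate(np.einsum("bclk,bol->ock", windows, grad))
        if b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2)))
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            L_out = grad.shape[2]
            for k in range(K):
                dx[:, :, k:k + L_out] += np.einsum("bol,oc->bcl", grad, w.data[:, :, k])
            x._accumulate(dx)

    return Tensor._make(out_data, (x, w, b), backward)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over rows; ``targets`` are int class ids.
    Rows with target < 0 are masked out (ignored)."""
    targets = np.asarray(targets)
    mask = targets >= 0
    safe_targets = np.where(mask, targets, 0)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = max(int(mask.sum()), 1)
    losses = -np.log(
        np.clip(probs[np.arange(len(targets)), safe_targets], 1e-300, None)
    )
    loss_value = (losses * mask).sum() / n

    def backward(grad):
        if logits.requires_grad:
            g = probs.copy()
            g[np.arange(len(targets)), safe_targets] -= 1.0
            g *= (mask / n)[:, None]
            logits._accumulate(grad * g)

    return Tensor._make(np.asarray(loss_value), (logits,), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def named_parameters(self) -> dict[str, Tensor]:
        raise NotImplementedError


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.W = Tensor(rng.uniform(-scale, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]

    def named_parameters(self):
        return {"W": self.W, "b": self.b}


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0, 0.1, (n_vocab, dim)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embedding(self.W, indices)

    def parameters(self):
        return [self.W]

    def named_parameters(self):
        return {"W": self.W}


class LSTMLayer(Module):
    """Single LSTM layer, optionally with dropconnect on the recurrent
    weights (a fresh mask per forward pass while training)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 weight_drop: float = 0.0):
        scale = np.sqrt(1.0 / n_in)
        hscale = np.sqrt(1.0 / n_hidden)
        self.Wx = Tensor(rng.uniform(-scale, scale, (n_in, 4 * n_hidden)),
                         requires_grad=True)
        self.Wh = Tensor(rng.uniform(-hscale, hscale, (n_hidden, 4 * n_hidden)),
                         requires_grad=True)
        self.b = Tensor(np.zeros(4 * n_hidden), requires_grad=True)
        # forget-gate bias init at 1 helps tiny corpora
        self.b.data[n_hidden: 2 * n_hidden] = 1.0
        self.n_hidden = n_hidden
        self.weight_drop = weight_drop

    def __call__(self, xs: list[Tensor], rng: np.random.Generator,
                 train: bool) -> list[Tensor]:
        """xs: list of (B, n_in) tensors over time. Returns hidden states."""
        H = self.n_hidden
        B = xs[0].shape[0]
        Wh = self.Wh
        if train and self.weight_drop > 0.0:
            mask = (rng.random(Wh.shape) >= self.weight_drop) / (1.0 - self.weight_drop)
            Wh = Wh * Tensor(mask)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outputs: list[Tensor] = []
        for x in xs:
            gates = x @ self.Wx + h @ Wh + self.b
            i = gates.narrow(1, 0, H).sigmoid()
            f = gates.narrow(1, H, H).sigmoid()
            g = gates.narrow(1, 2 * H, H).tanh()
            o = gates.narrow(1, 3 * H, H).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h)
        return outputs

    def parameters(self):
        return [self.Wx, self.Wh, self.b]

    def named_parameters(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def add_params(self, new_params: list[Tensor]):
        """Extend the optimizer with newly unfrozen parameters (fresh
        moments), keeping state for the existing ones."""
        known = {id(p) for p in self.params}
        for p in new_params:
            if id(p) in known:
                continue
            self.params.append(p)
            self.m.append(np.zeros_like(p.data))
            self.v.append(np.zeros_like(p.data))

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class WeightAverager:
    """Running average of parameters, for ASGD-style averaging after a
    non-improvement trigger fires."""

    def __init__(self, params: list[Tensor]):
        self.params = list(params)
        self.sums = None
        self.count = 0

    @property
    def active(self) -> bool:
        return self.sums is not None

    def trigger(self):
        if self.sums is None:
            self.sums = [p.data.copy() for p in self.params]
            self.count = 1

    def update(self):
        if self.sums is not None:
            for s, p in zip(self.sums, self.params):
                s += p.data
            self.count += 1

    def apply(self):
        if self.sums is not None:
            for s, p in zip(self.sums, self.params):
                p.data = s / self.count
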