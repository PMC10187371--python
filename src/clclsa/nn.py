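"""Minimal reverse-mode automatic differentiation and neural-network layers.

Everything in this package that learns — attention encoders, cross-omics
bridges, classification heads — is built from the pieces here: a ``Tensor``
holding a float64 numpy array plus its gradient, a handful of differentiable
operations, standard layers (``Linear``, ``ReLU``, ``Dropout``,
``BatchNorm1d``, ``Softmax``) and the Adam optimizer.  The engine is
deliberately small: full-batch training of MLPs with at most a few hundred
thousand parameters, which is the regime this method operates in.

Gradients are accumulated by topologically sorting the computation graph and
running each node's backward closure once.  Broadcasting follows numpy rules;
gradients of broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softmax",
    "Module",
    "Linear",
    "ReLU",
    "Sigmoid",
    "Softmax",
    "Dropout",
    "BatchNorm1d",
    "Sequential",
    "Adam",
    "build_mlp",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """A numpy array with reverse-mode gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # own a fresh buffer; incoming grad may be a shared/view array
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

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
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data.reshape(-1)[0]) if self.data.size == 1 else float(self.data)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = Tensor._make(self.data * other.data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        out = Tensor._make(self.data / other.data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only constant exponents are supported")

        def backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out = Tensor._make(self.data**exponent, (self,), backward)
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)

        def backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out = Tensor._make(self.data @ other.data, (self, other), backward)
        return out

    def __getitem__(self, idx):
        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out = Tensor._make(self.data[idx], (self,), backward)
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(self.data * mask, (self,), backward)
        return out

    def clip_min(self, lo: float):
        """Elementwise max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(np.maximum(self.data, lo), (self,), backward)
        return out

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    @property
    def T(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad.T)

        out = Tensor._make(self.data.T, (self,), backward)
        return out


def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Row softmax; the max-shift is a constant so gradients are exact."""
    x = _as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# layers


class Module:
    """Base class: tracks train/eval mode and exposes named parameters."""

    def __init__(self):
        self.training = True

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for child in self.children():
            child.set_training(flag)

    def children(self) -> list:
        return []

    def parameters(self) -> list:
        params = []
        for child in self.children():
            params.extend(child.parameters())
        return params

    def state_dict(self, prefix: str = "") -> dict:
        state = {}
        for i, child in enumerate(self.children()):
            state.update(child.state_dict(f"{prefix}{i}."))
        return state

    def load_state_dict(self, state: dict, prefix: str = "") -> None:
        for i, child in enumerate(self.children()):
            child.load_state_dict(state, f"{prefix}{i}.")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Linear(Module):
    """Affine map with fan-in uniform initialization U(-1/sqrt(in), 1/sqrt(in))."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        bound = 1.0 / np.sqrt(in_dim)
        self.W = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(out_dim,)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[-1] != self.in_dim:
            raise ValueError(
                f"input has {x.data.shape[-1]} features, layer expects {self.in_dim}"
            )
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]

    def state_dict(self, prefix=""):
        return {prefix + "W": self.W.data, prefix + "b": self.b.data}

    def load_state_dict(self, state, prefix=""):
        self.W.data = np.array(state[prefix + "W"], dtype=np.float64)
        self.b.data = np.array(state[prefix + "b"], dtype=np.float64)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Softmax(Module):
    def forward(self, x):
        return softmax(x, axis=1)


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Seeded through ``rng``."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class BatchNorm1d(Module):
    """Batch normalization over axis 0.

    Training mode normalizes by batch statistics (biased variance) and
    updates running statistics with momentum 0.1; eval mode uses the running
    statistics, making inference deterministic.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered**2).mean(axis=0, keepdims=True)
            n = x.data.shape[0]
            unbiased = var.data * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased.ravel()
            )
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]

    def state_dict(self, prefix=""):
        return {
            prefix + "gamma": self.gamma.data,
            prefix + "beta": self.beta.data,
            prefix + "running_mean": self.running_mean,
            prefix + "running_var": self.running_var,
        }

    def load_state_dict(self, state, prefix=""):
        self.gamma.data = np.array(state[prefix + "gamma"], dtype=np.float64)
        self.beta.data = np.array(state[prefix + "beta"], dtype=np.float64)
        self.running_mean = np.array(state[prefix + "running_mean"], dtype=np.float64)
        self.running_var = np.array(state[prefix + "running_var"], dtype=np.float64)


class Sequential(Module):
    def __init__(self, layers: list):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# architecture strings


_ACTIVATIONS = {"ReLU", "DP", "BN", "Softmax", "Sigmoid"}


def build_mlp(spec: str, rng: np.random.Generator, dropout_p: float = 0.5) -> Sequential:
    """Build an MLP from a compact layer string.

    The grammar follows the field's tabular convention: integers are layer
    widths (consecutive widths define a Linear layer) and the tokens
    ``ReLU``, ``DP`` (dropout), ``BN`` (batch norm), ``Softmax``, ``Sigmoid``
    insert the corresponding layer after the preceding Linear.  Examples::

        "200-200"                      one Linear 200->200
        "200-300-ReLU-DP"              Linear, ReLU, Dropout(0.5)
        "300-64-BN-ReLU-32-ReLU-64-BN-ReLU-300"   bottleneck autoencoder
        "900-2-Softmax"                Linear classifier head
    """
    layers: list[Module] = []
    width: int | None = None
    for token in spec.split("-"):
        token = token.strip()
        if token.isdigit():
            w = int(token)
            if width is not None:
                layers.append(Linear(width, w, rng))
            width = w
        elif token == "ReLU":
            layers.append(ReLU())
        elif token == "Sigmoid":
            layers.append(Sigmoid())
        elif token == "Softmax":
            layers.append(Softmax())
        elif token == "DP":
            layers.append(Dropout(dropout_p, rng))
        elif token == "BN":
            if width is None:
                raise ValueError(f"BN before any width in layer string {spec!r}")
            layers.append(BatchNorm1d(width))
        else:
            raise ValueError(f"unknown token {token!r} in layer string {spec!r}")
    if not layers:
        raise ValueError(f"layer string {spec!r} defines no layers")
    return Sequential(layers)


# ---------------------------------------------------------------------------
# optimization


class Adam:
    """Adam optimizer (Kingma & Ba) over a flat parameter list."""

    def __init__(self, params: list, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            mhat = self.m[i] / b1c
            vhat = self.v[i] / b2c
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
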