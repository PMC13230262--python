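"""Minimal reverse-mode autodiff on numpy arrays.

Purpose-built for the package's small neural components: the ConvGRU cell,
the recurrent residual U-Net feature extractor and the MLP hypothesis
scorer. Supports exactly the operations those need — elementwise arithmetic,
matmul, same-padding 2D convolution (im2col), 2x average pooling, 2x nearest
upsampling, channel concatenation, bilinear sampling with gradient scatter,
and a numerically stable logsumexp. Single-sample (no batch axis) by design:
images are ``(C, H, W)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "avg_pool2",
    "upsample2",
    "concat_channels",
    "bilinear_sample",
    "stack_scalars",
    "logsumexp_t",
    "Adam",
    "save_params",
    "load_params",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # --- graph construction ----------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def backward(g, out):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward(g, out):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        return Tensor._make(t, (self,), backward)

    def sum(self) -> "Tensor":
        def backward(g, out):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g))

        return Tensor._make(self.data.sum(), (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # --- backprop ---------------------------------------------------------

    def backward(self) -> None:
        if self.data.shape != ():
            raise ValueError("backward() requires a scalar output")
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
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad, node)


# --- structured ops -------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 convolution; ``x``: (Cin,H,W), ``w``: (Cout,Cin,k,k)."""
    cin, H, W = x.data.shape
    cout, cin_w, k, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel expects {cin_w}")
    if k % 2 != 1:
        raise ValueError("kernel size must be odd")
    pad = (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    cols = cols.transpose(0, 3, 4, 1, 2).reshape(cin * k * k, H * W)
    wm = w.data.reshape(cout, cin * k * k)
    out_data = (wm @ cols).reshape(cout, H, W)
    if b is not None:
        out_data = out_data + b.data[:, None, None]

    def backward(g, out):
        gf = g.reshape(cout, H * W)
        if w.requires_grad:
            w._accum((gf @ cols.T).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gf.sum(axis=1))
        if x.requires_grad:
            dcols = (wm.T @ gf).reshape(cin, k, k, H, W)
            dxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    dxp[:, di : di + H, dj : dj + W] += dcols[:, di, dj]
            x._accum(dxp[:, pad : pad + H, pad : pad + W])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling; spatial dims must be even."""
    c, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    out_data = x.data.reshape(c, H // 2, 2, W // 2, 2).mean(axis=(2, 4))

    def backward(g, out):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0
            x._accum(gx)

    return Tensor._make(out_data, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbor upsampling."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)
    c, H, W = x.data.shape

    def backward(g, out):
        if x.requires_grad:
            x._accum(g.reshape(c, H, 2, W, 2).sum(axis=(2, 4)))

    return Tensor._make(out_data, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[0]
    out_data = np.concatenate([a.data, b.data], axis=0)

    def backward(g, out):
        if a.requires_grad:
            a._accum(g[:ca])
        if b.requires_grad:
            b._accum(g[ca:])

    return Tensor._make(out_data, (a, b), backward)


def bilinear_sample(fmap: Tensor, points: np.ndarray) -> Tensor:
    """Sample a (C,H,W) map at subpixel ``(u, v)`` positions -> (K, C).

    Pixel centers sit at integer coordinates; points outside the image yield
    zero vectors (and receive no gradient).
    """
    c, H, W = fmap.data.shape
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    u, v = pts[:, 0], pts[:, 1]
    inside = (u >= 0) & (u <= W - 1) & (v >= 0) & (v <= H - 1)
    u0 = np.clip(np.floor(u).astype(int), 0, W - 1)
    v0 = np.clip(np.floor(v).astype(int), 0, H - 1)
    u1 = np.minimum(u0 + 1, W - 1)
    v1 = np.minimum(v0 + 1, H - 1)
    fu = np.clip(u - u0, 0.0, 1.0)
    fv = np.clip(v - v0, 0.0, 1.0)
    w00 = (1 - fu) * (1 - fv) * inside
    w01 = fu * (1 - fv) * inside
    w10 = (1 - fu) * fv * inside
    w11 = fu * fv * inside
    out_data = (
        fmap.data[:, v0, u0] * w00
        + fmap.data[:, v0, u1] * w01
        + fmap.data[:, v1, u0] * w10
        + fmap.data[:, v1, u1] * w11
    ).T  # (K, C)

    def backward(g, out):
        if fmap.requires_grad:
            gf = np.zeros_like(fmap.data)
            gT = g.T  # (C, K)
            np.add.at(gf, (slice(None), v0, u0), gT * w00)
            np.add.at(gf, (slice(None), v0, u1), gT * w01)
            np.add.at(gf, (slice(None), v1, u0), gT * w10)
            np.add.at(gf, (slice(None), v1, u1), gT * w11)
            fmap._accum(gf)

    return Tensor._make(out_data, (fmap,), backward)


def stack_scalars(scalars: list[Tensor]) -> Tensor:
    out_data = np.array([s.data for s in scalars])

    def backward(g, out):
        for i, s in enumerate(scalars):
            if s.requires_grad:
                s._accum(g[i])

    return Tensor._make(out_data, tuple(scalars), backward)


def logsumexp_t(x: Tensor) -> Tensor:
    """Stable logsumexp of a vector tensor -> scalar tensor."""
    m = x.data.max()
    e = np.exp(x.data - m)
    s = e.sum()
    out_data = np.array(m + np.log(s))

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * e / s)

    return Tensor._make(out_data, (x,), backward)


# --- optimization and serialization ---------------------------------------

class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
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


def save_params(path: str | Path, named: dict[str, np.ndarray]) -> None:
    """One archive holding all weights plus a JSON manifest of layer shapes."""
    manifest = json.dumps({k: list(v.shape) for k, v in named.items()})
    np.savez(path, __manifest__=np.array(manifest), **named)


def load_params(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["__manifest__"]))
        out = {}
        for k, shape in manifest.items():
            arr = z[k]
            if list(arr.shape) != shape:
                raise ValueError(f"weight {k} has shape {arr.shape}, manifest says {shape}")
            out[k] = arr
    return out
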