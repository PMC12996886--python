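"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine exists to train the adversarial convolution network on CPU.  It
implements exactly the operations the network needs — broadcast arithmetic,
matmul, ReLU, exp/log, reductions, strided 3D convolution (im2col) and the
gradient reversal layer — with a topological-order backward pass.  Arrays are
float64 unless the caller supplies float32; gradients always match the data
dtype of the tensor they flow into.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _as_array(x: ArrayLike) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        name: str = "",
    ) -> None:
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._backward = backward
        self._parents = tuple(parents)
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[Tuple[Tensor, bool]] = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    def __mul__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __truediv__(self, other: Union["Tensor", ArrayLike]) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other.pow(-1.0)

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return Tensor(other) - self

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------ nonlinear
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * sign)

        out._backward = bw
        return out

    def clip_min(self, lo: float) -> "Tensor":
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo
        out = Tensor(np.maximum(self.data, lo), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis: Optional[Union[int, Tuple[int, ...]]] = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            gg = g
            if not keepdims:
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis: Optional[Union[int, Tuple[int, ...]]] = None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out

    # ---------------------------------------------------------------- softmax
    def softmax(self, axis: int = -1) -> "Tensor":
        shift = self.data.max(axis=axis, keepdims=True)  # constant shift
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Gradient reversal layer.

    Identity in the forward pass; during backpropagation the gradient flowing
    into ``x`` is the upstream gradient multiplied by ``-lam``.  This is the
    mechanism by which the confound heads' objective is *ascended* by the
    encoder while the heads themselves descend on it.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    out = Tensor(x.data, parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(-lam * g)

    out._backward = bw
    return out


def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, stride: int = 1, pad: int = 1) -> Tensor:
    """Strided 3D convolution (cross-correlation) via im2col.

    x: (N, C_in, D, H, W); w: (C_out, C_in, k, k, k); b: (C_out,).
    Output: (N, C_out, Do, Ho, Wo) with Do = (D + 2*pad - k)//stride + 1.
    """
    N, C, D, H, W = x.data.shape
    C_out, C_in, k, _, _ = w.data.shape
    if C != C_in:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {C_in}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Do = (D + 2 * pad - k) // stride + 1
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]            # (N,C,Do,Ho,Wo,k,k,k)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(N, Do * Ho * Wo, C * k ** 3)
    wmat = w.data.reshape(C_out, C * k ** 3)
    out_val = cols @ wmat.T                                   # (N, P, C_out)
    if b is not None:
        out_val = out_val + b.data
    out_val = out_val.reshape(N, Do, Ho, Wo, C_out).transpose(0, 4, 1, 2, 3)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(out_val), parents=parents)

    def bw(g: np.ndarray) -> None:
        gcols = g.transpose(0, 2, 3, 4, 1).reshape(N, Do * Ho * Wo, C_out)
        if b is not None and b.requires_grad:
            b._accumulate(gcols.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.tensordot(gcols, cols, axes=([0, 1], [0, 1]))  # (C_out, C*k^3)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = (gcols @ wmat).reshape(N, Do, Ho, Wo, C, k, k, k)
            gx_pad = np.zeros_like(xp)
            for kd in range(k):
                for kh in range(k):
                    for kw in range(k):
                        gx_pad[:, :,
                               kd:kd + stride * Do:stride,
                               kh:kh + stride * Ho:stride,
                               kw:kw + stride * Wo:stride] += dcols[:, :, :, :, :, kd, kh, kw].transpose(0, 4, 1, 2, 3)
            if pad:
                gx = gx_pad[:, :, pad:-pad, pad:-pad, pad:-pad]
            else:
                gx = gx_pad
            x._accumulate(gx)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
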