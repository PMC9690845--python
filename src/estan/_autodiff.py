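"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation network needs: zero-padded
"same" 2-D convolution (arbitrary, possibly asymmetric odd kernels), 2x2
stride-2 transposed convolution, 2x2 max pooling, ReLU, sigmoid, channel
concatenation, element-wise addition and a fused soft-Dice loss.

Feature maps are laid out NHWC in float32. Convolutions are computed by
shift-and-gemm (one matrix product per kernel tap) rather than im2col, which
keeps peak memory at one padded copy of the input instead of a k_h*k_w-fold
patch tensor.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """A node in the backward graph: an array plus a gradient slot."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad", "name")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False,
                 name=""):
        data = np.asarray(data, dtype=DTYPE)
        if data.ndim and not data.flags.c_contiguous:
            data = np.ascontiguousarray(data)
        self.data = data
        self.grad = None
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Reverse-topological sweep seeding d(self)/d(self) = 1."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.backward_fn is not None:
                t.backward_fn(t.grad)

    def zero_grad(self):
        self.grad = None


def parameter(data, name=""):
    return Tensor(data, requires_grad=True, name=name)


# ---------------------------------------------------------------------------
# convolution


def _corr2d(x, w, ph, pw):
    """Cross-correlate NHWC input with (kh,kw,cin,cout) kernel, zero pad."""
    n, h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((n, h + 2 * ph - kh + 1, wd + 2 * pw - kw + 1, cout), dtype=DTYPE)
    oh, ow = out.shape[1], out.shape[2]
    out_flat = out.reshape(-1, cout)
    for di in range(kh):
        for dj in range(kw):
            patch = np.ascontiguousarray(xp[:, di:di + oh, dj:dj + ow, :])
            out_flat += patch.reshape(-1, cin) @ w[di, dj]
    return out, xp


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2-D convolution; kernel dims must be odd (1, 3, 5, 15, ...)."""
    kh, kw, cin, cout = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(f"same-padding requires odd kernel dims, got {kh}x{kw}")
    if x.shape[3] != cin:
        raise ValueError(f"channel mismatch: input {x.shape[3]}, kernel expects {cin}")
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    y_data, xp = _corr2d(x.data, w.data, ph, pw)
    y_data += b.data
    out = Tensor(y_data, parents=(x, w, b))
    n, h, wd, _ = x.shape

    def backward_fn(gy):
        g2 = gy.reshape(-1, cout)
        # weights: dW[di,dj] = shifted-input^T @ gy
        gw = np.empty_like(w.data)
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, di:di + h, dj:dj + wd, :].reshape(-1, cin)
                gw[di, dj] = patch.T @ g2
        w._accumulate(gw)
        b._accumulate(gy.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    gxp[:, di:di + h, dj:dj + wd, :] += (
                        g2 @ w.data[di, dj].T).reshape(n, h, wd, cin)
            x._accumulate(gxp[:, ph:ph + h, pw:pw + wd, :])

    out.backward_fn = backward_fn
    return out


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x upsampling by a 2x2 stride-2 transposed convolution (no tap overlap)."""
    n, h, wd, cin = x.shape
    kh, kw, cin_w, cout = w.shape
    if (kh, kw) != (2, 2) or cin_w != cin:
        raise ValueError("kernel must be (2,2,cin,cout) matching input channels")
    # y[n, 2i+a, 2j+c, o] = sum_k x[n,i,j,k] w[a,c,k,o]
    t = np.einsum("nijk,acko->niajco", x.data, w.data, optimize=True)
    y = t.reshape(n, 2 * h, 2 * wd, cout) + b.data
    out = Tensor(y, parents=(x, w, b))

    def backward_fn(gy):
        g = gy.reshape(n, h, 2, wd, 2, cout)
        w._accumulate(np.einsum("nijk,niajco->acko", x.data, g, optimize=True))
        b._accumulate(gy.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            x._accumulate(np.einsum("niajco,acko->nijk", g, w.data, optimize=True))

    out.backward_fn = backward_fn
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial size {h}x{w} not divisible by 2 for pooling")
    win = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    win = win.reshape(n, h // 2, w // 2, c, 4)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def backward_fn(gy):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], gy[..., None], axis=-1)
        gx = gwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        x._accumulate(gx.reshape(n, h, w, c))

    out.backward_fn = backward_fn
    return out


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)
    out = Tensor(y, parents=(x,))

    def backward_fn(gy):
        x._accumulate(gy * (x.data > 0))

    out.backward_fn = backward_fn
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    y = np.empty_like(x.data)
    pos = x.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    y[~pos] = ex / (1.0 + ex)
    out = Tensor(y, parents=(x,))

    def backward_fn(gy):
        x._accumulate(gy * y * (1.0 - y))

    out.backward_fn = backward_fn
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch in add: {a.shape} vs {b.shape}")
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward_fn(gy):
        if a.requires_grad:
            a._accumulate(gy)
        if b.requires_grad:
            b._accumulate(gy)

    out.backward_fn = backward_fn
    return out


def concat(tensors, axis=3) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    splits = np.cumsum([t.shape[axis] for t in tensors])[:-1]

    def backward_fn(gy):
        for t, g in zip(tensors, np.split(gy, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(g)

    out.backward_fn = backward_fn
    return out


def dice_loss_t(pred: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss 1 - (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps), fused node."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, target {target.shape}")
    t = target.astype(DTYPE)
    inter = float((pred.data * t).sum())
    denom = float(pred.data.sum()) + float(t.sum()) + eps
    loss = 1.0 - (2.0 * inter + eps) / denom
    out = Tensor(np.array(loss), parents=(pred,))

    def backward_fn(gy):
        # d/dp_i [(2I+eps)/D] = (2 t_i D - (2I+eps)) / D^2
        g = -(2.0 * t * denom - (2.0 * inter + eps)) / (denom * denom)
        pred._accumulate(gy * g)

    out.backward_fn = backward_fn
    return out


def batch_dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Mean over the batch of per-sample soft Dice losses (NHWC pred)."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, target {target.shape}")
    t = target.astype(DTYPE)
    nb = pred.shape[0]
    axes = tuple(range(1, pred.data.ndim))
    inter = (pred.data * t).sum(axis=axes, dtype=np.float64)
    denom = (pred.data.sum(axis=axes, dtype=np.float64)
             + t.sum(axis=axes, dtype=np.float64) + eps)
    losses = 1.0 - (2.0 * inter + eps) / denom
    out = Tensor(np.array(losses.mean()), parents=(pred,))

    def backward_fn(gy):
        shape = (nb,) + (1,) * (pred.data.ndim - 1)
        d = denom.reshape(shape)
        i2 = (2.0 * inter + eps).reshape(shape)
        g = -(2.0 * t * d - i2) / (d * d) / nb
        pred._accumulate(gy * g)

    out.backward_fn = backward_fn
    return out


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD:
    """Plain mini-batch gradient descent (kept for the lr=0 no-update contract)."""

    def __init__(self, params, lr=1e-2):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None
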