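"""Minimal 3D convolutional layers with hand-written backpropagation.

Everything operates on single samples shaped ``(channels, X, Y, Z)`` in
float32. Convolutions are evaluated as k³ slice/matmul pairs (one GEMM per
kernel offset), which keeps memory flat and runs entirely in BLAS; gradients
are the exact adjoints of the forward slices. This is deliberately a small,
deterministic substrate sized for toy-scale volumetric training on a CPU.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def _conv_out_size(n, k, s, p):
    return (n + 2 * p - k) // s + 1


class Conv3d:
    """3D convolution (cross-correlation), zero padding."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=None, rng=None,
                 init_std=0.02):
        if pad is None:
            pad = kernel // 2
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s, self.p = kernel, stride, pad
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, init_std, (c_out, c_in, kernel, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        return tuple(_conv_out_size(n, self.k, self.s, self.p) for n in in_shape)

    def forward(self, x):
        k, s, p = self.k, self.s, self.p
        c_in, c_out = self.c_in, self.c_out
        spatial = x.shape[1:]
        out_sp = self.out_shape(spatial)
        xpad = np.pad(x, ((0, 0),) + ((p, p),) * 3).astype(F32, copy=False)
        n = int(np.prod(out_sp))
        y = np.empty((c_out, n), dtype=F32)
        y[:] = self.b.value[:, None]
        Wf = self.W.value
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    xs = xpad[:, a:a + s * out_sp[0]:s,
                              bb:bb + s * out_sp[1]:s,
                              c:c + s * out_sp[2]:s].reshape(c_in, n)
                    y += Wf[:, :, a, bb, c] @ xs
        self._cache = (xpad, spatial, out_sp)
        return y.reshape((c_out,) + out_sp)

    def backward(self, dy):
        xpad, spatial, out_sp = self._cache
        k, s, p = self.k, self.s, self.p
        c_in, c_out = self.c_in, self.c_out
        n = int(np.prod(out_sp))
        dyf = dy.reshape(c_out, n).astype(F32, copy=False)
        self.b.grad += dyf.sum(axis=1)
        dxpad = np.zeros_like(xpad)
        Wf = self.W.value
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    sl = (slice(None),
                          slice(a, a + s * out_sp[0], s),
                          slice(bb, bb + s * out_sp[1], s),
                          slice(c, c + s * out_sp[2], s))
                    xs = xpad[sl].reshape(c_in, n)
                    self.W.grad[:, :, a, bb, c] += dyf @ xs.T
                    dxpad[sl] += (Wf[:, :, a, bb, c].T @ dyf).reshape(
                        (c_in,) + out_sp)
        if p:
            return dxpad[:, p:-p, p:-p, p:-p]
        return dxpad


class ConvTranspose3d:
    """Transposed 3D convolution (the adjoint of :class:`Conv3d`).

    With kernel 4 / stride 2 / pad 1 the spatial size exactly doubles; with
    kernel 3 / stride 1 / pad 1 it is preserved.
    """

    def __init__(self, c_in, c_out, kernel=4, stride=2, pad=1, rng=None,
                 init_std=0.02):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.s, self.p = kernel, stride, pad
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, init_std, (c_in, c_out, kernel, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        return tuple((n - 1) * self.s - 2 * self.p + self.k for n in in_shape)

    def forward(self, x):
        k, s, p = self.k, self.s, self.p
        c_in, c_out = self.c_in, self.c_out
        spatial = x.shape[1:]
        out_sp = self.out_shape(spatial)
        pad_sp = tuple(o + 2 * p for o in out_sp)
        ypad = np.zeros((c_out,) + pad_sp, dtype=F32)
        n = int(np.prod(spatial))
        xf = x.reshape(c_in, n).astype(F32, copy=False)
        Wf = self.W.value
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    contrib = (Wf[:, :, a, bb, c].T @ xf).reshape((c_out,) + spatial)
                    ypad[:, a:a + s * spatial[0]:s,
                         bb:bb + s * spatial[1]:s,
                         c:c + s * spatial[2]:s] += contrib
        y = ypad[:, p:p + out_sp[0], p:p + out_sp[1], p:p + out_sp[2]] \
            if p else ypad
        y = y + self.b.value[:, None, None, None]
        self._cache = (xf, spatial, out_sp, pad_sp)
        return y

    def backward(self, dy):
        xf, spatial, out_sp, pad_sp = self._cache
        k, s, p = self.k, self.s, self.p
        c_in, c_out = self.c_in, self.c_out
        self.b.grad += dy.sum(axis=(1, 2, 3))
        dypad = np.zeros((c_out,) + pad_sp, dtype=F32)
        if p:
            dypad[:, p:p + out_sp[0], p:p + out_sp[1], p:p + out_sp[2]] = dy
        else:
            dypad[...] = dy
        n = int(np.prod(spatial))
        dx = np.zeros((c_in, n), dtype=F32)
        Wf = self.W.value
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    ds = dypad[:, a:a + s * spatial[0]:s,
                               bb:bb + s * spatial[1]:s,
                               c:c + s * spatial[2]:s].reshape(c_out, n)
                    dx += Wf[:, :, a, bb, c] @ ds
                    self.W.grad[:, :, a, bb, c] += xf @ ds.T
        return dx.reshape((c_in,) + spatial)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(F32, copy=False)


class LeakyReLU:
    def __init__(self, slope=0.2):
        self.slope = F32(slope)
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(F32, copy=False)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(F32, copy=False)


class Tanh:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x):
        self._y = np.tanh(x).astype(F32, copy=False)
        return self._y

    def backward(self, dy):
        return (dy * (1.0 - self._y * self._y)).astype(F32, copy=False)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    def state_arrays(self):
        return [p.value for p in self.params()]


class Adam:
    """Adam with the CycleGAN-customary beta1 = 0.5."""

    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            p.value -= F32(self.lr) * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)
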