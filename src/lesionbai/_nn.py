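"""Minimal 3D conv-net machinery on numpy, sized for desk-scale volumes.

Implements exactly the pieces the Brain Age Network needs — 3x3x3
convolutions (stride 1 or 2), residual units with short-circuit
connections, ROI-Align pooling with trilinear interpolation, a linear
regression head, the Adam optimizer and a weighted L1 loss — each with a
hand-derived backward pass. Everything is deterministic for a fixed seed
and single-threaded numpy.

Layout convention: batched activations are (N, C, D, H, W).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "ReLU",
    "ResidualUnit",
    "Linear",
    "RoiAlign",
    "roi_align_pool",
    "Adam",
    "weighted_l1_loss",
]


class Parameter:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Conv3d:
    """k^3 convolution, padding k//2, arbitrary stride; He-initialized."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(c_out))
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        self._xpad: np.ndarray | None = None
        self._out_shape: tuple | None = None

    def parameters(self):
        return [self.weight, self.bias]

    @staticmethod
    def _out_dim(d: int, k: int, p: int, s: int) -> int:
        return (d + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p, s = self.kernel, self.pad, self.stride
        n, _, d, h, w = x.shape
        do, ho, wo = (self._out_dim(v, k, p, s) for v in (d, h, w))
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        c_out = self.weight.value.shape[0]
        out = np.zeros((n, c_out, do * ho * wo))
        wv = self.weight.value
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    xs = xpad[
                        :, :, kd : kd + s * do : s, kh : kh + s * ho : s, kw : kw + s * wo : s
                    ]
                    # (o,i) @ (n,i,V) -> (n,o,V), BLAS-backed
                    out += np.matmul(wv[:, :, kd, kh, kw], xs.reshape(n, -1, do * ho * wo))
        out = out.reshape(n, c_out, do, ho, wo)
        out += self.bias.value[None, :, None, None, None]
        self._xpad = xpad
        self._out_shape = (do, ho, wo)
        self._in_shape = (d, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, p, s = self.kernel, self.pad, self.stride
        do, ho, wo = self._out_shape
        d, h, w = self._in_shape
        xpad = self._xpad
        self.bias.grad += dout.sum(axis=(0, 2, 3, 4))
        dxpad = np.zeros_like(xpad)
        wv = self.weight.value
        n = dout.shape[0]
        v = do * ho * wo
        dout_r = dout.reshape(n, -1, v)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    sl = (
                        slice(None),
                        slice(None),
                        slice(kd, kd + s * do, s),
                        slice(kh, kh + s * ho, s),
                        slice(kw, kw + s * wo, s),
                    )
                    xs = xpad[sl]
                    ci = xs.shape[1]
                    xs_r = xs.reshape(n, ci, v)
                    # (n,o,V) x (n,V,i) summed over n -> (o,i)
                    self.weight.grad[:, :, kd, kh, kw] += np.matmul(
                        dout_r, xs_r.transpose(0, 2, 1)
                    ).sum(axis=0)
                    # (i,o) @ (n,o,V) -> (n,i,V)
                    dxpad[sl] += np.matmul(
                        wv[:, :, kd, kh, kw].T, dout_r
                    ).reshape(xs.shape)
        self._xpad = None
        if p == 0:
            return dxpad
        return dxpad[:, :, p : p + d, p : p + h, p : p + w]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def parameters(self):
        return []


class ResidualUnit:
    """conv-relu-conv with a short-circuit connection, relu after the sum.

    When the unit changes resolution (stride 2) or channel count, the
    shortcut is a 1x1x1 strided convolution; otherwise it is the identity.
    """

    def __init__(
        self, c_in: int, c_out: int, stride: int = 1, rng: np.random.Generator | None = None
    ):
        self.conv1 = Conv3d(c_in, c_out, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(c_out, c_out, 3, stride=1, rng=rng)
        self.proj = (
            Conv3d(c_in, c_out, 1, stride=stride, rng=rng)
            if (stride != 1 or c_in != c_out)
            else None
        )
        self.relu_out = ReLU()

    def parameters(self):
        ps = self.conv1.parameters() + self.conv2.parameters()
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        short = x if self.proj is None else self.proj.forward(x)
        return self.relu_out.forward(main + short)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        dmain = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        dshort = dsum if self.proj is None else self.proj.backward(dsum)
        return dmain + dshort


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_out, n_in)))
        self.bias = Parameter(np.zeros(n_out))

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


def _axis_samples(lo: float, hi: float, n_cells: int, n_samples: int) -> np.ndarray:
    """Sample coordinates: ``n_samples`` uniformly placed points per cell."""
    h = (hi - lo) / n_cells
    cells = np.arange(n_cells)[:, None]
    offs = (np.arange(n_samples)[None, :] + 0.5) / n_samples
    return (lo + (cells + offs) * h).ravel()


def _corners(coords: np.ndarray, size: int):
    c = np.clip(coords, 0.0, size - 1.0)
    lo = np.floor(c).astype(int)
    if size > 1:
        lo = np.minimum(lo, size - 2)
        hi = lo + 1
    else:
        lo = np.zeros_like(lo)
        hi = lo
    frac = c - lo
    return lo, hi, frac


def roi_align_pool(
    feature_map: np.ndarray,
    roi_box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    output_grid: tuple[int, int, int],
    samples_per_axis: int = 2,
) -> np.ndarray:
    """ROI-Align: pool an arbitrary continuous box to a fixed grid.

    ``feature_map`` is (C, D, H, W); ``roi_box`` gives per-axis continuous
    intervals in feature-map voxel coordinates (voxel centres at integers).
    Each output cell averages ``samples_per_axis**3`` trilinearly
    interpolated sample points placed uniformly inside the cell, so the
    output shape is (C,) + output_grid regardless of the box size.
    """
    fmap = np.asarray(feature_map, dtype=np.float64)
    if fmap.ndim == 3:
        fmap = fmap[None]
    c, d, h, w = fmap.shape
    (z0, z1), (y0, y1), (x0, x1) = roi_box
    if not (z1 > z0 and y1 > y0 and x1 > x0):
        raise ValueError(f"degenerate ROI box: {roi_box}")
    gz, gy, gx = output_grid
    if min(gz, gy, gx) < 1:
        raise ValueError("output grid must be positive")
    ns = samples_per_axis

    cz = _axis_samples(z0, z1, gz, ns)
    cy = _axis_samples(y0, y1, gy, ns)
    cx = _axis_samples(x0, x1, gx, ns)
    z_lo, z_hi, fz = _corners(cz, d)
    y_lo, y_hi, fy = _corners(cy, h)
    x_lo, x_hi, fx = _corners(cx, w)

    vals = np.zeros((c, cz.size, cy.size, cx.size))
    for iz, wz in ((z_lo, 1 - fz), (z_hi, fz)):
        for iy, wy in ((y_lo, 1 - fy), (y_hi, fy)):
            for ix, wx in ((x_lo, 1 - fx), (x_hi, fx)):
                weight = wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
                vals += weight * fmap[:, iz][:, :, iy][:, :, :, ix]
    pooled = vals.reshape(c, gz, ns, gy, ns, gx, ns).mean(axis=(2, 4, 6))
    return pooled if feature_map.ndim == 4 else pooled[0]


class RoiAlign:
    """Differentiable ROI-Align over a batch with per-sample boxes."""

    def __init__(self, output_grid: tuple[int, int, int], samples_per_axis: int = 2):
        self.output_grid = tuple(output_grid)
        self.ns = samples_per_axis

    def parameters(self):
        return []

    def forward(self, x: np.ndarray, boxes: list) -> np.ndarray:
        self._cache = []
        self._in_shape = x.shape
        n, c = x.shape[:2]
        gz, gy, gx = self.output_grid
        out = np.empty((n, c, gz, gy, gx))
        for i in range(n):
            out[i], cache = self._forward_one(x[i], boxes[i])
            self._cache.append(cache)
        return out

    def _forward_one(self, fmap: np.ndarray, box):
        c, d, h, w = fmap.shape
        gz, gy, gx = self.output_grid
        ns = self.ns
        (z0, z1), (y0, y1), (x0, x1) = box
        if not (z1 > z0 and y1 > y0 and x1 > x0):
            raise ValueError(f"degenerate ROI box: {box}")
        cz = _axis_samples(z0, z1, gz, ns)
        cy = _axis_samples(y0, y1, gy, ns)
        cx = _axis_samples(x0, x1, gx, ns)
        z_lo, z_hi, fz = _corners(cz, d)
        y_lo, y_hi, fy = _corners(cy, h)
        x_lo, x_hi, fx = _corners(cx, w)
        corners = []
        vals = np.zeros((c, cz.size, cy.size, cx.size))
        for iz, wz in ((z_lo, 1 - fz), (z_hi, fz)):
            for iy, wy in ((y_lo, 1 - fy), (y_hi, fy)):
                for ix, wx in ((x_lo, 1 - fx), (x_hi, fx)):
                    weight = wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
                    vals += weight * fmap[:, iz][:, :, iy][:, :, :, ix]
                    corners.append((iz, iy, ix, weight))
        pooled = vals.reshape(c, gz, ns, gy, ns, gx, ns).mean(axis=(2, 4, 6))
        return pooled, corners

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        gz, gy, gx = self.output_grid
        ns = self.ns
        dx = np.zeros(self._in_shape)
        scale = 1.0 / ns**3
        for i in range(n):
            # spread each cell gradient evenly over its sample points
            dsamp = (
                np.repeat(np.repeat(np.repeat(dout[i], ns, 1), ns, 2), ns, 3) * scale
            )
            flat = dx[i].reshape(c, -1)
            for iz, iy, ix, weight in self._cache[i]:
                zz, yy, xx = np.meshgrid(iz, iy, ix, indexing="ij")
                idx = (zz * h + yy) * w + xx
                contrib = weight * dsamp
                for ch in range(c):
                    np.add.at(flat[ch], idx.ravel(), contrib[ch].ravel())
        self._cache = None
        return dx


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weighted_l1_loss(
    pred: np.ndarray, target: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean of w_i * |pred_i - target_i| and its gradient wrt pred."""
    resid = pred - target
    loss = float(np.mean(weights * np.abs(resid)))
    grad = weights * np.sign(resid) / pred.size
    return loss, grad
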