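"""Minimal numpy implementation of the convolutional regressor.

Layers: stacked (1-D convolution → ReLU → non-overlapping max-pool) blocks
over the one-hot sequence, flatten, concatenation with the half-life and
miRNA feature blocks, one ReLU dense layer with optional dropout, and a
linear output unit.  Gradients are computed by hand; the optimiser is plain
stochastic gradient descent (optional momentum, off by default).

Everything is float32 and driven by a caller-supplied ``numpy`` Generator,
so training is bit-reproducible for a fixed seed on a given platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Net", "SGD"]


def _im2col(x: np.ndarray, kernel: int, dilation: int) -> np.ndarray:
    """(B, L, C) → (B, L_out, kernel*C) patch matrix for a valid, dilated
    1-D convolution."""
    B, L, C = x.shape
    L_out = L - (kernel - 1) * dilation
    cols = np.empty((B, L_out, kernel * C), dtype=x.dtype)
    for j in range(kernel):
        cols[:, :, j * C : (j + 1) * C] = x[:, j * dilation : j * dilation + L_out, :]
    return cols


def _col2im(dcols: np.ndarray, L: int, C: int, kernel: int, dilation: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    B, L_out, _ = dcols.shape
    dx = np.zeros((B, L, C), dtype=dcols.dtype)
    for j in range(kernel):
        dx[:, j * dilation : j * dilation + L_out, :] += dcols[:, :, j * C : (j + 1) * C]
    return dx


class Net:
    """The network: conv blocks + feature concatenation + dense head.

    Parameters are stored in ``self.params`` (a flat list of arrays) in a
    fixed order so the optimiser and best-epoch snapshots can treat them
    uniformly.
    """

    def __init__(self, window, conv_blocks, dense_units, dropout, k_mirnas, rng):
        self.conv_blocks = [tuple(b) for b in conv_blocks]
        self.dropout = float(dropout)
        self.k_mirnas = int(k_mirnas)
        self.params: list[np.ndarray] = []

        L, C = int(window), 4
        self._conv_params = []
        for filters, kernel, dilation, pool in self.conv_blocks:
            L_conv = L - (kernel - 1) * dilation
            if L_conv < 1:
                raise ValueError(
                    f"conv kernel {kernel} (dilation {dilation}) does not fit in length {L}"
                )
            L_pool = L_conv // pool
            if L_pool < 1:
                raise ValueError(f"pool width {pool} exceeds conv output length {L_conv}")
            fan_in = kernel * C
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters)).astype(np.float32)
            b = np.zeros(filters, dtype=np.float32)
            self.params += [W, b]
            self._conv_params.append((len(self.params) - 2, L, C, L_conv, L_pool))
            L, C = L_pool, filters
        self.flat_dim = L * C
        self.concat_dim = self.flat_dim + 8 + self.k_mirnas

        Wd = rng.normal(0.0, np.sqrt(2.0 / self.concat_dim), size=(self.concat_dim, dense_units)).astype(np.float32)
        bd = np.zeros(dense_units, dtype=np.float32)
        Wo = rng.normal(0.0, np.sqrt(1.0 / dense_units), size=(dense_units, 1)).astype(np.float32)
        bo = np.zeros(1, dtype=np.float32)
        self._dense_idx = len(self.params)
        self.params += [Wd, bd, Wo, bo]

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def restore(self, snapshot) -> None:
        for p, s in zip(self.params, snapshot):
            p[...] = s

    def im2col_first(self, X: np.ndarray) -> np.ndarray:
        """Precompute the first conv block's patch matrix for a whole input
        array (the one-hot input never changes, so this is reusable across
        epochs)."""
        kernel, dilation = self.conv_blocks[0][1], self.conv_blocks[0][2]
        return _im2col(np.ascontiguousarray(X, dtype=np.float32), kernel, dilation)

    # -- forward / backward --------------------------------------------

    def forward(self, X, H, M, *, train=False, rng=None, cols_first=None):
        """Return (predictions, cache).  ``cols_first`` optionally supplies
        the precomputed first-block patch matrix for this batch."""
        cache = {"conv": [], "train": train}
        a = np.ascontiguousarray(X, dtype=np.float32)
        for i, (filters, kernel, dilation, pool) in enumerate(self.conv_blocks):
            pi, L_in, C_in, L_conv, L_pool = self._conv_params[i]
            W, b = self.params[pi], self.params[pi + 1]
            cols = cols_first if (i == 0 and cols_first is not None) else _im2col(a, kernel, dilation)
            z = cols @ W + b
            relu_mask = z > 0
            z *= relu_mask
            trimmed = z[:, : L_pool * pool, :].reshape(z.shape[0], L_pool, pool, filters)
            arg = trimmed.argmax(axis=2)
            pooled = np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :]
            cache["conv"].append((cols, relu_mask, arg, L_in, C_in, L_conv, L_pool, pool))
            a = pooled
        flat = a.reshape(a.shape[0], self.flat_dim)
        h = np.concatenate(
            [flat, np.asarray(H, np.float32), np.asarray(M, np.float32).reshape(len(flat), self.k_mirnas)],
            axis=1,
        )
        Wd, bd, Wo, bo = self.params[self._dense_idx : self._dense_idx + 4]
        z1 = h @ Wd + bd
        mask1 = z1 > 0
        a1 = z1 * mask1
        if train and self.dropout > 0.0:
            keep = (rng.random(a1.shape) >= self.dropout).astype(np.float32) / (1.0 - self.dropout)
            a1 = a1 * keep
            cache["drop"] = keep
        out = (a1 @ Wo + bo)[:, 0]
        cache.update(h=h, mask1=mask1, a1=a1)
        return out, cache

    def backward(self, cache, dout):
        """Gradient of the scalar loss w.r.t. every parameter given
        d(loss)/d(predictions).  The gradient w.r.t. the one-hot input is
        never needed and is not computed for the first conv block."""
        grads = [np.zeros_like(p) for p in self.params]
        Wd, bd, Wo, bo = self.params[self._dense_idx : self._dense_idx + 4]
        a1, h, mask1 = cache["a1"], cache["h"], cache["mask1"]
        d_out = dout[:, None].astype(np.float32)
        grads[self._dense_idx + 2] = a1.T @ d_out
        grads[self._dense_idx + 3] = d_out.sum(axis=0)
        da1 = d_out @ Wo.T
        if cache["train"] and "drop" in cache:
            da1 *= cache["drop"]
        dz1 = da1 * mask1
        grads[self._dense_idx] = h.T @ dz1
        grads[self._dense_idx + 1] = dz1.sum(axis=0)
        dh = dz1 @ Wd.T
        dflat = dh[:, : self.flat_dim]

        filters_last = self.conv_blocks[-1][0]
        da = dflat.reshape(dflat.shape[0], -1, filters_last)
        for i in range(len(self.conv_blocks) - 1, -1, -1):
            filters, kernel, dilation, pool = self.conv_blocks[i]
            pi, L_in, C_in, L_conv, L_pool, = self._conv_params[i]
            cols, relu_mask, arg, *_ = cache["conv"][i]
            # un-pool: route each pooled gradient to its argmax position
            dtrim = np.zeros((da.shape[0], L_pool, pool, filters), dtype=np.float32)
            np.put_along_axis(dtrim, arg[:, :, None, :], da[:, :, None, :], axis=2)
            dz = np.zeros((da.shape[0], L_conv, filters), dtype=np.float32)
            dz[:, : L_pool * pool, :] = dtrim.reshape(da.shape[0], L_pool * pool, filters)
            dz *= relu_mask
            W = self.params[pi]
            flat_cols = cols.reshape(-1, cols.shape[-1])
            grads[pi] = flat_cols.T @ dz.reshape(-1, filters)
            grads[pi + 1] = dz.sum(axis=(0, 1))
            if i > 0:
                dcols = dz @ W.T
                da = _col2im(dcols, L_in, C_in, kernel, dilation)
        return grads


class SGD:
    """Plain stochastic gradient descent with optional classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p) for p in params] if momentum else None

    def step(self, grads) -> None:
        if self._velocity is None:
            for p, g in zip(self.params, grads):
                p -= self.lr * g
        else:
            for p, g, v in zip(self.params, grads, self._velocity):
                v *= self.momentum
                v -= self.lr * g
                p += v
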