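"""Spatial group-wise enhancement: attention gating per channel group.

The block splits channels into groups.  For each group it pools a global
descriptor ``g`` (spatial average), takes the position-wise inner product
of ``g`` with the group's features to score how similar each location is
to the group semantic, standardizes that score map over spatial positions
(zero mean, unit variance, ε-guarded), applies a per-group learnable
affine, gates through a sigmoid, and multiplies the gate back into the
original group features.  Output shape always equals input shape, and the
block carries exactly 2 parameters per group (the affine scale and shift).

At the initialization used here (scale=0, shift=1) the standardized term
is annihilated and the block reduces to multiplication by sigmoid(1) —
near-neutral, and exactly computable for testing.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .layers import Layer, Param

__all__ = ["SGEBlock", "sge_forward"]

_EPS = 1e-5


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sge_forward(x: np.ndarray, groups: int, scale: np.ndarray,
                shift: np.ndarray, eps: float = _EPS):
    """Functional forward pass; returns (y, cache for backward)."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channel count {c} not divisible by {groups} groups")
    cg, p = c // groups, h * w
    xg = x.reshape(n, groups, cg, p)
    g = xg.mean(axis=-1)                                   # (n, G, cg)
    raw = np.einsum("ngc,ngcp->ngp", g, xg, optimize=True)  # attention map
    mu = raw.mean(axis=-1, keepdims=True)
    var = raw.var(axis=-1, keepdims=True)
    istd = 1.0 / np.sqrt(var + eps)
    norm = (raw - mu) * istd
    act = scale[None, :, None] * norm + shift[None, :, None]
    gate = _sigmoid(act)
    y = (xg * gate[:, :, None, :]).reshape(n, c, h, w)
    cache = (xg, g, norm, istd, gate, groups)
    return y, cache


def sge_backward(dy: np.ndarray, cache, scale: np.ndarray):
    """Gradients of the functional forward; returns (dx, dscale, dshift)."""
    xg, g, norm, istd, gate, groups = cache
    n, G, cg, p = xg.shape
    dyg = dy.reshape(n, G, cg, p)
    dxg = dyg * gate[:, :, None, :]
    dgate = np.einsum("ngcp,ngcp->ngp", dyg, xg, optimize=True)
    dact = dgate * gate * (1.0 - gate)
    dscale = (dact * norm).sum(axis=(0, 2))
    dshift = dact.sum(axis=(0, 2))
    dnorm = dact * scale[None, :, None]
    # standardization backward over the spatial axis
    draw = istd * (dnorm
                   - dnorm.mean(axis=-1, keepdims=True)
                   - norm * (dnorm * norm).mean(axis=-1, keepdims=True))
    dg = np.einsum("ngp,ngcp->ngc", draw, xg, optimize=True)
    dxg = dxg + draw[:, :, None, :] * g[:, :, :, None]
    dxg += dg[:, :, :, None] / p
    dx = dxg.reshape(dy.shape)
    return dx, dscale, dshift


class SGEBlock(Layer):
    """Layer wrapper; affine initialized to (scale=0, shift=1)."""

    def __init__(self, channels: int, groups: int, eps: float = _EPS,
                 name: str = "sge"):
        if channels % groups:
            raise ValueError(
                f"channel count {channels} not divisible by {groups} groups")
        self.channels = channels
        self.groups = groups
        self.eps = eps
        self.scale = Param(f"{name}.scale", np.zeros(groups))
        self.shift = Param(f"{name}.shift", np.ones(groups))

    def params(self) -> List[Param]:
        return [self.scale, self.shift]

    def forward(self, x, train=True):
        y, self._cache = sge_forward(x, self.groups, self.scale.data,
                                     self.shift.data, self.eps)
        return y

    def backward(self, dy):
        dx, dscale, dshift = sge_backward(dy, self._cache, self.scale.data)
        self.scale.grad += dscale
        self.shift.grad += dshift
        self._cache = None
        return dx
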