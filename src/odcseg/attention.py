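"""Convolutional triple attention (CTAM): cross-dimensional attention weights.

Three parallel branches each compress one tensor dimension with Z-pool
(stacked max and mean), pass the 2-slice summary through a small conv +
batch-norm + sigmoid stack, and multiply the resulting attention weights
back onto the (rotated) input.  Two branches capture channel↔height and
channel↔width interactions by permuting the tensor before pooling; the
third is plain spatial attention.  The refined output is the average of the
three branch outputs and always has the shape of the input, so the module
can be dropped into any point of a network — here, the U-Net bottleneck.

"Rotation 90° along the H (or W) axis" is realized as a dimension
permutation (C↔W, resp. C↔H) so Z-pool always reduces the leading feature
dimension; the inverse permutation restores orientation.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor, as_tensor, stack

__all__ = ["z_pool", "CTAM"]

Rotation = Literal["h", "w", "none"]

# batched NCHW permutations realizing each branch's rotation
_PERM = {"h": (0, 3, 2, 1), "w": (0, 2, 1, 3), "none": (0, 1, 2, 3)}


def z_pool(t: Tensor | np.ndarray, axis: int = 0) -> Tensor:
    """Compress `axis` to size 2: slice 0 = max, slice 1 = mean over the axis."""
    t = as_tensor(t)
    return stack([t.max(axis=axis), t.mean(axis=axis)], axis=axis)


class CTAM(Module):
    """Triple attention operator on (C, H, W) or batched (N, C, H, W) tensors.

    Parameters
    ----------
    kernel_size : spatial size of the per-branch conv (2 -> 1 channels);
        7 with padding 3 keeps shapes and matches the cited triplet-attention
        design.
    """

    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        pad = kernel_size // 2
        self.conv_h = Conv2d(2, 1, kernel_size, padding=pad, bias=False, rng=rng)
        self.conv_w = Conv2d(2, 1, kernel_size, padding=pad, bias=False, rng=rng)
        self.conv_s = Conv2d(2, 1, kernel_size, padding=pad, bias=False, rng=rng)
        self.bn_h = BatchNorm2d(1)
        self.bn_w = BatchNorm2d(1)
        self.bn_s = BatchNorm2d(1)

    def _branch_ops(self, rotation: Rotation) -> tuple[Conv2d, BatchNorm2d]:
        return {
            "h": (self.conv_h, self.bn_h),
            "w": (self.conv_w, self.bn_w),
            "none": (self.conv_s, self.bn_s),
        }[rotation]

    def branch_attention(self, t: Tensor | np.ndarray, rotation: Rotation,
                         weight_override: float | None = None) -> Tensor:
        """One branch: rotate, Z-pool, conv+BN+sigmoid weights, re-weight,
        rotate back.  `weight_override` replaces the computed attention map
        by a constant (used to probe the identity limit)."""
        t, squeeze = self._batched(t)
        perm = _PERM[rotation]
        rot = t.transpose(perm) if rotation != "none" else t
        if weight_override is None:
            pooled = z_pool(rot, axis=1)
            conv, bn = self._branch_ops(rotation)
            weights = bn(conv(pooled)).sigmoid()  # (N, 1, d1, d2)
            out = rot * weights
        elif weight_override == 1.0:
            out = rot  # exact identity: skip the multiply entirely
        else:
            out = rot * weight_override
        out = out.transpose(perm) if rotation != "none" else out  # perms are involutions
        return out[0] if squeeze else out

    def forward(self, t: Tensor | np.ndarray,
                weight_override: float | None = None) -> Tensor:
        """Average of the three branch outputs, same shape as the input."""
        t, squeeze = self._batched(t)
        b1 = self.branch_attention(t, "h", weight_override)
        b2 = self.branch_attention(t, "w", weight_override)
        b3 = self.branch_attention(t, "none", weight_override)
        # anchored mean == (b1+b2+b3)/3 algebraically, but returns the input
        # bit-exactly when all three branches are identities
        y = b2 + ((b1 - b2) + (b3 - b2)) * (1.0 / 3.0)
        return y[0] if squeeze else y

    @staticmethod
    def _batched(t: Tensor | np.ndarray) -> tuple[Tensor, bool]:
        t = as_tensor(t)
        if t.ndim == 3:
            return t.reshape(1, *t.shape), True
        if t.ndim != 4:
            raise ValueError("CTAM expects a (C,H,W) or (N,C,H,W) tensor")
        return t, False
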