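"""Sub-networks of the unsupervised domain-adaptation segmentation framework.

The framework couples a content/style image-translation model with a
segmentation model:

* a shared content encoder ``EC`` mapping images of either domain into a
  common content space (feature maps at 1/4 resolution),
* a style encoder ``ES`` producing a fixed-length style code per image,
* a shared decoder ``G`` that recombines content and style into an image,
* two patch discriminators ``D1``/``D2`` judging translated images against
  real target/source images,
* a U-Net segmenter that consumes *content features* directly — because the
  content space already sits at 1/4 resolution, the first two downsampling
  stages of a standard U-Net are dropped — with triple attention (CTAM) at
  the bottleneck,
* a patch discriminator ``D`` on segmentation probability maps that aligns
  the output space of the two domains.

All discriminators emit sigmoid patch-score maps in (0, 1); higher means
"judged real".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .attention import CTAM
from .nn import Tensor, as_tensor, concatenate, upsample_nearest

__all__ = ["NetworkConfig", "SegOutput", "DomainAdaptationModel"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    base_channels scales every sub-network; content features live at
    ``base_channels * 4`` channels and 1/2**content_downsamples resolution.
    """

    image_size: int = 256
    base_channels: int = 16
    content_downsamples: int = 2
    style_dim: int = 8
    unet_depth: int = 4
    num_classes: int = 3
    ctam_kernel_size: int = 7

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.unet_depth < 2:
            raise ValueError("unet_depth must be >= 2")
        if min(self.image_size, self.base_channels, self.style_dim) < 1:
            raise ValueError("all counts must be positive")

    @property
    def content_channels(self) -> int:
        return self.base_channels * 2 ** self.content_downsamples

    @property
    def content_size(self) -> int:
        return self.image_size // 2 ** self.content_downsamples


@dataclass
class SegOutput:
    """Segmentation logits and their per-pixel softmax."""

    logits: Tensor
    probs: Tensor = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.probs is None:
            self.probs = self.logits.softmax(axis=1)


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, rng, stride=1):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class _ResBlock(nn.Module):
    def __init__(self, c, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(c, c, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(c)
        self.conv2 = nn.Conv2d(c, c, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(c)

    def forward(self, x, film: tuple[Tensor, Tensor] | None = None):
        h = self.bn1(self.conv1(x)).relu()
        if film is not None:
            gamma, beta = film
            h = h * (gamma + 1.0) + beta
        h = self.bn2(self.conv2(h))
        return (x + h).relu()


class ContentEncoder(nn.Module):
    """Conv stem + strided downsamples + residual blocks -> shared content space."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        b = cfg.base_channels
        self.stem = nn.Conv2d(3, b, 7, padding=3, rng=rng)
        downs = []
        c = b
        for _ in range(cfg.content_downsamples):
            downs.append(_ConvBlock(c, c * 2, rng, stride=2))
            c *= 2
        self.downs = nn.ModuleList(downs)
        self.res = nn.ModuleList([_ResBlock(c, rng) for _ in range(2)])

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x).relu()
        for d in self.downs:
            h = d(h)
        for r in self.res:
            h = r(h)
        return h


class StyleEncoder(nn.Module):
    """Conv stem + global pooling + linear head -> fixed-length style code."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        b = cfg.base_channels
        self.stem = nn.Conv2d(3, b, 7, padding=3, rng=rng)
        self.down1 = nn.Conv2d(b, 2 * b, 3, stride=2, padding=1, rng=rng)
        self.down2 = nn.Conv2d(2 * b, 2 * b, 3, stride=2, padding=1, rng=rng)
        self.head = nn.Linear(2 * b, cfg.style_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x).relu()
        h = self.down1(h).relu()
        h = self.down2(h).relu()
        return self.head(h.mean(axis=(2, 3)))


class Decoder(nn.Module):
    """Residual blocks with style injection (FiLM) + upsampling -> image."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        c = cfg.content_channels
        self.res1 = _ResBlock(c, rng)
        self.res2 = _ResBlock(c, rng)
        self.film = nn.Linear(cfg.style_dim, 4 * c, rng=rng)
        ups = []
        for _ in range(cfg.content_downsamples):
            ups.append(_ConvBlock(c, c // 2, rng))
            c //= 2
        self.ups = nn.ModuleList(ups)
        self.out = nn.Conv2d(c, 3, 7, padding=3, rng=rng)

    def forward(self, content: Tensor, style: Tensor) -> Tensor:
        n = content.shape[0]
        c = content.shape[1]
        film = self.film(style).reshape(n, 4 * c, 1, 1)
        h = self.res1(content, film=(film[:, :c], film[:, c:2 * c]))
        h = self.res2(h, film=(film[:, 2 * c:3 * c], film[:, 3 * c:]))
        for up in self.ups:
            h = up(upsample_nearest(h, 2))
        return self.out(h).tanh()


class UNetSegmenter(nn.Module):
    """U-Net over content features; its first two downsampling stages are
    dropped since the content space is already at 1/4 image resolution.
    CTAM refines the bottleneck tensor."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        cin = cfg.content_channels
        depth = cfg.unet_depth - cfg.content_downsamples  # stages kept
        if depth != 2:
            raise ValueError(
                "this U-Net keeps exactly 2 downsampling stages after the "
                "removed ones; set unet_depth = content_downsamples + 2")
        c_mid = cin * 2
        self.enc0 = _ConvBlock(cin, cin, rng)
        self.down1 = _ConvBlock(cin, c_mid, rng, stride=2)
        self.enc1 = _ConvBlock(c_mid, c_mid, rng)
        self.down2 = _ConvBlock(c_mid, c_mid, rng, stride=2)
        self.bottleneck = _ConvBlock(c_mid, c_mid, rng)
        self.ctam = CTAM(cfg.ctam_kernel_size, rng=rng)
        self.ctam_enabled = True
        self.up2 = _ConvBlock(c_mid, c_mid, rng)
        self.dec1 = _ConvBlock(2 * c_mid, c_mid, rng)
        self.up1 = _ConvBlock(c_mid, cin, rng)
        self.dec0 = _ConvBlock(2 * cin, cin, rng)
        self.head = nn.Conv2d(cin, cfg.num_classes, 1, rng=rng)
        self.upscale = 2 ** cfg.content_downsamples

    def forward(self, content: Tensor) -> SegOutput:
        e0 = self.enc0(content)
        e1 = self.enc1(self.down1(e0))
        b = self.bottleneck(self.down2(e1))
        if self.ctam_enabled:
            b = self.ctam(b)
        d1 = self.dec1(concatenate([self.up2(upsample_nearest(b, 2)), e1], axis=1))
        d0 = self.dec0(concatenate([self.up1(upsample_nearest(d1, 2)), e0], axis=1))
        logits = upsample_nearest(self.head(d0), self.upscale)
        return SegOutput(logits=logits)


class PatchDiscriminator(nn.Module):
    """Strided conv stack -> sigmoid patch-score map of shape (m, n)."""

    def __init__(self, in_channels: int, base: int, rng):
        super().__init__()
        self.c1 = nn.Conv2d(in_channels, base, 4, stride=2, padding=1, rng=rng)
        self.c2 = nn.Conv2d(base, 2 * base, 4, stride=2, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(2 * base)
        self.c3 = nn.Conv2d(2 * base, 4 * base, 4, stride=2, padding=1, rng=rng)
        self.bn3 = nn.BatchNorm2d(4 * base)
        self.c4 = nn.Conv2d(4 * base, 1, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).leaky_relu(0.2)
        h = self.bn2(self.c2(h)).leaky_relu(0.2)
        h = self.bn3(self.c3(h)).leaky_relu(0.2)
        return self.c4(h).sigmoid()


class DomainAdaptationModel(nn.Module):
    """All trainable sub-networks, keyed by role for checkpointing."""

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(seed)
        b = cfg.base_channels
        self.content_encoder = ContentEncoder(cfg, rng)
        self.style_encoder = StyleEncoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.disc_target = PatchDiscriminator(3, b, rng)   # D1: xt vs xs->t
        self.disc_source = PatchDiscriminator(3, b, rng)   # D2: xs vs xt->s
        self.segmenter = UNetSegmenter(cfg, rng)
        self.disc_seg = PatchDiscriminator(cfg.num_classes, b, rng)

    # -- operations ------------------------------------------------------------

    def _check_image(self, image: Tensor) -> Tensor:
        image = as_tensor(image)
        if image.ndim == 3:
            image = image.reshape(1, *image.shape)
        s = self.cfg.image_size
        if image.shape[1:] != (3, s, s):
            raise ValueError(f"expected (N, 3, {s}, {s}) image, got {image.shape}")
        return image

    def encode(self, image: Tensor) -> tuple[Tensor, Tensor]:
        """Image -> (content features, style code)."""
        image = self._check_image(image)
        return self.content_encoder(image), self.style_encoder(image)

    def decode(self, content: Tensor, style: Tensor) -> Tensor:
        """(content, style) -> image in [-1, 1]."""
        content, style = as_tensor(content), as_tensor(style)
        if content.shape[1] != self.cfg.content_channels:
            raise ValueError("content feature channel mismatch")
        if style.shape[-1] != self.cfg.style_dim:
            raise ValueError("style code length mismatch")
        return self.decoder(content, style)

    def segment(self, content: Tensor) -> SegOutput:
        """Content features -> per-class logits/probabilities at image size."""
        return self.segmenter(as_tensor(content))

    def discriminate_image(self, image: Tensor, which: str) -> Tensor:
        """Patch scores from the source-side (D2) or target-side (D1) critic."""
        image = self._check_image(image)
        if which in ("target", "target-side"):
            return self.disc_target(image)[:, 0]
        if which in ("source", "source-side"):
            return self.disc_source(image)[:, 0]
        raise ValueError(f"unknown discriminator side {which!r}")

    def discriminate_segmap(self, probs: Tensor) -> Tensor:
        """Patch scores in (0,1) for a segmentation probability map."""
        probs = as_tensor(probs)
        if probs.ndim == 3:
            probs = probs.reshape(1, *probs.shape)
        return self.disc_seg(probs)[:, 0]

    # -- checkpointing ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})
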