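"""Loss terms of the translation + segmentation framework.

Conventions
-----------
* Every function returns a *minimization* objective.  Adversarial terms that
  the original objectives maximize (discriminator log-likelihoods, the
  segmenter's adversarial confusion term) are therefore returned negated;
  their docstrings state the raw form.
* Expectations over batches / patches are batch means for the image-level
  GAN terms; the segmentation-map discriminator terms are patchwise sums.
* Scores entering a log are clamped to (eps, 1-eps), eps = 1e-7, so every
  loss is finite for any input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "TranslationBatch",
    "recon_loss_image",
    "recon_loss_content",
    "recon_loss_style",
    "gan_loss_translation",
    "total_translation_loss",
    "seg_ce_loss",
    "seg_disc_loss",
    "seg_adv_loss",
    "total_seg_loss",
    "grand_total",
]

EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights of the three loss totals.

    mu1..mu4 weight image / content / style reconstruction and the image
    GAN terms of the translation total; delta1/delta2 weight segmentation
    cross-entropy and output-space adversarial alignment; rho1/rho2 weight
    the segmentation total and the shape-constraint total in the grand
    total.  rho2 = 1.0 is the sweet spot of the shape-constraint weight
    sweep and the default.
    """

    mu1: float = 10.0
    mu2: float = 1.0
    mu3: float = 1.0
    mu4: float = 1.0
    delta1: float = 1.0
    delta2: float = 0.01
    rho1: float = 1.0
    rho2: float = 1.0

    def __post_init__(self):
        for name in ("mu1", "mu2", "mu3", "mu4", "delta1", "delta2", "rho1", "rho2"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be non-negative")


@dataclass
class TranslationBatch:
    """All roles of one translation step.

    xs/xt are source/target images; cs/ct and ss/st their content features
    and style codes; xs_t/xt_s the cross-translations, xs_s/xt_t the
    within-domain reconstructions; *_rec are latents re-encoded from the
    cross-translated images (used by the latent reconstruction terms).
    """

    xs: Tensor
    xt: Tensor
    cs: Tensor
    ct: Tensor
    ss: Tensor
    st: Tensor
    xs_t: Tensor
    xt_s: Tensor
    xs_s: Tensor
    xt_t: Tensor
    cs_rec: Tensor
    ct_rec: Tensor
    ss_rec: Tensor
    st_rec: Tensor


def _l1(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a - b).abs().mean()


def recon_loss_image(x, x_rec) -> Tensor:
    """Mean absolute (L1) reconstruction error between an image and its
    decode(encode(.)) reconstruction."""
    return _l1(x, x_rec)


def recon_loss_content(c, c_rec) -> Tensor:
    """L1 error between content features and their re-encoded counterpart."""
    return _l1(c, c_rec)


def recon_loss_style(s, s_rec) -> Tensor:
    """L1 error between a style code and its re-encoded counterpart."""
    return _l1(s, s_rec)


def _clamped_log(scores) -> Tensor:
    return as_tensor(scores).clamp(EPS, 1.0 - EPS).log()


def gan_loss_translation(real_scores, fake_scores, role: str = "discriminator") -> Tensor:
    """Image-translation GAN loss on sigmoid patch scores.

    role="discriminator": minimization form of the raw objective
    E[log D(real)] + E[log(1 - D(fake))], i.e. its negation.
    role="generator": non-saturating generator loss -E[log D(fake)]
    (real_scores is ignored and may be None).
    """
    if role == "discriminator":
        raw = _clamped_log(real_scores).mean() + _clamped_log(1.0 - as_tensor(fake_scores)).mean()
        return -raw
    if role == "generator":
        return -_clamped_log(fake_scores).mean()
    raise ValueError(f"unknown role {role!r}")


def total_translation_loss(batch: TranslationBatch, weights: LossWeights,
                           scores: Mapping[str, Tensor],
                           role: str = "generator") -> Tensor:
    """Weighted translation total:

    mu1 (image recon, both domains) + mu2 (content recon) + mu3 (style
    recon) + mu4 (both image GAN terms).

    `scores` supplies the discriminator patch scores: keys "real_target",
    "fake_target" (D1 on xt and xs->t) and "real_source", "fake_source"
    (D2 on xs and xt->s); with role="generator" only the fake scores are
    used (non-saturating form).
    """
    rec_img = recon_loss_image(batch.xs, batch.xs_s) + recon_loss_image(batch.xt, batch.xt_t)
    rec_c = recon_loss_content(batch.cs, batch.cs_rec) + recon_loss_content(batch.ct, batch.ct_rec)
    rec_s = recon_loss_style(batch.ss, batch.ss_rec) + recon_loss_style(batch.st, batch.st_rec)
    adv = (gan_loss_translation(scores.get("real_target"), scores["fake_target"], role)
           + gan_loss_translation(scores.get("real_source"), scores["fake_source"], role))
    return (weights.mu1 * rec_img + weights.mu2 * rec_c
            + weights.mu3 * rec_s + weights.mu4 * adv)


def seg_ce_loss(y_true, y_prob, reduction: str = "sum") -> Tensor:
    """Cross-entropy -sum y log y' between a one-hot label tensor and
    predicted class probabilities (any layout, shapes must match).

    reduction="sum" is the raw summed form; "mean" divides by the pixel
    count (the total one-hot mass), decoupling the scale from image size.
    """
    y_true, y_prob = as_tensor(y_true), as_tensor(y_prob)
    if y_true.shape != y_prob.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_prob.shape}")
    ce = -(y_true * _clamped_log(y_prob)).sum()
    if reduction == "sum":
        return ce
    if reduction == "mean":
        return ce / float(y_true.data.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def seg_disc_loss(scores_src, scores_tgt) -> Tensor:
    """Segmentation-map discriminator loss (minimization form).

    Raw objective (maximized by D): sum_{m,n} log D(ys')(m,n)
    + log(1 - D(yt')(m,n)); the negation is returned.
    """
    raw = _clamped_log(scores_src).sum() + _clamped_log(1.0 - as_tensor(scores_tgt)).sum()
    return -raw


def seg_adv_loss(scores_tgt) -> Tensor:
    """Adversarial confusion term for target-domain segmentations
    (minimization form of the raw sum_{m,n} log D(yt')(m,n))."""
    return -_clamped_log(scores_tgt).sum()


def total_seg_loss(ce, adv, weights: LossWeights) -> Tensor:
    """delta1 * cross-entropy + delta2 * adversarial term."""
    return weights.delta1 * as_tensor(ce) + weights.delta2 * as_tensor(adv)


def grand_total(trans_total, seg_total, shape_total, weights: LossWeights) -> Tensor:
    """Translation total + rho1 * segmentation total + rho2 * shape total."""
    return (as_tensor(trans_total) + weights.rho1 * as_tensor(seg_total)
            + weights.rho2 * as_tensor(shape_total))
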