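"""Shape-constrained (circularity) loss for joint optic disc / cup segmentation.

The optic disc and cup are anatomically close to circles.  For a perfect
circle every contour point lies at the same distance from the contour
centroid, so the normalized spread of contour-to-centroid distances is a
natural, scale-free penalty on malformed segmentations:

    L_region = (1/k) * sum_i (E_i - m)^2 / m^2

where ``E_i`` is the distance of the i-th contour point to the contour
centroid, ``m`` the mean distance and ``k`` the number of contour points.
The total loss is the sum of the cup term and the disc term; it is zero
exactly when both contours are circles, invariant to translation and scale,
and grows with eccentricity.

Two evaluation paths are provided:

* :func:`shape_loss_hard` — operates on integer label maps via explicit
  contour extraction; used for evaluation and as the reference.
* :func:`shape_loss_soft` — a differentiable surrogate on per-class
  probability maps for use during training.  The contour indicator is the
  morphological inner boundary ``p - minpool3x3(p)`` and all radial
  statistics are boundary-weight weighted, so on a one-hot input the soft
  loss coincides with the hard loss on the same region (up to connected-
  component selection, which only differs for fragmented regions).

Label-map convention: 0 = background, 1 = disc ring (neuroretinal rim),
2 = cup.  The disc REGION is the union of classes 1 and 2; the cup region
is class 2 alone.  Coordinates are (row, col), 0-based, pixel centers at
integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .nn import Tensor, as_tensor, minimum

__all__ = [
    "DegenerateRegionError",
    "ShapeLossConfig",
    "ContourSet",
    "Centroid",
    "RadialProfile",
    "ShapeLossValue",
    "extract_region_contours",
    "centroid",
    "radial_profile",
    "circularity_term",
    "shape_loss_hard",
    "shape_loss_soft",
    "shape_loss_total",
]

CUP_CLASS = 2
DISC_CLASSES = (1, 2)

_S8 = np.ones((3, 3), dtype=bool)  # 8-connected structuring element


class DegenerateRegionError(ValueError):
    """Raised when a region is empty or its contour carries no information."""


@dataclass(frozen=True)
class ShapeLossConfig:
    """Knobs of the circularity loss.

    normalization
        "scale_free" (default): (1/k) * sum dev / m**2 — dimensionless and
        independent of contour sampling density.
        "printed": sum dev / m — the raw unnormalized-count form.
    deviation
        "squared" (default) uses (E_i - m)^2; "absolute" uses |E_i - m|
        (with m instead of m^2 in the scale-free denominator so the term
        stays dimensionless).
    degenerate_penalty
        Constant returned (with zero gradient in the soft path) when a
        region is empty or has no usable contour; early in training the
        segmenter frequently predicts no cup at all.
    mass_fraction_threshold
        A soft region whose probability mass or boundary mass is below this
        fraction of the image area is treated as degenerate.
    """

    normalization: Literal["scale_free", "printed"] = "scale_free"
    deviation: Literal["squared", "absolute"] = "squared"
    degenerate_penalty: float = 10.0
    mass_fraction_threshold: float = 1e-6


DEFAULT_CONFIG = ShapeLossConfig()


@dataclass(frozen=True)
class Centroid:
    row: float
    col: float

    def as_array(self) -> np.ndarray:
        return np.array([self.row, self.col])


@dataclass(frozen=True)
class ContourSet:
    """Ordered outer-boundary points of the cup and disc regions."""

    cup_points: np.ndarray  # (k, 2) row/col
    disc_points: np.ndarray


@dataclass(frozen=True)
class RadialProfile:
    distances: np.ndarray  # (k,) contour-point-to-centroid distances, px
    mean_distance: float


@dataclass
class ShapeLossValue:
    """Cup and disc circularity terms; total is their sum."""

    cup_term: float | Tensor
    disc_term: float | Tensor
    total: float | Tensor = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.total is None:
            self.total = self.cup_term + self.disc_term

    def as_floats(self) -> "ShapeLossValue":
        return ShapeLossValue(float(self.cup_term), float(self.disc_term),
                              float(self.total))


# -- hard (label-map) path -----------------------------------------------------


def _region_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer boundary pixels of the largest 8-connected component, ordered by
    angle around the component centroid.  Holes are filled first so only the
    outer contour contributes (the disc and cup are simply connected)."""
    labeled, n = ndimage.label(mask, structure=_S8)
    if n == 0:
        raise DegenerateRegionError("region is empty")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
    comp = labeled == (1 + int(np.argmax(sizes)))
    comp = ndimage.binary_fill_holes(comp)
    # border_value=1: pixels clipped by the image frame are not contour
    interior = ndimage.binary_erosion(comp, structure=_S8, border_value=1)
    boundary = comp & ~interior
    pts = np.argwhere(boundary).astype(np.float64)
    if len(pts) < 3:
        raise DegenerateRegionError(
            f"contour has {len(pts)} point(s); at least 3 required")
    center = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 0] - center[0], pts[:, 1] - center[1]))
    return pts[order]


def extract_region_contours(label_map: np.ndarray) -> ContourSet:
    """Outer boundary point sets of the cup (class 2) and disc (classes 1∪2)."""
    label_map = np.asarray(label_map)
    if label_map.ndim != 2:
        raise ValueError("label map must be 2-D")
    cup = _region_boundary(label_map == CUP_CLASS)
    disc = _region_boundary(np.isin(label_map, DISC_CLASSES))
    return ContourSet(cup_points=cup, disc_points=disc)


def centroid(points: Sequence | np.ndarray) -> Centroid:
    """Arithmetic mean of a contour point set."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        raise DegenerateRegionError("cannot take centroid of an empty point set")
    pts = pts.reshape(-1, 2)
    m = pts.mean(axis=0)
    return Centroid(row=float(m[0]), col=float(m[1]))


def radial_profile(points: Sequence | np.ndarray, center: Centroid) -> RadialProfile:
    """Distances of each contour point to the centroid, plus their mean."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateRegionError("need at least 3 contour points")
    d = np.hypot(pts[:, 0] - center.row, pts[:, 1] - center.col)
    mean = float(d.mean())
    if mean <= 0.0:
        raise DegenerateRegionError("all contour points coincide with centroid")
    return RadialProfile(distances=d, mean_distance=mean)


def circularity_term(profile: RadialProfile,
                     config: ShapeLossConfig = DEFAULT_CONFIG) -> float:
    """Normalized spread of the radial profile; 0 iff the contour is a circle."""
    m = profile.mean_distance
    if m <= 0.0:
        raise DegenerateRegionError("mean contour distance must be positive")
    d = profile.distances
    if config.deviation == "squared":
        dev = (d - m) ** 2
        denom = m ** 2
    else:
        dev = np.abs(d - m)
        denom = m
    if config.normalization == "scale_free":
        return float(dev.mean() / denom)
    return float(dev.sum() / m)


def _hard_term(mask: np.ndarray, config: ShapeLossConfig) -> float:
    try:
        pts = _region_boundary(mask)
        prof = radial_profile(pts, centroid(pts))
        return circularity_term(prof, config)
    except DegenerateRegionError:
        return config.degenerate_penalty


def shape_loss_hard(label_map: np.ndarray,
                    config: ShapeLossConfig = DEFAULT_CONFIG) -> ShapeLossValue:
    """Circularity loss of a hard label map: cup term + disc term.

    Degenerate regions (empty, or contour under 3 points) contribute the
    configured penalty constant instead of raising.
    """
    label_map = np.asarray(label_map)
    cup = _hard_term(label_map == CUP_CLASS, config)
    disc = _hard_term(np.isin(label_map, DISC_CLASSES), config)
    return ShapeLossValue(cup_term=cup, disc_term=disc)


# -- soft (differentiable) path ------------------------------------------------


def _minpool3(p: Tensor) -> Tensor:
    """3x3 minimum filter with edge replication, so the image frame itself
    never registers as a region boundary (a constant map has no contour)."""
    h, w = p.shape[-2], p.shape[-1]
    pp = p.pad2d_edge(1)
    out = None
    for di in range(3):
        for dj in range(3):
            s = pp[..., di:di + h, dj:dj + w]
            out = s if out is None else minimum(out, s)
    return out


def _soft_term(p: Tensor, config: ShapeLossConfig) -> Tensor:
    h, w = p.shape[-2], p.shape[-1]
    area = h * w
    thresh = config.mass_fraction_threshold * area
    penalty = Tensor(config.degenerate_penalty)

    if float(p.data.sum()) < thresh:
        return penalty
    b = p - _minpool3(p)  # inner-boundary weights; == boundary mask when hard
    bsum = b.sum()
    if float(bsum.data) < thresh:
        return penalty

    dt = p.data.dtype  # keep float32 graphs in float32
    rows = Tensor(np.arange(h, dtype=dt)[:, None])
    cols = Tensor(np.arange(w, dtype=dt)[None, :])
    cr = (b * rows).sum() / bsum
    cc = (b * cols).sum() / bsum
    d = ((rows - cr) ** 2 + (cols - cc) ** 2 + 1e-12).sqrt()
    m = (b * d).sum() / bsum
    if float(m.data) <= 0.0:
        return penalty
    if config.deviation == "squared":
        dev = (d - m) ** 2
        denom = m ** 2
    else:
        dev = (d - m).abs()
        denom = m
    if config.normalization == "scale_free":
        return (b * dev).sum() / bsum / denom
    return (b * dev).sum() / m


def _validate_probs(probs: Tensor) -> None:
    data = probs.data
    if data.ndim != 3:
        raise ValueError("expected a (classes, H, W) probability tensor")
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.allclose(data.sum(axis=0), 1.0, atol=1e-4):
        raise ValueError("class probabilities must sum to 1 per pixel")


def shape_loss_soft(probs: Tensor | np.ndarray,
                    config: ShapeLossConfig = DEFAULT_CONFIG) -> ShapeLossValue:
    """Differentiable circularity loss on a (classes, H, W) probability tensor.

    The cup region is the class-2 probability map; the disc region is the sum
    of classes 1 and 2.  Regions whose probability or boundary mass is
    negligible return the degenerate penalty with zero gradient.
    """
    probs = as_tensor(probs)
    _validate_probs(probs)
    p_cup = probs[CUP_CLASS]
    p_disc = probs[DISC_CLASSES[0]] + probs[DISC_CLASSES[1]]
    cup = _soft_term(p_cup, config)
    disc = _soft_term(p_disc, config)
    return ShapeLossValue(cup_term=cup, disc_term=disc)


def shape_loss_total(seg_probs: Sequence[Tensor | np.ndarray],
                     config: ShapeLossConfig = DEFAULT_CONFIG) -> Tensor:
    """Sum of soft shape losses over the four segmentation outputs of the
    framework (source, target, source→target, target→source)."""
    if len(seg_probs) != 4:
        raise ValueError(f"expected exactly 4 segmentation outputs, got {len(seg_probs)}")
    total = None
    for p in seg_probs:
        t = shape_loss_soft(p, config).total
        total = t if total is None else total + t
    return total
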