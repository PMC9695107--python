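"""Two-domain synthetic fundus phantoms with ground-truth disc/cup masks.

Real cross-domain disc/cup benchmarks differ in color cast, contrast, blur
and vessel texture while sharing the same anatomy: a bright quasi-circular
optic disc containing a brighter quasi-circular cup.  The generator
emulates exactly that: geometry (a jittered-circle disc with a concentric,
radially scaled cup) is drawn from one distribution for both domains, while
appearance (palette, vessel density, blur, contrast, noise) is
domain-specific.  This gives every other module a controllable test bed
with known ground truth and a real, measurable domain shift — without any
claim of anatomical fidelity.

Geometry: the disc boundary radius is R * f(theta), where f is 1 plus a
few random low-order sinusoidal harmonics whose total amplitude is the
boundary jitter (capped at 15% so shapes stay circular-like).  The cup
uses the *same* angular profile scaled by the cup-to-disc ratio, so the
vertical cup-to-disc ratio of the rasterized masks equals the sampled CDR
up to rasterization error.

Label maps: 0 = background, 1 = disc ring, 2 = cup; images are uint8 RGB.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DomainStyle",
    "PhantomSpec",
    "DOMAIN_STYLES",
    "generate_phantom",
    "generate_dataset",
    "load_label_map",
    "load_image",
    "image_to_float",
    "one_hot",
]

MAX_JITTER = 0.15


@dataclass(frozen=True)
class DomainStyle:
    """Appearance parameters of one synthetic domain."""

    name: str
    background: tuple[float, float, float]
    disc_color: tuple[float, float, float]
    cup_color: tuple[float, float, float]
    vessel_color: tuple[float, float, float]
    vessel_count: int
    blur_sigma: float
    contrast: float
    brightness: float
    noise_std: float


# Domain A emulates a saturated, reddish-orange, sharp appearance; domain B a
# paler, washed-out, blurrier one — a deliberately strong appearance gap over
# identical anatomy.
DOMAIN_STYLES: dict[str, DomainStyle] = {
    "A": DomainStyle("A", background=(196, 110, 60), disc_color=(236, 186, 120),
                     cup_color=(252, 224, 160), vessel_color=(130, 40, 36),
                     vessel_count=6, blur_sigma=0.8, contrast=1.0,
                     brightness=0.0, noise_std=4.0),
    "B": DomainStyle("B", background=(150, 132, 128), disc_color=(214, 204, 188),
                     cup_color=(238, 232, 214), vessel_color=(96, 70, 78),
                     vessel_count=11, blur_sigma=1.8, contrast=0.8,
                     brightness=18.0, noise_std=8.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single phantom.

    Radii are in pixels; `disc_radius_range=None` defaults to
    (0.26, 0.36) x image_size.  `boundary_jitter` is the total relative
    amplitude of the sinusoidal boundary perturbation.
    """

    image_size: int = 256
    disc_radius_range: tuple[float, float] | None = None
    cup_to_disc_ratio_range: tuple[float, float] = (0.35, 0.65)
    boundary_jitter: float = 0.06
    domain_style: str = "A"
    seed: int = 0

    def resolved_radius_range(self) -> tuple[float, float]:
        if self.disc_radius_range is not None:
            return self.disc_radius_range
        return 0.26 * self.image_size, 0.36 * self.image_size

    def validate(self) -> None:
        lo, hi = self.resolved_radius_range()
        cl, ch = self.cup_to_disc_ratio_range
        if not (0 < cl <= ch < 1):
            raise ValueError("cup-to-disc ratios must lie strictly in (0, 1)")
        if not (0 < lo <= hi):
            raise ValueError("disc radii must be positive")
        if not (0 <= self.boundary_jitter <= MAX_JITTER):
            raise ValueError(f"boundary_jitter must be in [0, {MAX_JITTER}]")
        if hi * (1 + self.boundary_jitter) >= 0.46 * self.image_size:
            raise ValueError("disc does not fit inside the image")
        if self.domain_style not in DOMAIN_STYLES:
            raise ValueError(f"unknown domain style {self.domain_style!r}")


def _angular_profile(rng: np.random.Generator, jitter: float, theta: np.ndarray) -> np.ndarray:
    """1 + sum of low-order harmonics with total amplitude == jitter."""
    if jitter == 0:
        return np.ones_like(theta)
    amps = rng.uniform(0.2, 1.0, size=3)
    amps *= jitter / amps.sum()
    phases = rng.uniform(0, 2 * np.pi, size=3)
    prof = np.ones_like(theta)
    for k, (a, ph) in enumerate(zip(amps, phases), start=2):
        prof += a * np.sin(k * theta + ph)
    return prof


def _bezier(p0, p1, p2, n: int = 80) -> np.ndarray:
    t = np.linspace(0, 1, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _draw_vessels(img: np.ndarray, rng: np.random.Generator,
                  center: np.ndarray, radius: float, style: DomainStyle) -> None:
    """Quadratic Bezier strokes radiating from the disc outwards."""
    size = img.shape[0]
    color = np.array(style.vessel_color)
    for _ in range(style.vessel_count):
        ang = rng.uniform(0, 2 * np.pi)
        start = center + 0.3 * radius * np.array([np.sin(ang), np.cos(ang)])
        end_ang = ang + rng.uniform(-0.9, 0.9)
        reach = rng.uniform(1.8, 3.2) * radius
        end = center + reach * np.array([np.sin(end_ang), np.cos(end_ang)])
        ctrl = (start + end) / 2 + rng.uniform(-0.5, 0.5, 2) * radius
        pts = _bezier(start, ctrl, end)
        width = rng.integers(1, 3)
        for r, c in pts:
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < size and 0 <= ci < size:
                lo_r, hi_r = max(ri - width, 0), min(ri + width + 1, size)
                lo_c, hi_c = max(ci - width, 0), min(ci + width + 1, size)
                img[lo_r:hi_r, lo_c:hi_c] = (
                    0.55 * img[lo_r:hi_r, lo_c:hi_c] + 0.45 * color)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """One phantom: (uint8 RGB image HxWx3, uint8 label map HxW).

    Deterministic given `spec.seed`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    style = DOMAIN_STYLES[spec.domain_style]
    s = spec.image_size

    lo, hi = spec.resolved_radius_range()
    radius = rng.uniform(lo, hi)
    cdr = rng.uniform(*spec.cup_to_disc_ratio_range)
    max_off = max(0.0, 0.45 * s - radius * (1 + spec.boundary_jitter))
    center = 0.5 * s + rng.uniform(-1, 1, size=2) * min(0.04 * s, max_off)

    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    dr, dc = rows - center[0], cols - center[1]
    r = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    boundary = radius * _angular_profile(rng, spec.boundary_jitter, theta)

    disc_mask = r <= boundary
    cup_mask = r <= cdr * boundary
    label = np.zeros((s, s), dtype=np.uint8)
    label[disc_mask] = 1
    label[cup_mask] = 2

    img = np.empty((s, s, 3), dtype=np.float64)
    img[:] = style.background
    # gentle background vignette for texture
    img *= (1.0 - 0.25 * (r / r.max()) ** 2)[..., None]
    _draw_vessels(img, rng, center, radius, style)
    # soft-edged disc and cup fills over the vessels
    edge = np.clip((boundary - r) / 2.0, 0, 1)
    img = img * (1 - 0.85 * edge[..., None]) + np.array(style.disc_color) * 0.85 * edge[..., None]
    edge_cup = np.clip((cdr * boundary - r) / 2.0, 0, 1)
    img = img * (1 - 0.9 * edge_cup[..., None]) + np.array(style.cup_color) * 0.9 * edge_cup[..., None]

    if style.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(style.blur_sigma, style.blur_sigma, 0))
    img = (img - 127.5) * style.contrast + 127.5 + style.brightness
    img += rng.normal(0, style.noise_std, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), label


def generate_dataset(n_per_domain: int, out_dir: str | Path, seed: int = 0,
                     image_size: int = 256, train_fraction: float = 0.8,
                     boundary_jitter: float = 0.06) -> pd.DataFrame:
    """Write paired image/mask PNGs for domains A and B plus a manifest CSV.

    Layout: ``<out_dir>/domain_<D>/{img,mask}_<i>.png``; the manifest
    (``manifest.csv``) lists image_path, mask_path, domain, split and is
    returned as a DataFrame.  Deterministic given `seed`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    n_train = int(round(train_fraction * n_per_domain))
    for domain in ("A", "B"):
        ddir = out_dir / f"domain_{domain}"
        ddir.mkdir(exist_ok=True)
        for i in range(n_per_domain):
            sub_seed = int(master.integers(0, 2 ** 31 - 1))
            spec = PhantomSpec(image_size=image_size, domain_style=domain,
                               boundary_jitter=boundary_jitter, seed=sub_seed)
            img, mask = generate_phantom(spec)
            img_path = ddir / f"img_{i:04d}.png"
            mask_path = ddir / f"mask_{i:04d}.png"
            iio.imwrite(img_path, img)
            iio.imwrite(mask_path, mask)
            rows.append({
                "image_path": str(img_path.relative_to(out_dir)),
                "mask_path": str(mask_path.relative_to(out_dir)),
                "domain": domain,
                "split": "train" if i < n_train else "test",
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# -- I/O helpers ---------------------------------------------------------------


def load_label_map(path: str | Path) -> np.ndarray:
    """Read a single-channel label PNG with classes {0, 1, 2}."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if not np.isin(np.unique(arr), [0, 1, 2]).all():
        raise ValueError(f"{path}: label map contains values outside {{0,1,2}}")
    return arr.astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def image_to_float(img: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 -> float64 3xHxW in [-1, 1] (network input convention)."""
    return (img.astype(np.float64).transpose(2, 0, 1) / 127.5) - 1.0


def one_hot(label_map: np.ndarray, num_classes: int = 3) -> np.ndarray:
    """HxW integer labels -> (num_classes, H, W) one-hot float map."""
    return np.eye(num_classes, dtype=np.float64)[label_map].transpose(2, 0, 1)
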