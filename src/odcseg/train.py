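"""Seeded adversarial training loop, evaluation, and the weight-sweep runner.

One iteration performs the standard adversarial alternation:

(a) image discriminators D1/D2 on real vs (detached) translated images,
(b) translation generators (content/style encoders + decoder) via the
    weighted translation total (image/content/style reconstruction +
    non-saturating GAN terms),
(c) the segmentation-map discriminator on (detached) source vs target
    probability maps,
(d) the segmenter and content encoder via the grand total: segmentation
    cross-entropy on labeled source data + adversarial output-space
    alignment on target data + the four-term circularity shape loss on the
    segmentations of the source, target, and both translated images.

All randomness flows from a single integer seed (data order, network
initialization), so identical configurations reproduce identical logs on a
single CPU thread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import losses as L
from .metrics import EvalResult, evaluate_masks
from .networks import DomainAdaptationModel, NetworkConfig
from .nn import Adam, Tensor
from .shape_loss import ShapeLossConfig, shape_loss_soft
from .synthetic_data import image_to_float, load_image, load_label_map, one_hot

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate", "ablation_sweep"]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (Adam throughout, constant learning rate)."""

    epochs: int = 400
    batch_size: int = 2
    lr: float = 1e-4
    image_size: int = 256
    seed: int = 0
    weights: L.LossWeights = field(default_factory=L.LossWeights)
    shape_config: ShapeLossConfig = field(default_factory=ShapeLossConfig)
    network: NetworkConfig | None = None
    # summed pixel cross-entropy: delta1/delta2/rho2 are calibrated relative
    # to this scale (a per-pixel mean with the same weights lets the shape
    # term overwhelm the data term and suppress the cup class entirely)
    ce_reduction: str = "sum"
    shape_weight_sweep: tuple[float, ...] = tuple(round(0.2 * k, 1) for k in range(1, 11))

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.image_size) < 1 or self.lr <= 0:
            raise ValueError("epochs, batch_size, image_size and lr must be positive")

    def resolved_network(self) -> NetworkConfig:
        if self.network is not None:
            if self.network.image_size != self.image_size:
                raise ValueError("network.image_size must match image_size")
            return self.network
        return NetworkConfig(image_size=self.image_size)


@dataclass
class TrainResult:
    checkpoint_path: Path
    log_path: Path
    log: pd.DataFrame
    model: DomainAdaptationModel


class _Split:
    """In-memory images/masks for one (domain, split) subset."""

    def __init__(self, manifest: pd.DataFrame, root: Path, domain: str, split: str,
                 with_masks: bool):
        rows = manifest[(manifest["domain"] == domain) & (manifest["split"] == split)]
        if rows.empty:
            raise ValueError(f"manifest has no rows for domain {domain!r}, split {split!r}")
        self.names = rows["image_path"].tolist()
        # float32 keeps the conv-heavy training loop fast on CPU
        self.images = np.stack([image_to_float(load_image(root / p))
                                for p in rows["image_path"]]).astype(np.float32)
        self.masks = None
        if with_masks:
            self.masks = np.stack([load_label_map(root / p) for p in rows["mask_path"]])

    def __len__(self) -> int:
        return len(self.images)


def _load_manifest(data_manifest: str | Path | pd.DataFrame,
                   root: str | Path | None) -> tuple[pd.DataFrame, Path]:
    if isinstance(data_manifest, (str, Path)):
        path = Path(data_manifest)
        return pd.read_csv(path), Path(root) if root else path.parent
    if root is None:
        raise ValueError("root directory required when passing a manifest DataFrame")
    return data_manifest, Path(root)


def _check_finite(value: float, term: str, epoch: int) -> None:
    if not math.isfinite(value):
        raise RuntimeError(
            f"non-finite loss in term {term!r} at epoch {epoch}; aborting")


def _batch_shape_loss(probs: Tensor, cfg: ShapeLossConfig) -> Tensor:
    """Mean soft shape loss over a (N, C, H, W) probability batch."""
    total = None
    n = probs.shape[0]
    for i in range(n):
        t = shape_loss_soft(probs[i], cfg).total
        total = t if total is None else total + t
    return total * (1.0 / n)


def train(config: TrainConfig, data_manifest: str | Path | pd.DataFrame,
          out_dir: str | Path, root: str | Path | None = None) -> TrainResult:
    """Train the full framework on a two-domain manifest (domain A = labeled
    source, domain B = unlabeled target) and write checkpoint + CSV log."""
    manifest, data_root = _load_manifest(data_manifest, root)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    source = _Split(manifest, data_root, "A", "train", with_masks=True)
    target = _Split(manifest, data_root, "B", "train", with_masks=False)

    net_cfg = config.resolved_network()
    model = DomainAdaptationModel(net_cfg, seed=config.seed)
    w = config.weights
    shape_cfg = config.shape_config

    gen_params = (model.content_encoder.parameters()
                  + model.style_encoder.parameters() + model.decoder.parameters())
    disc_params = model.disc_target.parameters() + model.disc_source.parameters()
    seg_params = model.segmenter.parameters() + model.content_encoder.parameters()
    opt_gen = Adam(gen_params, lr=config.lr)
    opt_disc = Adam(disc_params, lr=config.lr)
    opt_seg = Adam(seg_params, lr=config.lr)
    opt_dseg = Adam(model.disc_seg.parameters(), lr=config.lr)

    n_iter = min(len(source), len(target)) // config.batch_size
    if n_iter == 0:
        raise ValueError("not enough training images for one batch")
    log_rows: list[dict] = []

    for epoch in range(config.epochs):
        src_order = rng.permutation(len(source))
        tgt_order = rng.permutation(len(target))
        for it in range(n_iter):
            sl = slice(it * config.batch_size, (it + 1) * config.batch_size)
            xs = Tensor(source.images[src_order[sl]])
            xt = Tensor(target.images[tgt_order[sl]])
            ys_onehot = Tensor(np.stack(
                [one_hot(m, net_cfg.num_classes) for m in source.masks[src_order[sl]]]
            ).astype(np.float32))

            # translation forward
            cs, ss = model.encode(xs)
            ct, st = model.encode(xt)
            xs_s = model.decode(cs, ss)
            xt_t = model.decode(ct, st)
            xs_t = model.decode(cs, st)
            xt_s = model.decode(ct, ss)
            cs_rec, st_rec = model.encode(xs_t)
            ct_rec, ss_rec = model.encode(xt_s)

            # (a) image discriminators on detached translations
            model.zero_grad()
            d_loss = (L.gan_loss_translation(model.discriminate_image(xt, "target"),
                                             model.discriminate_image(xs_t.detach(), "target"))
                      + L.gan_loss_translation(model.discriminate_image(xs, "source"),
                                               model.discriminate_image(xt_s.detach(), "source")))
            _check_finite(float(d_loss), "L_dis (discriminator step)", epoch)
            d_loss.backward()
            opt_disc.step()

            # (b) translation generators through the updated discriminators
            model.zero_grad()
            batch = L.TranslationBatch(xs=xs, xt=xt, cs=cs, ct=ct, ss=ss, st=st,
                                       xs_t=xs_t, xt_s=xt_s, xs_s=xs_s, xt_t=xt_t,
                                       cs_rec=cs_rec, ct_rec=ct_rec,
                                       ss_rec=ss_rec, st_rec=st_rec)
            scores = {
                "fake_target": model.discriminate_image(xs_t, "target"),
                "fake_source": model.discriminate_image(xt_s, "source"),
            }
            tra_total = L.total_translation_loss(batch, w, scores, role="generator")
            _check_finite(float(tra_total), "L_tra_total", epoch)
            tra_total.backward()
            opt_gen.step()

            # segmentation forward (fresh content after the generator step)
            cs2, _ = model.encode(xs)
            ct2, _ = model.encode(xt)
            c_st, _ = model.encode(xs_t.detach())
            c_ts, _ = model.encode(xt_s.detach())
            seg_s = model.segment(cs2)
            seg_t = model.segment(ct2)
            seg_st = model.segment(c_st)
            seg_ts = model.segment(c_ts)

            # (c) segmentation-map discriminator on detached probability maps
            model.zero_grad()
            dseg_loss = L.seg_disc_loss(
                model.discriminate_segmap(seg_s.probs.detach()),
                model.discriminate_segmap(seg_t.probs.detach()))
            _check_finite(float(dseg_loss), "L_dis_seg", epoch)
            dseg_loss.backward()
            opt_dseg.step()

            # (d) segmenter + content encoder via the grand total
            model.zero_grad()
            ce = L.seg_ce_loss(ys_onehot, seg_s.probs, reduction=config.ce_reduction)
            adv = L.seg_adv_loss(model.discriminate_segmap(seg_t.probs))
            seg_total = L.total_seg_loss(ce, adv, w)
            shp_s = _batch_shape_loss(seg_s.probs, shape_cfg)
            shp_t = _batch_shape_loss(seg_t.probs, shape_cfg)
            shp_st = _batch_shape_loss(seg_st.probs, shape_cfg)
            shp_ts = _batch_shape_loss(seg_ts.probs, shape_cfg)
            shape_total = shp_s + shp_t + shp_st + shp_ts
            total = L.grand_total(tra_total.detach(), seg_total, shape_total, w)
            for name, term in (("L_seg_ce", ce), ("L_seg_adv", adv),
                               ("L_shape_total", shape_total), ("L_total", total)):
                _check_finite(float(term), name, epoch)
            total.backward()
            opt_seg.step()

            log_rows.append({
                "epoch": epoch, "iter": it,
                "L_dis_images": float(d_loss),
                "L_tra_total": float(tra_total),
                "L_dis_seg": float(dseg_loss),
                "L_seg_ce": float(ce),
                "L_seg_adv": float(adv),
                "L_seg_total": float(seg_total),
                "L_shape_xs": float(shp_s),
                "L_shape_xt": float(shp_t),
                "L_shape_xs_t": float(shp_st),
                "L_shape_xt_s": float(shp_ts),
                "L_shape_total": float(shape_total),
                "L_total": float(total),
            })

    log = pd.DataFrame(log_rows)
    log_path = out_dir / "training_log.csv"
    log.to_csv(log_path, index=False)
    ckpt_path = out_dir / "checkpoint.npz"
    model.save(ckpt_path)
    return TrainResult(checkpoint_path=ckpt_path, log_path=log_path, log=log,
                       model=model)


def predict_label_map(model: DomainAdaptationModel, image: np.ndarray) -> np.ndarray:
    """Image (uint8 HxWx3 or float 3xHxW in [-1,1]) -> argmax label map."""
    if image.ndim == 3 and image.shape[-1] == 3 and image.dtype == np.uint8:
        image = image_to_float(image)
    model.eval()
    content, _ = model.encode(Tensor(image[None]))
    probs = model.segment(content).probs
    model.train()
    return np.argmax(probs.data[0], axis=0).astype(np.uint8)


def evaluate(checkpoint: str | Path | DomainAdaptationModel,
             test_manifest: str | Path | pd.DataFrame,
             root: str | Path | None = None,
             network: NetworkConfig | None = None,
             domain: str = "B", split: str = "test",
             out_csv: str | Path | None = None) -> EvalResult:
    """Per-image and mean IoU/Dice of a trained checkpoint on a test split."""
    manifest, data_root = _load_manifest(test_manifest, root)
    if isinstance(checkpoint, DomainAdaptationModel):
        model = checkpoint
    else:
        model = DomainAdaptationModel(network or NetworkConfig())
        model.load(checkpoint)
    subset = _Split(manifest, data_root, domain, split, with_masks=True)
    preds = [predict_label_map(model, img) for img in subset.images]
    result = evaluate_masks(zip(preds, subset.masks), names=subset.names)
    if out_csv is not None:
        result.to_csv(out_csv)
    return result


def ablation_sweep(config: TrainConfig, weights: list[float],
                   data_manifest: str | Path | pd.DataFrame,
                   out_dir: str | Path,
                   root: str | Path | None = None) -> pd.DataFrame:
    """Train one seeded run per shape-constraint weight (rho2) and tabulate
    the four test metrics.  The sweep is restartable: weights already
    present in the output CSV are skipped."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table_path = out_dir / "ablation.csv"
    done = pd.read_csv(table_path) if table_path.exists() else pd.DataFrame(
        columns=["rho2", "iou_od", "iou_oc", "dice_od", "dice_oc"])
    rows = done.to_dict("records")
    for rho2 in weights:
        if any(np.isclose(r["rho2"], rho2) for r in rows):
            continue
        cfg = replace(config, weights=replace(config.weights, rho2=rho2))
        run_dir = out_dir / f"rho2_{rho2:g}"
        result = train(cfg, data_manifest, run_dir, root=root)
        ev = evaluate(result.model, data_manifest, root=root,
                      network=cfg.resolved_network())
        rows.append({"rho2": rho2, "iou_od": ev.iou_od, "iou_oc": ev.iou_oc,
                     "dice_od": ev.dice_od, "dice_oc": ev.dice_oc})
        pd.DataFrame(rows).to_csv(table_path, index=False)
    return pd.DataFrame(rows)
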