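"""Dataset splitting, augmentation, and the optimization loop.

The regimen follows the published recipe — Adam, batch size 4, initial
learning rate 1e-3 decayed multiplicatively by 0.92 every epoch, random
horizontal flips, 0.5–1.5× scaling, HSV jitter, 0–15° rotation — with
desk-scale defaults (small widths, small phantoms, few epochs) available
for CPU runs.  The loss is unweighted per-pixel cross-entropy over the 6
classes; optional class weights are exposed for the thin classes.

Geometric transforms are applied identically to image and label map;
labels are always resampled nearest-neighbor, and rotation/scaling fill
exposed regions with the Background class and background color.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import transform as sktransform

from .metrics import mean_iou, mean_pixel_accuracy, pixel_accuracy, tally, ConfusionTally
from .nn import Adam, SegUNet
from .schema import AnnotatedSection, BACKGROUND
from .synthgen import HE_PALETTE

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentationPolicy",
    "TrainConfig",
    "TrainHistory",
    "split_dataset",
    "augment",
    "train",
    "cross_entropy",
    "pad_to_multiple",
]


@dataclass(frozen=True)
class AugmentationPolicy:
    hflip_prob: float = 0.5
    scale_range: Tuple[float, float] = (0.5, 1.5)
    hsv_jitter: bool = True
    hue_delta: float = 0.03
    sat_range: Tuple[float, float] = (0.8, 1.2)
    val_range: Tuple[float, float] = (0.8, 1.2)
    rotation_range_deg: Tuple[float, float] = (0.0, 15.0)

    IDENTITY = None  # set after class definition

    def __post_init__(self):
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be a probability")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be ordered")


AugmentationPolicy.IDENTITY = AugmentationPolicy(
    hflip_prob=0.0, scale_range=(1.0, 1.0), hsv_jitter=False,
    rotation_range_deg=(0.0, 0.0))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 0.001
    lr_decay_step: int = 1
    lr_decay_factor: float = 0.92
    optimizer: str = "adam"
    class_weights: Optional[Tuple[float, ...]] = None
    augmentation: Optional[AugmentationPolicy] = None
    eval_every: int = 1
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        """Learning rate used during 0-based ``epoch`` (multiplicative decay)."""
        return self.learning_rate * self.lr_decay_factor ** (epoch // self.lr_decay_step)


def split_dataset(sections: Sequence[AnnotatedSection], train_n: int,
                  test_n: int, seed: int):
    """Disjoint, seed-reproducible train/test subsets."""
    if train_n + test_n > len(sections):
        raise ValueError(
            f"requested {train_n}+{test_n} sections but only "
            f"{len(sections)} available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sections))
    train = [sections[i] for i in order[:train_n]]
    test = [sections[i] for i in order[train_n:train_n + test_n]]
    return train, test


def _bg_color() -> np.ndarray:
    return np.array(HE_PALETTE[BACKGROUND], dtype=np.float64)


def _fit_canvas(image: np.ndarray, labels: np.ndarray, h: int, w: int):
    """Center-crop or background-pad to an exact (h, w) canvas."""
    ih, iw = labels.shape
    # crop
    if ih > h:
        top = (ih - h) // 2
        image, labels = image[top:top + h], labels[top:top + h]
        ih = h
    if iw > w:
        left = (iw - w) // 2
        image, labels = image[:, left:left + w], labels[:, left:left + w]
        iw = w
    # pad
    if ih < h or iw < w:
        pt, pl = (h - ih) // 2, (w - iw) // 2
        pb, pr = h - ih - pt, w - iw - pl
        canvas = np.empty((h, w, 3), dtype=image.dtype)
        canvas[...] = _bg_color().astype(image.dtype)
        canvas[pt:pt + ih, pl:pl + iw] = image
        lcanvas = np.full((h, w), BACKGROUND, dtype=labels.dtype)
        lcanvas[pt:pt + ih, pl:pl + iw] = labels
        image, labels = canvas, lcanvas
    return image, labels


def augment(section: AnnotatedSection, policy: AugmentationPolicy,
            draw_seed: int) -> AnnotatedSection:
    """One random augmentation draw; identity policy is byte-preserving."""
    rng = np.random.default_rng(draw_seed)
    image = section.image
    labels = section.labels
    h, w = labels.shape

    if policy.hflip_prob > 0 and rng.random() < policy.hflip_prob:
        image = image[:, ::-1]
        labels = labels[:, ::-1]

    lo, hi = policy.scale_range
    scale = float(rng.uniform(lo, hi)) if hi > lo else lo
    if scale != 1.0:
        image = sktransform.rescale(
            image.astype(np.float64), scale, order=1, channel_axis=2,
            preserve_range=True, anti_aliasing=scale < 1.0)
        labels = sktransform.rescale(
            labels.astype(np.float64), scale, order=0,
            preserve_range=True, anti_aliasing=False).astype(section.labels.dtype)
        image, labels = _fit_canvas(image, labels, h, w)
        image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    rlo, rhi = policy.rotation_range_deg
    angle = float(rng.uniform(rlo, rhi)) if rhi > rlo else rlo
    if angle != 0.0:
        bg = _bg_color()
        chans = [ndi.rotate(image[..., c].astype(np.float64), angle,
                            reshape=False, order=1, cval=bg[c])
                 for c in range(3)]
        image = np.clip(np.rint(np.stack(chans, axis=-1)), 0, 255).astype(np.uint8)
        labels = ndi.rotate(labels, angle, reshape=False, order=0,
                            cval=BACKGROUND)

    if policy.hsv_jitter:
        hsv = skcolor.rgb2hsv(image.astype(np.float64) / 255.0)
        hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(
            -policy.hue_delta, policy.hue_delta), 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(*policy.sat_range), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(*policy.val_range), 0, 1)
        image = np.clip(np.rint(skcolor.hsv2rgb(hsv) * 255.0),
                        0, 255).astype(np.uint8)

    return AnnotatedSection(
        image=np.ascontiguousarray(image),
        labels=np.ascontiguousarray(labels),
        pixel_size_um=section.pixel_size_um,
        truth_profile=None,  # geometry changed; planted truth no longer valid
        provenance=section.provenance + f" +augment(seed={draw_seed})",
        group=section.group,
        schema=section.schema,
    )


def pad_to_multiple(section: AnnotatedSection, multiple: int = 16) -> AnnotatedSection:
    """Background-pad a section so both dimensions divide ``multiple``."""
    h, w = section.labels.shape
    nh = -(-h // multiple) * multiple
    nw = -(-w // multiple) * multiple
    if (nh, nw) == (h, w):
        return section
    image, labels = _fit_canvas(section.image, section.labels, nh, nw)
    return replace_section(section, image, labels,
                           note=f" +pad({h}x{w}->{nh}x{nw})")


def replace_section(section, image, labels, note=""):
    return AnnotatedSection(
        image=image, labels=labels, pixel_size_um=section.pixel_size_um,
        truth_profile=section.truth_profile,
        provenance=section.provenance + note,
        group=section.group, schema=section.schema)


def cross_entropy(scores: np.ndarray, targets: np.ndarray,
                  class_weights: Optional[np.ndarray] = None):
    """Per-pixel multi-class cross-entropy; returns (loss, dscores)."""
    n, k, h, w = scores.shape
    shifted = scores - scores.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    softmax = exp / exp.sum(axis=1, keepdims=True)
    idx_n, idx_h, idx_w = np.ix_(np.arange(n), np.arange(h), np.arange(w))
    p_true = softmax[idx_n, targets, idx_h, idx_w]
    logp = np.log(np.maximum(p_true, 1e-300))
    onehot = np.zeros_like(scores)
    onehot[idx_n, targets, idx_h, idx_w] = 1.0
    if class_weights is None:
        denom = n * h * w
        loss = -logp.sum() / denom
        dscores = (softmax - onehot) / denom
    else:
        wmap = class_weights[targets]  # (n, h, w)
        denom = wmap.sum()
        loss = -(wmap * logp).sum() / denom
        dscores = (softmax - onehot) * wmap[:, None] / denom
    return float(loss), dscores


@dataclass
class TrainHistory:
    epochs: List[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_miou: float = -1.0
    best_state: Optional[dict] = None

    def to_rows(self) -> List[dict]:
        return self.epochs


def _evaluate(model: SegUNet, sections: Sequence[AnnotatedSection]):
    tallies = None
    for sec in sections:
        pred = model.predict_labels(sec.image)
        t = tally(pred, sec.labels, sec.schema)
        if tallies is None:
            tallies = t
        else:
            tallies = ConfusionTally(tp=tallies.tp + t.tp, fp=tallies.fp + t.fp,
                                     fn=tallies.fn + t.fn, tn=tallies.tn + t.tn)
    return (pixel_accuracy(tallies), mean_pixel_accuracy(tallies),
            mean_iou(tallies))


def train(model: SegUNet, train_set: Sequence[AnnotatedSection],
          test_set: Sequence[AnnotatedSection],
          config: TrainConfig = TrainConfig()) -> Tuple[SegUNet, TrainHistory]:
    """Optimize the model; returns it loaded with the best-by-MIOU weights.

    History logs, per epoch: loss, the exact scheduled learning rate, and
    test PA/MPA/MIOU (every ``eval_every`` epochs).
    """
    if not train_set:
        raise ValueError("empty train set")
    train_set = [pad_to_multiple(s) for s in train_set]
    test_set = [pad_to_multiple(s) for s in test_set]
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params())
    weights = (np.asarray(config.class_weights, dtype=np.float64)
               if config.class_weights is not None else None)
    history = TrainHistory()
    n = len(train_set)
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            secs = []
            for i in batch_idx:
                sec = train_set[i]
                if config.augmentation is not None:
                    # augment preserves the canvas size, which is already
                    # a multiple of 16 after the padding above
                    sec = augment(sec, config.augmentation,
                                  int(rng.integers(0, 2 ** 63 - 1)))
                secs.append(sec)
            x = np.stack([model.preprocess(s.image) for s in secs])
            y = np.stack([s.labels for s in secs])
            scores = model.forward(x, train=True)
            loss, dscores = cross_entropy(scores, y, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; aborting "
                    "(try a lower learning rate)")
            optimizer.zero_grad()
            model.backward(dscores)
            optimizer.step(lr)
            epoch_loss += loss
            n_batches += 1
        row = {"epoch": epoch, "lr": lr, "loss": epoch_loss / n_batches}
        if test_set and (epoch % config.eval_every == 0
                         or epoch == config.epochs - 1):
            pa, mpa, miou = _evaluate(model, test_set)
            row.update(test_pa=pa, test_mpa=mpa, test_miou=miou)
            if miou > history.best_miou:
                history.best_miou = miou
                history.best_epoch = epoch
                history.best_state = copy.deepcopy(model.state_arrays())
        logger.info("epoch %d: loss=%.4f lr=%.6f %s", epoch, row["loss"], lr,
                    {k: round(v, 4) for k, v in row.items()
                     if k.startswith("test_")})
        history.epochs.append(row)
    if history.best_state is not None:
        model.load_state_arrays(history.best_state)
    return model, history
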