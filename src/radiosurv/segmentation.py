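"""Tumor segmentation front-end: dice/IoU metrics, a U-Net-style
segmenter trained with dice loss, and RoI cropping around the tumor.

The dice coefficient compares binarized masks; the dice loss is its
smoothed soft counterpart

    1 - (2 sum p_i t_i + eps) / (sum p_i^2 + sum t_i^2 + eps)

with eps = 1 by default. Empty-vs-empty mask pairs score dice = IoU = 1
so perfect negatives are not penalized.

The segmenter is a small U-Net: conv blocks with 2x2 max-pool on the
way down, transposed-convolution upsampling with skip connections on
the way up, sigmoid output. ``UNetSpec`` carries a pretrained-encoder
flag that is off by default (and in all tests) so that no weight
downloads are required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .autodiff import Tensor, concat, maxpool2d
from .layers import Adam, Conv2d, ConvTranspose2d, Module


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_binary(a, name):
    if not np.all(np.isin(a, [0, 1])):
        raise ValueError(f"{name} must be binary")


def dice_coefficient(ps, gt) -> float:
    """2|PS & GT| / (|PS| + |GT|); 1.0 when both masks are empty."""
    ps, gt = np.asarray(ps), np.asarray(gt)
    if ps.shape != gt.shape:
        raise ValueError("mask shapes differ")
    _check_binary(ps, "predicted mask")
    _check_binary(gt, "ground-truth mask")
    denom = ps.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(ps, gt).sum() / denom)


def dice_loss(p, t, eps: float = 1.0) -> float:
    """Smoothed dice loss between a soft prediction and a binary mask."""
    p, t = np.asarray(p, dtype=float), np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValueError("shapes differ")
    num = 2.0 * np.sum(p * t) + eps
    den = np.sum(p ** 2) + np.sum(t ** 2) + eps
    return float(1.0 - num / den)


def dice_loss_t(p: Tensor, t: np.ndarray, eps: float = 1.0) -> Tensor:
    """Tensor dice loss, mean over the leading (sample) axis.

    ``p``: (N, H, W) soft predictions, ``t``: matching binary masks.
    """
    tt = Tensor(np.asarray(t, dtype=float))
    axes = tuple(range(1, p.ndim))
    num = (p * tt).sum(axis=axes) * 2.0 + eps
    den = (p ** 2).sum(axis=axes) + (tt ** 2).sum(axis=axes) + eps
    return (1.0 - num / den).mean()


def mean_iou(ps, gt) -> float:
    """Jaccard index |PS & GT| / |PS | GT|, averaged over samples.

    Accepts a single (H, W) pair or stacks (N, H, W); an empty/empty
    pair contributes 1.
    """
    ps, gt = np.asarray(ps), np.asarray(gt)
    if ps.shape != gt.shape:
        raise ValueError("mask shapes differ")
    _check_binary(ps, "predicted mask")
    _check_binary(gt, "ground-truth mask")
    if ps.ndim == 2:
        ps, gt = ps[None], gt[None]
    ious = []
    for p, g in zip(ps, gt):
        union = np.logical_or(p, g).sum()
        ious.append(1.0 if union == 0
                    else np.logical_and(p, g).sum() / union)
    return float(np.mean(ious))


# ---------------------------------------------------------------------------
# RoI cropping
# ---------------------------------------------------------------------------

def roi_window(mask, margin: float = 1.5, min_side: int = 32):
    """Square crop window (top, left, side) centred on the centroid of
    the largest connected component, clamped to the mask bounds."""
    mask = np.asarray(mask)
    H, W = mask.shape
    labeled, n = ndimage.label(mask > 0)
    if n == 0:
        raise ValueError("empty mask: no tumor component to crop")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                               index=range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    cy, cx = ndimage.center_of_mass(labeled == biggest)
    ys, xs = np.nonzero(labeled == biggest)
    bbox_side = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    side = int(round(max(bbox_side * margin, min_side)))
    side = min(side, H, W)
    top = int(round(cy - side / 2))
    left = int(round(cx - side / 2))
    top = max(0, min(top, H - side))
    left = max(0, min(left, W - side))
    return top, left, side


def crop_roi(image, mask, out_size: int = 224, margin: float = 1.5,
             fallback_center_crop: bool = False) -> np.ndarray:
    """Crop a square window around the tumor and rescale it.

    The window is centred on the centroid of the largest connected
    component of ``mask`` and sized ``max(bbox_side * margin, 32)`` so
    the peritumoral context is retained; it is clamped to the image
    bounds and resized to ``out_size x out_size``.
    """
    image, mask = np.asarray(image, dtype=float), np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    try:
        top, left, side = roi_window(mask, margin=margin)
    except ValueError:
        if not fallback_center_crop:
            raise
        H, W = image.shape
        side = min(H, W)
        top, left = (H - side) // 2, (W - side) // 2
    window = image[top:top + side, left:left + side]
    out = resize(window, (out_size, out_size), order=1, mode="edge",
                 anti_aliasing=side > out_size, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

@dataclass
class UNetSpec:
    depth: int = 2
    base_channels: int = 4
    use_pretrained_encoder: bool = False
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("U-Net depth must be >= 2")


class UNet(Module):
    """Small U-Net with skip connections and sigmoid output."""

    def __init__(self, spec: UNetSpec, rng):
        self.spec = spec
        c = spec.base_channels
        self.down = []
        c_in = 1
        for i in range(spec.depth):
            c_out = c * 2 ** i
            self.down.append(Conv2d(c_in, c_out, rng, activation="relu"))
            c_in = c_out
        self.bottleneck = Conv2d(c_in, c_in * 2, rng, activation="relu")
        self.up = []
        self.merge = []
        c_b = c_in * 2
        for i in reversed(range(spec.depth)):
            c_out = c * 2 ** i
            self.up.append(ConvTranspose2d(c_b, c_out, rng))
            self.merge.append(Conv2d(2 * c_out, c_out, rng, activation="relu"))
            c_b = c_out
        self.head = Conv2d(c, 1, rng, kernel=1, padding=0,
                           activation="sigmoid")

    def __call__(self, images: np.ndarray) -> Tensor:
        """images: (N, H, W) in [0,1]; returns (N, H, W) soft masks."""
        x = Tensor(np.asarray(images, dtype=float)[:, None])
        skips = []
        for blk in self.down:
            x = blk(x)
            skips.append(x)
            x = maxpool2d(x, 2)
        x = self.bottleneck(x)
        for upc, mrg, skip in zip(self.up, self.merge, reversed(skips)):
            x = upc(x)
            x = mrg(concat([x, skip], axis=1))
        out = self.head(x)
        n, _, h, w = out.shape
        return out.reshape(n, h, w)

    def predict(self, images, threshold: float = 0.5) -> np.ndarray:
        return (self(images).data >= threshold).astype(int)


def _fit_unet(model: UNet, images, masks, epochs, lr, rng, batch_size=16):
    opt = Adam(model.parameters(), lr=lr)
    n = len(images)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            model.zero_grad()
            pred = model(images[idx])
            loss = dice_loss_t(pred, masks[idx])
            loss.backward()
            opt.step()


def train_segmenter(images, masks, spec: UNetSpec | None = None,
                    folds: int = 3, epochs: int = 30, seed: int = 0,
                    lr: float = 1e-2):
    """K-fold train/validate a U-Net with dice loss, then refit on all data.

    Returns ``(model, report)`` with per-fold validation dice loss and
    mean IoU plus their means. Deterministic for a given seed.
    """
    images = np.asarray(images, dtype=float)
    masks = np.asarray(masks)
    _check_binary(masks, "masks")
    n = len(images)
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample count ({n})")
    spec = spec or UNetSpec(input_size=images.shape[1:])
    fold_rng = np.random.default_rng(seed)
    assignment = fold_rng.permutation(n) % folds
    report = {"fold_dice_loss": [], "fold_mean_iou": []}
    for k in range(folds):
        val = assignment == k
        model = UNet(spec, np.random.default_rng([seed, k]))
        _fit_unet(model, images[~val], masks[~val], epochs, lr,
                  np.random.default_rng([seed, k, 1]))
        soft = model(images[val]).data
        report["fold_dice_loss"].append(dice_loss(soft, masks[val]))
        report["fold_mean_iou"].append(
            mean_iou((soft >= 0.5).astype(int), masks[val]))
    report["mean_dice_loss"] = float(np.mean(report["fold_dice_loss"]))
    report["mean_iou"] = float(np.mean(report["fold_mean_iou"]))
    report["fold_assignment"] = assignment
    final = UNet(spec, np.random.default_rng([seed, folds]))
    _fit_unet(final, images, masks, epochs, lr,
              np.random.default_rng([seed, folds, 1]))
    return final, report
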