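"""Deep supervision: foreground-preserving label pyramids and soft dice loss.

Plain downsampling of a lesion mask by averaging or subsampling erases
structures only a voxel or two wide; by the coarsest supervision scale a
thin perivascular space would simply vanish and the deep heads would be
trained against empty targets.  The label pyramid here therefore uses
*foreground-highlighting* 2x2 max pooling: a coarse pixel is foreground
iff any pixel of its fine-scale block is.  Each pyramid level is paired
with the network head of the same scale under a soft dice loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, div, tmean, tsum

__all__ = [
    "LabelPyramid",
    "LossConfig",
    "hf_downsample",
    "soft_dice_loss",
    "multiscale_loss",
]


@dataclass
class LabelPyramid:
    """Per-scale binary masks; ``masks[s]`` has sides ``input / 2**s``."""

    masks: list[np.ndarray]

    def __post_init__(self):
        for s, m in enumerate(self.masks):
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"pyramid level {s} is not binary")

    @property
    def levels(self) -> int:
        return len(self.masks)


@dataclass
class LossConfig:
    """Soft-dice deep-supervision settings.

    ``smooth`` stabilises the dice ratio on empty masks (and makes the
    empty-vs-empty case a perfect score); ``scale_weights`` weight the
    per-scale losses (uniform by default).
    """

    smooth: float = 1.0
    scale_weights: list[float] | None = None

    def __post_init__(self):
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")
        if self.scale_weights is not None:
            w = np.asarray(self.scale_weights, dtype=float)
            if (w < 0).any() or w.sum() == 0:
                raise ValueError("scale_weights must be >= 0 and not all zero")


def hf_downsample(label: np.ndarray, levels: int, policy: str = "max") -> LabelPyramid:
    """Build an ``levels``-deep label pyramid by repeated 2x2 pooling.

    ``policy='max'`` is the foreground-preserving rule (default);
    ``policy='mean'`` yields soft labels in [0, 1] instead.
    """
    label = np.asarray(label)
    if label.ndim != 2:
        raise ValueError("label must be 2D")
    h, w = label.shape
    d = 2 ** (levels - 1)
    if h % d or w % d:
        raise ValueError(f"label sides {h}x{w} not divisible by {d}")
    if policy not in ("max", "mean"):
        raise ValueError(f"unknown policy {policy!r}")
    cur = label.astype(np.float32)
    masks = [cur]
    for _ in range(levels - 1):
        blocks = cur.reshape(cur.shape[0] // 2, 2, cur.shape[1] // 2, 2)
        cur = blocks.max(axis=(1, 3)) if policy == "max" else blocks.mean(axis=(1, 3))
        masks.append(cur)
    if policy == "mean":
        # soft labels: skip the binary check
        pyr = LabelPyramid.__new__(LabelPyramid)
        pyr.masks = masks
        return pyr
    return LabelPyramid(masks)


def soft_dice_loss(prob, label, smooth: float = 1.0):
    """``1 - (2 * sum(p*y) + smooth) / (sum(p) + sum(y) + smooth)``.

    Accepts autograd tensors (differentiable, for training) or plain
    arrays (returns a float).  With a binary ``prob`` equal to ``label``
    the loss is exactly 0; as ``smooth -> 0`` on non-empty masks,
    ``1 - loss`` converges to the evaluation Dice coefficient.
    """
    if isinstance(prob, Tensor):
        if prob.data.shape != np.shape(label.data if isinstance(label, Tensor) else label):
            raise ValueError("prob/label shape mismatch")
        y = label if isinstance(label, Tensor) else Tensor(np.asarray(label, np.float32))
        inter = tsum(prob * y)
        denom = tsum(prob) + tsum(y)
        return 1.0 - div(2.0 * inter + smooth, denom + smooth)
    prob = np.asarray(prob, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if prob.shape != label.shape:
        raise ValueError("prob/label shape mismatch")
    inter = float((prob * label).sum())
    denom = float(prob.sum() + label.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def multiscale_loss(
    prob_pyramid,
    label_pyramid: LabelPyramid | list[np.ndarray],
    cfg: LossConfig | None = None,
):
    """Weighted mean of per-scale soft dice losses.

    Returns ``(loss, per_scale)`` where ``per_scale`` is a list of float
    per-scale losses for logging.  ``prob_pyramid`` may hold autograd
    tensors (training) or arrays.
    """
    cfg = cfg or LossConfig()
    labels = label_pyramid.masks if isinstance(label_pyramid, LabelPyramid) else label_pyramid
    if len(prob_pyramid) != len(labels):
        raise ValueError(
            f"pyramid level mismatch: {len(prob_pyramid)} vs {len(labels)}"
        )
    weights = cfg.scale_weights or [1.0] * len(labels)
    if len(weights) != len(labels):
        raise ValueError("scale_weights length must match pyramid levels")
    wsum = float(np.sum(weights))
    losses = []
    for p, y in zip(prob_pyramid, labels):
        p_shape = p.data.shape if isinstance(p, Tensor) else np.shape(p)
        if tuple(p_shape) != np.shape(y):
            raise ValueError(f"per-scale shape mismatch: {p_shape} vs {np.shape(y)}")
        losses.append(soft_dice_loss(p, y, cfg.smooth))
    per_scale = [float(l.data) if isinstance(l, Tensor) else float(l) for l in losses]
    total = None
    for w, l in zip(weights, losses):
        term = (w / wsum) * l
        total = term if total is None else total + term
    return total, per_scale


def batch_multiscale_loss(prob_maps, label_stack: list[np.ndarray], cfg: LossConfig | None = None):
    """Batched training loss.

    ``prob_maps``: list of L tensors shaped (N, 1, H/2^s, W/2^s);
    ``label_stack``: list of L arrays shaped (N, H/2^s, W/2^s).
    Soft dice is computed per scale over the whole batch (summing
    intersections and denominators across items), then averaged with the
    configured scale weights.
    """
    cfg = cfg or LossConfig()
    weights = cfg.scale_weights or [1.0] * len(prob_maps)
    wsum = float(np.sum(weights))
    total = None
    per_scale = []
    for w, p, y in zip(weights, prob_maps, label_stack):
        y_t = Tensor(np.asarray(y, np.float32)[:, None])
        inter = tsum(p * y_t)
        denom = tsum(p) + tsum(y_t)
        l = 1.0 - div(2.0 * inter + cfg.smooth, denom + cfg.smooth)
        per_scale.append(float(l.data))
        term = (w / wsum) * l
        total = term if total is None else total + term
    return total, per_scale
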