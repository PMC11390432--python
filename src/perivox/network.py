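"""Densely nested encoder--decoder with multi-scale output heads.

The model is a triangular grid of convolutional nodes ``X(i, j)`` with
``i`` the resolution row (0 = finest) and ``j`` the position along the
skip pathway (``i + j <= L - 1``).  Encoder nodes ``X(i, 0)`` consume the
max-pooled output of the row above; every interior node ``X(i, j > 0)``
consumes the concatenation of all same-row predecessors plus the
upsampled (bilinear 2x followed by a 1x1 channel-matching convolution)
output of ``X(i+1, j-1)``.  This dense nesting gives every target size a
U-shaped sub-network of matching depth, so small structures such as
perivascular spaces are not lost in the deepest rows.

The last node of each row feeds a 1x1 convolution + sigmoid head at that
row's native scale, producing a probability pyramid of ``L`` maps that the
deep-supervision loss pairs with a foreground-preserving label pyramid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor, concat, maxpool2x2, sigmoid, upsample_bilinear2x
from .nn.layers import Conv2d, ConvBlock, Module

__all__ = [
    "NetworkSpec",
    "NestedSegNet",
    "build_network",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters.

    Parameters
    ----------
    levels
        Number of resolution rows L (>= 2).  Input sides must be divisible
        by ``2**(levels - 1)``.
    base_channels
        Channel width of the finest row; row ``i`` has
        ``base_channels * channel_growth**i`` channels.
    channel_growth
        Per-row channel multiplier.
    attention
        Enable per-node channel attention (squeeze-and-excite gate).
    in_channels
        Input image channels (1: a single T2-weighted slice).
    """

    levels: int = 4
    base_channels: int = 32
    channel_growth: int = 2
    attention: bool = True
    in_channels: int = 1

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.base_channels < 1:
            raise ValueError(f"base_channels must be >= 1, got {self.base_channels}")
        if self.channel_growth < 1:
            raise ValueError(f"channel_growth must be >= 1, got {self.channel_growth}")
        if self.in_channels < 1:
            raise ValueError(f"in_channels must be >= 1, got {self.in_channels}")

    @property
    def divisor(self) -> int:
        """Spatial-size divisibility the input must satisfy."""
        return 2 ** (self.levels - 1)

    def channels(self, row: int) -> int:
        return self.base_channels * self.channel_growth**row


class NestedSegNet(Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        L = spec.levels
        ch = [spec.channels(i) for i in range(L)]
        for i in range(L):
            for j in range(L - i):
                if j == 0:
                    cin = spec.in_channels if i == 0 else ch[i - 1]
                else:
                    # j same-row predecessors + channel-matched upsample
                    cin = (j + 1) * ch[i]
                    setattr(
                        self,
                        f"up_{i}_{j}",
                        Conv2d(ch[i + 1], ch[i], 1, rng),
                    )
                setattr(self, f"node_{i}_{j}", ConvBlock(cin, ch[i], rng, spec.attention))
        for s in range(L):
            setattr(self, f"head_{s}", Conv2d(ch[s], 1, 1, rng))

    def __call__(self, x: Tensor) -> list[Tensor]:
        """Forward a batch (N, 1, H, W); returns L per-scale probability maps."""
        spec = self.spec
        L = spec.levels
        h, w = x.data.shape[2], x.data.shape[3]
        d = spec.divisor
        if h % d or w % d:
            raise ValueError(
                f"input sides {h}x{w} not divisible by {d}; pad slices first"
            )
        outputs: dict[tuple[int, int], Tensor] = {}
        # encoder column first, then skip pathways column by column
        for i in range(L):
            inp = x if i == 0 else maxpool2x2(outputs[(i - 1, 0)])
            outputs[(i, 0)] = getattr(self, f"node_{i}_0")(inp)
        for j in range(1, L):
            for i in range(L - j):
                up = upsample_bilinear2x(outputs[(i + 1, j - 1)])
                up = getattr(self, f"up_{i}_{j}")(up)
                parts = [outputs[(i, jj)] for jj in range(j)] + [up]
                outputs[(i, j)] = getattr(self, f"node_{i}_{j}")(concat(parts, axis=1))
        maps = []
        for s in range(L):
            head = getattr(self, f"head_{s}")
            maps.append(sigmoid(head(outputs[(s, L - 1 - s)])))
        return maps


def build_network(spec: NetworkSpec, seed: int = 0) -> NestedSegNet:
    """Construct the nested network with seeded He-normal initialisation."""
    return NestedSegNet(spec, np.random.default_rng(seed))


def parameter_count(model: NestedSegNet) -> int:
    """Total trainable parameter count."""
    return model.parameter_count()


def forward(model: NestedSegNet, batch: np.ndarray) -> list[np.ndarray]:
    """Inference helper: (N, H, W) or (N, 1, H, W) array in, pyramid of arrays out."""
    if batch.ndim == 3:
        batch = batch[:, None, :, :]
    maps = model(Tensor(batch.astype(np.float32)))
    return [m.data[:, 0] for m in maps]


def save_checkpoint(model: NestedSegNet, path: str | Path, meta: dict | None = None):
    """Self-describing checkpoint: weights + architecture spec (+ metadata)."""
    payload = {"spec_json": json.dumps(asdict(model.spec))}
    if meta:
        payload["meta_json"] = json.dumps(meta)
    payload.update(model.state_dict())
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[NestedSegNet, dict]:
    with np.load(path, allow_pickle=False) as npz:
        spec = NetworkSpec(**json.loads(str(npz["spec_json"])))
        meta = json.loads(str(npz["meta_json"])) if "meta_json" in npz else {}
        model = build_network(spec, seed=0)
        state = {k: npz[k] for k in npz.files if not k.endswith("_json")}
    model.load_state_dict(state)
    return model, meta
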