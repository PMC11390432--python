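"""NIfTI volume I/O, intensity normalisation, and 2D slice (de)composition.

The segmentation network consumes individual axial slices, so a subject
volume is decomposed into :class:`SlicePair` objects (image + optional
label per slice, zero-padded to the side multiple the network needs) and
per-slice probability maps are reassembled back into a 3D binary mask
with the padding cropped away.

Conventions: arrays are indexed (x, y, z) with z the slice axis; slice
spacing comes from the NIfTI header; coordinates are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "SlicePair",
    "read_volume",
    "write_volume",
    "normalize",
    "to_slices",
    "reassemble",
]


@dataclass
class Volume:
    """A 3D scalar image with anisotropic voxel spacing."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite voxels")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        self.voxel_size_mm = vs

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def slice_thickness_mm(self) -> float:
        return self.voxel_size_mm[2]


@dataclass
class SlicePair:
    """One axial slice, padded for the network, with optional label."""

    image: np.ndarray
    label: np.ndarray | None
    subject_id: str
    slice_index: int
    pad: tuple[int, int, int, int] = (0, 0, 0, 0)  # (x_before, x_after, y_before, y_after)

    def __post_init__(self):
        if self.label is not None and self.label.shape != self.image.shape:
            raise ValueError("image/label shapes differ")


def read_volume(path: str | Path, mask: bool = False) -> Volume:
    """Load a 3D single-channel NIfTI file.

    With ``mask=True`` the payload must be binary ({0, 1}).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D volume, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError(f"{path.name}: non-finite voxels")
    zooms = img.header.get_zooms()[:3]
    if mask:
        if not np.isin(data, (0, 1)).all():
            raise ValueError(f"{path.name}: mask values outside {{0, 1}}")
        data = data.astype(np.uint8)
    subject_id = path.name.split(".")[0]
    return Volume(data=data, voxel_size_mm=tuple(float(z) for z in zooms), subject_id=subject_id)


def write_volume(volume: Volume, path: str | Path, dtype=None):
    """Write a volume as NIfTI with voxel size in the affine/header."""
    data = volume.data if dtype is None else volume.data.astype(dtype)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def normalize(volume: Volume, policy: str = "zscore") -> Volume:
    """Intensity-normalise a volume (default: per-volume z-score).

    A constant volume maps to all zeros (with a warning), since the
    z-score is undefined there.
    """
    if policy != "zscore":
        raise ValueError(f"unknown normalisation policy {policy!r}")
    data = volume.data.astype(np.float64)
    std = data.std()
    if std == 0:
        import warnings

        warnings.warn(f"constant volume {volume.subject_id!r}: normalised to zeros")
        out = np.zeros_like(data, dtype=np.float32)
    else:
        out = ((data - data.mean()) / std).astype(np.float32)
    return Volume(data=out, voxel_size_mm=volume.voxel_size_mm, subject_id=volume.subject_id)


def _pad_amount(n: int, multiple: int) -> tuple[int, int]:
    target = ((n + multiple - 1) // multiple) * multiple
    extra = target - n
    return extra // 2, extra - extra // 2


def to_slices(
    image: Volume, label: Volume | None = None, pad_to: int = 8
) -> list[SlicePair]:
    """Decompose into per-slice pairs, zero-padded to a side multiple.

    Padding is symmetric (the odd voxel goes to the trailing side) and
    recorded per slice so :func:`reassemble` can invert it exactly.
    """
    if label is not None and label.data.shape != image.data.shape:
        raise ValueError(
            f"image/label grids misaligned: {image.data.shape} vs {label.data.shape}"
        )
    nx, ny, nz = image.data.shape
    px = _pad_amount(nx, pad_to)
    py = _pad_amount(ny, pad_to)
    pad = (px[0], px[1], py[0], py[1])
    pairs = []
    for k in range(nz):
        img2d = np.pad(image.data[:, :, k], (px, py)).astype(np.float32)
        lab2d = None
        if label is not None:
            lab2d = np.pad(label.data[:, :, k], (px, py)).astype(np.uint8)
        pairs.append(
            SlicePair(
                image=img2d,
                label=lab2d,
                subject_id=image.subject_id,
                slice_index=k,
                pad=pad,
            )
        )
    return pairs


def reassemble(
    prob_maps: dict[int, np.ndarray] | list[np.ndarray],
    pad: tuple[int, int, int, int],
    voxel_size_mm: tuple[float, float, float],
    subject_id: str = "",
    threshold: float = 0.5,
) -> Volume:
    """Stack per-slice probability maps into a 3D binary mask volume.

    Foreground iff probability is strictly above ``threshold`` (a map
    value exactly at the threshold stays background — a fixed tie rule
    for bit-reproducibility).  Padding recorded by :func:`to_slices` is
    cropped.
    """
    if isinstance(prob_maps, dict):
        indices = sorted(prob_maps)
        if indices != list(range(len(indices))):
            missing = sorted(set(range(max(indices) + 1)) - set(indices))
            raise ValueError(f"missing slice indices: {missing}")
        maps = [prob_maps[k] for k in indices]
    else:
        maps = list(prob_maps)
    if not maps:
        raise ValueError("no slices to reassemble")
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes: {shapes}")
    stack = np.stack(maps, axis=2)
    xb, xa, yb, ya = pad
    stack = stack[xb : stack.shape[0] - xa or None, yb : stack.shape[1] - ya or None, :]
    mask = (stack > threshold).astype(np.uint8)
    return Volume(data=mask, voxel_size_mm=voxel_size_mm, subject_id=subject_id)
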