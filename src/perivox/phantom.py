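"""Synthetic T2-like brain phantoms with ground-truth perivascular-space masks.

Perivascular spaces (PVSs) are thin fluid-filled channels around
penetrating vessels: on axial T2-weighted slices they read as bright
*lines* when the vessel runs in-plane and as bright *dots* when it runs
through-plane, at a signal close to CSF.  Real annotated cohorts are not
freely shareable, so this module builds schematic but statistically
matched volumes on which the whole pipeline (slicing, training,
evaluation, burden counting) can be exercised end to end:

* an ellipsoidal "brain" of tissue intensity on a dark exterior, with a
  central CSF-bright ventricle block whose top slice is recorded (the
  landmark that anchors the centrum-semiovale counting slice);
* capsule-shaped PVSs — in-plane tubes and through-plane dots — at
  CSF-like intensity, a configurable fraction rendered at reduced
  contrast to emulate faint PVSs;
* the known confounders: curvilinear sulcus-like arcs hugging the brain
  boundary and larger lacune-like blobs;
* Rician (magnitude-MR) or Gaussian noise.

Default voxel geometry follows high-resolution axial T2 protocols:
0.69 x 0.69 mm in plane, 2.0 mm slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .imageio import Volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Structure",
    "BrainGeometry",
    "PlacementError",
    "make_brain_background",
    "sample_pvs_structures",
    "rasterize",
    "render",
    "generate_subject",
    "phantom_dataset",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)


class PlacementError(RuntimeError):
    """Raised when the requested structure count cannot be placed."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generator configuration.

    Intensities are arbitrary units with ``pvs_mean ~ csf_mean >
    tissue_mean`` (PVSs are CSF-bright on T2).  All lengths are mm;
    ``grid_shape`` is (nx, ny, nz) voxels with z the slice axis.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 32)
    voxel_size_mm: tuple[float, float, float] = (0.69, 0.69, 2.0)
    n_tubes: int = 6
    n_dots: int = 8
    tube_length_mm: tuple[float, float] = (5.0, 15.0)
    pvs_radius_mm: tuple[float, float] = (0.4, 1.0)
    tissue_mean: float = 100.0
    csf_mean: float = 200.0
    pvs_mean: float = 200.0
    n_sulci: int = 3
    n_lacunes: int = 2
    low_signal_fraction: float = 0.2
    noise_sigma: float = 5.0
    noise_model: str = "rician"
    min_separation_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tubes", "n_dots", "n_sulci", "n_lacunes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.tube_length_mm) <= 0 or min(self.pvs_radius_mm) <= 0:
            raise ValueError("length and radius ranges must be positive")
        if not self.pvs_mean > self.tissue_mean:
            raise ValueError("pvs_mean must exceed tissue_mean")
        if not 0.0 <= self.low_signal_fraction <= 1.0:
            raise ValueError("low_signal_fraction must be in [0, 1]")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")


@dataclass
class Structure:
    """A capsule segment: PVS tube/dot, or a lacune (zero-length capsule)."""

    kind: str  # "tube" | "dot" | "lacune"
    center_mm: tuple[float, float, float]
    direction: tuple[float, float, float]  # unit vector
    length_mm: float
    radius_mm: float
    contrast: float = 1.0  # 1 = full CSF-like signal; <1 = faint PVS

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center_mm)
        d = np.asarray(self.direction)
        h = self.length_mm / 2.0
        return c - h * d, c + h * d


@dataclass
class BrainGeometry:
    """Ellipsoid + ventricle layout, in mm (voxel centres at (i+0.5)*spacing)."""

    center_mm: np.ndarray
    semi_axes_mm: np.ndarray  # brain ellipsoid
    ventricle_center_mm: np.ndarray
    ventricle_semi_axes_mm: np.ndarray
    ventricle_top_index: int
    bg_slice_index: int

    def inside_brain(self, pts_mm: np.ndarray, margin: float = 0.0) -> np.ndarray:
        rel = (pts_mm - self.center_mm) / (self.semi_axes_mm * (1.0 - margin))
        return (rel**2).sum(axis=-1) <= 1.0

    def inside_ventricle(self, pts_mm: np.ndarray, dilate_mm: float = 0.0) -> np.ndarray:
        rel = (pts_mm - self.ventricle_center_mm) / (
            self.ventricle_semi_axes_mm + dilate_mm
        )
        return (rel**2).sum(axis=-1) <= 1.0


@dataclass
class PhantomTruth:
    """Ground truth shipped with a phantom volume."""

    mask: np.ndarray  # uint8 {0,1}, same grid as the volume
    per_slice_counts: list[int]
    bg_slice_index: int
    cso_slice_index: int
    ventricle_top_index: int
    structure_table: list[Structure]

    def to_json_dict(self) -> dict:
        return {
            "per_slice_counts": [int(c) for c in self.per_slice_counts],
            "bg_slice_index": int(self.bg_slice_index),
            "cso_slice_index": int(self.cso_slice_index),
            "ventricle_top_index": int(self.ventricle_top_index),
            "structures": [asdict(s) for s in self.structure_table],
        }


def _voxel_centers_mm(grid_shape, voxel_size_mm):
    """Coordinate arrays (mm) of voxel centres along each axis."""
    return [
        (np.arange(n) + 0.5) * s for n, s in zip(grid_shape, voxel_size_mm)
    ]


def make_brain_background(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[Volume, BrainGeometry]:
    """Noise-free tissue substrate: ellipsoidal brain + central ventricle.

    The ventricle occupies the lower-middle slices; its top slice index
    and a mid-ventricle "anterior-commissure analogue" slice (the basal
    ganglia counting slice) are recorded in the returned geometry.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size_mm
    extent = np.array([nx * dx, ny * dy, nz * dz])
    center = extent / 2.0
    semi = extent * np.array([0.45, 0.45, 0.48])
    # require a handful of voxels of brain and of headroom above the ventricle
    if nx < 16 or ny < 16 or nz < 8:
        raise ValueError(
            f"grid {spec.grid_shape} too small for brain + ventricle layout"
        )
    # ventricle: small central ellipsoid in-plane, spanning ~25-55% of z
    z_lo, z_hi = 0.25 * extent[2], 0.55 * extent[2]
    v_center = np.array([center[0], center[1], (z_lo + z_hi) / 2.0])
    v_semi = np.array([0.10 * extent[0], 0.16 * extent[1], (z_hi - z_lo) / 2.0])
    xs, ys, zs = _voxel_centers_mm(spec.grid_shape, spec.voxel_size_mm)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    geom = BrainGeometry(
        center_mm=center,
        semi_axes_mm=semi,
        ventricle_center_mm=v_center,
        ventricle_semi_axes_mm=v_semi,
        ventricle_top_index=0,
        bg_slice_index=0,
    )
    brain = geom.inside_brain(grid)
    vent = geom.inside_ventricle(grid) & brain
    if not vent.any():
        raise ValueError("grid too small: ventricle rasterised to zero voxels")
    data = np.zeros(spec.grid_shape, dtype=np.float32)
    data[brain] = spec.tissue_mean
    data[vent] = spec.csf_mean
    vent_slices = np.where(vent.any(axis=(0, 1)))[0]
    geom.ventricle_top_index = int(vent_slices.max())
    geom.bg_slice_index = int(round(vent_slices.mean()))
    vol = Volume(data=data, voxel_size_mm=spec.voxel_size_mm, subject_id="phantom")
    return vol, geom


def sample_pvs_structures(
    spec: PhantomSpec, geom: BrainGeometry, rng: np.random.Generator
) -> list[Structure]:
    """Place tube (in-plane) and dot (through-plane) PVS capsules.

    Centres keep ``min_separation_mm`` from each other, lie inside the
    brain (with margin) and outside the (dilated) ventricle; both capsule
    endpoints must stay inside the brain.  A ``low_signal_fraction``
    subset is flagged with reduced contrast.
    """
    structures: list[Structure] = []
    centers: list[np.ndarray] = []
    kinds = ["tube"] * spec.n_tubes + ["dot"] * spec.n_dots
    max_tries = 400
    for kind in kinds:
        placed = False
        for _ in range(max_tries):
            u = rng.uniform(-1.0, 1.0, size=3)
            cand = geom.center_mm + u * geom.semi_axes_mm * 0.9
            if not geom.inside_brain(cand[None], margin=0.12)[0]:
                continue
            if geom.inside_ventricle(cand[None], dilate_mm=spec.min_separation_mm)[0]:
                continue
            if centers and min(
                np.linalg.norm(cand - c) for c in centers
            ) < spec.min_separation_mm:
                continue
            length = rng.uniform(*spec.tube_length_mm)
            radius = rng.uniform(*spec.pvs_radius_mm)
            if kind == "tube":
                theta = rng.uniform(0.0, 2 * math.pi)
                direction = np.array([math.cos(theta), math.sin(theta), 0.0])
            else:
                direction = np.array([0.0, 0.0, 1.0])
                length = min(length, 8.0)  # penetrating vessels span few slices
            s = Structure(
                kind=kind,
                center_mm=tuple(cand),
                direction=tuple(direction),
                length_mm=float(length),
                radius_mm=float(radius),
            )
            p0, p1 = s.endpoints
            ends = np.stack([p0, p1])
            if not geom.inside_brain(ends, margin=0.06).all():
                continue
            if geom.inside_ventricle(ends, dilate_mm=spec.min_separation_mm / 2).any():
                continue
            structures.append(s)
            centers.append(cand)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"placed only {len(structures)}/{len(kinds)} PVS structures at "
                f"min separation {spec.min_separation_mm} mm"
            )
    # flag faint PVSs (deterministic choice from the stream)
    n_low = int(round(spec.low_signal_fraction * len(structures)))
    if n_low:
        idx = rng.choice(len(structures), size=n_low, replace=False)
        for i in idx:
            structures[i].contrast = float(rng.uniform(0.3, 0.6))
    return structures


def _capsule_mask(s: Structure, grid_shape, voxel_size_mm) -> np.ndarray:
    """Voxels within ``radius`` of the capsule segment; centre voxel always on."""
    dx, dy, dz = voxel_size_mm
    spacing = np.array(voxel_size_mm)
    p0, p1 = s.endpoints
    r = s.radius_mm
    # bounding box in voxel indices, padded by the radius + a voxel
    lo_mm = np.minimum(p0, p1) - r - spacing
    hi_mm = np.maximum(p0, p1) + r + spacing
    lo = np.maximum(0, np.floor(lo_mm / spacing - 0.5).astype(int))
    hi = np.minimum(grid_shape, np.ceil(hi_mm / spacing + 0.5).astype(int))
    mask = np.zeros(grid_shape, dtype=bool)
    if (hi <= lo).any():
        lo = np.maximum(0, np.minimum(lo, np.array(grid_shape) - 1))
    sub_axes = [
        (np.arange(lo[k], hi[k]) + 0.5) * spacing[k] for k in range(3)
    ]
    gx, gy, gz = np.meshgrid(*sub_axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
        nearest = p0[None, None, None, :] + t[..., None] * seg[None, None, None, :]
        dist = np.linalg.norm(pts - nearest, axis=-1)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = dist <= r
    # guaranteed support: thin capsules must not vanish under coarse sampling
    cidx = np.clip(
        np.floor(np.asarray(s.center_mm) / spacing).astype(int),
        0,
        np.array(grid_shape) - 1,
    )
    mask[tuple(cidx)] = True
    return mask


def rasterize(
    structures: list[Structure], grid_shape, voxel_size_mm
) -> np.ndarray:
    """Union of capsule masks on the anisotropic grid (uint8 {0,1})."""
    mask = np.zeros(grid_shape, dtype=bool)
    for s in structures:
        mask |= _capsule_mask(s, grid_shape, voxel_size_mm)
    return mask.astype(np.uint8)


def _add_sulci(
    data: np.ndarray, spec: PhantomSpec, geom: BrainGeometry, rng: np.random.Generator
):
    """Bright curvilinear arcs just inside the brain boundary (sulcus mimics)."""
    nx, ny, nz = spec.grid_shape
    dz = spec.voxel_size_mm[2]
    for _ in range(spec.n_sulci):
        k = int(rng.integers(int(0.3 * nz), int(0.9 * nz)))
        z_mm = (k + 0.5) * dz
        # in-plane brain ellipse cross-section at this z
        rel_z = (z_mm - geom.center_mm[2]) / geom.semi_axes_mm[2]
        if abs(rel_z) >= 0.95:
            continue
        shrink = math.sqrt(1.0 - rel_z**2)
        a = geom.semi_axes_mm[0] * shrink * rng.uniform(0.88, 0.95)
        b = geom.semi_axes_mm[1] * shrink * rng.uniform(0.88, 0.95)
        t0 = rng.uniform(0.0, 2 * math.pi)
        span = rng.uniform(0.5, 1.3)
        ts = np.linspace(t0, t0 + span, 24)
        pts = np.stack(
            [
                geom.center_mm[0] + a * np.cos(ts),
                geom.center_mm[1] + b * np.sin(ts),
                np.full_like(ts, z_mm),
            ],
            axis=-1,
        )
        radius = rng.uniform(0.4, 0.8)
        for p, q in zip(pts[:-1], pts[1:]):
            seg = Structure(
                kind="sulcus",
                center_mm=tuple((p + q) / 2),
                direction=tuple((q - p) / (np.linalg.norm(q - p) + 1e-9)),
                length_mm=float(np.linalg.norm(q - p)),
                radius_mm=radius,
            )
            m = _capsule_mask(seg, spec.grid_shape, spec.voxel_size_mm)
            data[m] = spec.csf_mean


def _add_lacunes(
    data: np.ndarray,
    pvs_mask: np.ndarray,
    spec: PhantomSpec,
    geom: BrainGeometry,
    rng: np.random.Generator,
) -> list[Structure]:
    """Bright blobs larger than any PVS, kept clear of the PVS structures."""
    lacunes = []
    r_hi = max(spec.pvs_radius_mm)
    for _ in range(spec.n_lacunes):
        for _ in range(200):
            u = rng.uniform(-1.0, 1.0, size=3)
            cand = geom.center_mm + u * geom.semi_axes_mm * 0.7
            if not geom.inside_brain(cand[None], margin=0.2)[0]:
                continue
            if geom.inside_ventricle(cand[None], dilate_mm=4.0)[0]:
                continue
            radius = rng.uniform(1.6 * r_hi, 2.8 * r_hi)
            s = Structure(
                kind="lacune",
                center_mm=tuple(cand),
                direction=(0.0, 0.0, 1.0),
                length_mm=0.0,
                radius_mm=float(radius),
            )
            m = _capsule_mask(s, spec.grid_shape, spec.voxel_size_mm)
            dil = ndimage.binary_dilation(pvs_mask, iterations=2)
            if (m & dil.astype(bool)).any():
                continue
            data[m] = spec.csf_mean
            lacunes.append(s)
            break
    return lacunes


def _apply_noise(data: np.ndarray, spec: PhantomSpec, rng: np.random.Generator):
    if spec.noise_sigma == 0:
        return data
    if spec.noise_model == "gaussian":
        return data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    # Rician: magnitude of the complex signal with i.i.d. Gaussian channels
    re = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    im = rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return np.sqrt(re**2 + im**2)


def render(
    volume: Volume,
    mask: np.ndarray,
    structures: list[Structure],
    spec: PhantomSpec,
    geom: BrainGeometry,
    rng: np.random.Generator,
) -> Volume:
    """Paint PVSs and confounders onto the background, then apply noise.

    Each PVS voxel gets ``tissue_mean + contrast * (pvs_mean -
    tissue_mean)`` (full contrast 1.0, faint PVSs < 1); overlaps take the
    brighter value.  Sulcus arcs and lacune blobs are added at CSF
    intensity, away from the true PVSs, and noise is applied last.
    """
    data = volume.data.astype(np.float64).copy()
    for s in structures:
        m = _capsule_mask(s, spec.grid_shape, spec.voxel_size_mm).astype(bool)
        level = spec.tissue_mean + s.contrast * (spec.pvs_mean - spec.tissue_mean)
        data[m] = np.maximum(data[m], level)
    _add_sulci(data, spec, geom, rng)
    _add_lacunes(data, mask.astype(bool), spec, geom, rng)
    data = _apply_noise(data, spec, rng)
    return Volume(
        data=data.astype(np.float32),
        voxel_size_mm=spec.voxel_size_mm,
        subject_id=volume.subject_id,
    )


def per_slice_component_counts(mask: np.ndarray) -> list[int]:
    """Connected-component count per axial slice (8-connectivity in-plane)."""
    return [
        int(ndimage.label(mask[:, :, k], structure=EIGHT_CONN)[1])
        for k in range(mask.shape[2])
    ]


def generate_subject(spec: PhantomSpec, seed: int | None = None) -> tuple[Volume, PhantomTruth]:
    """Full phantom: background -> structures -> mask -> rendering -> truth."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    background, geom = make_brain_background(spec, rng)
    structures = sample_pvs_structures(spec, geom, rng)
    mask = rasterize(structures, spec.grid_shape, spec.voxel_size_mm)
    rendered = render(background, mask, structures, spec, geom, rng)
    dz = spec.voxel_size_mm[2]
    cso = geom.ventricle_top_index + math.ceil(10.0 / dz)
    truth = PhantomTruth(
        mask=mask,
        per_slice_counts=per_slice_component_counts(mask),
        bg_slice_index=geom.bg_slice_index,
        cso_slice_index=cso,
        ventricle_top_index=geom.ventricle_top_index,
        structure_table=structures,
    )
    return rendered, truth


def phantom_dataset(
    n_subjects: int,
    spec: PhantomSpec,
    seed: int = 0,
    age_range: tuple[int, int] = (42, 79),
) -> list[tuple[Volume, PhantomTruth, str, int]]:
    """Generate a cohort; subject k uses derived seed ``seed + k``.

    Per-subject seeds are fixed offsets so the cohort can be extended
    without reshuffling earlier subjects.  Ages are drawn uniformly over
    ``age_range`` (inclusive), emulating an age-spread patient cohort.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cohort = []
    for k in range(n_subjects):
        sub_seed = seed + k
        vol, truth = generate_subject(spec, seed=sub_seed)
        age_rng = np.random.default_rng(sub_seed + 1_000_003)
        age = int(age_rng.integers(age_range[0], age_range[1] + 1))
        sid = f"sub-{k:03d}"
        vol.subject_id = sid
        cohort.append((vol, truth, sid, age))
    return cohort
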