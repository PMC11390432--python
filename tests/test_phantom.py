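"""Phantom generator: determinism, geometry, rasterisation, noise, truth."""

import math

import numpy as np
import pytest

from conftest import flood_fill_components
from perivox.phantom import (
    PhantomSpec,
    PlacementError,
    Structure,
    generate_subject,
    make_brain_background,
    per_slice_component_counts,
    phantom_dataset,
    rasterize,
    render,
    sample_pvs_structures,
)


def quiet_spec(**kw):
    base = dict(
        grid_shape=(48, 48, 12),
        n_tubes=0,
        n_dots=0,
        n_sulci=0,
        n_lacunes=0,
        low_signal_fraction=0.0,
        noise_sigma=0.0,
    )
    base.update(kw)
    return PhantomSpec(**base)


# -- spec validation -------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_tubes": -1},
        {"pvs_radius_mm": (0.0, 1.0)},
        {"tissue_mean": 250.0},  # violates pvs_mean > tissue_mean
        {"low_signal_fraction": 1.5},
        {"noise_model": "poisson"},
        {"noise_sigma": -1.0},
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(ValueError):
        quiet_spec(**kwargs)


# -- background ------------------------------------------------------------


def test_background_intensities_are_exact_without_noise():
    spec = quiet_spec()
    vol, geom = make_brain_background(spec, np.random.default_rng(0))
    values = set(np.unique(vol.data).tolist())
    assert values == {0.0, spec.tissue_mean, spec.csf_mean}
    # ventricle (CSF) brighter than tissue
    assert spec.csf_mean > spec.tissue_mean
    assert 0 <= geom.ventricle_top_index < spec.grid_shape[2]
    assert 0 <= geom.bg_slice_index <= geom.ventricle_top_index


def test_background_deterministic():
    spec = quiet_spec()
    v1, _ = make_brain_background(spec, np.random.default_rng(5))
    v2, _ = make_brain_background(spec, np.random.default_rng(5))
    np.testing.assert_array_equal(v1.data, v2.data)


def test_too_small_grid_raises_sizing_error():
    with pytest.raises(ValueError, match="too small"):
        make_brain_background(quiet_spec(grid_shape=(8, 8, 4)), np.random.default_rng(0))


# -- structure sampling ----------------------------------------------------


def test_empty_request_gives_empty_table():
    spec = quiet_spec()
    _, geom = make_brain_background(spec, np.random.default_rng(0))
    assert sample_pvs_structures(spec, geom, np.random.default_rng(0)) == []


def test_dots_are_through_plane_and_inside_brain():
    spec = quiet_spec(n_dots=5)
    _, geom = make_brain_background(spec, np.random.default_rng(1))
    table = sample_pvs_structures(spec, geom, np.random.default_rng(1))
    assert len(table) == 5
    for s in table:
        assert s.kind == "dot"
        assert s.direction == (0.0, 0.0, 1.0)
        assert geom.inside_brain(np.asarray(s.center_mm)[None])[0]


def test_tubes_are_in_plane():
    spec = quiet_spec(n_tubes=4)
    _, geom = make_brain_background(spec, np.random.default_rng(2))
    for s in sample_pvs_structures(spec, geom, np.random.default_rng(2)):
        assert s.kind == "tube"
        assert s.direction[2] == 0.0


def test_min_separation_enforced():
    spec = quiet_spec(n_tubes=3, n_dots=3, min_separation_mm=5.0)
    _, geom = make_brain_background(spec, np.random.default_rng(3))
    table = sample_pvs_structures(spec, geom, np.random.default_rng(3))
    centers = [np.asarray(s.center_mm) for s in table]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            assert np.linalg.norm(centers[i] - centers[j]) >= 5.0


def test_impossible_placement_raises_naming_achieved_count():
    spec = quiet_spec(n_dots=500, min_separation_mm=12.0)
    _, geom = make_brain_background(spec, np.random.default_rng(4))
    with pytest.raises(PlacementError, match=r"placed only \d+/500"):
        sample_pvs_structures(spec, geom, np.random.default_rng(4))


# -- rasterisation ---------------------------------------------------------


def test_empty_table_rasterises_to_zero_mask():
    mask = rasterize([], (16, 16, 4), (0.69, 0.69, 2.0))
    assert mask.sum() == 0


def test_subvoxel_dot_still_paints_center_voxel():
    s = Structure(
        kind="dot",
        center_mm=(5.0, 5.0, 3.0),
        direction=(0.0, 0.0, 1.0),
        length_mm=0.5,
        radius_mm=0.1,  # below in-plane voxel size
    )
    mask = rasterize([s], (16, 16, 4), (0.69, 0.69, 2.0))
    assert mask.sum() >= 1


def test_separated_structures_give_k_components():
    """3D component count of well-separated capsules equals the capsule count
    (verified with a brute-force union-find over the full grid)."""
    spacing = (1.0, 1.0, 1.0)
    structures = [
        Structure("dot", (5.0, 5.0, 5.0), (0.0, 0.0, 1.0), 3.0, 0.8),
        Structure("dot", (15.0, 5.0, 5.0), (0.0, 0.0, 1.0), 3.0, 0.8),
        Structure("tube", (10.0, 15.0, 10.0), (1.0, 0.0, 0.0), 4.0, 0.8),
    ]
    mask = rasterize(structures, (20, 20, 14), spacing)
    # brute-force 3D flood fill (26-connectivity)
    seen = np.zeros_like(mask, dtype=bool)
    comps = 0
    idx = np.argwhere(mask)
    mask_b = mask.astype(bool)
    for start in map(tuple, idx):
        if seen[start]:
            continue
        comps += 1
        stack = [start]
        seen[start] = True
        while stack:
            c = stack.pop()
            for d in np.ndindex(3, 3, 3):
                n = tuple(np.array(c) + np.array(d) - 1)
                if all(0 <= n[k] < mask.shape[k] for k in range(3)):
                    if mask_b[n] and not seen[n]:
                        seen[n] = True
                        stack.append(n)
    assert comps == len(structures)


# -- rendering -------------------------------------------------------------


def test_noise_free_pvs_voxels_sit_at_assigned_contrast():
    spec = quiet_spec(n_dots=3)
    vol, geom = make_brain_background(spec, np.random.default_rng(6))
    rng = np.random.default_rng(6)
    table = sample_pvs_structures(spec, geom, rng)
    mask = rasterize(table, spec.grid_shape, spec.voxel_size_mm)
    rendered = render(vol, mask, table, spec, geom, rng)
    assert np.all(rendered.data[mask.astype(bool)] == spec.pvs_mean)


def test_full_low_signal_fraction_strictly_between_tissue_and_pvs():
    spec = quiet_spec(n_dots=4, low_signal_fraction=1.0)
    vol, geom = make_brain_background(spec, np.random.default_rng(7))
    rng = np.random.default_rng(7)
    table = sample_pvs_structures(spec, geom, rng)
    assert all(s.contrast < 1.0 for s in table)
    mask = rasterize(table, spec.grid_shape, spec.voxel_size_mm)
    rendered = render(vol, mask, table, spec, geom, rng)
    vals = rendered.data[mask.astype(bool)]
    assert (vals > spec.tissue_mean).all() and (vals < spec.pvs_mean).all()


def test_rician_noise_on_zero_background_is_nonnegative():
    """Magnitude-of-complex-Gaussian construction: |0 + n1 + i n2| >= 0."""
    spec = quiet_spec(noise_sigma=8.0, noise_model="rician")
    vol, truth = generate_subject(spec, seed=9)
    assert (vol.data >= 0).all()
    # and the same construction checked directly on a zero signal
    rng = np.random.default_rng(0)
    mag = np.sqrt(rng.normal(0, 8, 10_000) ** 2 + rng.normal(0, 8, 10_000) ** 2)
    assert (mag >= 0).all()


def test_contrast_ordering_without_noise():
    spec = quiet_spec(n_tubes=2, n_dots=2)
    vol, truth = generate_subject(spec, seed=12)
    pvs = truth.mask.astype(bool)
    tissue = (vol.data == spec.tissue_mean) & ~pvs
    assert vol.data[pvs].mean() > vol.data[tissue].mean()


# -- full subject / truth ---------------------------------------------------


def test_subject_determinism_bit_identical(small_spec):
    v1, t1 = generate_subject(small_spec)
    v2, t2 = generate_subject(small_spec)
    np.testing.assert_array_equal(v1.data, v2.data)
    np.testing.assert_array_equal(t1.mask, t2.mask)
    assert t1.per_slice_counts == t2.per_slice_counts
    assert t1.to_json_dict() == t2.to_json_dict()


def test_per_slice_counts_match_independent_flood_fill(small_subject):
    _, truth = small_subject
    for k in range(truth.mask.shape[2]):
        assert truth.per_slice_counts[k] == flood_fill_components(truth.mask[:, :, k])


def test_cso_landmark_is_ceil_10mm_above_ventricle_top(small_subject):
    _, truth = small_subject
    dz = 2.0
    assert truth.cso_slice_index - truth.ventricle_top_index == math.ceil(10.0 / dz)
    assert truth.cso_slice_index - truth.ventricle_top_index == 5


def test_counts_recompute_helper_agrees(small_subject):
    _, truth = small_subject
    assert per_slice_component_counts(truth.mask) == truth.per_slice_counts


# -- cohort ----------------------------------------------------------------


def test_cohort_ages_within_default_range(small_spec):
    cohort = phantom_dataset(20, small_spec, seed=1)
    ages = [age for _, _, _, age in cohort]
    assert all(42 <= a <= 79 for a in ages)


def test_cohort_determinism_and_subject_independence(small_spec):
    c1 = phantom_dataset(3, small_spec, seed=2)
    c2 = phantom_dataset(3, small_spec, seed=2)
    for (v1, t1, s1, a1), (v2, t2, s2, a2) in zip(c1, c2):
        np.testing.assert_array_equal(v1.data, v2.data)
        assert (s1, a1) == (s2, a2)
    # distinct derived seeds: volumes pairwise different
    vols = [v.data for v, _, _, _ in c1]
    assert not np.array_equal(vols[0], vols[1])
    assert not np.array_equal(vols[1], vols[2])


def test_extending_cohort_preserves_earlier_subjects(small_spec):
    c3 = phantom_dataset(3, small_spec, seed=4)
    c5 = phantom_dataset(5, small_spec, seed=4)
    for (v1, _, _, _), (v2, _, _, _) in zip(c3, c5):
        np.testing.assert_array_equal(v1.data, v2.data)
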