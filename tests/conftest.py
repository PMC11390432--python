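import numpy as np
import pytest

from perivox.phantom import PhantomSpec, generate_subject, phantom_dataset


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A fast low-count phantom configuration shared across tests."""
    return PhantomSpec(
        grid_shape=(48, 48, 12),
        n_tubes=2,
        n_dots=3,
        tube_length_mm=(4.0, 8.0),
        pvs_radius_mm=(0.5, 1.0),
        n_sulci=1,
        n_lacunes=1,
        low_signal_fraction=0.2,
        noise_sigma=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return generate_subject(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return phantom_dataset(4, small_spec, seed=3)


def flood_fill_components(mask2d: np.ndarray, connectivity: int = 8) -> int:
    """Independent brute-force 2D connected-component counter (BFS)."""
    mask = np.asarray(mask2d).astype(bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    ci, cj = stack.pop()
                    for di, dj in offsets:
                        ni, nj = ci + di, cj + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            stack.append((ni, nj))
    return count
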