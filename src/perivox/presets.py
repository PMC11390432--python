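"""Canonical desk-scale study conditions.

The full-scale protocol (20 patients, 320x320 slices, 1000-epoch
training) is a GPU-cluster workload on data that is not publicly
deposited.  These presets define the package's reduced reference
conditions — 5 phantom subjects on a 64x64x16 grid, a depth-3 network,
20 training epochs — used by the documentation examples, the end-to-end
tests and the acceptance script.  Two phantom regimes are defined:

* ``clean``: full-contrast PVSs, no confounders — the easy regime on
  which a correct implementation must reach high held-out Dice;
* ``confounded``: the same geometry plus sulcus-like arcs, lacune-like
  blobs and a 40% fraction of faint PVSs — the failure modes reported
  for PVS segmentation, which must strictly lower the score.
"""

from __future__ import annotations

from .network import NetworkSpec
from .phantom import PhantomSpec
from .supervision import LossConfig
from .training import TrainConfig, run_crossval
from .phantom import phantom_dataset

__all__ = [
    "reduced_phantom_spec",
    "reduced_network_spec",
    "reduced_train_config",
    "reduced_crossval",
]

REDUCED_GRID = (64, 64, 16)
REDUCED_EPOCHS = 20
N_SUBJECTS = 5


def reduced_phantom_spec(confounders: bool) -> PhantomSpec:
    """Desk-scale phantom regime (clean or confounded)."""
    common = dict(
        grid_shape=REDUCED_GRID,
        n_tubes=4,
        n_dots=6,
        tube_length_mm=(4.0, 10.0),
        pvs_radius_mm=(0.5, 1.0),
        noise_sigma=5.0,
    )
    if confounders:
        return PhantomSpec(
            n_sulci=3, n_lacunes=2, low_signal_fraction=0.4, **common
        )
    return PhantomSpec(n_sulci=0, n_lacunes=0, low_signal_fraction=0.0, **common)


def reduced_network_spec() -> NetworkSpec:
    """Depth-3 nested network sized for 64x64 slices on one CPU."""
    return NetworkSpec(levels=3, base_channels=8, channel_growth=2, attention=True)


def reduced_train_config(seed: int) -> TrainConfig:
    """Study optimiser settings at a reduced epoch budget."""
    return TrainConfig(
        batch_size=4,
        learning_rate=0.05,
        max_epochs=REDUCED_EPOCHS,
        select_epoch=REDUCED_EPOCHS,
        seed=seed,
        checkpoint_every=10,
    )


def reduced_crossval(seed: int, confounders: bool) -> dict:
    """Simulate the reduced cohort and run the five-fold protocol on it."""
    cohort = phantom_dataset(
        N_SUBJECTS, reduced_phantom_spec(confounders), seed=seed
    )
    return run_crossval(
        [(vol, truth, sid, age) for vol, truth, sid, age in cohort],
        reduced_train_config(seed),
        reduced_network_spec(),
        LossConfig(),
        k=N_SUBJECTS,
    )
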