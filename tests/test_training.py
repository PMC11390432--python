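"""Fold protocol, training loop determinism, checkpoint selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perivox.imageio import SlicePair
from perivox.network import NetworkSpec
from perivox.supervision import LossConfig
from perivox.training import (
    FoldSplit,
    TrainConfig,
    make_folds,
    select_checkpoint,
    train_model,
)


def subjects_with_ages(n, seed=0):
    rng = np.random.default_rng(seed)
    return [(f"s{i:03d}", int(a)) for i, a in enumerate(rng.integers(40, 80, size=n))]


# -- folds -----------------------------------------------------------------


def test_twenty_subjects_give_five_folds_of_four():
    split = make_folds(subjects_with_ages(20), k=5, seed=1)
    sizes = [len(split.fold_members(f)) for f in range(5)]
    assert sizes == [4, 4, 4, 4, 4]


def test_each_fold_tested_exactly_once_and_sets_disjoint():
    split = make_folds(subjects_with_ages(20), k=5, seed=2)
    tests = [r["test"] for r in split.rounds]
    assert sorted(tests) == [0, 1, 2, 3, 4]
    for r in split.rounds:
        assert r["validation"] != r["test"]
        assert sorted([r["test"], r["validation"], *r["train"]]) == [0, 1, 2, 3, 4]


def test_sorted_deal_age_balance_bound():
    """Ages 1..10 into 5 folds: each fold gets {k, 11-k}-style pairs, so the
    fold-mean deviation from the global mean 5.5 is at most 2.5."""
    subjects = [(f"s{i}", i + 1) for i in range(10)]
    split = make_folds(subjects, k=5, seed=0)
    ages = dict(subjects)
    global_mean = np.mean([a for _, a in subjects])
    for f in range(5):
        fold_mean = np.mean([ages[s] for s in split.fold_members(f)])
        assert abs(fold_mean - global_mean) <= 2.5


def test_split_deterministic_for_seed():
    s1 = make_folds(subjects_with_ages(17), k=5, seed=9)
    s2 = make_folds(subjects_with_ages(17), k=5, seed=9)
    assert s1.assignment == s2.assignment
    assert s1.rounds == s2.rounds


def test_fewer_subjects_than_folds_rejected():
    with pytest.raises(ValueError, match="at least"):
        make_folds(subjects_with_ages(3), k=5)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(n=st.integers(min_value=5, max_value=40), seed=st.integers(0, 1000))
def test_fold_invariants_hold_for_any_cohort(n, seed):
    split = make_folds(subjects_with_ages(n, seed), k=5, seed=seed)
    sizes = [len(split.fold_members(f)) for f in range(5)]
    assert sum(sizes) == n
    assert max(sizes) - min(sizes) <= 1
    assert len(split.assignment) == n
    for r in split.rounds:
        assert r["validation"] != r["test"]
        assert len(r["train"]) == 3


# -- training loop ---------------------------------------------------------


def _slice_set(n, seed=0, size=16):
    rng = np.random.default_rng(seed)
    pairs = []
    for k in range(n):
        label = (rng.random((size, size)) < 0.1).astype(np.uint8)
        image = label * 2.0 + rng.normal(0, 0.3, (size, size))
        pairs.append(
            SlicePair(image=image.astype(np.float32), label=label, subject_id="s0", slice_index=k)
        )
    return pairs


NET = NetworkSpec(levels=2, base_channels=4, channel_growth=2, attention=False)


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        train_model(TrainConfig(max_epochs=1, select_epoch=1), [], None, NET)


def test_loss_decreases_within_early_epochs():
    cfg = TrainConfig(max_epochs=8, select_epoch=8, seed=0, checkpoint_every=4)
    _, res = train_model(cfg, _slice_set(8), None, NET)
    assert min(res.train_loss[1:]) < res.train_loss[0]


def test_single_repeated_slice_overfits_below_005():
    """Capacity check: ~200 optimisation steps drive the loss near zero."""
    rng = np.random.default_rng(3)
    label = np.zeros((16, 16), np.uint8)
    label[4:10, 5:12] = 1
    image = (label * 2.0 + rng.normal(0, 0.3, (16, 16))).astype(np.float32)
    pair = SlicePair(image=image, label=label, subject_id="s0", slice_index=0)
    net = NetworkSpec(levels=2, base_channels=8, channel_growth=2, attention=False)
    cfg = TrainConfig(max_epochs=200, select_epoch=200, seed=1, checkpoint_every=200)
    _, res = train_model(cfg, [pair], None, net)
    assert res.train_loss[-1] < 0.05


def test_identical_config_and_seed_reproduce_loss_history():
    cfg = TrainConfig(max_epochs=3, select_epoch=3, seed=7, checkpoint_every=3)
    _, r1 = train_model(cfg, _slice_set(6), None, NET)
    _, r2 = train_model(cfg, _slice_set(6), None, NET)
    assert r1.train_loss == r2.train_loss


def test_foreground_only_sampling_drops_empty_slices():
    pairs = _slice_set(4, seed=1)
    empty = SlicePair(
        image=np.zeros((16, 16), np.float32),
        label=np.zeros((16, 16), np.uint8),
        subject_id="s0",
        slice_index=99,
    )
    cfg = TrainConfig(
        max_epochs=1, select_epoch=1, slice_sampling="foreground-only", checkpoint_every=1
    )
    # trains without error; with only empty slices the set becomes empty
    train_model(cfg, pairs + [empty], None, NET)
    with pytest.raises(ValueError, match="empty"):
        train_model(cfg, [empty], None, NET)


def test_validation_loss_logged_per_epoch():
    cfg = TrainConfig(max_epochs=2, select_epoch=2, checkpoint_every=2)
    _, res = train_model(cfg, _slice_set(4), _slice_set(2, seed=9), NET)
    assert len(res.val_loss) == 2 and np.isfinite(res.val_loss).all()


# -- checkpoint selection --------------------------------------------------


def _result_with_checkpoints():
    cfg = TrainConfig(max_epochs=6, select_epoch=4, seed=2, checkpoint_every=3)
    return train_model(cfg, _slice_set(4), _slice_set(2, seed=5), NET)


def test_fixed_epoch_returns_requested_checkpoint():
    model, res = _result_with_checkpoints()
    assert set(res.checkpoints) == {3, 4, 6}
    chosen = select_checkpoint(res, NET, epoch=4)
    np.testing.assert_array_equal(
        chosen.state_dict()["node_0_0.conv1.weight"],
        res.checkpoints[4]["node_0_0.conv1.weight"],
    )


def test_missing_epoch_error_lists_available():
    _, res = _result_with_checkpoints()
    with pytest.raises(KeyError, match=r"\[3, 4, 6\]"):
        select_checkpoint(res, NET, epoch=5)


def test_best_validation_policy_picks_argmin_epoch():
    _, res = _result_with_checkpoints()
    chosen_epoch = min(sorted(res.checkpoints), key=lambda e: (res.val_loss[e - 1], e))
    model = select_checkpoint(res, NET, policy="best-validation")
    np.testing.assert_array_equal(
        model.state_dict()["node_0_0.conv1.weight"],
        res.checkpoints[chosen_epoch]["node_0_0.conv1.weight"],
    )


def test_best_validation_on_monotone_improvement_returns_last_saved():
    _, res = _result_with_checkpoints()
    res.val_loss = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5]  # monotone improving
    model = select_checkpoint(res, NET, policy="best-validation")
    np.testing.assert_array_equal(
        model.state_dict()["node_0_0.conv1.weight"],
        res.checkpoints[6]["node_0_0.conv1.weight"],
    )
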