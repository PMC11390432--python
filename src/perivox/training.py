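"""Training loop, five-fold age-balanced cross-validation, checkpointing.

The protocol: subjects are split into five age-balanced folds
(sort-by-age round-robin deal).  Per round one fold is the test set, one
seeded-randomly chosen fold is the validation set, the remaining three
train the network.  Training uses mini-batches of 4 slices, Adagrad at
learning rate 0.05, and the multi-scale soft dice deep-supervision loss;
the deployed model is by default the checkpoint at a fixed selection
epoch (convergence is typically reached well before the nominal epoch
budget), with best-validation selection available as an alternative
policy.  Inference binarises the finest-scale head at probability 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .evaluation import MetricsRecord, evaluate_masks
from .imageio import SlicePair, Volume, normalize, reassemble, to_slices
from .network import NestedSegNet, NetworkSpec, build_network
from .nn.autograd import Tensor
from .phantom import PhantomTruth
from .supervision import LossConfig, batch_multiscale_loss, hf_downsample

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "Adagrad",
    "make_folds",
    "train_model",
    "select_checkpoint",
    "predict_volume",
    "run_crossval",
]


@dataclass
class TrainConfig:
    """Optimisation protocol (defaults follow the study protocol)."""

    batch_size: int = 4
    learning_rate: float = 0.05
    max_epochs: int = 1000
    select_epoch: int = 50
    seed: int = 0
    slice_sampling: str = "all"  # "all" | "foreground-only"
    checkpoint_every: int = 10
    selection_policy: str = "fixed-epoch"  # "fixed-epoch" | "best-validation"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 1 <= self.select_epoch <= self.max_epochs:
            raise ValueError("select_epoch must be in [1, max_epochs]")
        if self.slice_sampling not in ("all", "foreground-only"):
            raise ValueError(f"unknown slice_sampling {self.slice_sampling!r}")
        if self.selection_policy not in ("fixed-epoch", "best-validation"):
            raise ValueError(f"unknown selection_policy {self.selection_policy!r}")


@dataclass
class FoldSplit:
    """Subject-to-fold assignment plus per-round set roles."""

    assignment: dict[str, int]
    rounds: list[dict]  # {"test": f, "validation": f, "train": [f, f, f]}

    @property
    def k(self) -> int:
        return len(self.rounds)

    def fold_members(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


def make_folds(subjects: list[tuple[str, float]], k: int = 5, seed: int = 0) -> FoldSplit:
    """Age-balanced k-fold split: sort by age, deal round-robin.

    Each round designates one fold as test and draws the validation fold
    from the seeded stream among the others; the remaining k-2 folds
    train.  Across the k rounds each fold is the test fold exactly once.
    """
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    order = sorted(range(len(subjects)), key=lambda i: (subjects[i][1], subjects[i][0]))
    assignment = {subjects[i][0]: pos % k for pos, i in enumerate(order)}
    rng = np.random.default_rng(seed)
    rounds = []
    for test in range(k):
        others = [f for f in range(k) if f != test]
        validation = int(rng.choice(others))
        rounds.append(
            {
                "test": test,
                "validation": validation,
                "train": [f for f in others if f != validation],
            }
        )
    return FoldSplit(assignment=assignment, rounds=rounds)


class Adagrad:
    """Adagrad: per-parameter accumulated squared gradients."""

    def __init__(self, params, lr: float = 0.05, eps: float = 1e-10):
        self.params = list(params)
        self.lr = lr
        self.eps = eps
        self.acc = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self):
        for p, acc in zip(self.params, self.acc):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            acc += g * g
            p.data = (p.data - self.lr * g / (np.sqrt(acc) + self.eps)).astype(
                np.float32
            )

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


@dataclass
class TrainResult:
    checkpoints: dict[int, dict[str, np.ndarray]]  # epoch -> state dict
    train_loss: list[float]  # per epoch
    val_loss: list[float]  # per epoch (nan if no validation set)
    scale_loss: list[list[float]]  # per epoch, per scale (train)


def _label_pyramid_stack(labels: np.ndarray, levels: int) -> list[np.ndarray]:
    """Batched label pyramids: (N, H, W) -> list of (N, H/2^s, W/2^s)."""
    pyramids = [hf_downsample(lab, levels).masks for lab in labels]
    return [np.stack([p[s] for p in pyramids]) for s in range(levels)]


def _forward_loss(model, images, labels, loss_cfg):
    maps = model(Tensor(images[:, None]))
    stacks = _label_pyramid_stack(labels, model.spec.levels)
    return batch_multiscale_loss(maps, stacks, loss_cfg)


def train_model(
    config: TrainConfig,
    train_pairs: list[SlicePair],
    val_pairs: list[SlicePair] | None,
    net_spec: NetworkSpec,
    loss_cfg: LossConfig | None = None,
) -> tuple[NestedSegNet, TrainResult]:
    """Train a fresh network on slice pairs; returns model + checkpoint series.

    Mini-batches are reshuffled each epoch from a seeded stream; weight
    initialisation uses the same seed, so a (config, data) pair fully
    determines the loss history.  Checkpoints are kept every
    ``checkpoint_every`` epochs, at ``select_epoch`` and at the final
    epoch.
    """
    if config.slice_sampling == "foreground-only":
        train_pairs = [p for p in train_pairs if p.label is not None and p.label.any()]
    if not train_pairs:
        raise ValueError("empty training set")
    if any(p.label is None for p in train_pairs):
        raise ValueError("training slices must carry labels")
    loss_cfg = loss_cfg or LossConfig()
    model = build_network(net_spec, seed=config.seed)
    optim = Adagrad(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    images = np.stack([p.image for p in train_pairs]).astype(np.float32)
    labels = np.stack([p.label for p in train_pairs]).astype(np.float32)
    val_images = val_labels = None
    if val_pairs:
        val_images = np.stack([p.image for p in val_pairs]).astype(np.float32)
        val_labels = np.stack([p.label for p in val_pairs]).astype(np.float32)
    result = TrainResult(checkpoints={}, train_loss=[], val_loss=[], scale_loss=[])
    n = len(train_pairs)
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_scales = None
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, per_scale = _forward_loss(model, images[idx], labels[idx], loss_cfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}"
                )
            optim.zero_grad()
            loss.backward()
            optim.step()
            epoch_loss += float(loss.data)
            epoch_scales = (
                np.asarray(per_scale)
                if epoch_scales is None
                else epoch_scales + np.asarray(per_scale)
            )
            n_batches += 1
        result.train_loss.append(epoch_loss / n_batches)
        result.scale_loss.append((epoch_scales / n_batches).tolist())
        if val_images is not None:
            model.eval()
            vloss, _ = _forward_loss(model, val_images, val_labels, loss_cfg)
            result.val_loss.append(float(vloss.data))
        else:
            result.val_loss.append(float("nan"))
        if (
            epoch % config.checkpoint_every == 0
            or epoch == config.select_epoch
            or epoch == config.max_epochs
        ):
            result.checkpoints[epoch] = model.state_dict()
    return model, result


def select_checkpoint(
    result: TrainResult,
    net_spec: NetworkSpec,
    epoch: int | None = None,
    policy: str = "fixed-epoch",
) -> NestedSegNet:
    """Materialise the deployed model from the checkpoint series.

    ``fixed-epoch`` returns exactly the requested epoch's weights;
    ``best-validation`` returns the saved epoch with minimal validation
    loss.
    """
    if policy == "best-validation":
        saved = sorted(result.checkpoints)
        epoch = min(saved, key=lambda e: (result.val_loss[e - 1], e))
    elif policy == "fixed-epoch":
        if epoch is None:
            raise ValueError("fixed-epoch policy requires an epoch")
        if epoch not in result.checkpoints:
            raise KeyError(
                f"no checkpoint at epoch {epoch}; available: "
                f"{sorted(result.checkpoints)}"
            )
    else:
        raise ValueError(f"unknown policy {policy!r}")
    model = build_network(net_spec, seed=0)
    model.load_state_dict(result.checkpoints[epoch])
    return model


def predict_volume(
    model: NestedSegNet,
    volume: Volume,
    threshold: float = 0.5,
    batch_size: int = 8,
    fuse_heads: bool = False,
) -> Volume:
    """Slice-wise inference: normalise, pad, forward, reassemble at 0.5.

    By default only the finest-scale head drives the prediction;
    ``fuse_heads`` averages all heads after upsampling them to full
    resolution.
    """
    model.eval()
    spec = model.spec
    pairs = to_slices(normalize(volume), pad_to=spec.divisor)
    maps: list[np.ndarray] = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        batch = np.stack([p.image for p in chunk]).astype(np.float32)
        outs = model(Tensor(batch[:, None]))
        fine = outs[0].data[:, 0]
        if fuse_heads:
            acc = fine.copy()
            for s in range(1, spec.levels):
                coarse = outs[s].data[:, 0]
                factor = 2**s
                up = np.repeat(np.repeat(coarse, factor, axis=1), factor, axis=2)
                acc += up
            fine = acc / spec.levels
        maps.extend(fine[i] for i in range(fine.shape[0]))
    return reassemble(
        maps,
        pad=pairs[0].pad,
        voxel_size_mm=volume.voxel_size_mm,
        subject_id=volume.subject_id,
        threshold=threshold,
    )


def _truth_mask(truth) -> np.ndarray:
    if isinstance(truth, PhantomTruth):
        return truth.mask
    if isinstance(truth, Volume):
        return truth.data
    return np.asarray(truth)


def run_crossval(
    dataset: list[tuple[Volume, object, str, float]],
    config: TrainConfig,
    net_spec: NetworkSpec,
    loss_cfg: LossConfig | None = None,
    k: int = 5,
    model_name: str = "nested-segnet",
) -> dict:
    """Full k-fold cross-validation on a labelled cohort.

    ``dataset`` holds (volume, truth, subject_id, age) tuples; ``truth``
    may be a phantom truth object, a label volume, or a binary array.
    Every subject is predicted exactly once (in the round where its fold
    is the test set).  Returns folds, per-round loss histories,
    per-subject predicted masks and metrics records.
    """
    subjects = [(sid, age) for _, _, sid, age in dataset]
    folds = make_folds(subjects, k=k, seed=config.seed)
    by_id = {sid: (vol, truth) for vol, truth, sid, _ in dataset}
    predictions: dict[str, Volume] = {}
    records: list[MetricsRecord] = []
    histories = []
    for rnd in folds.rounds:
        train_ids = [
            s for f in rnd["train"] for s in folds.fold_members(f)
        ]
        val_ids = folds.fold_members(rnd["validation"])
        test_ids = folds.fold_members(rnd["test"])

        def slices_for(ids):
            pairs = []
            for sid in ids:
                vol, truth = by_id[sid]
                label = Volume(
                    data=_truth_mask(truth),
                    voxel_size_mm=vol.voxel_size_mm,
                    subject_id=sid,
                )
                pairs.extend(
                    to_slices(normalize(vol), label, pad_to=net_spec.divisor)
                )
            return pairs

        round_cfg = TrainConfig(
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            select_epoch=config.select_epoch,
            seed=config.seed + 101 * rnd["test"],
            slice_sampling=config.slice_sampling,
            checkpoint_every=config.checkpoint_every,
            selection_policy=config.selection_policy,
        )
        _, result = train_model(
            round_cfg, slices_for(train_ids), slices_for(val_ids), net_spec, loss_cfg
        )
        model = select_checkpoint(
            result,
            net_spec,
            epoch=config.select_epoch,
            policy=config.selection_policy,
        )
        histories.append(result)
        for sid in test_ids:
            vol, truth = by_id[sid]
            pred = predict_volume(model, vol)
            predictions[sid] = pred
            records.append(
                evaluate_masks(pred.data, _truth_mask(truth), sid, model_name)
            )
    return {
        "folds": folds,
        "histories": histories,
        "predictions": predictions,
        "records": records,
    }
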