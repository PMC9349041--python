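"""Dataset partitioning, augmentation and the optimization schedule.

Training follows the protocol common to large tagged-protein screens:
Adam with an initial learning rate of 4e-4; the learning rate is multiplied
by 0.1 whenever the validation loss fails to improve for four consecutive
epochs (the plateau counter resets after each decay), and training stops
once the validation loss has not improved for more than twelve consecutive
epochs.  Crops are split 8:1:1 into train/validation/test partitions and
augmented with lossless 90-degree rotations and flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .imgprep import CropSet
from .vqmodel import Model, total_loss, train_step


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 0.0004
    lr_factor: float = 0.1
    lr_patience: int = 4
    stop_patience: int = 12
    improvement_tol: float = 1e-6
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    batch_size: int = 64
    max_epochs: int = 100
    seed: int = 0
    augment: bool = True
    stratify: bool = False
    loss_weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.lr_factor < 1.0:
            raise ConfigurationError("lr_factor must be in (0, 1)")
        if self.lr_patience < 1 or self.stop_patience < 1:
            raise ConfigurationError("patiences must be >= 1")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ConfigurationError("split ratios must sum to 1")


@dataclass
class ValHistory:
    """Per-epoch validation losses, learning rates, and the stop epoch."""

    val_losses: list[float] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    train_losses: list[float] = field(default_factory=list)
    stop_epoch: int | None = None
    best_epoch: int | None = None


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------


def _partition_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    return n - n_val - n_test, n_val, n_test


def split_dataset(
    n_or_cropset,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    protein_ids: list[str] | None = None,
    stratify: bool = False,
) -> np.ndarray:
    """Assign each crop to train/val/test, reproducibly under ``seed``.

    Default granularity is crop-level; ``stratify=True`` partitions within
    each protein so every protein appears in all three partitions (given
    enough crops per protein).  Returns an array of partition labels.
    """
    if isinstance(n_or_cropset, CropSet):
        n = len(n_or_cropset)
        if protein_ids is None:
            protein_ids = n_or_cropset.protein_ids
    else:
        n = int(n_or_cropset)
    if n < 1:
        raise ConfigurationError("empty crop set")
    if any(r <= 0 for r in ratios):
        raise ConfigurationError("all three split ratios must be positive")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=object)

    def assign(idx: np.ndarray) -> None:
        idx = rng.permutation(idx)
        n_train, n_val, _ = _partition_sizes(len(idx), ratios)
        labels[idx[:n_train]] = "train"
        labels[idx[n_train : n_train + n_val]] = "val"
        labels[idx[n_train + n_val :]] = "test"

    if stratify:
        if protein_ids is None:
            raise ConfigurationError("stratified split requires protein ids")
        pids = np.asarray(protein_ids)
        for pid in sorted(set(protein_ids)):
            assign(np.flatnonzero(pids == pid))
    else:
        assign(np.arange(n))
    return labels


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def augment(values: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Random 90-degree rotation plus optional flip of a (C, H, W) crop.

    Both channels are transformed jointly; each channel's multiset of pixel
    values is unchanged (pure permutations), so channel ranges survive.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k = int(rng.integers(4))
    do_flip = bool(rng.integers(2))
    out = np.rot90(values, k=k, axes=(-2, -1))
    if do_flip:
        out = out[..., ::-1]
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# learning-rate schedule / early stopping
# ---------------------------------------------------------------------------


def schedule_step(
    val_losses,
    config: TrainConfig = TrainConfig(),
) -> tuple[float, bool]:
    """Pure function of the validation-loss history.

    Replays the counter rules over the full history: the learning rate
    decays by ``lr_factor`` each time ``lr_patience`` consecutive epochs
    pass without the best loss improving (counter resets on decay); training
    stops when more than ``stop_patience`` consecutive epochs pass without
    improvement.  Returns the learning rate to use next and the stop flag.
    """
    losses = list(val_losses)
    if not losses:
        raise ConfigurationError("history must be non-empty")
    lr = config.initial_lr
    best = np.inf
    since_improve = 0
    since_decay = 0
    stop = False
    for loss in losses:
        if loss < best - config.improvement_tol:
            best = loss
            since_improve = 0
            since_decay = 0
        else:
            since_improve += 1
            since_decay += 1
        if since_decay >= config.lr_patience:
            lr *= config.lr_factor
            since_decay = 0
        if since_improve > config.stop_patience:
            stop = True
            break
    return lr, stop


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------


def encode_targets(protein_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Map opaque protein identifiers to dense class indices."""
    classes = sorted(set(protein_ids))
    lut = {pid: i for i, pid in enumerate(classes)}
    return np.array([lut[p] for p in protein_ids]), classes


def _epoch_val_loss(model, x, y, cfg_model, batch_size, weights) -> float:
    losses, counts = [], []
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        out = model.forward(xb)
        losses.append(total_loss(out, xb, yb, cfg_model, weights).total)
        counts.append(len(xb))
    return float(np.average(losses, weights=counts))


def train(
    model: Model,
    cropset: CropSet,
    config: TrainConfig,
    assignment: np.ndarray | None = None,
) -> tuple[Model, ValHistory]:
    """Optimize the model on a crop set; returns the best-validation model.

    The input channel subset follows the model's ablation toggles (nuclear
    channel dropped when disabled).
    """
    x = cropset.stack().astype(np.float32)
    if not model.config.use_nuclear_channel:
        x = x[:, :1]
    y, _classes = encode_targets(cropset.protein_ids)
    assignment = (
        split_dataset(
            len(cropset),
            config.split_ratios,
            seed=config.seed,
            protein_ids=cropset.protein_ids,
            stratify=config.stratify,
        )
        if assignment is None
        else assignment
    )
    tr = np.flatnonzero(assignment == "train")
    va = np.flatnonzero(assignment == "val")
    if tr.size == 0:
        raise ConfigurationError("empty training partition")
    if va.size == 0:
        raise ConfigurationError("empty validation partition")

    rng = np.random.default_rng(config.seed + 1)
    optimizer = Adam(model.params(), lr=config.initial_lr)
    history = ValHistory()
    weights = config.loss_weights
    best_val = np.inf
    best_state = model.state_arrays()

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(tr)
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = x[idx]
            if config.augment:
                xb = np.stack([augment(v, rng) for v in xb])
            bundle = train_step(model, xb, y[idx], optimizer, weights)
            epoch_losses.append(bundle.total)
        val = _epoch_val_loss(
            model, x[va], y[va], model.config, config.batch_size, weights
        )
        history.train_losses.append(float(np.mean(epoch_losses)))
        history.val_losses.append(val)
        if val < best_val - config.improvement_tol:
            best_val = val
            best_state = model.state_arrays()
            history.best_epoch = epoch
        new_lr, stop = schedule_step(history.val_losses, config)
        history.lrs.append(optimizer.lr)
        optimizer.lr = new_lr
        if stop:
            history.stop_epoch = epoch
            break
    model.load_state_arrays(best_state)
    return model, history


def identification_accuracy(
    model: Model,
    cropset: CropSet,
    indices: np.ndarray | None = None,
    batch_size: int = 64,
    head: str = "global",
) -> float:
    """Fraction of crops whose protein is correctly identified by a head."""
    x = cropset.stack().astype(np.float32)
    if not model.config.use_nuclear_channel:
        x = x[:, :1]
    y, _ = encode_targets(cropset.protein_ids)
    if indices is not None:
        x, y = x[indices], y[indices]
    hits = 0
    for i in range(0, len(x), batch_size):
        out = model.forward(x[i : i + batch_size])
        logits = out.logits_global if head == "global" else out.logits_local
        hits += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return hits / len(x)
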