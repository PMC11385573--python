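"""Training loop, learning-rate schedule, Dice metric and evaluation.

One epoch is a complete pass through the sample universe: one
positive-guaranteed crop per annotated training slice plus a fixed number
of negative crops, shuffled and consumed in batches of ``batch_size``.
Optimization is AdamW (decoupled weight decay) with two parameter groups —
encoder layers run at ``encoder_lr_factor`` times the scheduled rate — and
a linear warmup from zero over the first ``warmup_epochs`` followed by
cosine annealing to zero.  After every epoch the full held-out validation
slice is predicted (no test-time augmentation during training) and the
weights with the best validation Dice are kept.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .annotation import AnnotationPlan
from .exceptions import (
    CoverageError,
    GeometryError,
    ScheduleError,
    TrainingDivergenceError,
)
from .sampler import (
    CropPair,
    assemble_input,
    augment,
    build_epoch,
    sample_negative_crop,
    sample_positive_crop,
)
from .stack_io import MaskStack, SliceStack


@dataclass
class TrainConfig:
    """All hyperparameters of one training run.

    The reference configuration for full-resolution synchrotron stacks is
    crop 512, batch 8, 5000 epochs, decoder channels
    [512, 256, 128, 64, 32]; the desk-scale defaults below exercise the
    identical code path on a laptop-sized phantom.
    """

    crop_size: int = 64
    batch_size: int = 8
    epochs: int = 200
    weight_decay: float = 0.01
    base_lr_coefficient: float = 0.01
    lr_divisor: float = 256.0
    encoder_lr_factor: float = 0.1
    warmup_epochs: int = 10
    decoder_channels: list[int] = field(default_factory=lambda: [32, 16])
    encoder_name: str = "tiny"
    channel_mode: str = "1ch"
    neg_crops_per_epoch: int = 2
    mixed_precision: bool = False
    threshold: float = 0.5
    augment: bool = True
    fill_value: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be < epochs")
        if any(
            a <= b for a, b in zip(self.decoder_channels, self.decoder_channels[1:])
        ):
            raise ValueError("decoder_channels must be strictly decreasing")
        if self.channel_mode not in ("1ch", "2.5d"):
            raise ValueError(f"unknown channel_mode: {self.channel_mode!r}")
        if self.encoder_name not in nn.ENCODERS:
            raise ValueError(
                f"unknown encoder {self.encoder_name!r}; "
                f"available: {sorted(nn.ENCODERS)}"
            )

    @property
    def in_channels(self) -> int:
        return 3 if self.channel_mode == "2.5d" else 1

    @property
    def dtype(self):
        # Mixed precision on CPU: compute in float32 instead of float64.
        return np.float32 if self.mixed_precision else np.float64


@dataclass
class TrainedModel:
    """Weights plus the best validation Dice and where it occurred."""

    network: nn.UNet
    best_val_dice: float
    best_epoch: int
    config: TrainConfig
    history: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        state = self.network.state_dict()
        meta = {
            "best_val_dice": self.best_val_dice,
            "best_epoch": self.best_epoch,
            **{f"cfg_{k}": v for k, v in asdict(self.config).items()},
        }
        np.savez(path, __meta__=np.array([repr(meta)], dtype=object), **state)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        import ast

        with np.load(path, allow_pickle=True) as z:
            meta = ast.literal_eval(str(z["__meta__"][0]))
            state = {k: z[k] for k in z.files if k != "__meta__"}
        cfg = TrainConfig(
            **{k[4:]: v for k, v in meta.items() if k.startswith("cfg_")}
        )
        net = build_network(cfg)
        net.load_state_dict(state)
        return cls(net, meta["best_val_dice"], meta["best_epoch"], cfg)


@dataclass
class DiceScore:
    """Sørensen-Dice overlap with the pixel counts behind it."""

    value: float
    n_intersection: int
    n_pred: int
    n_ref: int


def initial_learning_rate(
    batch_size: int, coefficient: float = 0.01, divisor: float = 256.0
) -> float:
    """The linear-scaling heuristic ``coefficient * batch_size / divisor``.

    At the reference batch size of 8 this gives 0.0003125.
    """
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    return coefficient * batch_size / divisor


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Warmup-then-cosine schedule value for one epoch.

    Linear from 0 up to the initial rate over ``warmup_epochs``, then
    ``lr0 * (1 + cos(pi * (e - W) / (E - W))) / 2`` down to zero.
    """
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    lr0 = initial_learning_rate(
        config.batch_size, config.base_lr_coefficient, config.lr_divisor
    )
    w, e = config.warmup_epochs, config.epochs
    if epoch < w:
        return lr0 * epoch / w
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * (epoch - w) / (e - w)))


def dice(pred: np.ndarray, ref: np.ndarray) -> DiceScore:
    """Sørensen-Dice coefficient ``2|A∩B| / (|A| + |B|)`` of binary arrays.

    Two entirely empty masks score 1 (an empty prediction of an empty
    slice is perfect).  Symmetric in its arguments.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise GeometryError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    p = pred.astype(bool)
    r = ref.astype(bool)
    n_pred = int(p.sum())
    n_ref = int(r.sum())
    n_int = int((p & r).sum())
    if n_pred + n_ref == 0:
        return DiceScore(1.0, 0, 0, 0)
    return DiceScore(2.0 * n_int / (n_pred + n_ref), n_int, n_pred, n_ref)


def bce_loss(probabilities: np.ndarray, targets: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross entropy of probabilities against binary targets.

    Probabilities are clamped to ``[eps, 1 - eps]`` so the loss stays
    finite even for saturated predictions.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if p.shape != y.shape:
        raise GeometryError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean())


def build_network(config: TrainConfig, rng: np.random.Generator | None = None) -> nn.UNet:
    """Instantiate the UNet described by a TrainConfig."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    widths = nn.ENCODERS[config.encoder_name]
    decoder = list(config.decoder_channels)
    if len(decoder) != len(widths) - 1:
        # Trim or error: the decoder ladder must mirror the encoder depth.
        raise ValueError(
            f"decoder_channels needs {len(widths) - 1} entries for encoder "
            f"{config.encoder_name!r} (widths {widths}), got {decoder}"
        )
    return nn.UNet(config.in_channels, widths, decoder, rng, dtype=config.dtype)


def predict_slice(
    network: nn.UNet, image: np.ndarray
) -> np.ndarray:
    """Probability map for one assembled input (h, w) or (c, h, w)."""
    x = image[None] if image.ndim == 3 else image[None, None]
    logits = network.forward(x, train=False)
    return nn.sigmoid(logits)[0, 0]


def _make_crop(
    kind: str,
    index: int | None,
    stack: SliceStack,
    annotations: MaskStack,
    plan: AnnotationPlan,
    config: TrainConfig,
    rng: np.random.Generator,
) -> CropPair:
    if kind == "pos":
        img = assemble_input(stack, index, config.channel_mode)
        mask = annotations[index]
        pair = sample_positive_crop(img, mask, config.crop_size, rng)
        pair.source_index = index
    else:
        pair = sample_negative_crop(
            stack, plan.negative_ranges, config.crop_size, rng, config.channel_mode
        )
    if config.augment:
        pair = augment(pair, rng, fill_value=config.fill_value)
    return pair


def train(
    stack: SliceStack,
    annotations: MaskStack,
    plan: AnnotationPlan,
    config: TrainConfig,
    log_path: str | Path | None = None,
    progress: bool = False,
) -> TrainedModel:
    """Run the full sparse-annotation training loop.

    All randomness (weight init, crop sampling, shuffling, augmentation)
    derives from ``config.seed``; with ``mixed_precision`` off two runs
    with the same seed are bitwise identical on one device.
    """
    training = plan.training_indices
    if not training:
        raise ScheduleError("plan has no training slices")
    missing = [i for i in plan.annotated_indices if i not in annotations]
    if missing:
        raise CoverageError(f"plan indices without masks: {missing}")
    if plan.validation_index is None:
        raise ScheduleError("plan has no validation slice")

    ss = np.random.SeedSequence(config.seed)
    init_rng, sample_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    network = build_network(config, init_rng)
    optimizer = nn.AdamW(
        network,
        weight_decay=config.weight_decay,
        group_scale={"encoder": config.encoder_lr_factor, "decoder": 1.0},
    )

    val_idx = plan.validation_index
    val_input = assemble_input(stack, val_idx, config.channel_mode)
    val_ref = annotations[val_idx]
    neg_available = bool(plan.negative_ranges)

    best_dice = -1.0
    best_epoch = 0
    best_state: dict | None = None
    history: list[dict] = []

    for epoch in range(config.epochs):
        lr = learning_rate_at(epoch, config)
        schedule = build_epoch(plan, config.neg_crops_per_epoch, sample_rng)
        items = [
            it for it in schedule.items if it[0] == "pos" or neg_available
        ]
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(items), config.batch_size):
            batch = items[start : start + config.batch_size]
            crops = [
                _make_crop(kind, idx, stack, annotations, plan, config, sample_rng)
                for kind, idx in batch
            ]
            x = np.stack([
                c.image_crop if c.image_crop.ndim == 3 else c.image_crop[None]
                for c in crops
            ])
            y = np.stack([c.mask_crop[None] for c in crops]).astype(np.float64)
            network.zero_grad()
            logits = network.forward(x, train=True)
            loss, dlogits = nn.bce_with_logits(logits, y)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            network.backward(dlogits)
            optimizer.step(lr)
            epoch_loss += loss
            n_batches += 1

        prob = predict_slice(network, val_input)
        vd = dice(prob >= config.threshold, val_ref).value
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_dice": vd,
            }
        )
        if vd > best_dice:
            best_dice = vd
            best_epoch = epoch
            best_state = network.state_dict()
        if progress and (epoch % 25 == 0 or epoch == config.epochs - 1):
            print(
                f"epoch {epoch:4d}  lr {lr:.2e}  loss "
                f"{epoch_loss / max(n_batches, 1):.4f}  val dice {vd:.4f}"
            )

    if best_state is not None:
        network.load_state_dict(best_state)
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "lr", "train_loss", "val_dice"]
            )
            writer.writeheader()
            writer.writerows(history)
    return TrainedModel(network, best_dice, best_epoch, copy.deepcopy(config), history)


def evaluate(
    model: TrainedModel,
    stack: SliceStack,
    reference: MaskStack,
    indices: list[int] | None = None,
    use_tta: bool = False,
) -> dict:
    """Per-slice and aggregate Dice of model predictions against reference.

    The aggregate is reported both as the mean of per-slice Dice values and
    as the pooled-counts Dice over all evaluated pixels.
    """
    from .tta import tta_predict  # local import to avoid a cycle

    if indices is None:
        indices = reference.indices
    missing = [i for i in indices if i not in reference]
    if missing:
        raise CoverageError(f"no reference masks for indices {missing}")
    cfg = model.config
    per_slice: dict[int, DiceScore] = {}
    pooled_int = pooled_pred = pooled_ref = 0
    for i in indices:
        img = assemble_input(stack, i, cfg.channel_mode)
        if use_tta:
            prob = tta_predict(model, img).probability_map
        else:
            prob = predict_slice(model.network, img)
        d = dice(prob >= cfg.threshold, reference[i])
        per_slice[i] = d
        pooled_int += d.n_intersection
        pooled_pred += d.n_pred
        pooled_ref += d.n_ref
    mean = float(np.mean([d.value for d in per_slice.values()]))
    pooled = (
        1.0
        if pooled_pred + pooled_ref == 0
        else 2.0 * pooled_int / (pooled_pred + pooled_ref)
    )
    return {"per_slice": per_slice, "mean_dice": mean, "pooled_dice": pooled}
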