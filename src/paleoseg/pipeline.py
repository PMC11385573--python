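"""Run orchestration: the two-iteration sparse-annotation workflow on disk.

Each command reads/writes plain files inside a run directory so a whole
experiment is replayable from its archived config and seed:

``simulate``  phantom stack + ground-truth masks + derived negative ranges
``plan``      initial annotation plan over the visible extent
``train``     fit the segmenter on the planned slices, checkpoint + log
``predict``   full-stack inference with dihedral TTA
``evaluate``  per-slice Dice table against reference masks
``iterate``   plan -> train -> predict -> report for iteration 1 or 2;
              iteration 2 refines the stored plan with midpoint slices
              (ground truth stands in for the human correction step).

Input stacks and annotation masks are never mutated in place.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .annotation import (
    AnnotationPlan,
    choose_validation_slice,
    derive_negative_ranges,
    make_initial_plan,
    refine_plan,
)
from .estimator import FossilSegmenter
from .exceptions import ConfigurationError, PipelineStateError
from .phantom import PhantomParams, generate_phantom
from .stack_io import (
    MaskStack,
    SliceStack,
    read_mask_stack,
    read_slice_stack,
    write_mask_stack,
    write_slice_stack,
)
from .trainer import TrainConfig, TrainedModel, evaluate


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for one run directory."""

    out_dir: Path
    stack_dir: Path | None = None
    mask_dir: Path | None = None
    phantom: PhantomParams = dataclasses.field(default_factory=PhantomParams)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    extent_start: int = 10
    extent_end: int = 85
    step: int = 10
    validation_policy: str = "simplest"
    use_tta: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        phantom = PhantomParams(**raw.pop("phantom", {}))
        train_cfg = TrainConfig(**raw.pop("train", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("out_dir", "stack_dir", "mask_dir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        seed = raw.get("seed")
        if seed is not None:
            phantom = dataclasses.replace(phantom, seed=int(seed))
            train_cfg = dataclasses.replace(train_cfg, seed=int(seed))
        return cls(phantom=phantom, train=train_cfg, **raw)

    def archive(self) -> None:
        """Drop an immutable copy of the resolved config into the run dir."""
        self.out_dir.mkdir(parents=True, exist_ok=True)
        doc = {
            "out_dir": str(self.out_dir),
            "stack_dir": str(self.stack_dir) if self.stack_dir else None,
            "mask_dir": str(self.mask_dir) if self.mask_dir else None,
            "phantom": dataclasses.asdict(self.phantom),
            "train": dataclasses.asdict(self.train),
            "extent_start": self.extent_start,
            "extent_end": self.extent_end,
            "step": self.step,
            "validation_policy": self.validation_policy,
            "use_tta": self.use_tta,
            "seed": self.seed,
        }
        (self.out_dir / "run_config.json").write_text(json.dumps(doc, indent=2))


def cmd_simulate(config: RunConfig) -> tuple[SliceStack, MaskStack]:
    """Generate the phantom and write stack, truth masks, negative ranges."""
    config.archive()
    stack, truth = generate_phantom(config.phantom)
    stack_dir = config.out_dir / "stack"
    truth_dir = config.out_dir / "truth"
    write_slice_stack(stack, stack_dir, format="tiff", bit_depth=16)
    write_mask_stack(truth, truth_dir, format="png")
    ranges = derive_negative_ranges(truth, stack.n_slices)
    (config.out_dir / "negative_ranges.json").write_text(
        json.dumps([list(r) for r in ranges])
    )
    return stack, truth


def _load_inputs(config: RunConfig) -> tuple[SliceStack, MaskStack]:
    stack_dir = config.stack_dir or config.out_dir / "stack"
    mask_dir = config.mask_dir or config.out_dir / "truth"
    if not Path(stack_dir).exists():
        raise PipelineStateError(f"no slice stack at {stack_dir}; run simulate first")
    stack = read_slice_stack(stack_dir)
    masks = read_mask_stack(mask_dir, expected_geometry=(stack.height, stack.width))
    return stack, masks


def cmd_plan(config: RunConfig, masks: MaskStack, n_slices: int) -> AnnotationPlan:
    """Build and store the iteration-1 plan over the visible extent."""
    plan = make_initial_plan(
        config.extent_start,
        config.extent_end,
        config.step,
        negative_ranges=derive_negative_ranges(masks, n_slices),
    )
    annotated = masks.subset(plan.annotated_indices)
    plan.validation_index = choose_validation_slice(
        annotated, config.validation_policy
    )
    config.out_dir.mkdir(parents=True, exist_ok=True)
    plan.to_json(config.out_dir / "plan_iter1.json")
    return plan


def _segmenter(config: RunConfig) -> FossilSegmenter:
    t = config.train
    return FossilSegmenter(
        crop_size=t.crop_size,
        batch_size=t.batch_size,
        epochs=t.epochs,
        weight_decay=t.weight_decay,
        base_lr_coefficient=t.base_lr_coefficient,
        lr_divisor=t.lr_divisor,
        encoder_lr_factor=t.encoder_lr_factor,
        warmup_epochs=t.warmup_epochs,
        decoder_channels=tuple(t.decoder_channels),
        encoder_name=t.encoder_name,
        channel_mode=t.channel_mode,
        neg_crops_per_epoch=t.neg_crops_per_epoch,
        mixed_precision=t.mixed_precision,
        threshold=t.threshold,
        augment=t.augment,
        fill_value=t.fill_value,
        use_tta=config.use_tta,
        seed=t.seed,
    )


def cmd_iterate(config: RunConfig, iteration: int) -> dict:
    """Run one full plan -> train -> predict -> report iteration."""
    if iteration not in (1, 2):
        raise ConfigurationError(f"iteration must be 1 or 2, got {iteration}")
    config.archive()
    stack, truth = _load_inputs(config)

    if iteration == 1:
        plan = cmd_plan(config, truth, stack.n_slices)
    else:
        plan_path = config.out_dir / "plan_iter1.json"
        if not plan_path.exists():
            raise PipelineStateError(
                "iteration 2 requires an iteration-1 plan; run iterate 1 first"
            )
        plan = refine_plan(AnnotationPlan.from_json(plan_path), config.extent_end)
        plan.to_json(config.out_dir / "plan_iter2.json")

    # On phantoms the ground truth plays the human annotator, including the
    # manual-correction step that produces the refinement masks.
    missing = [i for i in plan.annotated_indices if i not in truth]
    if missing:
        raise PipelineStateError(f"no annotation masks for slices {missing}")
    annotations = truth.subset(plan.annotated_indices)

    seg = _segmenter(config)
    seg.fit(
        stack,
        annotations,
        plan,
        log_path=config.out_dir / f"training_log_iter{iteration}.csv",
    )
    seg.model_.save(config.out_dir / f"checkpoint_iter{iteration}.npz")

    predicted = seg.predict(stack)
    write_mask_stack(predicted, config.out_dir / f"predicted_iter{iteration}")

    report = _dice_report(predicted, truth)
    report.update(
        {
            "iteration": iteration,
            "best_val_dice": seg.best_val_dice_,
            "best_epoch": seg.best_epoch_,
            "validation_index": plan.validation_index,
            "n_annotated": len(plan.annotated_indices),
            "seed": config.train.seed,
        }
    )
    (config.out_dir / f"report_iter{iteration}.json").write_text(
        json.dumps(report, indent=2)
    )
    return report


def _dice_report(predicted: MaskStack, reference: MaskStack) -> dict:
    from .trainer import dice

    common = sorted(set(predicted.indices) & set(reference.indices))
    per_slice = {}
    pooled_int = pooled_pred = pooled_ref = 0
    for i in common:
        d = dice(predicted[i], reference[i])
        per_slice[i] = d.value
        pooled_int += d.n_intersection
        pooled_pred += d.n_pred
        pooled_ref += d.n_ref
    pooled = (
        1.0
        if pooled_pred + pooled_ref == 0
        else 2.0 * pooled_int / (pooled_pred + pooled_ref)
    )
    return {
        "per_slice_dice": per_slice,
        "mean_dice": float(np.mean(list(per_slice.values()))) if per_slice else None,
        "pooled_dice": pooled,
        "n_slices_evaluated": len(common),
    }


def cmd_evaluate(
    predicted_dir: str | Path, truth_dir: str | Path, out_csv: str | Path | None = None
) -> dict:
    """Score a predicted mask stack against a reference mask stack."""
    predicted = read_mask_stack(predicted_dir)
    truth = read_mask_stack(truth_dir)
    common = sorted(set(predicted.indices) & set(truth.indices))
    if not common:
        raise PipelineStateError("no overlapping slice indices to evaluate")
    report = _dice_report(predicted, truth)
    if out_csv is not None:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["slice_index", "dice"])
            for i, v in report["per_slice_dice"].items():
                writer.writerow([i, f"{v:.6f}"])
            writer.writerow(["mean", f"{report['mean_dice']:.6f}"])
            writer.writerow(["pooled", f"{report['pooled_dice']:.6f}"])
    return report


def cmd_predict(
    config: RunConfig, checkpoint: str | Path, stack_dir: str | Path | None = None
) -> MaskStack:
    """Load a checkpoint and predict a full stack to the run directory."""
    model = TrainedModel.load(checkpoint)
    stack = read_slice_stack(stack_dir or config.stack_dir or config.out_dir / "stack")
    seg = _segmenter(config)
    seg.model_ = model
    seg.best_val_dice_ = model.best_val_dice
    seg.best_epoch_ = model.best_epoch
    predicted = seg.predict(stack)
    write_mask_stack(predicted, config.out_dir / "predicted")
    return predicted
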