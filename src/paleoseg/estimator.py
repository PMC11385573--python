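"""A scikit-learn-style estimator wrapping the whole train/predict pipeline.

`FossilSegmenter` exposes the sparse-annotation workflow as a familiar
``fit`` / ``predict`` / ``score`` object with ``get_params`` /
``set_params``, so it composes with scikit-learn model-selection tooling.
``fit`` consumes a slice stack plus sparse annotations and a plan;
``predict`` returns a full binary mask stack, by default with 8-fold
dihedral test-time augmentation.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .annotation import AnnotationPlan
from .stack_io import MaskStack, SliceStack
from .trainer import TrainConfig, TrainedModel, evaluate, train
from .tta import predict_stack


class FossilSegmenter(BaseEstimator):
    """UNet fossil/matrix segmenter trained from sparsely annotated slices.

    Parameters mirror :class:`~paleoseg.trainer.TrainConfig`; see there for
    the reference (full-scale) values.  Fitted attributes:

    ``model_`` : the trained network and checkpoint metadata
    ``best_val_dice_`` : best Dice on the held-out validation slice
    ``best_epoch_`` : epoch at which it occurred
    ``history_`` : per-epoch lr / loss / validation-Dice records

    Examples
    --------
    >>> from paleoseg.phantom import PhantomParams, generate_phantom
    >>> from paleoseg.annotation import (make_initial_plan,
    ...     choose_validation_slice, derive_negative_ranges)
    >>> stack, truth = generate_phantom(PhantomParams(seed=7))
    >>> plan = make_initial_plan(10, 85, 10,
    ...     negative_ranges=derive_negative_ranges(truth, stack.n_slices))
    >>> ann = truth.subset(plan.annotated_indices)
    >>> plan.validation_index = choose_validation_slice(ann)
    >>> seg = FossilSegmenter(epochs=40, seed=7).fit(stack, ann, plan)
    >>> masks = seg.predict(stack)                        # doctest: +SKIP
    """

    def __init__(
        self,
        crop_size: int = 64,
        batch_size: int = 8,
        epochs: int = 200,
        weight_decay: float = 0.01,
        base_lr_coefficient: float = 0.01,
        lr_divisor: float = 256.0,
        encoder_lr_factor: float = 0.1,
        warmup_epochs: int = 10,
        decoder_channels: tuple[int, ...] = (32, 16),
        encoder_name: str = "tiny",
        channel_mode: str = "1ch",
        neg_crops_per_epoch: int = 2,
        mixed_precision: bool = False,
        threshold: float = 0.5,
        augment: bool = True,
        fill_value: float = 0.4,
        use_tta: bool = True,
        seed: int = 0,
    ):
        self.crop_size = crop_size
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.base_lr_coefficient = base_lr_coefficient
        self.lr_divisor = lr_divisor
        self.encoder_lr_factor = encoder_lr_factor
        self.warmup_epochs = warmup_epochs
        self.decoder_channels = decoder_channels
        self.encoder_name = encoder_name
        self.channel_mode = channel_mode
        self.neg_crops_per_epoch = neg_crops_per_epoch
        self.mixed_precision = mixed_precision
        self.threshold = threshold
        self.augment = augment
        self.fill_value = fill_value
        self.use_tta = use_tta
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            crop_size=self.crop_size,
            batch_size=self.batch_size,
            epochs=self.epochs,
            weight_decay=self.weight_decay,
            base_lr_coefficient=self.base_lr_coefficient,
            lr_divisor=self.lr_divisor,
            encoder_lr_factor=self.encoder_lr_factor,
            warmup_epochs=self.warmup_epochs,
            decoder_channels=list(self.decoder_channels),
            encoder_name=self.encoder_name,
            channel_mode=self.channel_mode,
            neg_crops_per_epoch=self.neg_crops_per_epoch,
            mixed_precision=self.mixed_precision,
            threshold=self.threshold,
            augment=self.augment,
            fill_value=self.fill_value,
            seed=self.seed,
        )

    def fit(
        self,
        stack: SliceStack,
        annotations: MaskStack,
        plan: AnnotationPlan,
        log_path=None,
        progress: bool = False,
    ) -> "FossilSegmenter":
        """Train on the plan's training slices; validate on its holdout."""
        model = train(
            stack, annotations, plan, self._config(),
            log_path=log_path, progress=progress,
        )
        self.model_: TrainedModel = model
        self.best_val_dice_: float = model.best_val_dice
        self.best_epoch_: int = model.best_epoch
        self.history_ = model.history
        return self

    def predict(self, stack: SliceStack, use_tta: bool | None = None) -> MaskStack:
        """Predict a full binary mask stack at slice resolution."""
        self._check_fitted()
        tta = self.use_tta if use_tta is None else use_tta
        return predict_stack(
            self.model_, stack, threshold=self.threshold, use_tta=tta, pad=True
        )

    def predict_proba(self, stack: SliceStack, use_tta: bool | None = None):
        """Per-slice probability maps (index -> float map in [0, 1])."""
        self._check_fitted()
        tta = self.use_tta if use_tta is None else use_tta
        _, probs = predict_stack(
            self.model_, stack, threshold=self.threshold, use_tta=tta,
            pad=True, return_probabilities=True,
        )
        return probs

    def score(
        self,
        stack: SliceStack,
        reference: MaskStack,
        indices: list[int] | None = None,
        use_tta: bool | None = None,
    ) -> float:
        """Mean per-slice Dice of predictions against reference masks."""
        self._check_fitted()
        tta = self.use_tta if use_tta is None else use_tta
        report = evaluate(self.model_, stack, reference, indices, use_tta=tta)
        return report["mean_dice"]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("FossilSegmenter is not fitted; call fit() first")
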