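"""Full-slice prediction with 8-fold dihedral test-time augmentation.

The square has eight symmetries (the dihedral group D4): rotations by 0,
90, 180 and 270 degrees, each optionally composed with a flip.  At
inference time the model predicts all eight transformed copies of a slice;
each probability map is mapped back through the inverse symmetry and the
eight realigned maps are averaged — in probability space, before
thresholding.  All transforms are exact index permutations, so no
interpolation error enters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, GeometryError
from .stack_io import MaskStack, SliceStack
from .trainer import TrainedModel, predict_slice

N_VARIANTS = 8


@dataclass
class TTAPrediction:
    """Averaged probability map for one slice."""

    probability_map: np.ndarray
    slice_index: int = -1
    n_variants: int = N_VARIANTS


def _apply_variant(grid: np.ndarray, variant_id: int) -> np.ndarray:
    """Variant v = (rotation by 90°·(v mod 4)) then (flip if v >= 4)."""
    k = variant_id % 4
    out = np.rot90(grid, k, axes=(-2, -1)) if k else grid
    if variant_id >= 4:
        out = out[..., ::-1]
    return np.ascontiguousarray(out)


def dihedral_variants(image: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """All 8 dihedral transforms of a square grid, as (variant_id, grid).

    Variant 0 is the identity; 1-3 are the quarter-turn rotations; 4-7 are
    the same rotations followed by a horizontal flip.  Leading channel
    axes are preserved; only the last two axes transform.
    """
    if image.shape[-1] != image.shape[-2]:
        raise GeometryError(
            f"dihedral variants need a square grid, got {image.shape}"
        )
    return [(v, _apply_variant(image, v)) for v in range(N_VARIANTS)]


def inverse_dihedral(grid: np.ndarray, variant_id: int) -> np.ndarray:
    """Undo one dihedral variant exactly: inverse∘forward is the identity.

    Rotations invert to the opposite rotation; the flip-composed variants
    are involutions of the flip followed by the inverse rotation.
    """
    if not 0 <= variant_id < N_VARIANTS:
        raise ValueError(f"variant_id must be 0-7, got {variant_id}")
    out = grid
    if variant_id >= 4:
        out = out[..., ::-1]
    k = variant_id % 4
    if k:
        out = np.rot90(out, -k, axes=(-2, -1))
    return np.ascontiguousarray(out)


def tta_predict(model: TrainedModel, image: np.ndarray, slice_index: int = -1) -> TTAPrediction:
    """Average the model's probabilities over the 8 dihedral variants.

    The input is an assembled slice (``(h, w)`` or ``(c, h, w)``); the
    output map is the arithmetic mean of the realigned per-variant maps and
    therefore stays inside the range of the individual predictions.
    """
    if image.shape[-1] != image.shape[-2]:
        raise GeometryError("TTA requires square inputs (use pad=True upstream)")
    expected_c = model.config.in_channels
    got_c = image.shape[0] if image.ndim == 3 else 1
    if got_c != expected_c:
        raise ConfigurationError(
            f"model expects {expected_c} input channel(s), got {got_c}"
        )
    acc = None
    for v, transformed in dihedral_variants(image):
        prob = predict_slice(model.network, transformed)
        realigned = inverse_dihedral(prob, v)
        acc = realigned if acc is None else acc + realigned
    return TTAPrediction(acc / N_VARIANTS, slice_index=slice_index)


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities to a binary mask; pixels >= threshold are 1."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


def predict_stack(
    model: TrainedModel,
    stack: SliceStack,
    channel_mode: str | None = None,
    threshold: float | None = None,
    use_tta: bool = True,
    pad: bool = False,
    return_probabilities: bool = False,
) -> MaskStack | tuple[MaskStack, dict[int, np.ndarray]]:
    """Predict every slice at full resolution and assemble a MaskStack.

    Non-square slices are rejected when TTA is on unless ``pad`` is set, in
    which case they are symmetrically zero-padded to a square for the
    symmetry transforms and cropped back afterwards.
    """
    from .sampler import assemble_input  # local import to avoid a cycle

    cfg = model.config
    channel_mode = channel_mode or cfg.channel_mode
    threshold = cfg.threshold if threshold is None else threshold
    h, w = stack.height, stack.width
    square = h == w
    if use_tta and not square and not pad:
        raise GeometryError(
            "TTA needs square slices; pass pad=True to zero-pad symmetrically"
        )
    masks: dict[int, np.ndarray] = {}
    probs: dict[int, np.ndarray] = {}
    for i in range(stack.n_slices):
        img = assemble_input(stack, i, channel_mode)
        if use_tta:
            if not square:
                side = max(h, w)
                pt, pl = (side - h) // 2, (side - w) // 2
                pads = [(0, 0)] * (img.ndim - 2) + [
                    (pt, side - h - pt),
                    (pl, side - w - pl),
                ]
                padded = np.pad(img, pads)
                prob = tta_predict(model, padded, i).probability_map
                prob = prob[pt : pt + h, pl : pl + w]
            else:
                prob = tta_predict(model, img, i).probability_map
        else:
            prob = predict_slice(model.network, img)
        masks[i] = binarize(prob, threshold)
        if return_probabilities:
            probs[i] = prob
    out = MaskStack(masks, height=h, width=w)
    return (out, probs) if return_probabilities else out
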