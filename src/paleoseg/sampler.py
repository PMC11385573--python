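"""Epoch construction: positive-guaranteed crops, negative crops, augmentation.

Fossil pixels are a tiny fraction of each slice, so unconstrained random
crops would mostly show bare matrix.  Each epoch therefore takes one crop
per annotated training slice that is *guaranteed* to contain fossil pixels
(when the slice has any), plus a fixed number of crops drawn from declared
fossil-free ranges whose target masks are all-zero by construction.

The positive guarantee is implemented by picking a fossil pixel uniformly
at random and then picking the crop origin uniformly among all in-bounds
origins that keep that pixel inside the crop — every fossil pixel has
nonzero sampling mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotation import AnnotationPlan
from .exceptions import GeometryError, SamplingError, ScheduleError
from .stack_io import SliceStack


@dataclass
class CropPair:
    """An aligned (image, mask) training crop.

    ``image_crop`` is ``(crop, crop)`` for 1-channel input or
    ``(3, crop, crop)`` for 2.5D input; ``origin`` is the (row, col) of the
    crop's top-left corner in slice coordinates.
    """

    image_crop: np.ndarray
    mask_crop: np.ndarray
    source_index: int
    origin: tuple[int, int]


@dataclass
class EpochSchedule:
    """The sample universe for one epoch.

    ``items`` interleaves ``("pos", slice_index)`` and ``("neg", None)``
    entries in shuffled order; one positive per training slice plus a
    fixed count of negatives, independent of the positive count.
    """

    items: list[tuple[str, int | None]]

    @property
    def n_positive(self) -> int:
        return sum(1 for kind, _ in self.items if kind == "pos")

    @property
    def n_negative(self) -> int:
        return sum(1 for kind, _ in self.items if kind == "neg")

    def __len__(self) -> int:
        return len(self.items)


def _crop_origin_for_pixel(
    r: int, c: int, h: int, w: int, crop: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Uniform origin among those keeping (r, c) inside an in-bounds crop."""
    r0_lo, r0_hi = max(0, r - crop + 1), min(h - crop, r)
    c0_lo, c0_hi = max(0, c - crop + 1), min(w - crop, c)
    return int(rng.integers(r0_lo, r0_hi + 1)), int(rng.integers(c0_lo, c0_hi + 1))


def sample_positive_crop(
    slice_img: np.ndarray,
    mask: np.ndarray,
    crop_size: int,
    rng: np.random.Generator,
) -> CropPair:
    """A random crop guaranteed to contain at least one fossil pixel.

    Falls back to an unconstrained random crop when the mask is empty (the
    "if available in that slice" clause of the protocol).
    """
    h, w = slice_img.shape[-2:]
    if crop_size > h or crop_size > w:
        raise GeometryError(f"crop {crop_size} exceeds slice {h}x{w}")
    pos = np.flatnonzero(mask)
    if pos.size:
        k = pos[rng.integers(pos.size)]
        r, c = divmod(int(k), mask.shape[1])
        r0, c0 = _crop_origin_for_pixel(r, c, h, w, crop_size, rng)
    else:
        r0 = int(rng.integers(0, h - crop_size + 1))
        c0 = int(rng.integers(0, w - crop_size + 1))
    img = slice_img[..., r0 : r0 + crop_size, c0 : c0 + crop_size]
    msk = mask[r0 : r0 + crop_size, c0 : c0 + crop_size]
    return CropPair(img, msk, source_index=-1, origin=(r0, c0))


def sample_negative_crop(
    stack: SliceStack,
    negative_ranges: list[tuple[int, int]],
    crop_size: int,
    rng: np.random.Generator,
    channel_mode: str = "1ch",
) -> CropPair:
    """A random crop from the fossil-free ranges; its mask is all zeros."""
    if not negative_ranges:
        raise SamplingError("no negative ranges declared")
    h, w = stack.height, stack.width
    if crop_size > h or crop_size > w:
        raise GeometryError(f"crop {crop_size} exceeds slice {h}x{w}")
    sizes = np.array([b - a for a, b in negative_ranges])
    if (sizes <= 0).any():
        raise SamplingError(f"degenerate negative range in {negative_ranges}")
    # Uniform over the union of ranges.
    flat = int(rng.integers(sizes.sum()))
    for (a, b), s in zip(negative_ranges, np.cumsum(sizes)):
        if flat < s:
            index = b - (s - flat)
            break
    r0 = int(rng.integers(0, h - crop_size + 1))
    c0 = int(rng.integers(0, w - crop_size + 1))
    img = assemble_input(stack, index, channel_mode)
    img = img[..., r0 : r0 + crop_size, c0 : c0 + crop_size]
    msk = np.zeros((crop_size, crop_size), dtype=np.uint8)
    return CropPair(img, msk, source_index=index, origin=(r0, c0))


def build_epoch(
    plan: AnnotationPlan,
    neg_crops_per_epoch: int = 2,
    rng: np.random.Generator | None = None,
) -> EpochSchedule:
    """One positive item per training slice plus a fixed negative count.

    The negative count is a constant (default 2) regardless of how many
    training slices there are — 8 training slices give a 10-item epoch,
    17 give 19.
    """
    training = plan.training_indices
    if not training:
        raise ScheduleError("plan has no training slices")
    items: list[tuple[str, int | None]] = [("pos", i) for i in training]
    if neg_crops_per_epoch > 0:
        items += [("neg", None)] * neg_crops_per_epoch
    if rng is not None:
        perm = rng.permutation(len(items))
        items = [items[i] for i in perm]
    return EpochSchedule(items)


def assemble_input(stack: SliceStack, index: int, channel_mode: str) -> np.ndarray:
    """Build the model input for one slice.

    ``"1ch"`` returns the slice itself (h, w); ``"2.5d"`` returns a
    (3, h, w) array of the slice and its two axial neighbours, replicating
    the edge slice where a neighbour is missing.
    """
    if not 0 <= index < stack.n_slices:
        raise IndexError(f"slice index {index} out of range [0, {stack.n_slices})")
    if channel_mode == "1ch":
        return stack[index]
    if channel_mode == "2.5d":
        lo = max(index - 1, 0)
        hi = min(index + 1, stack.n_slices - 1)
        return np.stack([stack[lo], stack[index], stack[hi]])
    raise ValueError(f"unknown channel_mode: {channel_mode!r}")


def augment(
    pair: CropPair,
    rng: np.random.Generator,
    fill_value: float = 0.4,
) -> CropPair:
    """Random rotation (0-360°) and flips, identically on image and mask.

    Multiples of 90° are applied as exact index permutations; other angles
    use bilinear resampling for the image and nearest-neighbour for the
    mask, so the mask stays binary.  Regions rotated in from outside the
    frame are filled with ``fill_value`` (the matrix intensity level) in
    the image and 0 in the mask.
    """
    img, msk = pair.image_crop, pair.mask_crop
    if img.shape[-1] != img.shape[-2]:
        raise GeometryError("augmentation requires square crops")
    angle = float(rng.uniform(0.0, 360.0))
    flip_h = bool(rng.integers(2))
    flip_v = bool(rng.integers(2))

    quarter = angle % 90.0 == 0.0
    if quarter:
        k = int(angle // 90) % 4
        if k:
            img = np.rot90(img, k, axes=(-2, -1))
            msk = np.rot90(msk, k, axes=(-2, -1))
    else:
        axes = (-2, -1)
        img = ndimage.rotate(
            img, angle, axes=axes, reshape=False, order=1,
            mode="constant", cval=fill_value,
        )
        msk = ndimage.rotate(
            msk, angle, axes=axes, reshape=False, order=0,
            mode="constant", cval=0,
        )
    if flip_h:
        img = img[..., ::-1]
        msk = msk[..., ::-1]
    if flip_v:
        img = img[..., ::-1, :]
        msk = msk[..., ::-1, :]
    return CropPair(
        np.ascontiguousarray(img),
        np.ascontiguousarray(msk.astype(np.uint8)),
        pair.source_index,
        pair.origin,
    )
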