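"""The sparse-annotation protocol: every-Nth selection and midpoint refinement.

The workflow annotates a tiny fraction of the stack: every ``step``-th slice
across the visible fossil extent is segmented by hand, one annotated slice
is held out for validation, and fossil-free slice ranges are documented so
they can serve as negative samples.  A second iteration inserts annotations
mid-way between each existing pair (plus the tail needed to complete the
half-step grid), doubling coverage without touching existing work.

The visible extent is an explicit input, not auto-detected — in practice it
comes from a human scanning the volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .exceptions import (
    InsufficientAnnotationError,
    PaleosegError,
    RefinementError,
)
from .stack_io import MaskStack


@dataclass
class AnnotationPlan:
    """Bookkeeping for which slices are annotated and how.

    Fields
    ------
    annotated_indices : sorted list of slice indices that have masks
    step : current annotation stride
    validation_index : the single annotated slice held out for validation
    negative_ranges : disjoint ``[start, end)`` intervals known fossil-free
    iteration : 1 for the initial plan, 2 after midpoint refinement
    extent : (start, end) inclusive bounds of the visible fossil extent
    """

    annotated_indices: list[int]
    step: int
    validation_index: int | None = None
    negative_ranges: list[tuple[int, int]] = field(default_factory=list)
    iteration: int = 1
    extent: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.annotated_indices = sorted(set(int(i) for i in self.annotated_indices))
        self.negative_ranges = [(int(a), int(b)) for a, b in self.negative_ranges]
        if self.validation_index is not None:
            if self.validation_index not in self.annotated_indices:
                raise PaleosegError(
                    f"validation index {self.validation_index} is not annotated"
                )
        for (a, b), (c, _) in zip(self.negative_ranges, self.negative_ranges[1:]):
            if b > c:
                raise PaleosegError("negative ranges must be disjoint and sorted")

    @property
    def training_indices(self) -> list[int]:
        """Annotated indices minus the validation holdout."""
        return [i for i in self.annotated_indices if i != self.validation_index]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "annotated_indices": self.annotated_indices,
                    "step": self.step,
                    "validation_index": self.validation_index,
                    "negative_ranges": [list(r) for r in self.negative_ranges],
                    "iteration": self.iteration,
                    "extent": list(self.extent) if self.extent else None,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            annotated_indices=d["annotated_indices"],
            step=d["step"],
            validation_index=d["validation_index"],
            negative_ranges=[tuple(r) for r in d["negative_ranges"]],
            iteration=d["iteration"],
            extent=tuple(d["extent"]) if d.get("extent") else None,
        )


def select_initial_slices(extent_start: int, extent_end: int, step: int) -> list[int]:
    """Every ``step``-th slice index from ``extent_start`` to ``extent_end``.

    Returns ``extent_start, extent_start+step, ...`` up to and including
    ``extent_end`` when it falls on the grid; the count is
    ``floor((extent_end - extent_start) / step) + 1``.
    """
    if extent_start > extent_end:
        raise ValueError(
            f"inverted extent: start {extent_start} > end {extent_end}"
        )
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    return list(range(extent_start, extent_end + 1, step))


def make_initial_plan(
    extent_start: int,
    extent_end: int,
    step: int,
    negative_ranges: list[tuple[int, int]] | None = None,
) -> AnnotationPlan:
    """Build an iteration-1 plan over the visible extent (no validation yet)."""
    return AnnotationPlan(
        annotated_indices=select_initial_slices(extent_start, extent_end, step),
        step=step,
        negative_ranges=negative_ranges or [],
        iteration=1,
        extent=(extent_start, extent_end),
    )


def refine_plan(plan: AnnotationPlan, extent_end: int | None = None) -> AnnotationPlan:
    """Insert midpoint annotations, halving the stride (iteration 1 -> 2).

    New indices are the midpoints of consecutive annotated pairs plus any
    trailing half-step indices up to ``extent_end``, so the refined index
    set equals ``select_initial_slices(start, extent_end, step // 2)``.
    Existing indices (and the validation holdout) are always retained.
    """
    if plan.iteration != 1:
        raise RefinementError("plan already refined (iteration != 1)")
    if plan.step % 2 != 0:
        raise RefinementError(
            f"step {plan.step} is odd; midpoints would not be integral"
        )
    if extent_end is None:
        if plan.extent is None:
            raise RefinementError("extent_end required when plan has no extent")
        extent_end = plan.extent[1]
    start = plan.annotated_indices[0]
    half = plan.step // 2
    refined = set(select_initial_slices(start, extent_end, half))
    refined |= set(plan.annotated_indices)
    return replace(
        plan,
        annotated_indices=sorted(refined),
        step=half,
        iteration=2,
        extent=(start, extent_end),
    )


def choose_validation_slice(masks: MaskStack, policy: str = "simplest") -> int:
    """Pick the validation holdout by mask positive-pixel count.

    ``"simplest"`` returns the annotated index with the fewest positive
    pixels, ``"most_complex"`` the most; ties break to the lowest slice
    index.  Pixel count stands in for ROI complexity because it is
    objective and reproducible.
    """
    if policy not in ("simplest", "most_complex"):
        raise ValueError(f"unknown policy: {policy!r}")
    if len(masks) < 2:
        raise InsufficientAnnotationError(
            f"need >= 2 annotated masks to hold one out, have {len(masks)}"
        )
    counts = [(masks.positive_count(i), i) for i in masks.indices]
    if policy == "simplest":
        return min(counts)[1]
    best = max(c for c, _ in counts)
    return min(i for c, i in counts if c == best)


def derive_negative_ranges(
    masks: MaskStack, n_slices: int
) -> list[tuple[int, int]]:
    """Maximal ``[start, end)`` intervals whose available masks are all empty.

    With complete coverage (phantom ground truth) this is exact.  With
    sparse annotation, an interval spans from the first to the last of a
    run of consecutive *available* empty masks — it never extends past a
    slice known (or unknown) to contain fossil beyond that run's endpoints.
    """
    ranges: list[tuple[int, int]] = []
    run_start: int | None = None
    run_end: int | None = None
    for idx in masks.indices:
        if masks.positive_count(idx) == 0:
            if run_start is None:
                run_start = idx
            run_end = idx
        else:
            if run_start is not None:
                ranges.append((run_start, run_end + 1))
            run_start = None
    if run_start is not None:
        ranges.append((run_start, min(run_end + 1, n_slices)))
    return ranges
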