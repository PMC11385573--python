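"""Reading and writing CT slice stacks and binary mask stacks.

A *slice stack* is a directory of numbered single-channel images (TIFF or
PNG), one file per axial slice, all sharing the same height and width.  A
*mask stack* is the same layout restricted to binary images; it may cover
any subset of slice indices, because sparse annotation is the norm in this
workflow.

Intensities are normalized with a fixed per-dtype scaling ``v / dtype_max``
(not per-slice min-max), so fossil/matrix contrast keeps the same meaning
along the whole axis.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import (
    FormatError,
    GeometryError,
    MissingInputError,
    NotBinaryError,
)

_NUM_RE = re.compile(r"(\d+)(?!.*\d)")  # last run of digits in the stem


@dataclass
class SliceStack:
    """An ordered grayscale CT volume, one 2D slice per axial index.

    Parameters
    ----------
    data
        Array of shape ``(n_slices, height, width)`` with float intensities
        in ``[0, 1]``.
    voxel_size_um
        Edge length of a voxel in micrometres (metadata only).
    """

    data: np.ndarray
    voxel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(
                f"slice stack must be 3-D (n, h, w), got shape {self.data.shape}"
            )

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def __len__(self) -> int:
        return self.n_slices

    def __getitem__(self, index: int) -> np.ndarray:
        return self.data[index]


@dataclass
class MaskStack:
    """Binary masks aligned to (a subset of) slice indices.

    ``masks`` maps slice index -> 2-D uint8 array with values in {0, 1}.
    ``height``/``width`` pin the geometry so masks can be validated against
    a :class:`SliceStack` even when the mapping is empty.
    """

    masks: dict[int, np.ndarray] = field(default_factory=dict)
    height: int | None = None
    width: int | None = None

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for idx, m in self.masks.items():
            m = np.asarray(m)
            if m.ndim != 2:
                raise GeometryError(f"mask {idx} must be 2-D, got shape {m.shape}")
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise NotBinaryError(
                    f"mask {idx} has values outside {{0, 1}}: {vals[:5]}"
                )
            if self.height is None:
                self.height, self.width = m.shape
            elif m.shape != (self.height, self.width):
                raise GeometryError(
                    f"mask {idx} shape {m.shape} != ({self.height}, {self.width})"
                )
            clean[int(idx)] = m.astype(np.uint8)
        self.masks = dict(sorted(clean.items()))

    @property
    def indices(self) -> list[int]:
        return sorted(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def __contains__(self, index: int) -> bool:
        return index in self.masks

    def __getitem__(self, index: int) -> np.ndarray:
        return self.masks[index]

    def positive_count(self, index: int) -> int:
        return int(self.masks[index].sum())

    def subset(self, indices: Iterable[int]) -> "MaskStack":
        return MaskStack(
            {i: self.masks[i] for i in indices if i in self.masks},
            height=self.height,
            width=self.width,
        )


def normalize_intensities(raw: np.ndarray, bit_depth: int) -> np.ndarray:
    """Scale integer intensities to floats in [0, 1] by the dtype maximum.

    ``v`` maps to ``v / (2**bit_depth - 1)``; monotone, and the dtype
    extremes map to exactly 0.0 and 1.0.
    """
    if bit_depth not in (8, 16):
        raise FormatError(f"unsupported bit depth: {bit_depth}")
    raw = np.asarray(raw)
    dtype_max = float(2**bit_depth - 1)
    if raw.min() < 0 or raw.max() > dtype_max:
        raise FormatError(
            f"values outside the {bit_depth}-bit range [0, {int(dtype_max)}]"
        )
    return raw.astype(np.float64) / dtype_max


def _numeric_key(path: Path) -> int:
    m = _NUM_RE.search(path.stem)
    if m is None:
        raise FormatError(f"filename carries no numeric index: {path.name}")
    return int(m.group(1))


def _list_images(path_pattern: str | Path) -> list[Path]:
    p = Path(path_pattern)
    if p.is_dir():
        files = [
            f
            for f in p.iterdir()
            if f.suffix.lower() in {".tif", ".tiff", ".png"}
        ]
    else:
        files = [Path(f) for f in sorted(p.parent.glob(p.name))]
    if not files:
        raise MissingInputError(f"no image files found under {path_pattern}")
    return sorted(files, key=_numeric_key)


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a single-channel image, got shape {arr.shape}"
        )
    return arr


def _bit_depth_of(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"{path.name}: unsupported dtype {arr.dtype}")


def read_slice_stack(
    path_pattern: str | Path, voxel_size_um: float | None = None
) -> SliceStack:
    """Read a numbered image directory (or glob) into a :class:`SliceStack`.

    Slices are ordered by the numeric component of the filename (``s10``
    sorts after ``s2``), independent of filesystem listing order.  8-bit and
    16-bit single-channel images are accepted and normalized to [0, 1].

    A ``stack_meta.json`` sidecar in the directory may supply
    ``voxel_size_um`` when the argument is not given.
    """
    files = _list_images(path_pattern)
    slices = []
    shape: tuple[int, int] | None = None
    for f in files:
        arr = _read_image(f)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise GeometryError(
                f"{f.name}: shape {arr.shape} differs from first slice {shape}"
            )
        slices.append(normalize_intensities(arr, _bit_depth_of(arr, f)))
    if voxel_size_um is None:
        sidecar = files[0].parent / "stack_meta.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            voxel_size_um = meta.get("voxel_size_um")
    return SliceStack(np.stack(slices), voxel_size_um=voxel_size_um)


def read_mask_stack(
    path_pattern: str | Path,
    expected_geometry: tuple[int, int] | None = None,
    index_offset: int = 0,
) -> MaskStack:
    """Read binary mask images keyed by the numeric index in each filename.

    Any strictly positive pixel becomes 1; more than two distinct pixel
    values is an error.  An empty directory yields an empty (but valid)
    MaskStack — plans may start unannotated.  ``index_offset`` is subtracted
    from the filename number, for 1-based naming schemes.
    """
    try:
        files = _list_images(path_pattern)
    except MissingInputError:
        h, w = expected_geometry if expected_geometry else (None, None)
        return MaskStack({}, height=h, width=w)
    masks: dict[int, np.ndarray] = {}
    for f in files:
        arr = _read_image(f)
        levels = np.unique(arr)
        if levels.size > 2:
            raise NotBinaryError(
                f"{f.name}: {levels.size} distinct pixel values, expected ≤ 2"
            )
        if expected_geometry is not None and arr.shape != tuple(expected_geometry):
            raise GeometryError(
                f"{f.name}: shape {arr.shape} != expected {tuple(expected_geometry)}"
            )
        masks[_numeric_key(f) - index_offset] = (arr > 0).astype(np.uint8)
    h, w = expected_geometry if expected_geometry else next(iter(masks.values())).shape
    return MaskStack(masks, height=h, width=w)


def write_mask_stack(
    masks: MaskStack,
    out_dir: str | Path,
    format: str = "png",
    prefix: str = "mask",
) -> list[Path]:
    """Write each mask as an 8-bit image, 0 -> 0 and 1 -> 255 (white fossil).

    Filenames encode the slice index zero-padded to five digits, e.g.
    ``mask_00200.png``.  Round-tripping through :func:`read_mask_stack`
    reproduces the input bit-exactly.
    """
    if format not in ("png", "tiff"):
        raise FormatError(f"unsupported mask format: {format}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "png" if format == "png" else "tif"
    manifest: list[Path] = []
    for idx in masks.indices:
        img = (masks[idx].astype(np.uint8) * 255)
        path = out / f"{prefix}_{idx:05d}.{ext}"
        if format == "tiff":
            tifffile.imwrite(path, img)
        else:
            iio.imwrite(path, img)
        manifest.append(path)
    return manifest


def write_slice_stack(
    stack: SliceStack,
    out_dir: str | Path,
    format: str = "png",
    bit_depth: int = 8,
    prefix: str = "slice",
) -> list[Path]:
    """Write normalized slices back to numbered 8- or 16-bit images."""
    if format not in ("png", "tiff"):
        raise FormatError(f"unsupported stack format: {format}")
    if bit_depth not in (8, 16):
        raise FormatError(f"unsupported bit depth: {bit_depth}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dtype_max = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    ext = "png" if format == "png" else "tif"
    manifest: list[Path] = []
    for i in range(stack.n_slices):
        img = np.round(np.clip(stack[i], 0.0, 1.0) * dtype_max).astype(dtype)
        path = out / f"{prefix}_{i:05d}.{ext}"
        if format == "tiff":
            tifffile.imwrite(path, img)
        else:
            iio.imwrite(path, img)
        manifest.append(path)
    if stack.voxel_size_um is not None:
        (out / "stack_meta.json").write_text(
            json.dumps({"voxel_size_um": stack.voxel_size_um})
        )
    return manifest
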