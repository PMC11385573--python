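"""Seeded synthetic "fossil in matrix" CT phantoms with exact ground truth.

The phantom emulates the awkward features of real fossil micro-CT data —
low fossil-to-matrix contrast, thin plates, hollow tubes crossed by internal
struts, a narrow nutrient-foramen channel through one tube wall, additive
noise, and optional ring/streak reconstruction artefacts — while providing
a bit-exact ground-truth mask for every slice, so the whole training and
inference pipeline can be exercised and scored at desk scale.

Structures are analytic solids (tubes, tilted plates, strut slabs)
voxelized on the slice grid, so masks are exact by construction.  Noise is
added after structure rendering and before artefacts; artefacts perturb
intensities only, never masks.  All randomness flows from a single
generator seeded once per volume, drawing in a fixed documented order
(tube placement, plate placement, struts, noise, artefact phases), so a
(params, seed) pair is a pure function of its output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConstructionError
from .stack_io import MaskStack, SliceStack


@dataclass
class PhantomParams:
    """Geometry, optics and artefact settings for one synthetic volume.

    Defaults are the desk-scale study conditions: a 96-slice stack of
    192×192 voxels, matrix level 0.40, fossil contrast 0.25 (= 5× the noise
    sigma of 0.05), a 13-voxel foramen (130 µm at 10 µm voxels), and ten
    fossil-free slices at each end of the stack.
    """

    n_slices: int = 96
    height: int = 192
    width: int = 192
    matrix_level: float = 0.40
    contrast: float = 0.25
    noise_sigma: float = 0.05
    n_tubes: int = 2
    n_plates: int = 2
    strut_density: float = 0.15
    foramen_width_vox: int = 13
    ring_artefact: bool = False
    ring_amplitude: float = 0.05
    streak_artefact: bool = False
    streak_amplitude: float = 0.3
    n_streaks: int = 3
    empty_margin: int = 10
    voxel_size_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ConstructionError("contrast must be >= 0")
        if self.matrix_level + self.contrast > 1:
            raise ConstructionError("matrix_level + contrast must be <= 1")
        if self.noise_sigma < 0:
            raise ConstructionError("noise_sigma must be >= 0")
        if self.foramen_width_vox < 1:
            raise ConstructionError("foramen_width_vox must be >= 1")
        if self.empty_margin < 0 or 2 * self.empty_margin >= self.n_slices:
            raise ConstructionError(
                "empty_margin must satisfy 0 <= 2*margin < n_slices"
            )

    @property
    def fossil_range(self) -> tuple[int, int]:
        """[start, end) slice interval that may contain fossil."""
        return self.empty_margin, self.n_slices - self.empty_margin


def _tube_mask(
    params: PhantomParams,
    rng: np.random.Generator,
    yy: np.ndarray,
    xx: np.ndarray,
    carry_foramen: bool,
) -> np.ndarray | None:
    """Voxelize one hollow tube (axis along z) with interior struts.

    Returns the per-slice-constant 2-D fossil mask of the tube cross
    section, or None when the volume is too small to host it.
    """
    h, w = params.height, params.width
    r_out = max(6, min(h, w) // 6)
    wall = max(2, r_out // 6)
    lo = r_out + 2
    if h - r_out - 2 <= lo or w - r_out - 2 <= lo:
        return None
    cy = int(rng.integers(lo, h - r_out - 2))
    cx = int(rng.integers(lo, w - r_out - 2))
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    ring = (rr <= r_out) & (rr >= r_out - wall)

    if carry_foramen:
        # Cut a channel of exactly foramen_width_vox rows through one side
        # of the wall: rows cy-(w-1)//2 .. cy+w//2, columns right of centre.
        fw = params.foramen_width_vox
        y0 = cy - (fw - 1) // 2
        y1 = cy + fw // 2
        cut = (yy >= y0) & (yy <= y1) & (xx > cx)
        ring &= ~cut

    # Interior struts: thin chords across the hollow interior.
    interior = rr < r_out - wall
    n_struts = int(round(params.strut_density * 10))
    strut = np.zeros_like(ring)
    for _ in range(n_struts):
        theta = rng.uniform(0, np.pi)
        offset = rng.uniform(-0.6, 0.6) * (r_out - wall)
        d = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
        strut |= interior & (np.abs(d - offset) <= 1.0)
    return ring | strut


def _plate_mask(
    params: PhantomParams,
    rng: np.random.Generator,
    zz: np.ndarray,
    yy: np.ndarray,
    xx: np.ndarray,
) -> np.ndarray:
    """Voxelize one thin tilted plate inside the fossil-bearing z range."""
    z0, z1 = params.fossil_range
    cz = rng.uniform(z0 + 2, z1 - 2)
    cy = rng.uniform(0.25 * params.height, 0.75 * params.height)
    cx = rng.uniform(0.25 * params.width, 0.75 * params.width)
    # Random unit normal, biased away from the z axis so plates cut
    # several slices.
    n = rng.normal(size=3)
    n[0] *= 0.3
    n /= np.linalg.norm(n)
    thickness = rng.uniform(1.5, 3.0)
    half_extent = rng.uniform(0.15, 0.3) * min(params.height, params.width)
    d = n[0] * (zz - cz) + n[1] * (yy - cy) + n[2] * (xx - cx)
    radial = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    return (np.abs(d) <= thickness / 2) & (radial <= half_extent)


def generate_phantom(params: PhantomParams) -> tuple[SliceStack, MaskStack]:
    """Render a synthetic CT volume and its complete ground-truth masks.

    Fossil voxels take intensity ``matrix_level + contrast`` before noise;
    exactly one tube carries a foramen channel of the configured width; the
    first and last ``empty_margin`` slices are fossil-free.  Identical
    (params, seed) pairs give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    nz, h, w = params.n_slices, params.height, params.width
    z0, z1 = params.fossil_range
    yy, xx = np.mgrid[0:h, 0:w]

    truth = np.zeros((nz, h, w), dtype=bool)

    placed_tubes = 0
    for t in range(params.n_tubes):
        tube2d = _tube_mask(params, rng, yy, xx, carry_foramen=(t == 0))
        if tube2d is None:
            continue
        truth[z0:z1] |= tube2d[None, :, :]
        placed_tubes += 1
    if params.n_tubes > 0 and placed_tubes == 0:
        raise ConstructionError(
            f"volume {h}x{w} too small to place a tube of the requested size"
        )

    if params.n_plates > 0:
        zz3, yy3, xx3 = np.mgrid[0:nz, 0:h, 0:w].astype(np.float64)
        for _ in range(params.n_plates):
            plate = _plate_mask(params, rng, zz3, yy3, xx3)
            plate[:z0] = False
            plate[z1:] = False
            truth |= plate

    volume = np.full((nz, h, w), params.matrix_level, dtype=np.float64)
    volume[truth] = params.matrix_level + params.contrast
    if params.noise_sigma > 0:
        volume += rng.normal(0.0, params.noise_sigma, size=volume.shape)
    volume = np.clip(volume, 0.0, 1.0)

    stack = SliceStack(volume, voxel_size_um=params.voxel_size_um)
    masks = MaskStack(
        {i: truth[i].astype(np.uint8) for i in range(nz)}, height=h, width=w
    )
    if params.ring_artefact or params.streak_artefact:
        stack = inject_artefacts(stack, params, rng=rng)
    return stack, masks


def inject_artefacts(
    stack: SliceStack,
    params: PhantomParams,
    rng: np.random.Generator | None = None,
) -> SliceStack:
    """Overlay CT reconstruction artefacts on the intensities.

    Ring artefacts add concentric sinusoidal bands centred on the slice
    centre; streak artefacts add a few bright straight lines per affected
    slice.  Output is clipped to [0, 1]; masks are never modified.  With
    both amplitudes zero (or both toggles off) the input is returned
    bit-exactly.
    """
    ring_on = params.ring_artefact and params.ring_amplitude > 0
    streak_on = params.streak_artefact and params.streak_amplitude > 0
    if not ring_on and not streak_on:
        return stack
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    nz, h, w = stack.shape
    data = stack.data.copy()

    if ring_on:
        yy, xx = np.mgrid[0:h, 0:w]
        rr = np.sqrt((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2)
        period = rng.uniform(6.0, 12.0)
        phase = rng.uniform(0, 2 * np.pi)
        bands = params.ring_amplitude * np.sin(2 * np.pi * rr / period + phase)
        data += bands[None, :, :]

    if streak_on:
        yy, xx = np.mgrid[0:h, 0:w]
        for z in range(nz):
            if rng.uniform() > 0.5:
                continue
            for _ in range(params.n_streaks):
                theta = rng.uniform(0, np.pi)
                rho = rng.uniform(0, 0.4) * min(h, w)
                d = (
                    (yy - (h - 1) / 2) * np.sin(theta)
                    + (xx - (w - 1) / 2) * np.cos(theta)
                    - rho
                )
                data[z][np.abs(d) <= 0.8] += params.streak_amplitude

    return SliceStack(np.clip(data, 0.0, 1.0), voxel_size_um=stack.voxel_size_um)


def threshold_oracle(stack: SliceStack, params: PhantomParams) -> MaskStack:
    """Global-threshold segmentation at the midpoint between matrix and fossil.

    A sanity oracle: with contrast well above the noise level it recovers
    the bulk of fossil voxels, guaranteeing the phantom poses a solvable
    learning problem.  Never used by the trainer.
    """
    thr = params.matrix_level + params.contrast / 2.0
    return MaskStack(
        {i: (stack[i] >= thr).astype(np.uint8) for i in range(stack.n_slices)},
        height=stack.height,
        width=stack.width,
    )
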