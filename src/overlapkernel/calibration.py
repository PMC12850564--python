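"""Inter-shot overlap regions and sliding-window calibration matrices.

Two shots that sample a common k-space band observe the same object under
different image-space phase modulations; on the overlap, their data are
linked by small shift-invariant interpolation kernels.  This module locates
the overlap band of a shot pair and turns it into a calibration matrix by
sliding a w x w window over the band with stride 1: every window position in
every coil contributes one row.  Coils contribute rows only (the kernels are
shift-invariant across receive channels), never columns.

Two layouts are produced:

``oneway``
    GRAPPA-style: the row holds the *source* shot's patch; a separate target
    vector holds the *target* shot's sample at the window center.
``symmetric``
    ESPIRiT-style: the row concatenates every shot's patch, shot-major; the
    kernels live in the null/row-space structure of this matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .errors import CalibrationError, ConfigurationError
from .sim import AcquisitionBundle, TrajectorySpec

__all__ = [
    "OverlapRegion",
    "CalibMatrix",
    "find_overlap",
    "build_calibration_matrix",
    "calibration_matrix_from_blocks",
]

DEFAULT_WINDOW = 7


@dataclass
class OverlapRegion:
    """Maximal rectangle jointly sampled by a shot pair (inclusive ranges)."""

    shot_pair: tuple[int, int]
    rect: tuple[int, int, int, int]  # (ky_lo, ky_hi, kx_lo, kx_hi)
    n_coils: int

    @property
    def shape(self) -> tuple[int, int]:
        ky_lo, ky_hi, kx_lo, kx_hi = self.rect
        return (ky_hi - ky_lo + 1, kx_hi - kx_lo + 1)


@dataclass
class CalibMatrix:
    """Sliding-window calibration matrix over an overlap region.

    ``matrix`` has one row per (coil, window position); columns follow the
    layout: a single row-major w x w source patch (``oneway``) or all row
    groups' patches concatenated group-major (``symmetric``).  ``target``
    (oneway only) holds the target shot's window-center samples, aligned
    with the rows.
    """

    matrix: NDArray[np.complexfloating]
    window: tuple[int, int]
    layout: str
    shot_pair: tuple[int, ...]
    n_coils: int
    region: OverlapRegion | None = None
    target: NDArray[np.complexfloating] | None = None

    @property
    def n_row_groups(self) -> int:
        """Number of shots whose patches are concatenated in each row."""
        return self.matrix.shape[1] // (self.window[0] * self.window[1])


def _max_rectangle(mask: NDArray[np.bool_], dc: tuple[int, int]) -> tuple[int, int, int, int] | None:
    """Largest axis-aligned all-True rectangle; ties broken nearest to DC.

    Histogram-stack sweep over rows; every popped bar yields a maximal
    candidate.  Among maximum-area candidates the one whose center is
    closest to ``dc`` wins.
    """
    h, w = mask.shape
    heights = np.zeros(w, dtype=int)
    best: tuple[int, float, tuple[int, int, int, int]] | None = None  # (-area, dist, rect)
    for r in range(h):
        heights = np.where(mask[r], heights + 1, 0)
        stack: list[int] = []  # column indices with increasing heights
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            while stack and heights[stack[-1]] >= cur:
                top = stack.pop()
                height = heights[top]
                left = stack[-1] + 1 if stack else 0
                area = height * (c - left)
                if area == 0:
                    continue
                rect = (r - height + 1, r, left, c - 1)
                cy = 0.5 * (rect[0] + rect[1])
                cx = 0.5 * (rect[2] + rect[3])
                dist = (cy - dc[0]) ** 2 + (cx - dc[1]) ** 2
                key = (-area, dist, rect)
                if best is None or key < best:
                    best = key
            stack.append(c)
    return best[2] if best is not None else None


def find_overlap(
    trajectory: TrajectorySpec,
    shot_i: int,
    shot_j: int,
    n_coils: int = 1,
    min_extent: int = DEFAULT_WINDOW,
) -> OverlapRegion:
    """Maximal rectangle sampled by both shots, ties broken toward DC."""
    n_shots = trajectory.n_shots
    if not (0 <= shot_i < n_shots and 0 <= shot_j < n_shots):
        raise CalibrationError(f"shot pair ({shot_i}, {shot_j}) outside 0..{n_shots - 1}")
    common = trajectory.masks[shot_i] & trajectory.masks[shot_j]
    dc = (trajectory.grid_size // 2, trajectory.grid_size // 2)
    rect = _max_rectangle(common, dc)
    if rect is None:
        raise CalibrationError(f"shots ({shot_i}, {shot_j}) share no k-space coordinates")
    hgt, wid = rect[1] - rect[0] + 1, rect[3] - rect[2] + 1
    if min(hgt, wid) < min_extent:
        raise CalibrationError(
            f"overlap of shots ({shot_i}, {shot_j}) is {hgt}x{wid}, "
            f"smaller than the {min_extent}-pixel window on one axis"
        )
    return OverlapRegion(shot_pair=(shot_i, shot_j), rect=rect, n_coils=n_coils)


def calibration_matrix_from_blocks(
    blocks: NDArray[np.complexfloating],
    window_w: int,
    layout: str,
    source_group: int = 0,
    target_group: int = 1,
) -> tuple[NDArray, NDArray | None]:
    """Core sliding-window assembly from dense blocks.

    ``blocks`` has shape (n_groups, n_coils, H, W): fully sampled data of each
    row group (shot) on a common rectangle.  Returns (matrix, target); target
    is None for the symmetric layout.
    """
    if window_w % 2 == 0:
        raise ConfigurationError(f"window_w must be odd, got {window_w}")
    n_groups, n_coils, hgt, wid = blocks.shape
    if hgt < window_w or wid < window_w:
        raise ConfigurationError(f"window {window_w} exceeds region extent {hgt}x{wid}")
    if layout not in ("oneway", "symmetric"):
        raise ConfigurationError(f"unknown layout {layout!r}")
    # (n_groups, n_coils, H-w+1, W-w+1, w, w) view, then rows = coil-major
    # positions in row-major order; patch flattened row-major.
    win = np.lib.stride_tricks.sliding_window_view(blocks, (window_w, window_w), axis=(2, 3))
    n_pos = win.shape[2] * win.shape[3]
    patches = win.reshape(n_groups, n_coils * n_pos, window_w * window_w)
    if layout == "oneway":
        matrix = np.ascontiguousarray(patches[source_group])
        c = window_w // 2
        centers = blocks[target_group, :, c : hgt - c, c : wid - c]
        target = np.ascontiguousarray(centers.reshape(n_coils * n_pos))
        return matrix, target
    matrix = np.ascontiguousarray(np.concatenate(list(patches), axis=1))
    return matrix, None


def build_calibration_matrix(
    bundle: AcquisitionBundle,
    region: OverlapRegion,
    window_w: int = DEFAULT_WINDOW,
    layout: str = "symmetric",
) -> CalibMatrix:
    """Assemble the calibration matrix of a shot pair over its overlap.

    For ``oneway`` the first shot of ``region.shot_pair`` is the source and
    the second the target; swap the pair to calibrate the other direction.
    """
    i, j = region.shot_pair
    ky_lo, ky_hi, kx_lo, kx_hi = region.rect
    sub = bundle.kspace[[i, j], :, ky_lo : ky_hi + 1, kx_lo : kx_hi + 1]
    if not (
        bundle.trajectory.masks[i, ky_lo : ky_hi + 1, kx_lo : kx_hi + 1].all()
        and bundle.trajectory.masks[j, ky_lo : ky_hi + 1, kx_lo : kx_hi + 1].all()
    ):
        raise CalibrationError(f"region {region.rect} is not fully sampled by shots ({i}, {j})")
    matrix, target = calibration_matrix_from_blocks(sub, window_w, layout)
    if not np.all(np.isfinite(matrix)):
        raise CalibrationError("calibration data contain non-finite values")
    return CalibMatrix(
        matrix=matrix,
        window=(window_w, window_w),
        layout=layout,
        shot_pair=(i, j),
        n_coils=bundle.n_coils,
        region=region,
        target=target,
    )
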