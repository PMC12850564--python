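"""GRAPPA-type extraction: solve the one-way inter-shot interpolation kernel.

On the overlap band, the target shot's samples are (approximately) a fixed
w x w k-space convolution of the source shot's samples — the k-space face of
multiplying the image by the smooth relative phase map between the shots.
Solving the one-way calibration system ``A u = target`` in least squares
gives that kernel directly; transforming the zero-filled kernel back to image
space yields the relative complex modulation map between the two shots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg
from numpy.typing import NDArray

from .calibration import CalibMatrix
from .errors import CalibrationError, ConfigurationError
from .fourier import fft2c

__all__ = [
    "InterpKernel",
    "RelativeMap",
    "solve_interp_kernel",
    "kernel_to_relative_map",
    "canonical_gauge",
]

# default regularization per solver (relative to sigma_max / residual tol)
SOLVER_DEFAULT_REG = {"pinv": 1e-3, "tsvd": 0.05, "lsqr": 1e-8}


@dataclass
class InterpKernel:
    """w x w inter-shot interpolation kernel (source-patch offset order)."""

    values: NDArray[np.complexfloating]
    source_shot: int
    target_shot: int
    solver: str
    reg: float


@dataclass
class RelativeMap:
    """Image-space complex modulation of target shot relative to source."""

    values: NDArray[np.complexfloating]
    pair: tuple[int, int]
    method: str = "grappa"

    @property
    def phase(self) -> NDArray[np.floating]:
        return np.angle(self.values)


def solve_interp_kernel(
    calib: CalibMatrix,
    solver: str = "tsvd",
    reg: float | None = None,
) -> InterpKernel:
    """Least-squares solution of ``A u = target`` for the one-way kernel.

    ``pinv`` solves the Tikhonov-regularized normal equations with damping
    ``reg * sigma_max``; ``tsvd`` truncates singular values below
    ``reg * sigma_max``; ``lsqr`` iterates to relative residual ``reg``
    (at most 500 iterations).
    """
    if calib.layout != "oneway":
        raise CalibrationError("solve_interp_kernel needs a oneway-layout calibration matrix")
    a, b = calib.matrix, calib.target
    if a.size == 0:
        raise CalibrationError("empty calibration matrix")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise CalibrationError("non-finite calibration data")
    if solver not in SOLVER_DEFAULT_REG:
        raise ConfigurationError(f"unknown solver {solver!r}")
    if reg is None:
        reg = SOLVER_DEFAULT_REG[solver]
    if solver == "pinv":
        smax = np.linalg.norm(a, 2)
        lam = (reg * smax) ** 2
        u = np.linalg.solve(
            a.conj().T @ a + lam * np.eye(a.shape[1]), a.conj().T @ b
        )
    elif solver == "tsvd":
        uu, ss, vh = np.linalg.svd(a, full_matrices=False)
        keep = ss >= reg * ss[0]
        u = (vh[keep].conj().T / ss[keep]) @ (uu[:, keep].conj().T @ b)
    else:  # lsqr
        res = scipy.sparse.linalg.lsqr(a, b, atol=reg, btol=reg, iter_lim=500)
        u = res[0]
    w = calib.window[0]
    src, tgt = calib.shot_pair
    return InterpKernel(
        values=u.reshape(w, w), source_shot=src, target_shot=tgt, solver=solver, reg=reg
    )


def kernel_to_relative_map(kernel: InterpKernel, grid_size: int) -> RelativeMap:
    """Image-space relative modulation map of the kernel.

    The w x w kernel is embedded at the DC of a zero ``grid_size``-square
    array and transformed with the centered DFT acting as a correlation in
    patch-offset order, normalized so a pure center-delta kernel (identical
    shots) maps to the all-ones image.  The result approximates
    ``P_target / P_source`` on the object support.
    """
    w = kernel.values.shape[0]
    n = grid_size
    if w > n:
        raise ConfigurationError(f"kernel width {w} exceeds grid {n}")
    zf = np.zeros((n, n), dtype=np.complex128)
    c, hw = n // 2, w // 2
    zf[c - hw : c - hw + w, c - hw : c - hw + w] = kernel.values
    # forward centered DFT == flipped-kernel inverse DFT: a kernel delta at
    # patch offset -k0 (target = source shifted by +k0) maps to the plane
    # wave exp(+i 2 pi k0 x / n), the true relative phase.
    values = fft2c(zf)
    return RelativeMap(values=values, pair=(kernel.source_shot, kernel.target_shot))


def canonical_gauge(
    values: NDArray[np.complexfloating],
    weight: NDArray[np.floating] | None = None,
) -> NDArray[np.complexfloating]:
    """Rotate a complex map so its (weighted) mean is real-positive.

    Relative maps are physically defined only up to a global phase; this
    fixes one canonical representative for comparisons.
    """
    if weight is None:
        weight = np.ones(values.shape, dtype=float)
    mean = np.sum(weight * values)
    if mean == 0:
        return values.copy()
    return values * np.exp(-1j * np.angle(mean))
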