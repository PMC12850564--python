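"""Shot-combination reconstructions.

Two ways to merge all shots once per-shot phase maps are known:

1. ``combine_mosaic`` — conjugate-phase combination for mosaic-style
   segmentations: each fully sampled segment is phase-corrected in image
   space, re-windowed onto its k-space support (optionally apodized), all
   segments are summed, and the summed window weights are divided out (the
   inverse modulation-transfer-function filter), so overlap bands are not
   double-counted.

2. ``cg_sense`` — forward-model reconstruction: coil sensitivities, shot
   phase maps and the per-shot sampling masks form a linear encoding
   operator; the image solves the normal equations by conjugate gradients.
   This is the route for phase-interleaved shots, whose segments are not
   fully sampled on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
from numpy.typing import NDArray

from .errors import ConfigurationError, DimensionError
from .fourier import fft2c, ifft2c
from .sim import AcquisitionBundle, CoilMapSet, ShotPhaseSet, TrajectorySpec

__all__ = [
    "CombineConfig",
    "ForwardModel",
    "coil_combine_segments",
    "combine_mosaic",
    "cg_sense",
]


@dataclass
class CombineConfig:
    """Options for the conjugate-phase mosaic combination."""

    # Cosine-taper ramp width at segment edges (0 = hard window).  A ramp of
    # about half the kernel width keeps the phase-kernel convolution tails
    # from being hard-truncated at segment boundaries; the inverse filter
    # removes the window from the final image.
    apodization_px: int = 4
    mtf_floor: float = 0.05  # relative floor for the inverse-MTF division
    reference_shot: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mtf_floor < 1.0:
            raise ConfigurationError("mtf_floor must lie in (0, 1)")


@dataclass
class ForwardModel:
    """Multi-shot SENSE encoding: sampling o DFT o coil o shot-phase."""

    coil_maps: CoilMapSet
    phase_maps: ShotPhaseSet
    masks: NDArray[np.bool_]  # (n_shots, N, N)
    tol: float = 1e-8
    maxiter: int = 200

    def __post_init__(self) -> None:
        n = self.masks.shape[-1]
        if self.coil_maps.maps.shape[-1] != n or self.phase_maps.phase_maps.shape[-1] != n:
            raise DimensionError("coil maps, phase maps and masks grids disagree")

    def apply(self, image: NDArray) -> NDArray:
        """Image -> sampled multi-shot multi-coil k-space (S, C, N, N)."""
        mods = np.stack(
            [self.phase_maps.modulation(s) for s in range(self.masks.shape[0])]
        )
        y = fft2c(self.coil_maps.maps[None, :] * (mods[:, None] * image))
        return y * self.masks[:, None]

    def apply_adjoint(self, y: NDArray) -> NDArray:
        """Adjoint of :meth:`apply` (unnormalized DFT: adjoint = N^2 ifft)."""
        n = self.masks.shape[-1]
        mods = np.stack(
            [self.phase_maps.modulation(s) for s in range(self.masks.shape[0])]
        )
        imgs = ifft2c(y * self.masks[:, None]) * (n * n)
        return np.sum(np.conj(self.coil_maps.maps[None, :]) * imgs * np.conj(mods[:, None]), axis=(0, 1))


def coil_combine_segments(bundle: AcquisitionBundle, coil_maps: CoilMapSet) -> NDArray:
    """Reduce each fully sampled segment to a single channel.

    Per shot the zero-filled k-space of every coil is brought to image
    space, combined pixelwise with ``conj(coil) / sum |coil|^2`` (guarded
    against zero sensitivity), and transformed back, restricted to the
    shot's support.  With exact coil maps this inverts the coil weighting on
    the segment.
    """
    if coil_maps.maps.shape[-1] != bundle.grid_size:
        raise DimensionError("coil map grid disagrees with bundle grid")
    rss2 = np.sum(np.abs(coil_maps.maps) ** 2, axis=0)
    eps = 1e-12 * max(rss2.max(), 1.0)
    weights = np.conj(coil_maps.maps) / (rss2 + eps)
    out = np.zeros((bundle.n_shots,) + bundle.kspace.shape[-2:], dtype=np.complex128)
    for s in range(bundle.n_shots):
        imgs = ifft2c(bundle.kspace[s])
        combined = np.sum(weights * imgs, axis=0)
        out[s] = fft2c(combined) * bundle.trajectory.masks[s]
    return out


def _apodized_window(mask: NDArray[np.bool_], ramp_px: int) -> NDArray[np.floating]:
    """Support indicator, optionally cosine-tapered over ``ramp_px`` pixels."""
    if ramp_px <= 0:
        return mask.astype(float)
    dist = scipy.ndimage.distance_transform_edt(mask)
    t = np.clip(dist / (ramp_px + 1), 0.0, 1.0)
    return np.where(mask, 0.5 * (1.0 - np.cos(np.pi * t)), 0.0)


def combine_mosaic(
    segments: NDArray[np.complexfloating],
    phase_maps: ShotPhaseSet | NDArray,
    trajectory: TrajectorySpec,
    config: CombineConfig | None = None,
) -> NDArray[np.complexfloating]:
    """Conjugate-phase combination with inverse-MTF filtering.

    ``segments`` is the (n_shots, N, N) single-channel k-space (zero outside
    each shot's support).  Each segment is phase-corrected in image space by
    ``exp(-i phase_s)``, re-windowed onto its (apodized) support, summed, and
    divided by the summed window weights floored at ``mtf_floor`` times their
    maximum; unsampled k-space stays zero.
    """
    config = config or CombineConfig()
    phases = phase_maps.phase_maps if isinstance(phase_maps, ShotPhaseSet) else np.asarray(phase_maps)
    n = trajectory.grid_size
    if segments.shape != (trajectory.n_shots, n, n) or phases.shape != segments.shape:
        raise DimensionError("segments / phase maps / trajectory shapes disagree")
    ksum = np.zeros((n, n), dtype=np.complex128)
    wsum = np.zeros((n, n))
    for s in range(trajectory.n_shots):
        win = _apodized_window(trajectory.masks[s], config.apodization_px)
        corrected = ifft2c(segments[s]) * np.exp(-1j * phases[s])
        ksum += fft2c(corrected) * win
        wsum += win
    floor = config.mtf_floor * wsum.max()
    denom = np.maximum(wsum, floor)
    kfinal = np.where(wsum > 0, ksum / denom, 0.0)
    return ifft2c(kfinal)


def cg_sense(bundle: AcquisitionBundle, model: ForwardModel) -> NDArray[np.complexfloating]:
    """Conjugate-gradient solution of the multi-shot SENSE normal equations.

    Starts from zero and stops when the normal-equation residual drops below
    ``model.tol`` relative to its initial value, or after ``model.maxiter``
    iterations (then the best iterate is returned with a warning).
    """
    if model.masks.shape[0] != bundle.n_shots or model.masks.shape[-1] != bundle.grid_size:
        raise DimensionError("forward model grids disagree with bundle")
    b = model.apply_adjoint(bundle.kspace)
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    b0 = np.sqrt(rs)
    if b0 == 0:
        return x
    for _ in range(model.maxiter):
        ap = model.apply_adjoint(model.apply(p))
        alpha = rs / np.vdot(p, ap).real
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        if np.sqrt(rs_new) <= model.tol * b0:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    else:
        warnings.warn(
            f"cg_sense did not reach tol {model.tol} in {model.maxiter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return x
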