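"""Quantitative diagnostics: CV maps, phase errors, singular-value profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .calibration import CalibMatrix
from .eigen_extract import SubspaceBasis
from .sim import ShotPhaseSet

__all__ = ["CVMap", "SVProfile", "cv_map", "phase_rmse", "sv_profile", "nrmse"]


@dataclass
class CVMap:
    """Pixelwise coefficient of variation (1 / tSNR) over repetitions."""

    values: NDArray[np.floating]
    n_repetitions: int


@dataclass
class SVProfile:
    """Normalized singular values sigma / sigma_1, descending."""

    values: NDArray[np.floating]
    kept_count: int | None = None


def cv_map(magnitude_stack: NDArray[np.floating]) -> CVMap:
    """Pixelwise std / mean of magnitudes over the repetition axis (axis 0).

    Pixels with zero temporal mean are set to 0 (guarded division).
    """
    stack = np.abs(np.asarray(magnitude_stack))
    if stack.shape[0] < 2:
        raise ValueError("cv_map needs at least 2 repetitions")
    # deviations are taken against the first repetition so that identical
    # repetitions yield exactly zero (no summation round-off)
    dev = stack - stack[0]
    mean = stack[0] + dev.mean(axis=0)
    std = np.sqrt(((stack - mean) ** 2).mean(axis=0))
    cv = np.where(mean > 0, std / np.where(mean > 0, mean, 1.0), 0.0)
    return CVMap(values=cv, n_repetitions=stack.shape[0])


def _wrap(phi: NDArray) -> NDArray:
    return np.angle(np.exp(1j * phi))


def phase_rmse(
    estimated: ShotPhaseSet,
    truth: ShotPhaseSet,
    weight: NDArray[np.floating],
) -> NDArray[np.floating]:
    """Per-shot magnitude-weighted RMS of the wrapped phase difference.

    One global phase per shot (the weighted circular mean of the difference)
    is removed first, since relative maps are defined only up to it.  All
    arithmetic is on wrapped phases via complex exponentials.
    """
    if estimated.phase_maps.shape != truth.phase_maps.shape:
        raise ValueError("shot phase sets have different shapes")
    w = np.asarray(weight, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("zero total weight")
    out = np.empty(estimated.n_shots)
    for s in range(estimated.n_shots):
        diff = _wrap(estimated.phase_maps[s] - truth.phase_maps[s])
        gauge = np.angle(np.sum(w * np.exp(1j * diff)))
        resid = _wrap(diff - gauge)
        out[s] = np.sqrt(np.sum(w * resid**2) / wsum)
    return out


def sv_profile(source: CalibMatrix | SubspaceBasis) -> SVProfile:
    """sigma / sigma_1 profile of a calibration matrix or its SVD basis."""
    if isinstance(source, SubspaceBasis):
        s, kept = source.singular_values, source.kept_count
    elif isinstance(source, CalibMatrix):
        s = np.linalg.svd(source.matrix, compute_uv=False)
        kept = None
    else:
        raise TypeError(f"cannot profile object of type {type(source).__name__}")
    if s.size == 0 or s[0] == 0:
        raise ValueError("all-zero matrix has no singular-value profile")
    return SVProfile(values=s / s[0], kept_count=kept)


def nrmse(
    estimate: NDArray,
    reference: NDArray,
    fit_scale: bool = False,
) -> float:
    """||estimate - reference|| / ||reference||; optionally remove one
    global complex scale (least-squares fit of estimate to reference)."""
    est = np.asarray(estimate, dtype=np.complex128)
    ref = np.asarray(reference, dtype=np.complex128)
    if fit_scale:
        denom = np.vdot(est, est)
        if denom != 0:
            est = est * (np.vdot(est, ref) / denom)
    return float(np.linalg.norm(est - ref) / np.linalg.norm(ref))
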