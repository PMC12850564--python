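"""End-to-end convenience wrappers tying the pipeline stages together.

These functions carry no science of their own: they wire simulator output
through overlap search, calibration, kernel or eigenvalue extraction, chain
alignment and reconstruction, in the order the method runs.  The CLI and the
reproduction script are thin layers over them.
"""

from __future__ import annotations

import numpy as np

from .calibration import build_calibration_matrix, find_overlap
from .eigen_extract import (
    EigenResult,
    align_shots,
    build_pixel_operators,
    calib_svd,
    eigen_phase_maps,
    inpaint_low_confidence,
    muse_kernel_extract,
)
from .errors import ConfigurationError
from .kernel_extract import RelativeMap, kernel_to_relative_map, solve_interp_kernel
from .sim import (
    AcquisitionBundle,
    CoilMapSet,
    ShotPhaseSet,
    make_coil_maps,
    make_phantom,
    make_shot_phase_maps,
    make_trajectory,
    noise_sigma_for_snr,
    simulate_acquisition,
)

__all__ = [
    "consecutive_pairs",
    "eigen_pair_result",
    "grappa_pair_map",
    "extract_phase_maps",
    "simulate_study",
]


def consecutive_pairs(n_shots: int) -> list[tuple[int, int]]:
    """The chain of consecutive shot pairs used for pairwise calibration."""
    return [(s, s + 1) for s in range(n_shots - 1)]


def eigen_pair_result(
    bundle: AcquisitionBundle,
    pair: tuple[int, int],
    window_w: int = 7,
    keep: float = 0.5,
    keep_mode: str = "fraction",
) -> EigenResult:
    """Eigenvalue extraction for one overlapped shot pair."""
    region = find_overlap(bundle.trajectory, *pair, n_coils=bundle.n_coils, min_extent=window_w)
    calib = build_calibration_matrix(bundle, region, window_w, layout="symmetric")
    basis = calib_svd(calib, keep=keep, keep_mode=keep_mode)
    stack = build_pixel_operators(basis, window_w, bundle.grid_size, 2)
    result = eigen_phase_maps(stack, reference_shot=0)
    result.pair = pair
    return result


def grappa_pair_map(
    bundle: AcquisitionBundle,
    pair: tuple[int, int],
    window_w: int = 7,
    solver: str = "tsvd",
    reg: float | None = None,
) -> RelativeMap:
    """GRAPPA-type kernel solve and image-space map for one shot pair."""
    region = find_overlap(bundle.trajectory, *pair, n_coils=bundle.n_coils, min_extent=window_w)
    calib = build_calibration_matrix(bundle, region, window_w, layout="oneway")
    kernel = solve_interp_kernel(calib, solver=solver, reg=reg)
    return kernel_to_relative_map(kernel, bundle.grid_size)


def extract_phase_maps(
    bundle: AcquisitionBundle,
    method: str = "espirit",
    coil_maps: CoilMapSet | None = None,
    window_w: int = 7,
    keep: float = 0.5,
    solver: str = "tsvd",
    reference_shot: int = 0,
    mask_threshold: float = 0.7,
) -> ShotPhaseSet:
    """Full-bundle phase-map extraction by either method.

    Mosaic-style trajectories are processed pairwise over the consecutive
    chain and aligned to the reference shot; phase-interleaved trajectories
    go through the MUSE-with-kernel route (requires ``coil_maps`` for the
    intermediate reconstructions).  For the eigen method, low-confidence
    pixels (top eigenvalue below ``mask_threshold``) are inpainted from
    their nearest confident neighbor before alignment.
    """
    if bundle.trajectory.scheme == "phase_interleaved":
        if coil_maps is None:
            raise ConfigurationError("phase_interleaved extraction needs coil maps")
        return muse_kernel_extract(
            bundle, coil_maps, keep=keep, window_w=window_w, reference_shot=reference_shot
        )
    pairwise: list = []
    for pair in consecutive_pairs(bundle.n_shots):
        if method == "espirit":
            res = eigen_pair_result(bundle, pair, window_w=window_w, keep=keep)
            vec, _ = inpaint_low_confidence(res, threshold=mask_threshold)
            res = EigenResult(
                shot_vector_map=vec,
                eigenvalue_map=res.eigenvalue_map,
                pair=pair,
                reference_shot=0,
            )
            pairwise.append(res)
        elif method == "grappa":
            pairwise.append(grappa_pair_map(bundle, pair, window_w=window_w, solver=solver))
        else:
            raise ConfigurationError(f"unknown extraction method {method!r}")
    return align_shots(pairwise, reference_shot, n_shots=bundle.n_shots)


def simulate_study(
    scheme: str = "mosaic2",
    grid_size: int = 64,
    n_shots: int = 2,
    n_coils: int = 4,
    overlap_px: int = 15,
    poly_order: int = 2,
    amplitude_rad: float = 1.5,
    random_fraction: float = 0.0,
    snr: float | None = None,
    undersample_R: int = 1,
    eddy_shift_px=None,
    seed: int = 0,
):
    """One fully specified synthetic acquisition with its ground truth.

    Defaults are the package's standard study conditions: 64x64 grid, 4
    coils, 15-pixel overlap, polynomial (order 2) shot phases of 1.5 rad
    peak amplitude, noiseless.  ``snr`` switches on complex Gaussian noise
    at the requested image-domain SNR.  Returns (bundle, phantom, coils,
    phases).
    """
    phantom = make_phantom(grid_size, "ellipses")
    coils = make_coil_maps(n_coils, grid_size, seed=seed + 1)
    phases = make_shot_phase_maps(
        n_shots, grid_size, poly_order, amplitude_rad, random_fraction, seed=seed + 2
    )
    traj = make_trajectory(scheme, grid_size, n_shots, overlap_px, undersample_R)
    sigma = 0.0 if snr is None else noise_sigma_for_snr(phantom, snr)
    bundle = simulate_acquisition(
        phantom, coils, phases, traj, noise_sigma=sigma, eddy_shift_px=eddy_shift_px, seed=seed + 3
    )
    return bundle, phantom, coils, phases
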