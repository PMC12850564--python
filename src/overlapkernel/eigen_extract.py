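"""ESPIRiT-type extraction: eigenvalue calibration of shot-phase maps.

The symmetric calibration matrix stacks, for every sliding-window position
and coil, the patches of all shots in one row.  Its row space is spanned by
shift-invariant kernel structure; an SVD with singular-value thresholding
separates that signal subspace from noise.  Zero-filling the kept right
singular vectors, Fourier transforming them to image space and collecting
them per pixel yields a small per-pixel operator whose top eigenvector (for
eigenvalue ~1) is exactly the vector of per-shot complex modulations at that
pixel — the shot-to-shot phase-fluctuation maps, obtained without any
navigator acquisition.

The normalization absorbs the window-counting operator and DFT scalings into
one constant, calibrated analytically so that noiseless identical-shot data
yields a top eigenvalue of exactly 1; with that normalization the per-pixel
operator is an average of projections and its eigenvalues lie in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
from numpy.typing import NDArray

from .calibration import CalibMatrix, calibration_matrix_from_blocks
from .errors import AlignmentError, CalibrationError, ConfigurationError
from .fourier import fft2c, ifft2c
from .kernel_extract import RelativeMap
from .sim import AcquisitionBundle, CoilMapSet, ShotPhaseSet

__all__ = [
    "SubspaceBasis",
    "PixelOperatorStack",
    "EigenResult",
    "calib_svd",
    "build_pixel_operators",
    "eigen_phase_maps",
    "align_shots",
    "muse_kernel_extract",
    "inpaint_low_confidence",
]


@dataclass
class SubspaceBasis:
    """Kept/discarded split of the calibration-matrix right singular vectors."""

    singular_values: NDArray[np.floating]  # descending
    kept_count: int
    V_par: NDArray[np.complexfloating]  # (n_groups * w^2, kept_count)
    window: int
    n_groups: int


@dataclass
class PixelOperatorStack:
    """Per-pixel matrices M_q assembled from the kept subspace.

    ``m`` has shape (kept_count, n_groups, N, N); the per-pixel operator is
    ``G_q = M_q^H M_q`` with ``M_q = m[:, :, qy, qx]``.  The scaling makes
    G_q an average of projections: top eigenvalue <= 1.
    """

    m: NDArray[np.complexfloating]
    window: int
    n_groups: int

    def gram(self) -> NDArray[np.complexfloating]:
        """Per-pixel (N, N, n_groups, n_groups) Gram matrices M_q^H M_q."""
        return np.einsum("ksyx,ktyx->yxst", np.conj(self.m), self.m)


@dataclass
class EigenResult:
    """Per-pixel top eigenpair of the normalized pixelwise operator."""

    shot_vector_map: NDArray[np.complexfloating]  # (N, N, n_groups), unit norm
    eigenvalue_map: NDArray[np.floating]  # (N, N)
    pair: tuple[int, ...]
    reference_shot: int = 0

    def relative_phase(self, shot_index: int) -> NDArray[np.floating]:
        """Phase of a shot relative to the reference shot, per pixel."""
        ref = self.pair.index(self.reference_shot) if self.reference_shot in self.pair else 0
        v = self.shot_vector_map
        return np.angle(v[..., shot_index] * np.conj(v[..., ref]))


def calib_svd(
    calib: CalibMatrix,
    keep: float = 0.5,
    keep_mode: str = "fraction",
) -> SubspaceBasis:
    """Economy SVD of the symmetric calibration matrix with thresholding.

    ``keep_mode='fraction'`` keeps ``round(keep * n_columns)`` vectors
    (around half subspace truncation by default); ``keep_mode='sigma'``
    keeps singular values >= ``keep * sigma_max``.
    """
    if calib.layout != "symmetric":
        raise CalibrationError("calib_svd needs a symmetric-layout calibration matrix")
    a = calib.matrix
    if a.size == 0:
        raise CalibrationError("empty calibration matrix")
    _, s, vh = np.linalg.svd(a, full_matrices=False)
    if keep_mode == "fraction":
        kept = int(round(keep * a.shape[1]))
    elif keep_mode == "sigma":
        kept = int(np.count_nonzero(s >= keep * s[0]))
    else:
        raise ConfigurationError(f"unknown keep_mode {keep_mode!r}")
    kept = max(1, min(kept, s.size))
    return SubspaceBasis(
        singular_values=s,
        kept_count=kept,
        V_par=vh[:kept].conj().T,
        window=calib.window[0],
        n_groups=calib.n_row_groups,
    )


def build_pixel_operators(
    basis: SubspaceBasis,
    window_w: int,
    grid_size: int,
    n_shots_pair: int,
) -> PixelOperatorStack:
    """Zero-fill, Fourier transform and stack the kept subspace per pixel.

    Each kept vector splits shot-major into ``n_shots_pair`` patches of
    ``window_w`` square (inverting the calibration column ordering).  Each
    patch is embedded at the DC of the full grid and transformed with the
    *forward* centered DFT — with ``A = U S V^H`` the columns of V span the
    conjugated rows, so the forward transform (conjugate-reversed patch
    under the inverse DFT) is what makes the operator act as a correlation
    on the acquired data itself rather than on its conjugate mirror.  The
    1 / w scaling (with the unnormalized forward DFT) makes the per-pixel
    Gram an average of projections: identical-shot data reaches top
    eigenvalue exactly 1.
    """
    w, n = window_w, grid_size
    if basis.V_par.shape[0] != n_shots_pair * w * w:
        raise ConfigurationError(
            f"basis column length {basis.V_par.shape[0]} != n_shots_pair * w^2 "
            f"= {n_shots_pair * w * w}: ordering mismatch with calibration layout"
        )
    kept = basis.kept_count
    patches = basis.V_par.T.reshape(kept, n_shots_pair, w, w)
    zf = np.zeros((kept, n_shots_pair, n, n), dtype=np.complex128)
    c, hw = n // 2, w // 2
    zf[:, :, c - hw : c - hw + w, c - hw : c - hw + w] = patches
    m = fft2c(zf) / w
    return PixelOperatorStack(m=m, window=w, n_groups=n_shots_pair)


def eigen_phase_maps(stack: PixelOperatorStack, reference_shot: int = 0) -> EigenResult:
    """Per-pixel top eigenpair of ``M_q^H M_q``.

    The eigenvector is unit-normalized and phase-referenced so its
    reference-shot component is real-nonnegative; its components are the
    relative complex shot modulations at that pixel.  Degenerate (all-zero)
    pixels return eigenvalue 0 and the canonical basis vector.
    """
    g = stack.gram()
    vals, vecs = np.linalg.eigh(g)  # ascending
    top = vals[..., -1].real
    vec = vecs[..., :, -1]
    # gauge: reference component real-nonnegative
    ref = vec[..., reference_shot]
    phase = np.where(np.abs(ref) > 0, np.exp(-1j * np.angle(ref)), 1.0)
    vec = vec * phase[..., None]
    degenerate = top <= 0
    if np.any(degenerate):
        canon = np.zeros(stack.n_groups, dtype=np.complex128)
        canon[reference_shot] = 1.0
        vec[degenerate] = canon
        top = np.where(degenerate, 0.0, top)
    return EigenResult(
        shot_vector_map=vec,
        eigenvalue_map=top,
        pair=tuple(range(stack.n_groups)),
        reference_shot=reference_shot,
    )


def _pairwise_phase(item) -> tuple[tuple[int, int], NDArray]:
    """(pair, relative-phase map of pair[1] vs pair[0]) from either method."""
    if isinstance(item, RelativeMap):
        return item.pair, np.angle(item.values)
    if isinstance(item, EigenResult):
        if len(item.pair) != 2:
            raise AlignmentError("align_shots needs pairwise (2-shot) eigen results")
        v = item.shot_vector_map
        return item.pair, np.angle(v[..., 1] * np.conj(v[..., 0]))
    raise TypeError(f"cannot align object of type {type(item).__name__}")


def align_shots(pairwise: list, reference_shot: int, n_shots: int | None = None) -> ShotPhaseSet:
    """Compose pairwise relative phases along the chain from the reference.

    Pairwise maps carry tags (i, j) meaning "phase of shot j relative to
    shot i"; shots are aligned by accumulating complex exponentials along a
    path from ``reference_shot`` (the reference map is identically 0).  A
    disconnected chain raises an alignment error.
    """
    edges = [_pairwise_phase(item) for item in pairwise]
    shots = {reference_shot}
    for (i, j), _ in edges:
        shots.update((i, j))
    if n_shots is None:
        n_shots = max(shots) + 1
    grid = edges[0][1].shape if edges else None
    if grid is None:
        raise AlignmentError("no pairwise maps given")
    z = {reference_shot: np.ones(grid, dtype=np.complex128)}
    remaining = list(range(len(edges)))
    while remaining:
        progressed = False
        for k in list(remaining):
            (i, j), phi = edges[k]
            if i in z and j not in z:
                z[j] = z[i] * np.exp(1j * phi)
            elif j in z and i not in z:
                z[i] = z[j] * np.exp(-1j * phi)
            elif not (i in z and j in z):
                continue
            remaining.remove(k)
            progressed = True
        if not progressed:
            missing = sorted(shots - set(z))
            raise AlignmentError(f"shots {missing} are not connected to shot {reference_shot}")
    maps = np.zeros((n_shots,) + grid)
    for s, zs in z.items():
        if s != reference_shot:
            maps[s] = np.angle(zs)
    return ShotPhaseSet(n_shots=n_shots, phase_maps=maps)


def inpaint_low_confidence(
    result: EigenResult, threshold: float = 0.7
) -> tuple[NDArray[np.complexfloating], NDArray[np.bool_]]:
    """Replace low-eigenvalue pixels by their nearest confident neighbor.

    Pixels whose top eigenvalue falls below ``threshold`` are flagged
    low-confidence; their shot vectors are copied from the nearest pixel
    above threshold so downstream phase composition never sees undefined
    values.  Returns (inpainted shot-vector map, low-confidence flag map).
    """
    low = result.eigenvalue_map < threshold
    vec = result.shot_vector_map.copy()
    if low.any() and not low.all():
        _, idx = scipy.ndimage.distance_transform_edt(low, return_indices=True)
        vec = vec[idx[0], idx[1]]
    return vec, low


def muse_kernel_extract(
    bundle: AcquisitionBundle,
    coil_maps: CoilMapSet,
    central_block: int | None = None,
    keep: float = 0.5,
    window_w: int = 7,
    reference_shot: int = 0,
    cg_tol: float = 1e-8,
    cg_maxiter: int = 200,
) -> ShotPhaseSet:
    """MUSE-with-kernel: eigen extraction for phase-interleaved shots.

    Raw interleaved shots share no k-space coordinates, so each shot is first
    reconstructed alone by CG-SENSE (zero phase), transformed back to k-space
    and cropped to the central calibration block.  The cropped blocks act as
    the shot-dependent ACS: one symmetric calibration matrix over *all* shots
    jointly feeds the eigenvalue machinery, replacing the image-space
    total-variation phase smoothing of the original MUSE.
    """
    from .shot_recon import ForwardModel, cg_sense  # deferred: avoid cycle

    traj = bundle.trajectory
    if traj.scheme != "phase_interleaved":
        raise ConfigurationError("muse_kernel_extract requires a phase_interleaved trajectory")
    if central_block is None:
        central_block = traj.central_block or min(50, traj.grid_size // 2)
    if central_block < window_w:
        raise ConfigurationError(
            f"central_block {central_block} smaller than window {window_w}"
        )
    n = traj.grid_size
    n_shots = traj.n_shots
    under = n_shots * traj.undersample_R
    if under > 2 * coil_maps.n_coils:
        warnings.warn(
            f"per-shot undersampling {under}x exceeds 2x coil count "
            f"({coil_maps.n_coils}); intermediate reconstructions may fail and "
            "degrade the extracted phase maps",
            RuntimeWarning,
            stacklevel=2,
        )
    c, hb = n // 2, central_block // 2
    sl = slice(c - hb, c - hb + central_block)
    blocks = np.empty((n_shots, 1, central_block, central_block), dtype=np.complex128)
    zero_phase = ShotPhaseSet(n_shots=1, phase_maps=np.zeros((1, n, n)))
    for s in range(n_shots):
        sub = AcquisitionBundle(
            kspace=bundle.kspace[s : s + 1],
            trajectory=bundle.trajectory.__class__(
                scheme=traj.scheme,
                grid_size=n,
                n_shots=1,
                masks=traj.masks[s : s + 1],
                overlap_px=traj.overlap_px,
                undersample_R=traj.undersample_R,
                central_block=traj.central_block,
            ),
            noise_sigma=bundle.noise_sigma,
        )
        model = ForwardModel(
            coil_maps=coil_maps, phase_maps=zero_phase, masks=traj.masks[s : s + 1],
            tol=cg_tol, maxiter=cg_maxiter,
        )
        inter = cg_sense(sub, model)
        blocks[s, 0] = fft2c(inter)[sl, sl]
    matrix, _ = calibration_matrix_from_blocks(blocks, window_w, "symmetric")
    calib = CalibMatrix(
        matrix=matrix,
        window=(window_w, window_w),
        layout="symmetric",
        shot_pair=tuple(range(n_shots)),
        n_coils=1,
    )
    basis = calib_svd(calib, keep=keep)
    stack = build_pixel_operators(basis, window_w, n, n_shots)
    result = eigen_phase_maps(stack, reference_shot=reference_shot)
    maps = np.zeros((n_shots, n, n))
    v = result.shot_vector_map
    for s in range(n_shots):
        if s != reference_shot:
            maps[s] = np.angle(v[..., s] * np.conj(v[..., reference_shot]))
    return ShotPhaseSet(n_shots=n_shots, phase_maps=maps)
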