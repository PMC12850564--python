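"""Synthetic multi-shot, multi-coil EPI acquisitions with known ground truth.

The simulator realizes the multi-shot signal model: each shot observes the
same complex object modulated by a smooth, shot-specific image-space phase
map (the image-space face of the shot-to-shot phase-fluctuation kernels), as
seen through smooth complex coil sensitivities, sampled on that shot's subset
of a common Cartesian k-space grid.  Four segmentation schemes are provided
(two-shot mosaic, four-shot mosaic, readout-segmented, phase-interleaved),
each with configurable inter-shot overlap bands, an optional per-shot k-space
shift standing in for shot-dependent eddy currents, and i.i.d. complex
Gaussian noise.

All Fourier transforms use the shared centered-DFT convention (DC at index
``N // 2``).  Every randomized constructor takes an explicit seed and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .errors import ConfigurationError, DimensionError
from .fourier import centered_coords, fft2c

__all__ = [
    "Phantom",
    "CoilMapSet",
    "ShotPhaseSet",
    "TrajectorySpec",
    "AcquisitionBundle",
    "make_phantom",
    "make_coil_maps",
    "make_shot_phase_maps",
    "make_trajectory",
    "simulate_acquisition",
    "noise_sigma_for_snr",
]

SCHEMES = ("mosaic2", "mosaic4", "readout_segmented", "phase_interleaved")


# ----------------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------------


@dataclass
class Phantom:
    """Piecewise-smooth complex test object on a square grid.

    Magnitude lies in [0, 1] and is exactly zero outside ``support_mask``.
    """

    grid_size: int
    values: NDArray[np.complexfloating]
    support_mask: NDArray[np.bool_]


@dataclass
class CoilMapSet:
    """Smooth complex receiver sensitivity maps, RSS-normalized to ~1."""

    n_coils: int
    maps: NDArray[np.complexfloating]  # (n_coils, N, N)


@dataclass
class ShotPhaseSet:
    """Per-shot image-space phase maps (radians); shot 0 is the reference.

    ``amplitude_maps`` model shot-to-shot magnitude fluctuation and default
    to all-ones (magnitude fluctuation is simulated only on request).
    """

    n_shots: int
    phase_maps: NDArray[np.floating]  # (n_shots, N, N), radians
    amplitude_maps: NDArray[np.floating] | None = None

    def modulation(self, shot: int) -> NDArray[np.complexfloating]:
        """Complex per-pixel modulation amplitude * exp(i * phase) of a shot."""
        mod = np.exp(1j * self.phase_maps[shot])
        if self.amplitude_maps is not None:
            mod = self.amplitude_maps[shot] * mod
        return mod


@dataclass
class TrajectorySpec:
    """Per-shot Cartesian sampling masks for one segmentation scheme."""

    scheme: str
    grid_size: int
    n_shots: int
    masks: NDArray[np.bool_]  # (n_shots, N, N) over (ky, kx)
    overlap_px: int
    undersample_R: int = 1
    central_block: int | None = None  # phase_interleaved calibration block

    def coordinates(self, shot: int) -> NDArray[np.int64]:
        """(n_samples, 2) array of (ky, kx) grid indices sampled by a shot."""
        return np.argwhere(self.masks[shot])


@dataclass
class AcquisitionBundle:
    """Sampled multi-shot multi-coil k-space plus the generating truth."""

    kspace: NDArray[np.complexfloating]  # (n_shots, n_coils, N, N)
    trajectory: TrajectorySpec
    noise_sigma: float = 0.0
    truth: tuple | None = None  # (Phantom, CoilMapSet, ShotPhaseSet, eddy)

    @property
    def n_shots(self) -> int:
        return self.kspace.shape[0]

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[1]

    @property
    def grid_size(self) -> int:
        return self.kspace.shape[-1]


# ----------------------------------------------------------------------------
# Object, coils, phase maps
# ----------------------------------------------------------------------------


def make_phantom(grid_size: int, kind: str = "ellipses") -> Phantom:
    """Deterministic analytic test object.

    ``ellipses`` composes a few nested ellipses with distinct intensities
    (a simplified head-phantom look); ``blocks`` tiles rectangles.  The
    output depends only on (grid_size, kind).
    """
    if grid_size < 16:
        raise ConfigurationError(f"grid_size must be >= 16, got {grid_size}")
    n = grid_size
    y, x = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
    img = np.zeros((n, n))
    if kind == "ellipses":
        # (cy, cx, ry, rx, angle_deg, additive intensity)
        parts = [
            (0.0, 0.0, 0.86, 0.68, 0.0, 0.8),
            (-0.02, 0.0, 0.78, 0.60, 0.0, -0.3),
            (0.15, 0.22, 0.25, 0.12, -18.0, 0.35),
            (0.15, -0.22, 0.28, 0.14, 18.0, 0.25),
            (-0.35, 0.0, 0.18, 0.30, 0.0, -0.25),
            (0.45, 0.0, 0.10, 0.10, 0.0, 0.4),
        ]
        for cy, cx, ry, rx, ang, val in parts:
            t = np.deg2rad(ang)
            yr = (y - cy) * np.cos(t) - (x - cx) * np.sin(t)
            xr = (y - cy) * np.sin(t) + (x - cx) * np.cos(t)
            img[(yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0] += val
    elif kind == "blocks":
        img[(np.abs(y) < 0.8) & (np.abs(x) < 0.7)] = 0.55
        img[(np.abs(y + 0.3) < 0.25) & (np.abs(x - 0.2) < 0.3)] += 0.3
        img[(np.abs(y - 0.35) < 0.2) & (np.abs(x + 0.25) < 0.25)] -= 0.25
        img[(np.abs(y - 0.1) < 0.08) & (np.abs(x - 0.45) < 0.12)] += 0.4
    else:
        raise ConfigurationError(f"unknown phantom kind {kind!r}")
    img = np.clip(img, 0.0, 1.0)
    support = img > 0
    return Phantom(grid_size=n, values=img.astype(np.complex128), support_mask=support)


def make_coil_maps(n_coils: int, grid_size: int, seed: int) -> CoilMapSet:
    """Smooth complex coil maps, root-sum-of-squares normalized to 1.

    Each raw map is a broad Gaussian (randomized center outside the FOV
    interior, emulating a surface coil) times a low-order complex polynomial;
    the stack is then divided pixelwise by its RSS, so the RSS is exactly 1
    everywhere.  For a single coil this forces unit magnitude.
    """
    if n_coils < 1:
        raise ConfigurationError("n_coils must be >= 1")
    rng = np.random.default_rng(seed)
    n = grid_size
    y, x = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
    maps = np.empty((n_coils, n, n), dtype=np.complex128)
    for c in range(n_coils):
        # coil center on a ring of radius ~1.2, evenly spaced + jitter
        ang = 2 * np.pi * (c / n_coils + 0.05 * rng.standard_normal())
        cy, cx = 1.2 * np.sin(ang), 1.2 * np.cos(ang)
        width = 1.4 + 0.2 * rng.random()
        gauss = np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * width**2))
        a = 0.3 * rng.standard_normal(3) + 1j * 0.3 * rng.standard_normal(3)
        poly = 1.0 + a[0] * x + a[1] * y + a[2] * x * y
        maps[c] = gauss * poly
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    rss = np.where(rss > 0, rss, 1.0)
    maps /= rss
    return CoilMapSet(n_coils=n_coils, maps=maps)


def make_shot_phase_maps(
    n_shots: int,
    grid_size: int,
    poly_order: int,
    amplitude_rad: float,
    random_fraction: float,
    seed: int,
) -> ShotPhaseSet:
    """Smooth per-shot phase maps: random 2D polynomial + band-limited field.

    Shot 0 is identically zero (the phase reference).  The non-reference maps
    mix a random polynomial of total order ``poly_order`` with a band-limited
    random field (weight ``random_fraction``), then are scaled jointly so the
    maximum absolute phase over all shots and pixels equals ``amplitude_rad``.
    """
    if n_shots < 2:
        raise ConfigurationError("n_shots must be >= 2")
    if poly_order > 4:
        raise ConfigurationError("poly_order must be <= 4")
    if amplitude_rad < 0:
        raise ValueError("amplitude_rad must be nonnegative")
    if not 0.0 <= random_fraction <= 1.0:
        raise ValueError("random_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = grid_size
    y, x = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, n), indexing="ij")
    phases = np.zeros((n_shots, n, n))
    for s in range(1, n_shots):
        poly = np.zeros((n, n))
        for a in range(poly_order + 1):
            for b in range(poly_order + 1 - a):
                poly += rng.standard_normal() * (x**a) * (y**b)
        # band-limited field: random low spatial frequencies only
        kmax = max(2, n // 16)
        spec = np.zeros((n, n), dtype=np.complex128)
        ky, kx = centered_coords(n), centered_coords(n)
        low = (np.abs(ky)[:, None] <= kmax) & (np.abs(kx)[None, :] <= kmax)
        spec[low] = rng.standard_normal(low.sum()) + 1j * rng.standard_normal(low.sum())
        fieldmap = np.real(np.fft.ifft2(np.fft.ifftshift(spec))) * n
        for arr in (poly, fieldmap):
            peak = np.max(np.abs(arr))
            if peak > 0:
                arr /= peak
        phases[s] = (1 - random_fraction) * poly + random_fraction * fieldmap
    peak = np.max(np.abs(phases))
    if peak > 0:
        phases *= amplitude_rad / peak
    return ShotPhaseSet(n_shots=n_shots, phase_maps=phases)


# ----------------------------------------------------------------------------
# Trajectories
# ----------------------------------------------------------------------------


def _band(center: int, width: int) -> tuple[int, int]:
    """Inclusive index range of a width-``width`` band containing ``center``."""
    lo = center - (width - 1) // 2
    return lo, lo + width - 1


def make_trajectory(
    scheme: str,
    grid_size: int,
    n_shots: int,
    overlap_px: int = 15,
    undersample_R: int = 1,
    central_block: int | None = None,
) -> TrajectorySpec:
    """Per-shot Cartesian sampling masks for one of the four schemes.

    mosaic2
        Top / bottom k-space half-planes sharing ``overlap_px`` full-width
        rows about the DC row.
    mosaic4
        Quadrant partition; consecutive shots (0,1), (1,2), (2,3) share an
        ``overlap_px``-wide band through the central row/column.
    readout_segmented
        Full-height vertical bands tiled along kx; consecutive bands share
        exactly ``overlap_px`` columns.
    phase_interleaved
        Shot ``s`` samples every ``n_shots * undersample_R``-th ky row with
        offset ``s * undersample_R``; raw shots share no coordinates, and a
        central calibration block (used on intermediate reconstructions) is
        recorded in the spec instead.
    """
    n = grid_size
    c = n // 2
    expected = {"mosaic2": (2, 2), "mosaic4": (4, 4), "readout_segmented": (2, 8), "phase_interleaved": (2, 8)}
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    lo_s, hi_s = expected[scheme]
    if not lo_s <= n_shots <= hi_s:
        raise ConfigurationError(f"{scheme} supports {lo_s}..{hi_s} shots, got {n_shots}")
    if scheme != "phase_interleaved":
        if overlap_px < 7:
            raise ConfigurationError("overlap_px must be >= 7 (kernel-compatible minimum)")
        if overlap_px >= n // 2:
            raise ConfigurationError(f"overlap_px={overlap_px} too large for grid {n}")

    masks = np.zeros((n_shots, n, n), dtype=bool)
    if scheme == "mosaic2":
        lo, hi = _band(c, overlap_px)
        masks[0, : hi + 1, :] = True
        masks[1, lo:, :] = True
    elif scheme == "mosaic4":
        rlo, rhi = _band(c, overlap_px)  # central row band
        clo, chi = _band(c, overlap_px)  # central column band
        masks[0, : rhi + 1, : chi + 1] = True  # top-left
        masks[1, : rhi + 1, clo:] = True  # top-right
        masks[2, rlo:, clo:] = True  # bottom-right
        masks[3, rlo:, : chi + 1] = True  # bottom-left
    elif scheme == "readout_segmented":
        # band s covers columns a[s] .. a[s+1] + overlap - 1 (exact overlap)
        starts = [round(s * (n - overlap_px) / n_shots) for s in range(n_shots)]
        starts.append(n - overlap_px)
        for s in range(n_shots):
            masks[s, :, starts[s] : starts[s + 1] + overlap_px] = True
    else:  # phase_interleaved
        step = n_shots * undersample_R
        for s in range(n_shots):
            masks[s, (s * undersample_R) % step :: step, :] = True
        if central_block is None:
            central_block = min(50, n // 2)
        if central_block < 7:
            raise ConfigurationError("central_block must be >= 7")
    return TrajectorySpec(
        scheme=scheme,
        grid_size=n,
        n_shots=n_shots,
        masks=masks,
        overlap_px=overlap_px,
        undersample_R=undersample_R,
        central_block=central_block,
    )


# ----------------------------------------------------------------------------
# Acquisition
# ----------------------------------------------------------------------------


def simulate_acquisition(
    phantom: Phantom,
    coils: CoilMapSet,
    phases: ShotPhaseSet,
    trajectory: TrajectorySpec,
    noise_sigma: float = 0.0,
    eddy_shift_px: NDArray | None = None,
    seed: int = 0,
) -> AcquisitionBundle:
    """Sample each shot's modulated object on its k-space coordinates.

    Per shot ``s`` and coil ``c`` the full-grid k-space is the centered DFT of
    ``coil_c * amplitude_s * exp(i phase_s) * phantom``; the shot's eddy shift
    ``(dx, dy)`` (fractional pixels) is applied as a k-space coordinate-linear
    phase, then the trajectory mask selects the acquired samples and i.i.d.
    complex Gaussian noise of std ``noise_sigma`` per real/imag part is added.
    """
    n = phantom.grid_size
    if coils.maps.shape[-1] != n or phases.phase_maps.shape[-1] != n or trajectory.grid_size != n:
        raise DimensionError("phantom, coils, phases and trajectory grids disagree")
    if phases.n_shots != trajectory.n_shots:
        raise DimensionError("shot counts of phases and trajectory disagree")
    rng = np.random.default_rng(seed)
    n_shots, n_coils = trajectory.n_shots, coils.n_coils
    kspace = np.zeros((n_shots, n_coils, n, n), dtype=np.complex128)
    k = centered_coords(n)
    ky, kx = k[:, None], k[None, :]
    for s in range(n_shots):
        mod = phases.modulation(s) * phantom.values
        ramp = 1.0
        if eddy_shift_px is not None:
            dx, dy = eddy_shift_px[s]
            ramp = np.exp(1j * 2 * np.pi * (kx * dx + ky * dy) / n)
        for ci in range(n_coils):
            full = fft2c(coils.maps[ci] * mod) * ramp
            kspace[s, ci][trajectory.masks[s]] = full[trajectory.masks[s]]
    if noise_sigma > 0:
        for s in range(n_shots):
            noise = noise_sigma * (
                rng.standard_normal((n_coils, n, n)) + 1j * rng.standard_normal((n_coils, n, n))
            )
            kspace[s][:, trajectory.masks[s]] += noise[:, trajectory.masks[s]]
    truth = (phantom, coils, phases, eddy_shift_px)
    return AcquisitionBundle(kspace=kspace, trajectory=trajectory, noise_sigma=noise_sigma, truth=truth)


def noise_sigma_for_snr(phantom: Phantom, snr: float) -> float:
    """k-space noise std giving a target image-domain SNR.

    SNR is defined as the mean object magnitude over the support divided by
    the per-pixel complex noise std in a single-coil image reconstruction.
    With the unnormalized centered DFT, k-space noise of std ``sigma`` per
    real/imag part becomes image noise of complex std ``sigma * sqrt(2) / N``.
    """
    mu = float(np.mean(np.abs(phantom.values[phantom.support_mask])))
    return mu * phantom.grid_size / (snr * np.sqrt(2.0))
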