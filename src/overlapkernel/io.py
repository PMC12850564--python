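"""HDF5 containers for acquisitions and extracted maps; NIfTI export.

Acquisition layout: ``/kspace`` (complex, shot x coil x ky x kx), ``/mask``
(uint8, shot x ky x kx), optional ``/truth/*`` datasets, and the scheme /
overlap / seed / noise attributes needed to regenerate or interpret the
data.  Maps layout: ``/phase_maps`` (radians, shot x y x x) plus optional
``/eigenvalue_maps`` and ``/singular_values`` with extraction metadata.
"""

from __future__ import annotations

import numpy as np

from .sim import AcquisitionBundle, CoilMapSet, Phantom, ShotPhaseSet, TrajectorySpec

__all__ = [
    "save_bundle",
    "load_bundle",
    "save_maps",
    "load_maps",
    "export_nifti",
]


def save_bundle(path, bundle: AcquisitionBundle, seed: int | None = None) -> None:
    import h5py

    traj = bundle.trajectory
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=bundle.kspace)
        f.create_dataset("mask", data=traj.masks.astype(np.uint8))
        f.attrs["scheme"] = traj.scheme
        f.attrs["overlap_px"] = traj.overlap_px
        f.attrs["undersample_R"] = traj.undersample_R
        if traj.central_block is not None:
            f.attrs["central_block"] = traj.central_block
        f.attrs["noise_sigma"] = bundle.noise_sigma
        if seed is not None:
            f.attrs["seed"] = seed
        if bundle.truth is not None:
            phantom, coils, phases, eddy = bundle.truth
            g = f.create_group("truth")
            if phantom is not None:
                g.create_dataset("phantom", data=phantom.values)
                g.create_dataset("support_mask", data=phantom.support_mask.astype(np.uint8))
            if coils is not None:
                g.create_dataset("coil_maps", data=coils.maps)
            if phases is not None:
                g.create_dataset("phase_maps", data=phases.phase_maps)
                if phases.amplitude_maps is not None:
                    g.create_dataset("amplitude_maps", data=phases.amplitude_maps)
            if eddy is not None:
                g.create_dataset("eddy_shift_px", data=np.asarray(eddy, dtype=float))


def load_bundle(path) -> AcquisitionBundle:
    import h5py

    with h5py.File(path, "r") as f:
        kspace = f["kspace"][()]
        masks = f["mask"][()].astype(bool)
        traj = TrajectorySpec(
            scheme=str(f.attrs["scheme"]),
            grid_size=kspace.shape[-1],
            n_shots=kspace.shape[0],
            masks=masks,
            overlap_px=int(f.attrs["overlap_px"]),
            undersample_R=int(f.attrs.get("undersample_R", 1)),
            central_block=int(f.attrs["central_block"]) if "central_block" in f.attrs else None,
        )
        truth = None
        if "truth" in f:
            g = f["truth"]
            phantom = coils = phases = eddy = None
            if "phantom" in g:
                values = g["phantom"][()]
                phantom = Phantom(
                    grid_size=values.shape[-1],
                    values=values,
                    support_mask=g["support_mask"][()].astype(bool),
                )
            if "coil_maps" in g:
                maps = g["coil_maps"][()]
                coils = CoilMapSet(n_coils=maps.shape[0], maps=maps)
            if "phase_maps" in g:
                pm = g["phase_maps"][()]
                am = g["amplitude_maps"][()] if "amplitude_maps" in g else None
                phases = ShotPhaseSet(n_shots=pm.shape[0], phase_maps=pm, amplitude_maps=am)
            if "eddy_shift_px" in g:
                eddy = g["eddy_shift_px"][()]
            truth = (phantom, coils, phases, eddy)
        return AcquisitionBundle(
            kspace=kspace,
            trajectory=traj,
            noise_sigma=float(f.attrs.get("noise_sigma", 0.0)),
            truth=truth,
        )


def save_maps(
    path,
    phases: ShotPhaseSet,
    eigenvalue_maps=None,
    singular_values=None,
    metadata: dict | None = None,
) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("phase_maps", data=phases.phase_maps)
        if eigenvalue_maps is not None:
            f.create_dataset("eigenvalue_maps", data=np.asarray(eigenvalue_maps))
        if singular_values is not None:
            f.create_dataset("singular_values", data=np.asarray(singular_values))
        for key, val in (metadata or {}).items():
            f.attrs[key] = val


def load_maps(path) -> tuple[ShotPhaseSet, dict]:
    import h5py

    with h5py.File(path, "r") as f:
        pm = f["phase_maps"][()]
        extras: dict = {k: f.attrs[k] for k in f.attrs}
        for name in ("eigenvalue_maps", "singular_values"):
            if name in f:
                extras[name] = f[name][()]
    return ShotPhaseSet(n_shots=pm.shape[0], phase_maps=pm), extras


def export_nifti(path, image) -> None:
    """Write a 2D real image (e.g., magnitude, phase, CV) as NIfTI."""
    import nibabel as nib

    data = np.asarray(image, dtype=np.float64)
    nib.save(nib.Nifti1Image(data[..., None], affine=np.eye(4)), str(path))
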