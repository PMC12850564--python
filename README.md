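# overlapkernel

Self-navigated shot-to-shot phase estimation for multi-shot EPI from small
k-space overlap bands.

Multi-shot EPI splits k-space over several excitations to reach higher
resolution and shorter echo spacing, but motion during strong encoding
gradients (diffusion imaging above all) stamps each shot with a smooth,
unknown image-space phase.  Left uncorrected, the inconsistent segments
ghost the combined image; the classical remedy is an extra navigator
acquisition per shot.  When neighboring segments instead *overlap* by a
small k-space band (~15 lines along the shorter axis), the inter-shot phase
can be calibrated directly from the acquired data.  This package implements
that calibration for researchers developing multi-shot reconstruction
pipelines, together with everything needed to validate it end to end on
synthetic acquisitions.

## Method

With `F` the centered 2D DFT, object `m`, coil maps `c_c`, and per-shot
phase maps `φ_s` (modulations `p_s = e^{iφ_s}`, reference shot `φ_0 = 0`),
the acquired data are `f_{s,c} = Sample_s F [c_c p_s m]`.  Multiplying by
`p_t / p_s` in image space is convolution by a small `w x w` kernel `u` in
k-space, so on an overlap band the shots obey `f_t(k̇) = Σ u(δ) f_s(k̇+δ)`.
Sliding a `w x w` window over the band (all coils, stride 1) builds a
calibration matrix `A`, and the kernels are estimated two ways:

* **GRAPPA-type** — solve `A u = target` in least squares (tSVD / Tikhonov
  / LSQR); the zero-filled kernel transforms to the relative map
  `p_t / p_s`.
* **ESPIRiT-type (eigenvalue approach)** — SVD `A = U Σ V^H`, keep ~half
  the right-singular subspace `V∥`, reshape to k-space filters, transform
  to image space, and at each pixel take the top eigenvector of the small
  operator `G_q = M_q^H M_q`: its components are the per-shot modulations
  at that pixel, and its top eigenvalue — normalized to lie in `[0, 1]` —
  equals 1 where the subspace model explains the data.

Extracted maps feed two shot-combination reconstructions: conjugate-phase
mosaic combination with apodization and an inverse-MTF filter, and a
CG-SENSE forward model with phase-fluctuation encoding (also used, per
shot, to build the shot-dependent calibration data for phase-interleaved
trajectories — "MUSE with kernel extraction").  See `docs/methods.md` for
the full account.

## Worked example

```bash
overlapkernel demo --seed 1
```

simulates a two-shot mosaic acquisition (64x64 grid, 4 coils, 15-row
overlap band about DC, polynomial shot phases of 1.5 rad peak), runs the
eigenvalue extraction (7x7 kernel, half subspace), and reconstructs with
the estimated maps:

```
median top eigenvalue on support : 1.0000
max top eigenvalue (all pixels)  : 0.99999594
phase RMSE vs truth [rad]        : 0.0072
image NRMSE corrected            : 0.0084
image NRMSE uncorrected          : 0.2004
```

The median eigenvalue of 1 on the object says the calibrated subspace model
explains the overlap data; the extracted phase maps match the simulated
truth to 0.007 rad (magnitude-weighted, one global phase removed); and
phase correction reduces the image error by more than an order of magnitude relative
to combining the shots uncorrected.

The same stages are available step by step:

```python
import overlapkernel as ok

bundle, phantom, coils, phases = ok.simulate_study(seed=1)   # ground truth known
result = ok.eigen_pair_result(bundle, (0, 1))                # eigenvalue approach
rel_phase = result.relative_phase(1)                         # shot 1 vs shot 0, rad
maps = ok.extract_phase_maps(bundle, method="grappa")        # or the GRAPPA route
segments = ok.coil_combine_segments(bundle, coils)
image = ok.combine_mosaic(segments, maps, bundle.trajectory)
```

and through the CLI subcommands `simulate`, `extract`, `recon`, `diagnose`
(HDF5 acquisition containers, NIfTI image export, YAML configs).

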