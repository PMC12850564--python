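# Methods

## Signal model

Multi-shot EPI acquires k-space in several excitations ("shots").  Between
shots, physiological motion during strong encoding gradients (most severely
in diffusion imaging) adds a smooth, shot-specific phase to the image.  For
shot `s` with per-pixel complex modulation `p_s(x)` (unit magnitude by
default), coil `c` with sensitivity `c_c(x)`, and object `m(x)`, the sampled
data are

    f_{s,c} = Sample_s · F · [ c_c · p_s · m ],

with `F` the centered 2D DFT (DC at index `N//2` on each axis, shared by all
modules).  Uncorrected, the shot-wise phases make the segments inconsistent
and ghost the combined image.

Pointwise multiplication by `p_t / p_s` in image space is convolution by a
small kernel in k-space.  Where two shots sample a common k-space band, the
target shot's samples are therefore a shift-invariant `w x w` interpolation
of the source shot's samples, and that kernel — hence the relative phase
map — can be calibrated directly from the overlap band, with no navigator
acquisition.  Because the phase maps are smooth, the kernels span only a few
pixels; `w = 7` is the default kernel width.

## Calibration matrix

For a shot pair, the overlap region is the maximal axis-aligned rectangle
jointly sampled by both shots (ties broken toward DC; found by a
histogram-stack maximal-rectangle sweep, so arbitrary mask shapes work).  A
`w x w` window slides over the region with stride 1; each window position in
each coil contributes one row.  Coils contribute rows only: the inter-shot
kernels are shift-invariant across receive channels (unlike parallel-imaging
kernels, which are receiver-specific).  Two layouts are built:

* **oneway** — the row holds the source shot's patch (row-major); a target
  vector holds the other shot's sample at the window center.
* **symmetric** — the row concatenates both shots' patches, shot-major.

Row count is `n_coils * (H-w+1) * (W-w+1)` for an `H x W` region; column
count is `w^2` (oneway) or `n_shots_in_row * w^2` (symmetric).

## GRAPPA-type route

The one-way system `A u = target` is solved in least squares; solvers are
truncated SVD (default, relative cut 0.05), Tikhonov-regularized normal
equations (`pinv`, damping 1e-3 of the top singular value), and LSQR
(relative tolerance 1e-8, at most 500 iterations).  The kernel, zero-filled
at DC of the full grid and transformed with the centered forward DFT (which
acts as a correlation in source-patch offset order), yields the relative
complex map `p_target / p_source`; only its angle is used downstream.  The
transform normalization makes a pure center-delta kernel (identical shots)
map to the all-ones image.  A note on indexing: when the target shot equals
the source shifted by `+k0` along x, the solved kernel is a delta at source
patch offset `-k0`; the forward transform then produces the correct
`exp(+i 2π k0 x / N)` plane wave.

## Eigenvalue route

The symmetric matrix is decomposed as `A = U Σ V^H`, and the leading
right-singular vectors are kept — by default half the columns ("around half
subspace truncation"), or alternatively all vectors above a relative
singular-value cut.  Each kept vector is reshaped shot-major into `w x w`
patches, zero-filled and carried to image space, giving per pixel `q` a
small matrix `M_q` (kept x shots) whose Gram `G_q = M_q^H M_q` is, exactly,
the per-pixel block of the image-space operator `F^{-1} W F`, where `W`
rearranges k-space neighborhoods, projects them onto the kept subspace, and
redistributes them (window-count normalized).  Two numerical choices matter
here and are pinned by a dense-operator oracle test on a 16x16 grid:

* **Conjugation.**  With `A = U Σ V^H` the columns of `V` span the
  *conjugated* rows of `A`; projecting raw data patches with `V∥ V∥^H`
  would leave the conjugate mirror image invariant and return mirrored,
  negated phase maps.  The per-pixel operators therefore use conjugated
  patches — equivalently, the kept vectors transform with the *forward*
  centered DFT.  Parameter recovery on simulations with known phase maps
  admits only this choice.
* **Normalization.**  The window-count operator and all DFT scalings
  collapse into the single constant `1/w` on the forward-DFT patches,
  calibrated analytically so that noiseless identical-shot data reach a top
  eigenvalue of exactly 1.  With orthonormal kept vectors and circular
  window sliding the operator is an average of projections, so all
  per-pixel eigenvalues lie in `[0, 1]` — for any input, noisy or not.

Per pixel, the top eigenvector of `G_q` (computed from the small
`shots x shots` eigenproblem) is the vector of relative shot modulations;
it is unit-normalized and gauged so the reference-shot component is real
and nonnegative.  Degenerate (all-zero) pixels return eigenvalue 0 and the
canonical basis vector.  Pixels whose top eigenvalue falls below a
confidence threshold (default 0.7, essentially the non-object background)
are flagged and inpainted from their nearest confident neighbor before any
phase composition, so downstream reconstruction never sees undefined phase.

### Multi-shot chains and phase-interleaved data

Trajectories with more than two shots are processed over the chain of
consecutive overlapping pairs; relative phases compose multiplicatively
(complex exponentials, never unwrapped) from the reference shot.  Redundant
pair graphs (cycles) do not occur in the supported trajectories; a
least-squares cycle closure would be the natural extension.

Phase-interleaved shots share no raw coordinates.  Each shot is first
reconstructed alone by CG-SENSE with zero phase, returned to k-space, and
cropped to a central calibration block (default `min(50, N/2)`); the blocks
from all shots jointly feed the same eigen machinery (single-channel rows,
all shots' patches per row).  This replaces image-space total-variation
phase smoothing in MUSE-style processing.  When the per-shot undersampling
factor exceeds twice the coil count the intermediate reconstructions are
unreliable; the routine warns and degraded maps must be expected.

## Shot combination

* **Conjugate-phase mosaic combination** — each fully sampled segment is
  brought to image space, multiplied by the conjugate of its estimated
  phase map, returned to k-space, re-windowed onto its support, and summed;
  the summed window weights are divided out (inverse MTF filter, floored at
  5% of the weight maximum), so overlap bands are not double-counted.
  Segment windows are cosine-tapered by default (ramp 4 px, about half the
  kernel width): hard edges truncate the phase-kernel convolution tails and
  leave ~1% residual error at the standard study conditions, while the
  taper — which the inverse filter removes again wherever segments
  overlap — reduces this to ~0.7%.  With zero phases the combination
  reproduces the direct full-grid reconstruction exactly for any window
  choice whose overlaps cover the tapers.
* **CG-SENSE forward model** — sampling ∘ DFT ∘ coil ∘ shot-phase as one
  linear operator; the normal equations are solved by conjugate gradients
  from zero (relative residual 1e-8, at most 200 iterations, warning on
  non-convergence).  The adjoint is exact (verified by inner-product test
  to 1e-10), which is what makes the solver trustworthy.

## Synthetic data

The simulator generates: a deterministic piecewise-constant complex phantom
(nested ellipses or blocks, magnitude in [0,1]); smooth complex coil maps
(broad Gaussians times low-order complex polynomials, RSS-normalized to 1);
per-shot phase maps (random 2D polynomial up to order 4 plus a band-limited
random field, jointly scaled to a prescribed peak amplitude, shot 0
identically zero); four trajectory families (two-shot mosaic about the DC
row, four-shot quadrant mosaic, readout-segmented vertical bands with exact
column overlap, phase-interleaved rows with a recorded central calibration
block); optional per-shot fractional k-space shifts as an eddy-current
surrogate; and i.i.d. complex Gaussian noise per coil (pre-whitened
assumption).  Amplitude (magnitude) fluctuation between shots is supported
through per-shot amplitude maps but off by default.

Default study conditions: 64x64 grid, 4 coils, 2 shots, 15-pixel overlap,
polynomial order 2, peak amplitude 1.5 rad, noiseless; the noisy variant
sets the k-space noise std from a target image SNR of 20 (mean support
magnitude over per-pixel complex image noise std).  These sizes keep every
stage — including the dense-operator oracle and the 10-realization noise
sweep — within seconds on one CPU while exercising the full machinery.

What the simulator does **not** model: T2/T2* decay along the echo train,
B0 off-resonance distortion, partial-Fourier sampling, intra-shot gradient
errors, readout oversampling, and gradient-polarity effects (polarity
alternation appears only as the *absence* of polarity-dependent
inconsistency).  Passing tests therefore demonstrate correctness of the
calibration and reconstruction machinery under the stated model, not
robustness to those real-world effects.

A note on realism of the default phase maps: a polynomial phase is not
periodic over the FOV, so its modulation spectrum carries slow tails beyond
any finite kernel width.  At 1.5 rad peak amplitude the 7x7 kernel fit
leaves a ~1.5% k-space residual — yet phase recovery stays below ~0.01 rad
(weighted RMSE) for both routes, which is precisely the robustness the
kernel-averaging formulation is designed to provide.  Exactly band-limited
modulations (constructed through the amplitude-map channel) drive the fit
residual to numerical zero and are used to verify solver quality in
isolation.

## Numerical choices and degenerate inputs

* One centered-DFT convention everywhere; DC at `N//2`.
* Wrapped-phase arithmetic throughout (angles of complex products); no
  unwrapping anywhere.
* Global phase of relative maps is a gauge; comparisons remove one weighted
  circular mean per shot (`phase_rmse`), and maps can be put in a canonical
  gauge (weighted mean real-positive).
* Coil combination guards against zero sensitivity (`eps`-guarded division);
  CV maps return 0 at pixels with zero temporal mean; `cv_map` computes
  deviations against the first repetition so identical repetitions give an
  exactly zero map.
* Sliding-window stride is 1 (maximal kernel averaging).
* Eigen decomposition uses the small Gram `M_q^H M_q` per pixel (memory-
  saving variant) rather than an SVD of the tall per-pixel operator.

## Known limitations

* Only chain-connected pair graphs are aligned; no cycle closure.
* Non-rectangular calibration regions are reduced to their largest inscribed
  rectangle.
* The mosaic combination assumes segments fully sampled on their own
  supports (after coil combination); per-segment parallel-imaging recovery
  of undersampled segments is out of scope.
* Map magnitudes are retained but not used; no multi-set ("soft") forward
  model and no null-space residual images are produced, since small overlap
  bands carry no encoding redundancy for them.
* Very low-SNR overlap bands (strong diffusion weighting at peripheral
  k-space) degrade both extraction routes; the singular-value profile of
  the calibration matrix is the practical diagnostic — a flatter profile
  predicts poorer extraction.
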