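"""Eigenvalue-approach machinery: SVD thresholding, per-pixel operators,
pixelwise eigen decomposition, chain alignment, MUSE-with-kernel."""

import numpy as np
import pytest

import overlapkernel as ok
from overlapkernel.calibration import build_calibration_matrix, find_overlap
from overlapkernel.eigen_extract import (
    build_pixel_operators,
    calib_svd,
    eigen_phase_maps,
    inpaint_low_confidence,
)


def symmetric_calib(bundle, window_w=7):
    region = find_overlap(bundle.trajectory, 0, 1, n_coils=bundle.n_coils, min_extent=window_w)
    return build_calibration_matrix(bundle, region, window_w, layout="symmetric")


def dense_pixel_operator_oracle(basis, window_w, grid_size, n_shots):
    """Explicit dense assembly of the image-space subspace operator.

    Builds W = (1/w^2) sum_t R_t^H P R_t with t sliding circularly over the
    whole periodic grid (where the window-count normalization is exactly
    w^2) and P the projector onto the span of the calibration rows, then
    conjugates W with the dense centered unitary DFT and extracts the
    per-pixel shot blocks.  Feasible only on tiny grids; pins the fast
    zero-fill + DFT construction end to end.
    """
    w, n, S = window_w, grid_size, n_shots
    n2 = n * n
    V = np.conj(basis.V_par)  # projector onto the span of the actual rows
    P = V @ V.conj().T
    W = np.zeros((S * n2, S * n2), dtype=complex)
    idx_template = np.array(
        [
            s * n2 + dy * n + dx
            for s in range(S)
            for dy in range(w)
            for dx in range(w)
        ]
    )
    for ty in range(n):
        for tx in range(n):
            idx = np.array(
                [
                    s * n2 + ((ty + dy) % n) * n + ((tx + dx) % n)
                    for s in range(S)
                    for dy in range(w)
                    for dx in range(w)
                ]
            )
            W[np.ix_(idx, idx)] += P
    W /= w * w
    k = np.arange(n) - n // 2
    f1 = np.exp(-2j * np.pi * np.outer(k, k) / n) / np.sqrt(n)
    f2 = np.kron(f1, f1)
    fbig = np.kron(np.eye(S), f2)
    G = fbig.conj().T @ W @ fbig
    Gd = G.reshape(S, n2, S, n2)
    out = np.zeros((n, n, S, S), dtype=complex)
    for s in range(S):
        for t in range(S):
            out[:, :, s, t] = np.diag(Gd[s, :, t, :]).reshape(n, n)
    return out


class TestCalibSVD:
    def test_identical_shots_rank_and_profile(self, identical_shot_bundle):
        bundle, _ = identical_shot_bundle
        basis = calib_svd(symmetric_calib(bundle), keep=0.5)
        s = basis.singular_values
        assert s[49] / s[0] < 1e-10
        assert basis.kept_count == 49
        assert np.all(np.diff(s) <= 1e-12)

    def test_sigma_cut_mode(self, study64):
        bundle, *_ = study64
        calib = symmetric_calib(bundle)
        basis = calib_svd(calib, keep=0.05, keep_mode="sigma")
        s = basis.singular_values
        assert basis.kept_count == np.count_nonzero(s >= 0.05 * s[0])

    def test_structured_matrix_has_smaller_tail_than_noise(self):
        """Signal-bearing calibration data are more low-rank than pure noise."""
        bundle, *_ = ok.simulate_study(seed=6)
        calib = symmetric_calib(bundle)
        rng = np.random.default_rng(0)
        noise_bundle = ok.AcquisitionBundle(
            kspace=(
                rng.standard_normal(bundle.kspace.shape)
                + 1j * rng.standard_normal(bundle.kspace.shape)
            )
            * bundle.trajectory.masks[:, None],
            trajectory=bundle.trajectory,
        )
        calib_noise = symmetric_calib(noise_bundle)
        tail = lambda c: (lambda s: np.sum(s[49:] / s[0]))(
            np.linalg.svd(c.matrix, compute_uv=False)
        )
        assert tail(calib) < tail(calib_noise)

    def test_wrong_layout_rejected(self, study64):
        bundle, *_ = study64
        region = find_overlap(bundle.trajectory, 0, 1, n_coils=4)
        oneway = build_calibration_matrix(bundle, region, 7, layout="oneway")
        with pytest.raises(ok.CalibrationError):
            calib_svd(oneway)


class TestBuildPixelOperators:
    def test_single_delta_vector_gives_constant_single_shot_row(self):
        vec = np.zeros((2 * 49, 1), dtype=complex)
        vec[24] = 1.0  # center of shot-0 patch, zero in shot 1
        basis = ok.SubspaceBasis(
            singular_values=np.ones(1), kept_count=1, V_par=vec, window=7, n_groups=2
        )
        stack = build_pixel_operators(basis, 7, 32, 2)
        np.testing.assert_allclose(np.abs(stack.m[0, 0]), 1.0 / 7, atol=1e-12)
        np.testing.assert_allclose(stack.m[0, 1], 0.0, atol=1e-15)

    def test_identical_shots_top_vector_is_symmetric(self, identical_shot_bundle):
        bundle, phantom = identical_shot_bundle
        basis = calib_svd(symmetric_calib(bundle), keep=0.5)
        stack = build_pixel_operators(basis, 7, 64, 2)
        result = eigen_phase_maps(stack)
        target = np.array([1.0, 1.0]) / np.sqrt(2)
        inner = np.abs(result.shot_vector_map @ target)
        support = np.abs(phantom.values) > 0.1 * np.abs(phantom.values).max()
        assert inner[support].min() > 0.999

    def test_matches_dense_operator_oracle(self):
        """Zero-fill + DFT pixel operators equal the dense F^-1 W F blocks."""
        bundle, *_ = ok.simulate_study(
            grid_size=16, n_coils=2, overlap_px=7, amplitude_rad=1.0, seed=3
        )
        region = find_overlap(bundle.trajectory, 0, 1, n_coils=2, min_extent=3)
        calib = build_calibration_matrix(bundle, region, 3, layout="symmetric")
        basis = calib_svd(calib, keep=0.5)
        stack = build_pixel_operators(basis, 3, 16, 2)
        oracle = dense_pixel_operator_oracle(basis, 3, 16, 2)
        assert np.abs(stack.gram() - oracle).max() < 1e-10

    def test_ordering_mismatch_rejected(self):
        basis = ok.SubspaceBasis(
            singular_values=np.ones(1),
            kept_count=1,
            V_par=np.zeros((50, 1), dtype=complex),
            window=7,
            n_groups=2,
        )
        with pytest.raises(ok.ConfigurationError):
            build_pixel_operators(basis, 7, 32, 2)


class TestEigenPhaseMaps:
    def test_identical_shots_eigenvalue_one_phase_zero(self, identical_shot_bundle):
        bundle, phantom = identical_shot_bundle
        basis = calib_svd(symmetric_calib(bundle), keep=0.5)
        result = eigen_phase_maps(build_pixel_operators(basis, 7, 64, 2))
        support = np.abs(phantom.values) > 0.1 * np.abs(phantom.values).max()
        assert np.abs(result.eigenvalue_map[support] - 1.0).max() < 0.02
        assert np.abs(result.relative_phase(1)[support]).max() < 1e-3

    def test_eigenvalue_bounded_by_one(self, study64_eigen):
        assert study64_eigen.eigenvalue_map.max() <= 1.0 + 1e-6

    @pytest.mark.parametrize("seed", [1, 2, 4])
    def test_phase_recovery(self, seed):
        bundle, phantom, _, phases = ok.simulate_study(seed=seed)
        res = ok.eigen_pair_result(bundle, (0, 1))
        rel = res.relative_phase(1)
        w = np.abs(phantom.values)
        est = ok.ShotPhaseSet(2, np.stack([np.zeros_like(rel), rel]))
        assert ok.phase_rmse(est, phases, w)[1] < 0.05

    def test_gauge_invariance_under_global_shot_phase(self, study64):
        """Multiplying one shot's k-space by e^{i theta} shifts that shot's
        recovered phase by theta uniformly."""
        bundle, phantom, *_ = study64
        theta = 0.83
        shifted = bundle.kspace.copy()
        shifted[1] *= np.exp(1j * theta)
        bundle_s = ok.AcquisitionBundle(kspace=shifted, trajectory=bundle.trajectory)
        res_a = ok.eigen_pair_result(bundle, (0, 1))
        res_b = ok.eigen_pair_result(bundle_s, (0, 1))
        support = np.abs(phantom.values) > 0.1 * np.abs(phantom.values).max()
        diff = np.angle(
            np.exp(1j * (res_b.relative_phase(1) - res_a.relative_phase(1) - theta))
        )
        assert np.abs(diff[support]).max() < 1e-6

    def test_agreement_with_grappa_route(self, study64, study64_eigen):
        bundle, phantom, _, phases = study64
        rel_e = study64_eigen.relative_phase(1)
        rel_g = np.angle(ok.grappa_pair_map(bundle, (0, 1)).values)
        w = np.abs(phantom.values)
        a = ok.ShotPhaseSet(2, np.stack([np.zeros_like(rel_e), rel_e]))
        b = ok.ShotPhaseSet(2, np.stack([np.zeros_like(rel_g), rel_g]))
        assert ok.phase_rmse(a, b, w)[1] < 0.05

    def test_degenerate_pixels_return_canonical_vector(self):
        stack = ok.PixelOperatorStack(m=np.zeros((1, 2, 8, 8), dtype=complex), window=3, n_groups=2)
        res = eigen_phase_maps(stack)
        assert np.all(res.eigenvalue_map == 0.0)
        np.testing.assert_array_equal(res.shot_vector_map[..., 0], 1.0)


class TestAlignShots:
    def test_two_pair_composition(self):
        rng = np.random.default_rng(0)
        phi1 = rng.uniform(-2, 2, (16, 16))
        phi2 = rng.uniform(-2, 2, (16, 16))
        maps = [
            ok.RelativeMap(np.exp(1j * phi1), (0, 1)),
            ok.RelativeMap(np.exp(1j * phi2), (1, 2)),
        ]
        out = ok.align_shots(maps, reference_shot=0)
        np.testing.assert_array_equal(out.phase_maps[0], 0.0)
        np.testing.assert_allclose(
            np.angle(np.exp(1j * (out.phase_maps[2] - phi1 - phi2))), 0.0, atol=1e-12
        )

    def test_single_pair_and_reverse_edge(self):
        phi = np.full((8, 8), 0.4)
        out = ok.align_shots([ok.RelativeMap(np.exp(1j * phi), (1, 0))], reference_shot=0)
        np.testing.assert_allclose(out.phase_maps[1], -0.4, atol=1e-12)

    def test_disconnected_chain_raises(self):
        phi = np.zeros((8, 8))
        with pytest.raises(ok.AlignmentError):
            ok.align_shots([ok.RelativeMap(np.exp(1j * phi), (2, 3))], reference_shot=0)

    def test_three_shot_chained_recovery(self):
        bundle, phantom, _, phases = ok.simulate_study(
            scheme="readout_segmented", n_shots=3, seed=5
        )
        est = ok.extract_phase_maps(bundle, method="espirit")
        w = np.abs(phantom.values)
        rmse = ok.phase_rmse(est, phases, w)
        assert np.all(rmse < 0.07)


class TestInpaint:
    def test_low_confidence_pixels_copied_from_neighbors(self, study64_eigen):
        vec, low = inpaint_low_confidence(study64_eigen, threshold=0.7)
        assert low.any() and not low.all()  # background is low-confidence
        assert np.all(np.linalg.norm(vec, axis=-1) > 0.99)


class TestMuseKernelExtract:
    def test_two_shot_interleave_recovery(self):
        bundle, phantom, coils, phases = ok.simulate_study(
            scheme="phase_interleaved", n_shots=2, amplitude_rad=1.0, seed=7
        )
        est = ok.muse_kernel_extract(bundle, coils, central_block=32)
        w = np.abs(phantom.values)
        assert ok.phase_rmse(est, phases, w)[1] < 0.05

    def test_zero_fluctuation_gives_zero_maps(self):
        bundle, phantom, coils, _ = ok.simulate_study(
            scheme="phase_interleaved", n_shots=2, amplitude_rad=0.0, seed=8
        )
        est = ok.muse_kernel_extract(bundle, coils, central_block=32)
        support = np.abs(phantom.values) > 0.1 * np.abs(phantom.values).max()
        assert np.abs(est.phase_maps[1][support]).max() < 1e-3

    def test_excessive_undersampling_warns(self):
        bundle, phantom, coils, phases = ok.simulate_study(
            scheme="phase_interleaved", n_shots=4, n_coils=2, undersample_R=2,
            amplitude_rad=1.0, seed=9,
        )
        with pytest.warns(RuntimeWarning):
            ok.muse_kernel_extract(bundle, coils, central_block=32, cg_maxiter=30)

    def test_block_smaller_than_window_rejected(self):
        bundle, _, coils, _ = ok.simulate_study(
            scheme="phase_interleaved", n_shots=2, seed=7
        )
        with pytest.raises(ok.ConfigurationError):
            ok.muse_kernel_extract(bundle, coils, central_block=5)
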