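"""Reconstruction core: training interpolation, PCA temporal subspace,
sensitivity estimation, the CG spatial-subspace solve, and composition."""

import numpy as np
import pytest

from conftest import build_dense_kt, plug_truth
from pcflow.fourier import fft2c, ifft2c
from pcflow.kt_data import (ImageSeries, KTSamples, SpatialSubspace,
                            TemporalSubspace, ValidationError)
from pcflow.phantom_sim import make_sensitivities
from pcflow.subspace_recon import (ReconConfig, TrainingMatrix, compose,
                                   default_frame_times,
                                   estimate_sensitivities,
                                   estimate_temporal_subspace,
                                   interpolate_training, joint_casorati,
                                   reconstruct, solve_spatial_subspace)


def exact_temporal_subspace(truth, L, mode="joint") -> TemporalSubspace:
    """Ground-truth temporal basis from an SVD of the true Casorati matrix."""
    if mode == "joint":
        _, _, Vh = np.linalg.svd(joint_casorati(truth), full_matrices=True)
        basis = Vh[:L]
    else:
        basis = np.stack([np.linalg.svd(s.data, full_matrices=True)[2][:L]
                          for s in truth])
    return TemporalSubspace(basis, mode, truth[0].frame_times, len(truth))


# ---------------------------------------------------------------------------
# Training interpolation
# ---------------------------------------------------------------------------


class TestInterpolateTraining:
    @pytest.fixture()
    def kt(self, geom32, sens32):
        truth = plug_truth(geom32, [0.0, 20.0, 40.0, 60.0])
        return build_dense_kt(truth, sens32, lines_per_frame=3, TR_ms=5.0,
                              seed=0)

    def test_values_unchanged_at_acquisition_times(self, kt):
        train = kt.training()
        t0 = train.t_ms[train.v == 1][0]
        tm = interpolate_training(kt, np.array([t0, t0 + 1.0]))
        # channel rows for coil 0 are the first nx of the block
        line = train.data[(train.v == 1) & (train.coil == 0)][0]
        np.testing.assert_allclose(tm.data[:32, 0, 0], line, atol=1e-12)

    def test_constant_channel_stays_constant(self, geom32, sens32):
        truth = plug_truth(geom32, [30.0, 30.0, 30.0])
        kt = build_dense_kt(truth, sens32, 2, 5.0, seed=1)
        tm = interpolate_training(kt, np.array([1.0, 7.0, 23.0, 40.0]))
        spread = np.ptp(tm.data, axis=2)
        assert np.abs(spread).max() < 1e-12

    def test_linear_channel_exact_at_midpoint(self, grid32):
        """A channel a + b*t sampled at t in {0, 10} interpolates to a + 5b."""
        nx = grid32.nx
        a = 1.5 + 0.5j
        b = -0.25 + 1.0j
        lines = np.array([[a + b * t] * nx for t in (0.0, 10.0)])
        kt = KTSamples(v=np.array([1, 1]), coil=np.array([0, 0]),
                       ky=np.array([16, 16]), t_ms=np.array([0.0, 10.0]),
                       role=np.array(["training", "training"]), data=lines,
                       Nv=1, Nc=1, TR_ms=5.0, VENC=100.0, grid=grid32)
        tm = interpolate_training(kt, np.array([5.0]))
        np.testing.assert_allclose(tm.data[:, 0, 0], a + 5.0 * b, atol=1e-12)

    def test_single_sample_channel_named_in_error(self, grid32):
        nx = grid32.nx
        kt = KTSamples(v=np.array([1]), coil=np.array([0]),
                       ky=np.array([16]), t_ms=np.array([0.0]),
                       role=np.array(["training"]),
                       data=np.zeros((1, nx), dtype=complex),
                       Nv=1, Nc=1, TR_ms=5.0, VENC=100.0, grid=grid32)
        with pytest.raises(ValidationError, match=r"ky=16"):
            interpolate_training(kt, np.array([0.0]))


# ---------------------------------------------------------------------------
# Temporal subspace (PCA)
# ---------------------------------------------------------------------------


class TestTemporalSubspace:
    def _training(self, X, Nv=1):
        n_ch, T = X.shape
        M = T // Nv
        return TrainingMatrix(X.reshape(n_ch, Nv, M),
                              (np.arange(M) + 0.5) * 20.0, Nv)

    def test_exact_rank_two_perfect_projection(self):
        rng = np.random.default_rng(0)
        X = (rng.standard_normal((40, 2)) + 1j * rng.standard_normal((40, 2))) \
            @ (rng.standard_normal((2, 12)) + 1j * rng.standard_normal((2, 12)))
        V = estimate_temporal_subspace(self._training(X), L=2)
        resid = np.linalg.norm(X - X @ V.basis.conj().T @ V.basis)
        assert resid / np.linalg.norm(X) < 1e-10

    def test_full_subspace_is_identity_projection(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 6)) + 1j * rng.standard_normal((30, 6))
        V = estimate_temporal_subspace(self._training(X), L=6)
        np.testing.assert_allclose(V.basis @ V.basis.conj().T, np.eye(6),
                                   atol=1e-10)
        resid = np.linalg.norm(X - X @ V.basis.conj().T @ V.basis)
        assert resid / np.linalg.norm(X) < 1e-10

    def test_eckart_young_residual_fraction(self):
        """Singular values (3, 2, 1): keeping L=2 leaves Frobenius fraction
        1/sqrt(14) (best rank-2 approximation error)."""
        rng = np.random.default_rng(2)
        U = np.linalg.qr(rng.standard_normal((20, 3)))[0]
        Vt = np.linalg.qr(rng.standard_normal((10, 3)))[0].T
        X = U @ np.diag([3.0, 2.0, 1.0]) @ Vt
        V = estimate_temporal_subspace(self._training(X), L=2)
        frac = np.linalg.norm(X - X @ V.basis.conj().T @ V.basis) \
            / np.linalg.norm(X)
        assert frac == pytest.approx(1.0 / np.sqrt(14.0), abs=1e-8)

    def test_projection_residual_nonincreasing_in_L(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 10)) + 1j * rng.standard_normal((25, 10))
        tm = self._training(X)
        resids = []
        for L in range(1, 11):
            V = estimate_temporal_subspace(tm, L)
            resids.append(np.linalg.norm(X - X @ V.basis.conj().T @ V.basis))
        assert np.all(np.diff(resids) <= 1e-9)

    def test_rank_deficient_request_warns(self):
        X = np.outer(np.ones(8), np.arange(1.0, 5.0))  # rank 1
        with pytest.warns(UserWarning, match="rank"):
            V = estimate_temporal_subspace(self._training(X), L=3)
        V.validate()  # trailing rows still orthonormal

    def test_joint_mode_concatenates_encodings(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((16, 8)) + 1j * rng.standard_normal((16, 8))
        Vj = estimate_temporal_subspace(self._training(X, Nv=2), L=2, mode="joint")
        assert Vj.basis.shape == (2, 8)
        assert Vj.n_frames == 4
        Vs = estimate_temporal_subspace(self._training(X, Nv=2), L=2,
                                        mode="separate")
        assert Vs.basis.shape == (2, 2, 4)


# ---------------------------------------------------------------------------
# Sensitivity estimation
# ---------------------------------------------------------------------------


class TestSensitivityEstimation:
    def test_single_coil_unit_magnitude_on_support(self, geom32):
        truth = plug_truth(geom32, [0.0, 0.0])
        sens = make_sensitivities(1, geom32.grid, seed=5)
        kt = build_dense_kt(truth, sens, lines_per_frame=32, TR_ms=5.0, seed=0)
        est = estimate_sensitivities(kt)
        np.testing.assert_allclose(np.abs(est.maps[0][est.support]), 1.0,
                                   atol=1e-9)

    def test_full_sampling_recovers_relative_coil_phases(self, geom32):
        """On a static phantom with full coverage, estimated maps match the
        truth up to a per-voxel phase shared across coils."""
        truth = plug_truth(geom32, [0.0, 0.0])
        sens = make_sensitivities(4, geom32.grid, seed=6)
        kt = build_dense_kt(truth, sens, lines_per_frame=32, TR_ms=5.0, seed=0)
        est = estimate_sensitivities(kt)
        for i in range(4):
            for j in range(i + 1, 4):
                got = (est.maps[i] * np.conj(est.maps[j]))[est.support]
                want = (sens.maps[i] * np.conj(sens.maps[j]))[est.support]
                np.testing.assert_allclose(got, want, atol=1e-6)

    def test_pulsatile_average_still_rss_normalised(self, geom32, sens32):
        truth = plug_truth(geom32, [0.0, 30.0, 60.0, 30.0])
        kt = build_dense_kt(truth, sens32, lines_per_frame=8, TR_ms=5.0,
                            seed=2, noise_sd=0.01)
        est = estimate_sensitivities(kt)
        rss = np.sqrt(np.sum(np.abs(est.maps) ** 2, axis=0))
        np.testing.assert_allclose(rss[est.support], 1.0, atol=1e-9)

    def test_no_flow_compensated_lines_rejected(self, geom32, sens32):
        truth = plug_truth(geom32, [0.0, 10.0])
        kt = build_dense_kt(truth, sens32, 4, 5.0, seed=3)
        kt2 = kt._subset(kt.v == 2)
        with pytest.raises(ValidationError, match="v=1"):
            estimate_sensitivities(kt2)


# ---------------------------------------------------------------------------
# Spatial-subspace solve and composition
# ---------------------------------------------------------------------------


class TestSolveSpatialSubspace:
    def test_zero_data_gives_zero_solution(self, geom32, sens32):
        truth = plug_truth(geom32, [0.0, 20.0, 40.0])
        kt = build_dense_kt(truth, sens32, 6, 5.0, seed=4)
        kt.data[:] = 0.0
        V = exact_temporal_subspace(truth, L=2)
        U = solve_spatial_subspace(kt, sens32, V, ReconConfig(L=2))
        assert np.abs(U.basis).max() == 0.0

    def test_fully_sampled_exact_subspace_recovers_truth(self, geom32, sens32):
        truth = plug_truth(geom32, [0.0, 25.0, 50.0, 75.0])
        kt = build_dense_kt(truth, sens32, lines_per_frame=32, TR_ms=5.0,
                            seed=5)
        V = exact_temporal_subspace(truth, L=2)
        cfg = ReconConfig(L=2, cg_tol=1e-12, cg_maxiter=200)
        U = solve_spatial_subspace(kt, sens32, V, cfg)
        C_hat = U.basis @ V.basis
        C_true = joint_casorati(truth)
        err = np.linalg.norm(C_hat - C_true) / np.linalg.norm(C_true)
        assert err < 1e-8

    def test_cg_residual_decreases_on_well_posed_system(self, geom32, sens32):
        truth = plug_truth(geom32, [0.0, 30.0, 60.0])
        kt = build_dense_kt(truth, sens32, 32, 5.0, seed=6)
        V = exact_temporal_subspace(truth, L=2)
        _, info = solve_spatial_subspace(kt, sens32, V,
                                         ReconConfig(L=2, cg_tol=1e-10),
                                         return_info=True)
        hist = info["cg"][0]["history"]
        assert hist[-1] <= 1e-10
        assert np.all(np.diff(hist) <= 1e-12)


class TestCompose:
    def test_rank_one_frames_are_scalar_multiples(self, grid32):
        rng = np.random.default_rng(7)
        u = rng.standard_normal((grid32.n_voxels, 1)) + 0j
        v = (rng.standard_normal(6) + 1j * rng.standard_normal(6))[None, :]
        v = v / np.linalg.norm(v)
        t = (np.arange(6) + 0.5) * 20.0
        U = SpatialSubspace(u, "joint", grid32)
        V = TemporalSubspace(v, "joint", t[:3], Nv=2)
        series = compose(U, V, VENC=100.0)
        for s in series:
            for m in range(3):
                ratio = s.data[:, m] / u[:, 0]
                assert np.ptp(ratio.real) < 1e-9 and np.ptp(ratio.imag) < 1e-9

    def test_factorisation_identity_round_trip(self, geom32):
        truth = plug_truth(geom32, [0.0, 20.0, 40.0, 60.0])
        C = joint_casorati(truth)
        Uf, s, Vh = np.linalg.svd(C, full_matrices=False)
        L = 2
        U = SpatialSubspace(Uf[:, :L] * s[:L], "joint", geom32.grid)
        V = TemporalSubspace(Vh[:L], "joint", truth[0].frame_times, Nv=2)
        series = compose(U, V, VENC=100.0)
        np.testing.assert_allclose(joint_casorati(series), C, atol=1e-9)

    def test_joint_split_column_bookkeeping(self, grid32):
        """Columns j < M of the joint Casorati matrix belong to encoding 1."""
        M, L = 4, 2
        rng = np.random.default_rng(8)
        u = rng.standard_normal((grid32.n_voxels, L)) + 0j
        basis = np.linalg.qr(rng.standard_normal((2 * M, L))
                             + 1j * rng.standard_normal((2 * M, L)))[0].T
        t = (np.arange(M) + 0.5) * 20.0
        U = SpatialSubspace(u, "joint", grid32)
        V = TemporalSubspace(basis, "joint", t, Nv=2)
        series = compose(U, V, VENC=100.0)
        C = u @ basis
        np.testing.assert_array_equal(series[0].data, C[:, :M])
        np.testing.assert_array_equal(series[1].data, C[:, M:])


class TestReconstructPipeline:
    def test_full_sampling_matches_direct_fourier_recon(self, geom32):
        """Unconstrained limit: full sampling, L = M, separate mode equals
        the coil-combined inverse-FFT reconstruction frame by frame."""
        truth = plug_truth(geom32, [10.0, 40.0, 70.0])
        sens = make_sensitivities(3, geom32.grid, seed=9)
        # every ky line of every frame, all flagged training so the temporal
        # basis is estimated from the complete data
        kt = build_dense_kt(truth, sens, lines_per_frame=32, TR_ms=5.0, seed=7)
        kt.role[:] = "training"
        cfg = ReconConfig(L=3, mode="separate", cg_tol=1e-10, cg_maxiter=300)
        series = reconstruct(kt, cfg)
        est = estimate_sensitivities(kt)
        for v in (1, 2):
            for m in range(3):
                ksp = np.zeros((32, 32), dtype=complex)
                sel = (kt.v == v) & (np.floor(kt.t_ms / 20.0) == m)
                for c in range(3):
                    cs = sel & (kt.coil == c)
                    ksp[kt.ky[cs]] = kt.data[cs]
                    if c == 0:
                        direct = np.conj(est.maps[c]) * ifft2c(ksp)
                    else:
                        direct += np.conj(est.maps[c]) * ifft2c(ksp)
                    ksp[:] = 0
                got = series[v - 1].frame(m)
                np.testing.assert_allclose(got, direct, atol=1e-6)

    def test_separate_mode_matches_joint_shapes(self, geom32, sens32):
        truth = plug_truth(geom32, [0.0, 30.0, 60.0, 30.0])
        kt = build_dense_kt(truth, sens32, 4, 5.0, seed=8, noise_sd=0.01)
        for mode in ("joint", "separate"):
            series = reconstruct(kt, ReconConfig(L=3, mode=mode,
                                                 cg_maxiter=30))
            assert len(series) == 2
            assert all(s.data.shape == (1024, 4) for s in series)

    def test_default_frame_times_cover_acquisition(self, geom32, sens32):
        truth = plug_truth(geom32, [0.0, 10.0, 20.0, 30.0, 40.0])
        kt = build_dense_kt(truth, sens32, 2, 5.0, seed=9)
        t = default_frame_times(kt)
        assert t.size == 5
        np.testing.assert_allclose(np.diff(t), 20.0)
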