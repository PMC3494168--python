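"""FFT magnitudes, the three PCA variants, kernels, and dispatch."""

import numpy as np
import pytest

from fmridx.errors import DegenerateInputError, ValidationError
from fmridx.reduction import (
    build_spacetime_matrix,
    build_time_matrix,
    center_kernel,
    fft_magnitudes,
    fit_kpca_st,
    fit_pca_st,
    fit_pca_t,
    make_features,
    parse_process,
    project_kpca_st,
    project_pca_st,
    project_pca_t,
    rbf_kernel,
)

from conftest import make_masked


def dft_magnitudes_oracle(x):
    """Brute-force O(T^2) one-sided DFT magnitudes, DC excluded."""
    T = len(x)
    n = np.arange(T)
    out = []
    for k in range(1, T // 2 + 1):
        c = np.sum(x * np.cos(2 * np.pi * k * n / T))
        s = np.sum(x * np.sin(2 * np.pi * k * n / T))
        out.append(np.hypot(c, s))
    return np.array(out)


class TestFFTMagnitudes:
    def test_370_points_give_185_magnitudes(self):
        x = np.random.default_rng(0).normal(size=370)
        assert fft_magnitudes(x).shape == (185,)

    def test_constant_waveform_is_all_zero(self):
        np.testing.assert_allclose(fft_magnitudes(np.full(370, 4.2)), 0.0, atol=1e-9)

    def test_bin_aligned_cosine_peaks_at_T_over_2(self):
        # cos(2*pi*7*n/370): all energy in bin 7 with magnitude 370/2
        n = np.arange(370)
        x = np.cos(2 * np.pi * 7 * n / 370)
        mags = fft_magnitudes(x)
        assert mags[6] == pytest.approx(185.0)
        others = np.delete(mags, 6)
        assert np.max(others) < 1e-9

    def test_matches_bruteforce_dft(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_allclose(fft_magnitudes(x), dft_magnitudes_oracle(x), atol=1e-9)

    def test_rowwise_application(self, rng):
        W = rng.normal(size=(5, 20))
        out = fft_magnitudes(W)
        assert out.shape == (5, 10)
        np.testing.assert_allclose(out[2], fft_magnitudes(W[2]))

    def test_odd_length_rejected(self):
        with pytest.raises(ValidationError):
            fft_magnitudes(np.zeros(371))


class TestMatrixLayout:
    def test_time_matrix_subject_major(self, rng):
        scans = [make_masked(rng.normal(size=(3, 4))) for _ in range(2)]
        X = build_time_matrix(scans)
        assert X.X_t.shape == (6, 4)
        np.testing.assert_array_equal(X.X_t[3], scans[1].waveforms[0])
        for s in range(2):
            np.testing.assert_array_equal(X.subject(s), scans[s].waveforms)

    def test_single_subject_time_matrix_is_waveforms(self, rng):
        scan = make_masked(rng.normal(size=(3, 4)))
        np.testing.assert_array_equal(build_time_matrix([scan]).X_t, scan.waveforms)

    def test_spacetime_matrix_row_layout_and_roundtrip(self, rng):
        scans = [make_masked(rng.normal(size=(3, 4))) for _ in range(2)]
        X = build_spacetime_matrix(scans)
        assert X.X_st.shape == (2, 12)
        # entries 4..7 of a row are that subject's voxel-2 waveform
        np.testing.assert_array_equal(X.X_st[0, 4:8], scans[0].waveforms[1])
        for s in range(2):
            np.testing.assert_array_equal(X.subject(s), scans[s].waveforms)

    def test_inconsistent_shapes_rejected(self, rng):
        scans = [make_masked(rng.normal(size=(3, 4))),
                 make_masked(rng.normal(size=(3, 5)))]
        with pytest.raises(ValidationError):
            build_time_matrix(scans)


class TestPCAt:
    def test_rank_one_input_has_one_nonzero_eigenvalue(self):
        base = np.array([1.0, 2.0, -1.0, 0.5])
        X = build_time_matrix([make_masked(np.outer([1.0, 2.0, 3.0], base))])
        # rows span {base}; after centering still rank 1
        model = fit_pca_t(X)
        assert model.m == 1
        assert model.eigenvalues[1] < 1e-10 * model.eigenvalues[0]

    def test_matches_dense_eigendecomposition(self, rng):
        A = rng.normal(size=(20, 6))
        model = fit_pca_t(build_time_matrix([make_masked(A)]))
        Ac = A - A.mean(axis=0)
        w_oracle, V_oracle = np.linalg.eigh(Ac.T @ Ac / 20)
        np.testing.assert_allclose(model.eigenvalues, w_oracle[::-1], atol=1e-10)
        # eigenvectors agree up to sign; scores agree with brute-force dots
        scores = project_pca_t(model, A).reshape(20, model.m)
        for i in range(model.m):
            dots = np.array([Ac[j] @ model.eigenvectors[:, i] for j in range(20)])
            np.testing.assert_allclose(scores[:, i], dots, atol=1e-10)
            overlap = abs(model.eigenvectors[:, i] @ V_oracle[:, ::-1][:, i])
            assert overlap == pytest.approx(1.0, abs=1e-8)

    def test_variance_fraction_selects_two_dominant_modes(self, rng):
        # two strong orthogonal temporal modes + tiny residual noise
        t = np.linspace(0, 1, 12)
        m1, m2 = np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)
        rows = [10 * rng.normal() * m1 + 6 * rng.normal() * m2
                + 1e-4 * rng.normal(size=12) for _ in range(40)]
        model = fit_pca_t(build_time_matrix([make_masked(np.array(rows))]), m=0.999)
        assert model.m == 2

    def test_projecting_the_mean_gives_zero_scores(self, rng):
        A = rng.normal(size=(10, 5))
        model = fit_pca_t(build_time_matrix([make_masked(A)]))
        scores = project_pca_t(model, A.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_full_basis_projection_preserves_norm(self, rng):
        A = rng.normal(size=(9, 5))
        model = fit_pca_t(build_time_matrix([make_masked(A)]), m=5)
        row = A[3:4] - A.mean(axis=0)
        scores = project_pca_t(model, A[3:4])
        assert np.linalg.norm(scores) == pytest.approx(np.linalg.norm(row))

    def test_identical_rows_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_pca_t(build_time_matrix([make_masked(np.ones((6, 4)))]))


class TestPCAst:
    def test_two_subjects_one_component(self, rng):
        X = build_spacetime_matrix([make_masked(rng.normal(size=(2, 5))) for _ in range(2)])
        model = fit_pca_st(X)
        assert model.m == 1

    def test_dual_eigenvalues_match_primal_covariance(self, rng):
        A = rng.normal(size=(5, 12))
        model = fit_pca_st(build_spacetime_matrix([make_masked(r.reshape(3, 4)) for r in A]))
        Ac = A - A.mean(axis=0)
        w_primal = np.linalg.eigh(Ac.T @ Ac / 5)[0][::-1]
        np.testing.assert_allclose(model.eigenvalues[: model.m], w_primal[: model.m],
                                   rtol=1e-8, atol=1e-12)

    def test_scores_match_bruteforce_inner_products(self, rng):
        A = rng.normal(size=(5, 12))
        model = fit_pca_st(build_spacetime_matrix([make_masked(r.reshape(3, 4)) for r in A]))
        Z = project_pca_st(model, A)
        Ac = A - A.mean(axis=0)
        for j in range(5):
            for i in range(model.m):
                oracle = sum(Ac[j, l] * model.eigenvectors[l, i] for l in range(12))
                assert Z[j, i] == pytest.approx(oracle, abs=1e-10)

    def test_eigenvectors_unit_norm_orthogonal(self, rng):
        A = rng.normal(size=(6, 15))
        model = fit_pca_st(build_spacetime_matrix([make_masked(r.reshape(3, 5)) for r in A]))
        E = model.eigenvectors
        np.testing.assert_allclose(E.T @ E, np.eye(model.m), atol=1e-8)

    def test_excessive_m_clipped_with_warning(self, rng, caplog):
        A = rng.normal(size=(4, 10))
        with caplog.at_level("WARNING"):
            model = fit_pca_st(
                build_spacetime_matrix([make_masked(r.reshape(2, 5)) for r in A]), m=10
            )
        assert model.m == 3  # centering removes one of the 4 dimensions
        assert any("clipping" in r.message for r in caplog.records)


class TestKernel:
    def test_identical_rows_give_unit_kernel(self):
        A = np.ones((3, 4))
        K = rbf_kernel(A, None, sigma=2.0)
        np.testing.assert_allclose(K.K, 1.0)

    def test_known_distance_value(self):
        # ||a - b||^2 = 45000 with sigma=150 -> exp(-1)
        a = np.zeros((1, 2))
        b = np.array([[np.sqrt(45000.0), 0.0]])
        K = rbf_kernel(a, b, sigma=150.0)
        assert K.K[0, 0] == pytest.approx(np.exp(-1.0))

    def test_strict_positive_definiteness(self, rng):
        A = rng.normal(size=(10, 6))
        K = rbf_kernel(A, None, sigma=1.5)
        assert np.all(np.diag(K.K) == 1.0)
        assert np.linalg.eigvalsh(K.K).min() > 0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            rbf_kernel(np.ones((2, 2)), None, sigma=0.0)

    def test_centering_matches_hand_formula(self, rng):
        from fmridx.reduction import KernelMatrix

        K = rng.normal(size=(3, 3))
        K = K + K.T
        Kc = center_kernel(KernelMatrix(K=K, sigma=1.0)).K
        ones = np.full((3, 3), 1 / 3)
        oracle = K - ones @ K - K @ ones + ones @ K @ ones
        np.testing.assert_allclose(Kc, oracle, atol=1e-12)
        assert np.abs(Kc.sum(axis=0)).max() < 1e-8
        assert np.abs(Kc.sum(axis=1)).max() < 1e-8

    def test_centering_idempotent(self, rng):
        from fmridx.reduction import KernelMatrix

        K = rbf_kernel(rng.normal(size=(5, 4)), None, 2.0)
        once = center_kernel(K)
        twice = center_kernel(KernelMatrix(K=once.K, sigma=once.sigma))
        np.testing.assert_allclose(once.K, twice.K, atol=1e-12)


class TestKPCAst:
    def test_training_score_columns_are_lambda_times_eigenvector(self, rng):
        A = rng.normal(size=(6, 8))
        model = fit_kpca_st(A, sigma=2.0)
        for i in range(model.m):
            np.testing.assert_allclose(
                model.train_scores[:, i],
                model.eigenvalues[i] * model.eigenvectors[:, i],
                atol=1e-10,
            )

    def test_distinct_rows_give_n_positive_uncentered_eigenvalues(self, rng):
        A = rng.normal(size=(7, 5))
        model = fit_kpca_st(A, sigma=3.0)
        assert np.linalg.eigvalsh(model.kernel_uncentered).min() > 0

    def test_projecting_training_rows_reproduces_training_scores(self, rng):
        A = rng.normal(size=(6, 10))
        model = fit_kpca_st(A, sigma=2.5)
        Z = project_kpca_st(model, A).features
        np.testing.assert_allclose(Z, model.train_scores, atol=1e-10)

    def test_linear_limit_recovers_pca_st_scores(self, rng):
        # sigma far above the data scale: RBF kPCA ~ linear PCA-st
        A = rng.normal(size=(6, 20))
        kmodel = fit_kpca_st(A, sigma=150.0)
        lmodel = fit_pca_st(build_spacetime_matrix([make_masked(r.reshape(4, 5)) for r in A]))
        Zk = project_kpca_st(kmodel, A).features
        Zl = project_pca_st(lmodel, A)
        for i in range(lmodel.m):
            corr = np.corrcoef(Zk[:, i], Zl[:, i])[0, 1]
            assert abs(corr) > 0.999

    def test_matches_sklearn_kernel_pca(self, rng):
        # independent oracle: sklearn's KernelPCA on the same kernel
        from sklearn.decomposition import KernelPCA

        A = rng.normal(size=(8, 6))
        sigma = 2.0
        model = fit_kpca_st(A, sigma=sigma)
        ref = KernelPCA(n_components=7, kernel="rbf", gamma=1.0 / (2 * sigma**2))
        Z_ref = ref.fit_transform(A)  # columns are sqrt(lambda) * e_i
        for i in range(7):
            ours = model.train_scores[:, i] / model.eigenvalues[i]
            theirs = Z_ref[:, i] / np.sqrt(ref.eigenvalues_[i])
            assert abs(ours @ theirs) == pytest.approx(1.0, abs=1e-6)

    def test_scores_invariant_to_training_order(self, rng):
        A = rng.normal(size=(7, 9))
        perm = rng.permutation(7)
        m1 = fit_kpca_st(A, sigma=2.0)
        m2 = fit_kpca_st(A[perm], sigma=2.0)
        probe = rng.normal(size=(3, 9))
        Z1 = project_kpca_st(m1, probe).features
        Z2 = project_kpca_st(m2, probe).features
        np.testing.assert_allclose(np.abs(Z1), np.abs(Z2), atol=1e-8)

    def test_duplicate_cohort_preserves_pairwise_score_distances(self, rng):
        A = rng.normal(size=(5, 8))
        model = fit_kpca_st(A, sigma=2.0)
        Z = project_kpca_st(model, A).features
        Z_dup = project_kpca_st(model, np.vstack([A, A])).features
        np.testing.assert_allclose(Z_dup[:5], Z_dup[5:], atol=1e-12)
        d_before = np.linalg.norm(Z[0] - Z[3])
        d_after = np.linalg.norm(Z_dup[5] - Z_dup[8])
        assert d_after == pytest.approx(d_before, abs=1e-10)


class TestMakeFeatures:
    def test_fft_only_feature_count_at_full_scale(self, rng):
        # one 3584-voxel masked subject, 370 time points -> 3584 x 185 features
        W = rng.normal(size=(3584, 370))
        _, block = make_features([W, W + 1.0], None, use_fft=True)
        assert block.d == 3584 * 185

    def test_fft_only_without_fft_rejected(self, rng):
        with pytest.raises(ValidationError):
            make_features([rng.normal(size=(3, 10))], None, use_fft=False)

    def test_fft_preprocessing_feeds_pca_t(self, rng):
        scans = [rng.normal(size=(3, 20)) for _ in range(4)]
        model, block = make_features(scans, "pca_t", use_fft=True, m=2)
        assert model.mean_.shape == (10,)  # fitted on 10 magnitudes, not 20 samples
        assert block.d == 3 * 2  # V * m

    @pytest.mark.parametrize("process", ["pca-t", "pca-st", "kpca-st", "fft",
                                         "fft+pca-t", "fft+pca-st", "fft+kpca-st"])
    def test_all_seven_processes_run_end_to_end(self, process, small_cohort):
        from fmridx.preprocess import apply_mask, compute_brain_mask

        processed, _, _ = small_cohort
        mask = compute_brain_mask(processed[0])
        masked = [apply_mask(s, mask) for s in processed]
        variant, use_fft = parse_process(process)
        model, block = make_features(masked, variant, use_fft, m=2)
        V, T = masked[0].waveforms.shape
        n = len(masked)
        if variant is None:
            assert block.d == V * T // 2
        elif variant == "pca_t":
            assert block.d == V * 2
        else:
            assert block.d == 2
        assert block.features.shape[0] == n
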