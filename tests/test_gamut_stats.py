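import numpy as np
import pytest

from gamutkit import gamut_stats as gs
from gamutkit.exceptions import DegenerateInputError, DomainError
from gamutkit.gamut_gen import GamutParams, sample_gamut


class TestSummarize:
    def test_isotropic_sample_has_z_near_half(self):
        x = np.random.default_rng(0).standard_normal((100_000, 3))
        summary = gs.summarize(x)
        assert summary.z == pytest.approx(0.5, abs=0.02)

    def test_model_structured_sample_recovers_z(self):
        eps = 0.01
        cov = gs.model_covariance(eps, 2 * eps, eps).matrix
        chol = np.linalg.cholesky(cov)
        x = np.random.default_rng(1).standard_normal((1_000_000, 3)) @ chol.T
        summary = gs.summarize(x)
        assert summary.z == pytest.approx(9.0 / (8.0 * eps), rel=0.10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((500, 3))
        a = gs.summarize(x)
        b = gs.summarize(rng.permutation(x))
        np.testing.assert_allclose(a.cov, b.cov, atol=1e-12)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-12)

    def test_z_scale_invariant(self):
        x = np.random.default_rng(3).standard_normal((2000, 3)) * [1.0, 0.5, 0.2]
        assert gs.summarize(x).z == pytest.approx(gs.summarize(17.3 * x).z, rel=1e-12)

    def test_normalization_constant(self):
        x = np.random.default_rng(4).standard_normal((1000, 3))
        summary = gs.summarize(x, normalize_to=1000.0)
        assert np.abs(summary.cov_normalized).max() == pytest.approx(1000.0)

    def test_eigenvectors_orthonormal_and_sign_fixed(self):
        x = np.random.default_rng(5).standard_normal((1000, 3)) @ np.diag([3, 2, 1])
        summary = gs.summarize(x)
        np.testing.assert_allclose(
            summary.eigenvectors.T @ summary.eigenvectors, np.eye(3), atol=1e-10
        )
        for j in range(3):
            col = summary.eigenvectors[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            gs.summarize(np.ones((100, 3)))
        with pytest.raises(DegenerateInputError):
            gs.summarize(np.random.default_rng(6).standard_normal((3, 3)))


class TestModelCovariance:
    def test_substitution(self):
        m = gs.model_covariance(0.1, 0.2, 0.1).matrix
        np.testing.assert_allclose(
            m, [[1, 0.9, 0.8], [0.9, 1, 0.9], [0.8, 0.9, 1]], atol=1e-15
        )

    def test_small_eps_limit_is_rank_one(self):
        m = gs.model_covariance(1e-9, 2e-9, 1e-9).matrix
        np.testing.assert_allclose(m, np.ones((3, 3)), atol=1e-8)
        assert np.linalg.matrix_rank(np.ones((3, 3))) == 1

    def test_asymmetric_epsilons_still_symmetric_matrix(self):
        m = gs.model_covariance(0.05, 0.2, 0.1).matrix
        np.testing.assert_allclose(m, m.T)

    @pytest.mark.parametrize("bad", [(0.0, 0.1, 0.1), (0.1, 1.0, 0.1)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(DomainError):
            gs.model_covariance(*bad)


class TestModelEigen:
    @pytest.mark.parametrize("eps", [1e-6, 1e-4, 1e-2, 0.09])
    def test_red_blue_axis_is_exact_eigenvector(self, eps):
        matrix = gs.model_covariance(eps, 2 * eps, eps).matrix
        u = np.array([1.0, 0.0, -1.0]) / np.sqrt(2.0)
        np.testing.assert_allclose(matrix @ u, 2.0 * eps * u, atol=1e-14)
        result = gs.model_eigen(eps)
        assert result.eigenvalues[1] == pytest.approx(2.0 * eps, rel=1e-12)

    def test_second_third_ratio_approaches_three(self):
        result = gs.model_eigen(1e-6)
        ratio = result.eigenvalues[1] / result.eigenvalues[2]
        assert round(ratio, 6) == 3.0

    @pytest.mark.parametrize("eps", [1e-2, 1e-3, 1e-4])
    def test_dominance_formula(self, eps):
        result = gs.model_eigen(eps)
        assert abs(result.z * 8.0 * eps / 9.0 - 1.0) <= 10.0 * eps

    def test_normalized_spectrum_small_eps(self):
        result = gs.model_eigen(1e-5)
        lam = result.eigenvalues / result.eigenvalues[0]
        np.testing.assert_allclose(
            lam, [1.0, 2e-5 / 3.0, 2e-5 / 9.0], rtol=1e-3
        )


class TestStereographicFrame:
    def test_pole_maps_to_origin(self):
        frame = gs.stereographic_frame(gs.OPPONENT_AXES[:, :1])
        np.testing.assert_allclose(frame.projected_points[0], [0.0, 0.0], atol=1e-14)

    def test_equatorial_directions_on_unit_circle(self):
        frame = gs.stereographic_frame(gs.OPPONENT_AXES)
        radii = np.linalg.norm(frame.projected_points, axis=1)
        np.testing.assert_allclose(radii, [0.0, 1.0, 1.0], atol=1e-14)
        np.testing.assert_allclose(frame.projected_points[1], [1.0, 0.0], atol=1e-14)
        # the nonnegative-first-coordinate rule flips (-1,2,-1)/sqrt6, so the
        # green-purple axis lands at (0, -1)
        np.testing.assert_allclose(frame.projected_points[2], [0.0, -1.0], atol=1e-14)

    def test_sign_ambiguity_resolved(self):
        flipped = -gs.OPPONENT_AXES
        frame = gs.stereographic_frame(flipped)
        np.testing.assert_allclose(frame.projected_points[1], [1.0, 0.0], atol=1e-14)

    def test_model_eigenframe_near_reference_points(self):
        # the red-blue eigenvector is exact at any eps; the others deviate
        # by O(eps), so the tight bound holds only for tiny eps.  The sign
        # of the green-purple image is a convention, so compare magnitudes.
        ref = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        frame = gs.stereographic_frame(gs.model_eigen(0.01))
        np.testing.assert_allclose(frame.projected_points[1], ref[1], atol=1e-12)
        assert np.abs(np.abs(frame.projected_points) - ref).max() < 2e-3
        tiny = gs.stereographic_frame(gs.model_eigen(1e-6))
        assert np.abs(np.abs(tiny.projected_points) - ref).max() < 1e-6

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            gs.stereographic_frame(np.zeros((3, 1)))


class TestGamutSignature:
    def test_constant_field_has_zero_signature(self):
        sig = gs.gamut_signature(np.full((64, 64, 3), 0.5))
        assert sig.mus == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)
        assert sig.sigmas == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)

    def test_recovers_generator_parameters(self):
        params = GamutParams(0.2, -0.1, 0.05, 0.8, 0.4, 0.1)
        n = 100_000
        sig = gs.gamut_signature(sample_gamut(params, n, seed=11))
        se_mu = params.sigmas / np.sqrt(n)
        se_sd = params.sigmas / np.sqrt(2 * n)
        assert np.all(np.abs(sig.mus - params.mus) < 3 * se_mu)
        assert np.all(np.abs(sig.sigmas - params.sigmas) < 3 * se_sd)


class TestPsiRegression:
    def test_exact_power_law_recovered(self):
        sigmas = np.linspace(0.2, 0.8, 7)
        sigs = [
            gs.GamutSignature(0, 0, 0, 1.0, s, 0.114 * s) for s in sigmas
        ]
        fit = gs.psi_regression(sigs)
        assert fit.power == pytest.approx(1.0, abs=1e-10)
        assert fit.psi == pytest.approx(0.114, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.psi_linear == pytest.approx(0.114, abs=1e-10)

    def test_recovery_under_lognormal_noise(self):
        rng = np.random.default_rng(21)
        sigmas = np.linspace(0.2, 0.8, 16)
        powers, psis = [], []
        for _ in range(100):
            noise = np.exp(rng.normal(0.0, 0.1, 16))
            sigs = [
                gs.GamutSignature(0, 0, 0, 1.0, s, 0.114 * s * z)
                for s, z in zip(sigmas, noise)
            ]
            fit = gs.psi_regression(sigs)
            powers.append(fit.power)
            psis.append(fit.psi)
        powers, psis = np.array(powers), np.array(psis)
        assert abs(np.median(powers) - 1.0) < 0.15
        assert abs(np.median(psis) - 0.114) < 0.2 * 0.114
        assert np.mean(np.abs(powers - 1.0) < 0.15) >= 0.9
        assert np.mean(np.abs(psis - 0.114) < 0.2 * 0.114) >= 0.9

    def test_too_few_or_degenerate_signatures_rejected(self):
        two = [gs.GamutSignature(0, 0, 0, 1, 0.5, 0.1)] * 2
        with pytest.raises(DegenerateInputError):
            gs.psi_regression(two)
        equal = [gs.GamutSignature(0, 0, 0, 1, 0.5, 0.1 * k) for k in (1, 2, 3)]
        # equal sigma_theta everywhere -> no regression
        with pytest.raises(DegenerateInputError):
            gs.psi_regression(equal)
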