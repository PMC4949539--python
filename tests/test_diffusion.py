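"""Watson ODF, dispersed-stick forward model, and nonlinear fit recovery."""

import numpy as np
import pytest

from neomyelin.diffusion import (
    DiffusionFit,
    DiffusionProtocol,
    DiffusionSettings,
    WatsonKernel,
    dispersed_stick_attenuation,
    fit_diffusion_model,
    fit_dwi_volume,
    gamma_to_kappa,
    kappa_to_gamma,
    predict_signal,
    two_shell_protocol,
)
from neomyelin.synthetic import VoxelTruth, add_rician_noise
from neomyelin.diffusion import watson_odf

from oracles import sphere_quadrature_oracle


class TestWatson:
    def test_uniform_limit(self):
        kernel = WatsonKernel(0.0, np.array([0.0, 0.0, 1.0]))
        for d in (np.array([1.0, 0, 0]), np.array([0, 1 / np.sqrt(2), 1 / np.sqrt(2)])):
            assert watson_odf(d, kernel) == pytest.approx(1.0 / (4 * np.pi), rel=1e-12)

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 4.0, 16.0, 64.0])
    def test_odf_integrates_to_one(self, kappa):
        """The ODF integrates to 1 over the sphere (adaptive 1-D quadrature in
        cos(theta), independent of the confluent-hypergeometric constant)."""
        from scipy.integrate import quad

        kernel = WatsonKernel(kappa, np.array([0.0, 0.0, 1.0]))
        pole = watson_odf(np.array([0.0, 0.0, 1.0]), kernel)
        # density(t) = pole * exp(kappa (t^2 - 1)); integrate over the sphere
        val, _ = quad(lambda t: pole * np.exp(kappa * (t * t - 1.0)), -1.0, 1.0, epsabs=1e-12, epsrel=1e-12)
        assert 2.0 * np.pi * val == pytest.approx(1.0, abs=1e-6)

    def test_density_matches_dense_grid_oracle(self):
        """Pole density at kappa=16 equals the value implied by a dense
        latitude-longitude normalization of the unnormalized kernel."""
        kappa = 16.0
        kernel = WatsonKernel(kappa, np.array([0.0, 0.0, 1.0]))
        integral = sphere_quadrature_oracle(lambda nx, ny, nz: np.exp(kappa * (nz**2 - 1.0)), n_theta=600)
        oracle_density = 1.0 / integral  # kernel value at the pole is exp(0)
        assert watson_odf(np.array([0.0, 0.0, 1.0]), kernel) == pytest.approx(oracle_density, rel=1e-4)

    def test_antipodal_symmetry(self, rng):
        kernel = WatsonKernel(7.3, np.array([0.6, 0.0, 0.8]))
        for _ in range(5):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            assert watson_odf(d, kernel) == pytest.approx(watson_odf(-d, kernel), rel=1e-12)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            watson_odf(np.array([1.0, 1.0, 0.0]), WatsonKernel(4.0, np.array([0.0, 0.0, 1.0])))

    def test_gamma_kappa_mapping_monotone_and_inverse(self):
        kappas = np.array([0.0, 0.5, 2.0, 9.0, 64.0])
        gammas = kappa_to_gamma(kappas)
        assert np.all(np.diff(gammas) < 0)
        assert gammas[0] == 1.0
        back = gamma_to_kappa(gammas[1:])
        assert np.allclose(back, kappas[1:], rtol=1e-12)


class TestForwardModel:
    def test_b0_returns_s0_exactly(self, protocol):
        fit = DiffusionFit(s0=123.0, v_in_prime=0.3, v_ex_prime=0.5, v_iso_prime=0.2, kappa=5.0, theta=0.3, phi=1.0)
        sig = predict_signal(fit, protocol)
        assert np.all(sig[protocol.b0_mask] == pytest.approx(123.0, rel=1e-12))

    def test_pure_isotropic_closed_form(self):
        proto = DiffusionProtocol(np.array([0.0, 1000.0]), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        fit = DiffusionFit(s0=1.0, v_in_prime=0.0, v_ex_prime=0.0, v_iso_prime=1.0, kappa=1.0, theta=0.0, phi=0.0)
        sig = predict_signal(fit, proto)
        assert sig[1] == pytest.approx(np.exp(-3.0), rel=1e-9)

    def test_parallel_stick_limits(self):
        b = np.array([0.0, 2000.0, 2000.0])
        bvecs = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 0, 1.0]])
        proto = DiffusionProtocol(b, bvecs)
        # near-parallel sticks along z: kappa very large
        fit = DiffusionFit(
            s0=1.0, v_in_prime=1.0, v_ex_prime=0.0, v_iso_prime=0.0, kappa=2e4, theta=0.0, phi=0.0
        )
        sig = predict_signal(fit, proto)
        assert sig[1] == pytest.approx(1.0, abs=0.01)  # perpendicular: no attenuation
        assert sig[2] == pytest.approx(np.exp(-2000 * fit.d_par), abs=0.01)  # parallel

    @pytest.mark.parametrize("kappa", [1.0, 4.0, 16.0, 64.0])
    @pytest.mark.parametrize("b", [750.0, 2000.0])
    def test_dispersed_stick_matches_quadrature_oracle(self, kappa, b):
        d_par = 1.9e-3
        for cos_beta in (0.0, 0.35, 0.8, 1.0):
            sin_beta = np.sqrt(1 - cos_beta**2)

            def integrand(nx, ny, nz):
                return np.exp(kappa * nz**2) * np.exp(-b * d_par * (sin_beta * nx + cos_beta * nz) ** 2)

            num = sphere_quadrature_oracle(integrand)
            den = sphere_quadrature_oracle(lambda nx, ny, nz: np.exp(kappa * nz**2))
            mine = dispersed_stick_attenuation(b, cos_beta, kappa, d_par)[0]
            assert mine == pytest.approx(num / den, abs=1e-4)


class TestFit:
    def test_noiseless_generative_recovery(self, protocol):
        truth = VoxelTruth(v_mwf=0.0, v_in=0.20, v_ex=0.70, v_iso=0.10, kappa=9.0, orientation=(0.36, 0.48, 0.8))
        from neomyelin.synthetic import emit_dwi_signal

        sig = emit_dwi_signal(truth, protocol)
        fit = fit_diffusion_model(sig, protocol)
        assert fit.v_in_prime == pytest.approx(0.20, abs=0.02)
        assert fit.v_iso_prime == pytest.approx(0.10, abs=0.02)
        angle = np.degrees(np.arccos(min(1.0, abs(fit.mu @ np.array(truth.orientation)))))
        assert angle <= 5.0
        assert fit.v_in_prime + fit.v_ex_prime + fit.v_iso_prime == pytest.approx(1.0, abs=1e-9)

    def test_pure_isotropic_voxel(self, protocol):
        fit_true = DiffusionFit(s0=1.0, v_in_prime=0.0, v_ex_prime=0.0, v_iso_prime=1.0, kappa=1.0, theta=0.0, phi=0.0)
        sig = predict_signal(fit_true, protocol)
        fit = fit_diffusion_model(sig, protocol)
        assert fit.v_iso_prime >= 0.95

    def test_noisy_median_error(self, protocol, rng):
        truth = VoxelTruth(v_mwf=0.0, v_in=0.20, v_ex=0.70, v_iso=0.10, kappa=9.0, orientation=(0.0, 0.6, 0.8))
        from neomyelin.synthetic import emit_dwi_signal

        clean = emit_dwi_signal(truth, protocol)
        errors = []
        for _ in range(20):
            noisy = add_rician_noise(clean, 25.0, clean[protocol.b0_mask].mean(), rng)
            fit = fit_diffusion_model(noisy, protocol)
            errors.append(abs(fit.v_in_prime - 0.20))
        assert np.median(errors) <= 0.05

    def test_requires_b0(self):
        proto = DiffusionProtocol(np.array([1000.0, 1000.0]), np.array([[1.0, 0, 0], [0.0, 1.0, 0]]))
        with pytest.raises(ValueError):
            fit_diffusion_model(np.array([0.5, 0.5]), proto)

    def test_non_finite_signals_rejected(self, protocol):
        sig = np.ones(protocol.n_volumes)
        sig[3] = np.nan
        with pytest.raises(ValueError):
            fit_diffusion_model(sig, protocol)


class TestVolumeFit:
    def test_empty_mask(self, protocol):
        maps = fit_dwi_volume(np.ones((2, 1, 1, protocol.n_volumes)), np.zeros((2, 1, 1), dtype=bool), protocol)
        assert all(np.isnan(m).all() for m in maps.values())

    def test_single_voxel_matches_scalar_fit(self, protocol):
        truth = VoxelTruth(v_mwf=0.0, v_in=0.25, v_ex=0.6, v_iso=0.15, kappa=6.0)
        from neomyelin.synthetic import emit_dwi_signal

        sig = emit_dwi_signal(truth, protocol)
        dwi = np.zeros((1, 2, 1, protocol.n_volumes))
        mask = np.zeros((1, 2, 1), dtype=bool)
        dwi[0, 0, 0] = sig
        mask[0, 0, 0] = True
        maps = fit_dwi_volume(dwi, mask, protocol)
        scalar = fit_diffusion_model(sig, protocol)
        assert maps["v_in_prime"][0, 0, 0] == pytest.approx(scalar.v_in_prime, abs=1e-9)
        assert np.isnan(maps["v_in_prime"][0, 1, 0])
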