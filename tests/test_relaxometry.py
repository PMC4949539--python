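"""Two-stage T2 spectrum fitting: flip-angle search, NNLS spectra, summaries."""

import numpy as np
import pytest

from neomyelin.epg import epg_decay_curve
from neomyelin.relaxometry import (
    EchoTrain,
    RelaxometrySettings,
    T2Grid,
    T2Spectrum,
    default_t2_grid,
    estimate_flip_angle,
    fit_t2_spectrum,
    fit_volume,
    fit_voxel,
    summarize_spectrum,
)
from neomyelin.synthetic import VoxelTruth, add_rician_noise, emit_t2_signal

TE, N = 12.0, 32


def two_component_train(alpha, mwf=0.10, t2_short=20.0, t2_long=150.0):
    sig = mwf * epg_decay_curve(alpha, t2_short, 2000.0, TE, N) + (1 - mwf) * epg_decay_curve(
        alpha, t2_long, 2000.0, TE, N
    )
    return EchoTrain(TE, sig)


class TestFlipAngle:
    @pytest.mark.parametrize("alpha", [130.0, 150.0, 180.0])
    def test_generative_recovery(self, alpha):
        est = estimate_flip_angle(two_component_train(alpha))
        assert abs(est - alpha) <= 1.0  # within one grid step

    def test_all_zero_signal_is_unfittable(self):
        est = estimate_flip_angle(EchoTrain(TE, np.zeros(N)))
        assert np.isnan(est)

    def test_noisy_mean_within_3_degrees(self, rng):
        truth = 130.0
        clean = two_component_train(truth).signal
        estimates = [
            estimate_flip_angle(EchoTrain(TE, add_rician_noise(clean, 200.0, clean[0], rng))) for _ in range(100)
        ]
        assert abs(np.mean(estimates) - truth) <= 3.0

    def test_angle_grid_bounds_enforced(self):
        with pytest.raises(ValueError):
            estimate_flip_angle(two_component_train(150.0), angle_grid=np.array([50.0, 120.0]))


class TestSpectrumFit:
    def test_single_component_identity(self):
        grid = default_t2_grid()
        sig = epg_decay_curve(180.0, 120.0, 2000.0, TE, N)
        spec = fit_t2_spectrum(EchoTrain(TE, sig), grid, 180.0)
        # mass concentrated within one grid step of 120 ms
        peak = grid.t2_values[np.argmax(spec.amplitudes)]
        step = grid.t2_values[1] / grid.t2_values[0]
        assert 120.0 / step <= peak <= 120.0 * step
        assert summarize_spectrum(spec).v_mwf == pytest.approx(0.0, abs=1e-6)

    def test_two_component_mwf_recovery(self):
        spec = fit_t2_spectrum(two_component_train(180.0), default_t2_grid(), 180.0)
        assert summarize_spectrum(spec).v_mwf == pytest.approx(0.10, abs=0.01)

    def test_uncorrected_fit_biases_short_component(self):
        """Fitting a reduced-flip-angle train with a pure-exponential basis
        (i.e. assuming 180°) distorts the short-T2 mass; the EPG basis at the
        true angle recovers it."""
        train = two_component_train(140.0)
        biased = summarize_spectrum(fit_t2_spectrum(train, default_t2_grid(), 180.0)).v_mwf
        corrected = summarize_spectrum(fit_t2_spectrum(train, default_t2_grid(), 140.0)).v_mwf
        assert abs(biased - 0.10) > 0.03
        assert corrected == pytest.approx(0.10, abs=0.015)

    def test_regularization_monotone_tradeoff(self):
        train = two_component_train(160.0)
        basis_angle = 160.0
        grid = default_t2_grid()

        def data_residual(lam):
            spec = fit_t2_spectrum(train, grid, basis_angle, regularization=lam)
            from neomyelin.relaxometry import epg_basis

            basis = np.asarray(epg_basis(basis_angle, grid.t2_values, TE, N))
            return np.linalg.norm(basis @ spec.amplitudes - train.signal)

        residuals = [data_residual(lam) for lam in (0.0, 1e-4, 1e-2, 1.0)]
        assert all(r2 >= r1 - 1e-12 for r1, r2 in zip(residuals, residuals[1:]))

    def test_residual_no_worse_than_best_single_component(self):
        train = two_component_train(160.0)
        grid = default_t2_grid()
        from neomyelin.relaxometry import epg_basis

        basis = np.asarray(epg_basis(160.0, grid.t2_values, TE, N))
        spec = fit_t2_spectrum(train, grid, 160.0)
        full = np.linalg.norm(basis @ spec.amplitudes - train.signal)
        singles = []
        for j in range(grid.n_components):
            col = basis[:, [j]]
            amp, _ = np.linalg.lstsq(col, train.signal, rcond=None)[0], None
            singles.append(np.linalg.norm(col @ np.maximum(amp, 0) - train.signal))
        assert full <= min(singles) + 1e-12

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            T2Grid(np.array([100.0, 50.0, 20.0]))


class TestSummary:
    def _spectrum(self, t2s, amps):
        return T2Spectrum(grid=T2Grid(np.asarray(t2s, float)), amplitudes=np.asarray(amps, float), flip_angle=180.0)

    def test_all_mass_below_cutoff(self):
        s = summarize_spectrum(self._spectrum([20.0, 100.0], [1.0, 0.0]))
        assert (s.v_mwf, s.v_tissue, s.v_iso) == (1.0, 0.0, 0.0)

    def test_three_band_sums(self):
        s = summarize_spectrum(self._spectrum([20.0, 150.0, 1000.0], [0.1, 0.7, 0.2]))
        assert (s.v_mwf, s.v_tissue, s.v_iso) == pytest.approx((0.1, 0.7, 0.2))
        assert s.tissue_t2 == pytest.approx(150.0)

    def test_tissue_t2_geometric_mean(self):
        s = summarize_spectrum(self._spectrum([100.0, 225.0], [0.5, 0.5]))
        assert s.tissue_t2 == pytest.approx(150.0, abs=1e-9)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t2s = np.sort(rng.uniform(16, 1500, 8))
            amps = rng.uniform(0, 1, 8)
            s = summarize_spectrum(self._spectrum(t2s, amps))
            assert s.v_mwf + s.v_tissue + s.v_iso == pytest.approx(1.0, abs=1e-12)

    def test_zero_spectrum_is_missing(self):
        s = summarize_spectrum(self._spectrum([20.0, 100.0], [0.0, 0.0]))
        assert np.isnan(s.v_mwf)

    def test_cutoff_points_belong_to_tissue_band(self):
        s = summarize_spectrum(self._spectrum([50.0, 350.0], [0.5, 0.5]))
        assert s.v_tissue == 1.0


class TestVolumeFit:
    def test_empty_mask_gives_all_missing(self):
        maps = fit_volume(np.ones((2, 2, 1, N)), np.zeros((2, 2, 1), dtype=bool), TE)
        assert all(np.isnan(m).all() for m in maps.values())

    def test_single_voxel_consistency(self):
        truth = VoxelTruth(v_mwf=0.1, v_in=0.2, v_ex=0.6, v_iso=0.1, flip_angle=160.0)
        sig = emit_t2_signal(truth)
        stack = np.zeros((2, 2, 1, N))
        mask = np.zeros((2, 2, 1), dtype=bool)
        stack[0, 1, 0] = sig
        mask[0, 1, 0] = True
        maps = fit_volume(stack, mask, TE)
        summary, alpha = fit_voxel(EchoTrain(TE, sig), RelaxometrySettings())
        assert maps["v_mwf"][0, 1, 0] == pytest.approx(summary.v_mwf, abs=1e-12)
        assert maps["flip_angle"][0, 1, 0] == alpha
        assert np.isnan(maps["v_mwf"][0, 0, 0])

    def test_phantom_recovery_noiseless(self):
        shape = (4, 2, 1)
        stack = np.zeros(shape + (N,))
        truth_map = np.zeros(shape)
        vals = [0.0, 0.05, 0.10, 0.20]
        for i, vm in enumerate(vals):
            truth = VoxelTruth(v_mwf=vm, v_in=0.2, v_ex=0.7 - vm, v_iso=0.1, flip_angle=150.0)
            sig = emit_t2_signal(truth)
            for j in range(shape[1]):
                stack[i, j, 0] = sig
                truth_map[i, j, 0] = vm
        maps = fit_volume(stack, np.ones(shape, dtype=bool), TE)
        assert np.nanmax(np.abs(maps["v_mwf"] - truth_map)) <= 0.01

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            fit_volume(np.ones((2, 2, 1, N)), np.ones((3, 2, 1), dtype=bool), TE)
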