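"""Dual-regression loop: initializers, refinement, convergence, recovery."""

import numpy as np
import pytest

from physpec import (
    BandSpectrumSet,
    PhysioTrace,
    alias_frequency,
    band_normalize,
    compute_amplitude_spectrum,
    data_driven_init,
    dominant_frequency,
    fit_spatial_glm,
    informed_init,
    refine_spectra,
    run_dual_regression,
    solve_frequency_glm,
)
from physpec.simulate import default_ground_truth, generate_epi_dataset

from conftest import make_regressors


def exact_band_set(truth):
    """Noiseless normalized spectra constructed directly from a ground truth."""
    regs = truth.regressors
    rows = (
        truth.alpha[:, None]
        + np.outer(truth.beta_r, regs.xr)
        + np.outer(truth.beta_c, regs.xc)
    )
    return BandSpectrumSet(rows, regs.band_frequencies_hz,
                           fmin_hz=truth.fmin_hz, normalized=True)


class TestInformedInit:
    TR, NVOL = 0.328, 512

    def tone_trace(self, f_hz, fs=1000.0, duration=200.0):
        t = np.arange(int(duration * fs)) / fs
        return PhysioTrace(np.cos(2 * np.pi * f_hz * t), fs)

    def test_tone_puts_all_mass_near_its_bin(self):
        cardiac = self.tone_trace(1.0)
        resp = self.tone_trace(0.3)
        regs = informed_init(cardiac, resp, self.TR, self.NVOL)
        fc = dominant_frequency(regs.xc, regs.band_frequencies_hz)
        spacing = 1 / (self.NVOL * self.TR)
        assert abs(fc - 1.0) <= spacing
        # a non-bin-centred tone leaks, but the peak region dominates
        near = np.abs(regs.band_frequencies_hz - 1.0) <= 3 * spacing
        assert regs.xc[near].sum() > 0.5

    def test_above_nyquist_tone_appears_at_alias(self):
        cardiac = self.tone_trace(2.2)
        resp = self.tone_trace(0.3)
        regs = informed_init(cardiac, resp, self.TR, self.NVOL)
        expected = alias_frequency(2.2, 1 / self.TR)  # ~0.849 Hz
        fc = dominant_frequency(regs.xc, regs.band_frequencies_hz)
        assert abs(fc - expected) <= 1 / (self.NVOL * self.TR)

    def test_white_noise_trace_gives_roughly_flat_spectrum(self):
        rng = np.random.default_rng(0)
        fs = 1000.0
        noise = PhysioTrace(rng.normal(size=int(400 * fs)), fs)
        regs = informed_init(noise, noise, self.TR, 1024)
        # smoothed flatness: block-averaged bins vary within a small factor
        blocks = regs.xc[: (regs.xc.size // 16) * 16].reshape(-1, 16).mean(axis=1)
        assert blocks.max() / blocks.min() < 5.0


class TestDataDrivenInit:
    def test_split_assigns_tone_and_floor_correctly(self, small_dataset):
        spectra = small_dataset["spectra"]
        truth = small_dataset["truth"]
        regs = data_driven_init(spectra, split_hz=0.6)
        fc = dominant_frequency(regs.xc, regs.band_frequencies_hz)
        spacing = 1 / (truth.n_volumes * truth.tr_seconds)
        assert abs(fc - truth.cardiac_rate_hz) <= 5 * spacing
        assert np.all(regs.xr[regs.band_frequencies_hz > 0.6] == 0)
        assert np.all(regs.xc[regs.band_frequencies_hz <= 0.6] == 0)

    def test_split_at_bin_frequency_goes_to_respiratory_side(self):
        freqs = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        rows = np.full((2, 5), 0.2)
        spectra = BandSpectrumSet(rows, freqs, 0.2, normalized=True)
        regs = data_driven_init(spectra, split_hz=0.6)
        assert regs.xr[2] > 0  # the 0.6 Hz bin
        assert regs.xc[2] == 0

    def test_identical_voxels_equal_single_voxel_initializer(self):
        freqs = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        row = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        spectra = BandSpectrumSet(np.vstack([row, row]), freqs, 0.2, normalized=True)
        regs = data_driven_init(spectra)
        low = row[:3] / row[:3].sum()
        high = row[3:] / row[3:].sum()
        assert np.allclose(regs.xr[:3], low) and np.allclose(regs.xc[3:], high)

    def test_all_mass_on_one_side_rejected(self):
        freqs = np.array([0.2, 0.3, 0.4, 0.5, 0.55])
        rows = np.full((2, 5), 0.2)
        spectra = BandSpectrumSet(rows, freqs, 0.2, normalized=True)
        with pytest.raises(ValueError, match="both sides|one side"):
            data_driven_init(spectra, split_hz=0.6)


class TestRefineSpectra:
    def test_exact_construction_is_a_fixed_point(self, noiseless_truth):
        spectra = exact_band_set(noiseless_truth)
        pe = fit_spatial_glm(spectra, noiseless_truth.regressors)
        refined = refine_spectra(spectra, pe)
        assert np.allclose(refined.xc, noiseless_truth.regressors.xc, atol=1e-8)
        assert np.allclose(refined.xr, noiseless_truth.regressors.xr, atol=1e-8)

    def test_zero_cardiac_column_rejected(self, noiseless_truth):
        spectra = exact_band_set(noiseless_truth)
        pe = fit_spatial_glm(spectra, noiseless_truth.regressors)
        pe.beta_c[:] = 0.0
        with pytest.raises(np.linalg.LinAlgError, match="condition number"):
            refine_spectra(spectra, pe)

    def test_raw_rows_match_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(10, 3)) + np.array([2.0, 0, 0])
        P = rng.uniform(0.1, 1.0, size=(10, 12))
        rows = solve_frequency_glm(A, P)
        oracle = np.linalg.solve(A.T @ A, A.T @ P)
        assert np.allclose(rows, oracle, atol=1e-8)


class TestRunDualRegression:
    def test_exact_init_converges_in_one_iteration(self, noiseless_truth):
        spectra = exact_band_set(noiseless_truth)
        res = run_dual_regression(spectra, noiseless_truth.regressors)
        assert res.converged and res.n_iterations == 1
        assert np.allclose(res.change_trace, 0.0, atol=1e-10)

    def test_zero_tolerance_hits_iteration_cap(self, small_dataset):
        res = run_dual_regression(
            small_dataset["spectra"],
            small_dataset["truth"].regressors,
            tolerance=0.0,
            max_iter=3,
        )
        assert res.n_iterations == 3 and not res.converged

    def test_every_iteration_keeps_regressor_invariants(self, small_dataset):
        res = run_dual_regression(
            small_dataset["spectra"],
            data_driven_init(small_dataset["spectra"]),
            keep_history=True,
        )
        for regs in res.history:
            assert np.all(regs.xc >= 0) and np.all(regs.xr >= 0)
            assert regs.xc.sum() == pytest.approx(1.0, abs=1e-9)
            assert regs.xr.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(regs.baseline == 1.0)

    def test_convergence_decision_reproduces_from_change_trace(self, small_dataset):
        res = run_dual_regression(
            small_dataset["spectra"], data_driven_init(small_dataset["spectra"])
        )
        assert np.isfinite(res.change_trace).all()
        replay = bool(np.all(res.change_trace[-1] < res.tolerance))
        assert replay == res.converged

    def test_perturbed_init_moves_back_toward_truth(self):
        """On low-noise data, the final cardiac spectrum is closer (L1) to
        the generating one than a mildly perturbed initializer was."""
        truth = default_ground_truth(
            grid_shape=(6, 6, 2), n_volumes=512, seed=13, noise_scale=0.05
        )
        ts, _, _ = generate_epi_dataset(truth)
        spec, grid = compute_amplitude_spectrum(ts)
        spectra = band_normalize(spec, grid, truth.fmin_hz)
        rng = np.random.default_rng(0)
        from physpec import SpectralRegressors

        true_regs = truth.regressors
        perturbed = SpectralRegressors.from_raw(
            true_regs.xr + rng.uniform(0, 0.2 / true_regs.xr.size, true_regs.xr.size),
            true_regs.xc + rng.uniform(0, 0.2 / true_regs.xc.size, true_regs.xc.size),
            true_regs.band_frequencies_hz,
        )
        res = run_dual_regression(spectra, perturbed, init_mode="informed")
        l1_init = np.abs(perturbed.xc - true_regs.xc).sum()
        l1_final = np.abs(res.regressors.xc - true_regs.xc).sum()
        assert l1_final < l1_init

    def test_informed_and_data_driven_masks_agree_on_separable_data(self):
        """Spectrally separated cardiac and respiratory content leads the two
        initializations to near-identical significant-cardiac masks."""
        from physpec import informed_init, mask_overlap

        truth = default_ground_truth(grid_shape=(8, 8, 3), n_volumes=512, seed=29)
        ts, _, (cardiac, resp) = generate_epi_dataset(truth)
        spec, grid = compute_amplitude_spectrum(ts)
        spectra = band_normalize(spec, grid, truth.fmin_hz)
        res_inf = run_dual_regression(
            spectra,
            informed_init(cardiac, resp, truth.tr_seconds, truth.n_volumes),
            init_mode="informed",
        )
        res_dd = run_dual_regression(
            spectra, data_driven_init(spectra), init_mode="data_driven"
        )
        m_inf = res_inf.pe_maps.p_beta_c < 0.01
        m_dd = res_dd.pe_maps.p_beta_c < 0.01
        assert mask_overlap(m_inf, m_dd) >= 95.0
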