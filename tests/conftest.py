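import numpy as np
import pytest

from physpec import (
    band_normalize,
    compute_amplitude_spectrum,
    default_ground_truth,
    generate_epi_dataset,
)


@pytest.fixture(scope="session")
def small_truth():
    """Small, moderately noisy ground truth shared across tests."""
    return default_ground_truth(grid_shape=(6, 6, 2), n_volumes=256, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    ts, mask, traces = generate_epi_dataset(small_truth)
    spectrum, grid = compute_amplitude_spectrum(ts)
    spectra = band_normalize(spectrum, grid, small_truth.fmin_hz)
    return {
        "truth": small_truth,
        "ts": ts,
        "mask": mask,
        "traces": traces,
        "grid": grid,
        "spectra": spectra,
    }


@pytest.fixture(scope="session")
def noiseless_truth():
    return default_ground_truth(
        grid_shape=(5, 5, 2), n_volumes=256, seed=3, noise_scale=0.0
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_truth):
    ts, mask, traces = generate_epi_dataset(noiseless_truth)
    spectrum, grid = compute_amplitude_spectrum(ts)
    spectra = band_normalize(spectrum, grid, noiseless_truth.fmin_hz)
    return {
        "truth": noiseless_truth,
        "ts": ts,
        "mask": mask,
        "traces": traces,
        "grid": grid,
        "spectra": spectra,
    }


def make_normalized_rows(rng, n_voxels, n_bins):
    """Random valid normalized band spectra."""
    rows = rng.uniform(0.1, 1.0, size=(n_voxels, n_bins))
    return rows / rows.sum(axis=1, keepdims=True)


def make_regressors(rng, n_bins, fmin=0.2, spacing=0.01):
    from physpec import SpectralRegressors

    freqs = fmin + spacing * np.arange(n_bins)
    xr = rng.uniform(0.05, 1.0, n_bins)
    xc = rng.uniform(0.05, 1.0, n_bins)
    # make them clearly distinct so the design is well conditioned
    xr[: n_bins // 2] *= 3.0
    xc[n_bins // 2 :] *= 3.0
    return SpectralRegressors.from_raw(xr, xc, freqs)
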