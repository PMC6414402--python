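"""Fit the three-regressor spectral GLM on a synthetic dataset.

Each voxel's normalized band spectrum is decomposed into a thermal baseline
(alpha), a respiratory (beta_r) and a cardiac (beta_c) contribution.  The
dataset is built so the model holds by construction, so the fitted maps can
be compared against the generating coefficients.
"""

import numpy as np

from physpec import (
    band_normalize,
    compute_amplitude_spectrum,
    default_ground_truth,
    fit_spatial_glm,
    generate_epi_dataset,
)

truth = default_ground_truth(grid_shape=(10, 10, 4), n_volumes=512, seed=5)
ts, mask, _ = generate_epi_dataset(truth)
spectrum, grid = compute_amplitude_spectrum(ts)
spectra = band_normalize(spectrum, grid, truth.fmin_hz)

pe = fit_spatial_glm(spectra, truth.regressors)

print(f"{spectra.n_voxels} voxels x {spectra.n_bins} band bins, dof = {pe.dof}")
for name in ("alpha", "beta_r", "beta_c"):
    r = np.corrcoef(getattr(pe, name), getattr(truth, name))[0, 1]
    print(f"correlation of fitted {name} with ground truth: {r:.4f}")
n_sig = int((pe.p_beta_c < 0.01).sum())
n_true = int((truth.beta_c > 0).sum())
print(f"significant cardiac voxels at p<0.01: {n_sig} (truly modulated: {n_true})")
# Correlations near 1 mean the per-voxel decomposition recovers the
# generating coefficients; the significant count tracks the number of
# voxels that actually carry cardiac power.
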