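"""Iterative dual regression, informed vs data-driven initialization.

The informed mode seeds the loop with the spectra of the external traces;
the data-driven mode splits the mask-average EPI spectrum at 0.6 Hz.  Both
iterate spatial and frequency GLMs until the refined spectra change by less
than 0.01 (L1), and on spectrally separable data they converge to nearly
the same significant-cardiac mask.
"""

import numpy as np

from physpec import (
    band_normalize,
    compute_amplitude_spectrum,
    data_driven_init,
    default_ground_truth,
    generate_epi_dataset,
    informed_init,
    mask_overlap,
    run_dual_regression,
)

truth = default_ground_truth(grid_shape=(16, 16, 8), n_volumes=512, seed=29)
ts, mask, (cardiac, resp) = generate_epi_dataset(truth)
spectrum, grid = compute_amplitude_spectrum(ts)
spectra = band_normalize(spectrum, grid, truth.fmin_hz)

res_inf = run_dual_regression(
    spectra,
    informed_init(cardiac, resp, truth.tr_seconds, truth.n_volumes, truth.fmin_hz),
    init_mode="informed",
)
res_dd = run_dual_regression(spectra, data_driven_init(spectra),
                             init_mode="data_driven")

for res in (res_inf, res_dd):
    print(
        f"{res.init_mode:12s}: {res.n_iterations} iterations, "
        f"converged={res.converged}, final L1 change "
        f"(cardiac, respiratory) = ({res.change_trace[-1, 0]:.4f}, "
        f"{res.change_trace[-1, 1]:.4f})"
    )
overlap = mask_overlap(res_inf.pe_maps.p_beta_c < 0.01,
                       res_dd.pe_maps.p_beta_c < 0.01)
print(f"Jaccard overlap of significant-cardiac masks: {overlap:.1f}%")
# A high overlap means the data-driven variant is a usable substitute when
# no external physiological recordings exist.
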