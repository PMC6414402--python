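"""Iterative dual regression between spatial and frequency GLMs.

A single spatial GLM fits per-voxel coefficient maps given shared
explanatory spectra.  The dual-regression loop then turns those maps around:
a second GLM along the frequency dimension, with the (alpha, beta_r, beta_c)
maps as the design, re-estimates the shared spectra themselves — yielding
tissue-specific ("brain-specific") cardiac and respiratory spectra rather
than the externally recorded ones.  Iterating the two regressions refines
both maps and spectra until the refined spectra stop changing.

Two initializers are provided.  The *informed* mode seeds the loop with the
amplitude spectra of externally recorded pulse-oximetry and respiratory-pad
traces, sub-sampled to the scan TR.  The *data-driven* mode needs no
external recordings: it splits the mask-average EPI spectrum at 0.6 Hz,
assigning the lower part to respiration and the upper part to the cardiac
component; subsequent iterations are free to redistribute power (e.g.
aliased cardiac harmonics below 0.6 Hz migrate back into the cardiac
spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import PEMaps, fit_spatial_glm
from .spectra import (
    BandSpectrumSet,
    PhysioTrace,
    SpectralRegressors,
    band_normalize,
    compute_amplitude_spectrum,
    subsample_trace,
)

__all__ = [
    "DualRegressionResult",
    "informed_init",
    "data_driven_init",
    "refine_spectra",
    "solve_frequency_glm",
    "run_dual_regression",
]

#: PE matrices with a condition number above this are rejected as
#: rank-deficient (e.g. a coefficient identically zero across voxels)
MAX_CONDITION = 1e8

#: convergence threshold on the L1 change of each refined spectrum
DEFAULT_TOLERANCE = 0.01

DEFAULT_MAX_ITER = 50

#: band-split frequency separating respiratory from cardiac content in the
#: data-driven initializer
DEFAULT_SPLIT_HZ = 0.6


@dataclass
class DualRegressionResult:
    """Converged spectra and maps plus the iteration record."""

    regressors: SpectralRegressors
    pe_maps: PEMaps
    n_iterations: int
    #: (n_iterations x 2) array of per-iteration L1 changes,
    #: columns (cardiac, respiratory)
    change_trace: np.ndarray
    converged: bool
    init_mode: str = "unspecified"
    tolerance: float = DEFAULT_TOLERANCE
    #: regressors before each iteration (index 0 is the initializer); only
    #: populated when requested
    history: list[SpectralRegressors] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.change_trace = np.asarray(self.change_trace, dtype=float).reshape(-1, 2)
        if self.n_iterations < 1 or self.change_trace.shape[0] != self.n_iterations:
            raise ValueError("change_trace must hold one row per iteration")
        if not np.isfinite(self.change_trace).all():
            raise ValueError("change_trace contains non-finite entries")
        last_ok = bool(np.all(self.change_trace[-1] < self.tolerance))
        if self.converged != last_ok:
            raise ValueError("converged flag inconsistent with change_trace")


def informed_init(
    cardiac: PhysioTrace,
    respiratory: PhysioTrace,
    tr_seconds: float,
    n_volumes: int,
    fmin_hz: float = 0.2,
) -> SpectralRegressors:
    """Initial explanatory spectra from external physiological recordings.

    Each trace is sub-sampled to the scan TR (so above-Nyquist content
    aliases exactly as it does in the EPI data), magnitude-spectrum
    transformed, band-restricted and unit-sum normalized.
    """
    spectra = {}
    for name, trace in (("xc", cardiac), ("xr", respiratory)):
        sub = subsample_trace(trace, tr_seconds, n_volumes)
        spec, grid = compute_amplitude_spectrum(sub)
        band = band_normalize(spec, grid, fmin_hz)
        spectra[name] = band
    return SpectralRegressors(
        baseline=np.ones(spectra["xc"].n_bins),
        xr=spectra["xr"].power[0],
        xc=spectra["xc"].power[0],
        band_frequencies_hz=spectra["xc"].band_frequencies_hz,
    )


def data_driven_init(
    spectra: BandSpectrumSet, split_hz: float = DEFAULT_SPLIT_HZ
) -> SpectralRegressors:
    """Initial spectra from the EPI data alone, split at ``split_hz``.

    The mask-average band spectrum below (and at) the split seeds the
    respiratory regressor; the part above the split seeds the cardiac
    regressor.  Each half is renormalized to unit sum.
    """
    freqs = spectra.band_frequencies_hz
    low = freqs <= split_hz
    high = ~low
    if not low.any() or not high.any():
        raise ValueError(
            f"band [{freqs[0]:.3g}, {freqs[-1]:.3g}] Hz has no bins on "
            f"both sides of the {split_hz} Hz split"
        )
    mean_spec = spectra.power.mean(axis=0)
    xr_raw = np.where(low, mean_spec, 0.0)
    xc_raw = np.where(high, mean_spec, 0.0)
    if xr_raw.sum() <= 0 or xc_raw.sum() <= 0:
        raise ValueError(
            f"all spectral mass lies on one side of the {split_hz} Hz split"
        )
    return SpectralRegressors.from_raw(xr_raw, xc_raw, freqs)


def solve_frequency_glm(pe_matrix: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Least-squares spectra rows given coefficient maps (the raw second GLM).

    Solves ``power[s, f] ~ pe_matrix[s, :] @ rows[:, f]`` jointly for the
    three rows (baseline, respiratory, cardiac) and returns them without any
    reset, clipping or renormalization.
    """
    pe_matrix = np.asarray(pe_matrix, dtype=float)
    if pe_matrix.shape[0] < 4:
        raise ValueError("need at least 4 voxels to refine spectra")
    cond = np.linalg.cond(pe_matrix)
    if cond > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"PE matrix is rank-deficient (condition number {cond:.3g}); "
            "a coefficient map may be constant or identically zero"
        )
    rows, *_ = np.linalg.lstsq(pe_matrix, power, rcond=None)
    return rows


def refine_spectra(spectra: BandSpectrumSet, pe_maps: PEMaps) -> SpectralRegressors:
    """Second GLM along the frequency dimension: maps -> refined spectra.

    The jointly solved baseline row is reset to the constant-1 vector (a
    non-flat thermal baseline would contradict the white-noise premise),
    negative entries of the physiological rows are clipped to zero (amplitude
    spectra are physically nonnegative), and each row is renormalized to
    unit band sum so the coefficient scale stays stable across iterations.
    """
    rows = solve_frequency_glm(pe_maps.pe_matrix, spectra.power)
    xr = np.clip(rows[1], 0.0, None)
    xc = np.clip(rows[2], 0.0, None)
    if xr.sum() <= 0 or xc.sum() <= 0:
        raise ValueError("refined spectrum is all-zero after clipping")
    return SpectralRegressors.from_raw(xr, xc, spectra.band_frequencies_hz)


def run_dual_regression(
    spectra: BandSpectrumSet,
    init: SpectralRegressors,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
    alternative: str = "two-sided",
    init_mode: str = "unspecified",
    keep_history: bool = False,
) -> DualRegressionResult:
    """Alternate spatial and frequency GLMs until the spectra stabilize.

    Convergence requires the L1 change of the cardiac *and* the respiratory
    spectrum to drop below ``tolerance`` in the same iteration.  Hitting
    ``max_iter`` without convergence yields a flagged result, not an error.
    The final coefficient maps are refit against the final spectra.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    regs = init
    history = [init.copy()] if keep_history else []
    changes = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        pe = fit_spatial_glm(spectra, regs, alternative=alternative)
        new = refine_spectra(spectra, pe)
        dc = float(np.abs(new.xc - regs.xc).sum())
        dr = float(np.abs(new.xr - regs.xr).sum())
        changes.append((dc, dr))
        regs = new
        if keep_history:
            history.append(regs.copy())
        if dc < tolerance and dr < tolerance:
            converged = True
            break
    final_pe = fit_spatial_glm(spectra, regs, alternative=alternative)
    return DualRegressionResult(
        regressors=regs,
        pe_maps=final_pe,
        n_iterations=n_iter,
        change_trace=np.asarray(changes),
        converged=converged,
        init_mode=init_mode,
        tolerance=tolerance,
        history=history,
    )
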