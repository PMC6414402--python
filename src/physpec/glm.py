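"""Per-voxel spectral GLM: baseline + respiratory + cardiac amplitude model.

Each voxel's normalized band spectrum ``P(f)`` is modelled as

    P(f) = alpha * 1 + beta_r * Xr(f) + beta_c * Xc(f) + eps(f)

fitted by ordinary least squares along the frequency dimension.  Because the
spectrum and both physiological regressors are unit-sum over the band while
the baseline column sums to the number of bins ``Nb``, noiseless coefficients
obey the coupling identity ``alpha * Nb + beta_r + beta_c = 1``: voxels with
strong physiological power necessarily show a lower thermal baseline.

Coefficients are unconstrained; negative estimates are allowed and simply
fail the significance mask in practice.  Per-coefficient p-values come from
the t-statistic with ``Nb - 3`` degrees of freedom; no correction across
voxels is applied by default (an optional Benjamini-Hochberg switch exists),
mirroring a fixed per-voxel threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import BandSpectrumSet, SpectralRegressors

__all__ = ["PEMaps", "fit_spatial_glm", "fdr_adjust"]

#: design matrices with a condition number above this are treated as
#: rank-deficient (e.g. when Xr and Xc nearly coincide)
MAX_CONDITION = 1e8


@dataclass
class PEMaps:
    """Per-voxel parameter estimates of the three-regressor spectral GLM."""

    alpha: np.ndarray
    beta_r: np.ndarray
    beta_c: np.ndarray
    se_alpha: np.ndarray
    se_beta_r: np.ndarray
    se_beta_c: np.ndarray
    t_alpha: np.ndarray
    t_beta_r: np.ndarray
    t_beta_c: np.ndarray
    p_alpha: np.ndarray
    p_beta_r: np.ndarray
    p_beta_c: np.ndarray
    residual_rms: np.ndarray
    dof: int
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        n = self.alpha.size
        arrays = {
            name: getattr(self, name)
            for name in (
                "alpha", "beta_r", "beta_c",
                "se_alpha", "se_beta_r", "se_beta_c",
                "t_alpha", "t_beta_r", "t_beta_c",
                "p_alpha", "p_beta_r", "p_beta_c",
                "residual_rms",
            )
        }
        for name, arr in arrays.items():
            if arr.shape != (n,):
                raise ValueError(f"{name} is not voxel-aligned")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")
        if np.any(self.residual_rms < 0):
            raise ValueError("residual_rms must be nonnegative")
        for name in ("p_alpha", "p_beta_r", "p_beta_c"):
            p = arrays[name]
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def n_voxels(self) -> int:
        return self.alpha.size

    @property
    def pe_matrix(self) -> np.ndarray:
        """(voxels x 3) matrix [alpha, beta_r, beta_c]."""
        return np.column_stack([self.alpha, self.beta_r, self.beta_c])

    def p_for(self, which: str) -> np.ndarray:
        return {"alpha": self.p_alpha, "beta_r": self.p_beta_r,
                "beta_c": self.p_beta_c}[which]

    def pe_for(self, which: str) -> np.ndarray:
        return {"alpha": self.alpha, "beta_r": self.beta_r,
                "beta_c": self.beta_c}[which]


def fit_spatial_glm(
    spectra: BandSpectrumSet,
    regressors: SpectralRegressors,
    alternative: str = "two-sided",
) -> PEMaps:
    """Fit the band model to every voxel spectrum by OLS.

    Parameters
    ----------
    spectra:
        Normalized band spectra (one row per voxel).
    regressors:
        Unit-sum explanatory spectra on the same band grid.
    alternative:
        ``"two-sided"`` (default) or ``"greater"`` for a one-sided test of
        positive physiological contribution.

    Returns
    -------
    PEMaps with coefficients, standard errors, t and p per voxel.
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if not spectra.normalized:
        raise ValueError("spectra must be band-normalized before fitting")
    if not np.allclose(spectra.band_frequencies_hz, regressors.band_frequencies_hz):
        raise ValueError("spectra and regressors are on different frequency grids")
    nb = spectra.n_bins
    if nb <= 3:
        raise ValueError(f"need more than 3 band frequencies, got {nb}")

    X = regressors.design_matrix  # (Nb, 3)
    cond = np.linalg.cond(X)
    if cond > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"design matrix is rank-deficient (condition number {cond:.3g}); "
            "respiratory and cardiac spectra may be collinear"
        )
    xtx_inv = np.linalg.inv(X.T @ X)
    P = spectra.power  # (S, Nb)
    betas = P @ X @ xtx_inv  # (S, 3)
    resid = P - betas @ X.T
    dof = nb - 3
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas / se, np.inf * np.sign(betas))
    t = np.where(np.isnan(t), 0.0, t)  # beta == 0 with zero residual
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    else:
        p = stats.t.sf(t, dof)
    return PEMaps(
        alpha=betas[:, 0], beta_r=betas[:, 1], beta_c=betas[:, 2],
        se_alpha=se[:, 0], se_beta_r=se[:, 1], se_beta_c=se[:, 2],
        t_alpha=t[:, 0], t_beta_r=t[:, 1], t_beta_c=t[:, 2],
        p_alpha=np.clip(p[:, 0], 0, 1),
        p_beta_r=np.clip(p[:, 1], 0, 1),
        p_beta_c=np.clip(p[:, 2], 0, 1),
        residual_rms=np.sqrt((resid**2).mean(axis=1)),
        dof=dof,
        alternative=alternative,
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional across-voxel control)."""
    p = np.asarray(p_values, dtype=float).ravel()
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adjusted, 0, 1)
    return out
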