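"""Scalar summaries of the fitted maps: weighted means, extents, pulsatility.

Within a tissue mask (voxels whose partial-volume estimate exceeds a
threshold, default 0.7), the fitted coefficient maps are summarized as

* the PVE-weighted mean coefficient over significantly modulated voxels,
  ``<beta> = sum(beta * PVE) / sum(PVE)`` over voxels with PVE > 0.7 and
  p < 0.01;
* the spatial extent ``R``: the PVE-weighted fraction of the tissue mask
  showing significant modulation;
* a windowed cardiac pulsatility metric: the mean normalized band power in
  a 0.04 Hz window centred on the dominant frequency of the externally
  measured cardiac spectrum, averaged either over all mask voxels or over
  the significantly cardiac-modulated subset only.

``partial_correlation`` provides the covariate-controlled correlation used
for group analyses (residualize both variables on the covariates, then
correlate the residuals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .glm import PEMaps
from .spectra import BandSpectrumSet, SpectralRegressors, dominant_frequency

__all__ = [
    "EmptySelectionError",
    "TissueMask",
    "MetricsReport",
    "mean_pe",
    "spatial_extent",
    "cardiac_pulsatility_metric",
    "mask_overlap",
    "partial_correlation",
    "summarize_metrics",
]

DEFAULT_PVE_THRESHOLD = 0.7
DEFAULT_P_THRESHOLD = 0.01
DEFAULT_WINDOW_HZ = 0.04


class EmptySelectionError(ValueError):
    """No voxel passes the joint PVE and significance thresholds.

    Raised instead of silently returning 0: an empty selection is an
    undefined weighted mean, not a zero one.
    """


@dataclass
class TissueMask:
    """Per-voxel partial-volume estimates with a binarization threshold."""

    pve: np.ndarray
    pve_threshold: float = DEFAULT_PVE_THRESHOLD
    label: str = "other"

    def __post_init__(self) -> None:
        self.pve = np.asarray(self.pve, dtype=float).ravel()
        if np.any((self.pve < 0) | (self.pve > 1)):
            raise ValueError("PVE values must lie in [0, 1]")
        if not (0 <= self.pve_threshold < 1):
            raise ValueError("pve_threshold must lie in [0, 1)")

    @property
    def members(self) -> np.ndarray:
        """Boolean membership: strictly above the PVE threshold."""
        return self.pve > self.pve_threshold

    @property
    def n_members(self) -> int:
        return int(self.members.sum())


class PartialCorrelation(NamedTuple):
    r: float
    p: float


@dataclass
class MetricsReport:
    """Scalar summaries for one subject/tissue; reproducible from its inputs."""

    label: str
    mean_alpha: float | None
    mean_beta_r: float | None
    mean_beta_c: float | None
    extent_c: float
    extent_r: float
    n_significant_alpha: int
    n_significant_beta_r: int
    n_significant_beta_c: int
    pulsatility_all_voxels: float | None = None
    pulsatility_significant_only: float | None = None
    p_threshold: float = DEFAULT_P_THRESHOLD
    pve_threshold: float = DEFAULT_PVE_THRESHOLD
    window_hz: float = DEFAULT_WINDOW_HZ

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _selection(pe_maps: PEMaps, mask: TissueMask, which: str, p_threshold: float):
    if pe_maps.n_voxels != mask.pve.size:
        raise ValueError("PE maps and tissue mask are not voxel-aligned")
    return mask.members & (pe_maps.p_for(which) < p_threshold)


def mean_pe(
    pe_maps: PEMaps,
    mask: TissueMask,
    which: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> float:
    """PVE-weighted mean coefficient over significantly modulated mask voxels.

    ``sum(beta * PVE) / sum(PVE)`` over voxels with both PVE above the mask
    threshold and p below ``p_threshold``.  Raises EmptySelectionError when
    no voxel qualifies.
    """
    sel = _selection(pe_maps, mask, which, p_threshold)
    if not sel.any():
        raise EmptySelectionError(
            f"no voxel with PVE > {mask.pve_threshold} and "
            f"p_{which} < {p_threshold}"
        )
    w = mask.pve[sel]
    return float(np.sum(pe_maps.pe_for(which)[sel] * w) / np.sum(w))


def spatial_extent(
    pe_maps: PEMaps,
    mask: TissueMask,
    which: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> float:
    """PVE-weighted fraction of the tissue mask with significant modulation."""
    if which not in ("beta_c", "beta_r"):
        raise ValueError("spatial extent is defined for beta_c or beta_r")
    members = mask.members
    if pe_maps.n_voxels != mask.pve.size:
        raise ValueError("PE maps and tissue mask are not voxel-aligned")
    if not members.any():
        raise ValueError("empty tissue mask")
    sig = members & (pe_maps.p_for(which) < p_threshold)
    return float(mask.pve[sig].sum() / mask.pve[members].sum())


def cardiac_pulsatility_metric(
    spectra: BandSpectrumSet,
    external_cardiac: SpectralRegressors,
    voxel_subset: np.ndarray | None = None,
    window_hz: float = DEFAULT_WINDOW_HZ,
) -> float:
    """Mean band power in a narrow window around the external cardiac peak.

    The window (default 0.04 Hz) is centred at the dominant frequency of the
    externally measured cardiac spectrum and clipped at the band edges; the
    per-voxel mean over window bins is averaged across the selected voxels.
    Operates on the normalized band spectrum so values are comparable across
    voxels and subjects.
    """
    freqs = spectra.band_frequencies_hz
    centre = dominant_frequency(external_cardiac.xc, external_cardiac.band_frequencies_hz)
    in_window = np.abs(freqs - centre) <= window_hz / 2.0 + 1e-12
    if not in_window.any():
        spacing = float(np.median(np.diff(freqs))) if freqs.size > 1 else float("nan")
        raise ValueError(
            f"no band bins within {window_hz} Hz window at {centre:.3g} Hz "
            f"(bin spacing {spacing:.3g} Hz)"
        )
    per_voxel = spectra.power[:, in_window].mean(axis=1)
    if voxel_subset is not None:
        voxel_subset = np.asarray(voxel_subset)
        per_voxel = per_voxel[voxel_subset]
    if per_voxel.size == 0:
        raise EmptySelectionError("no voxels selected for the pulsatility metric")
    return float(per_voxel.mean())


def mask_overlap(
    mask_a: np.ndarray, mask_b: np.ndarray, method: str = "jaccard"
) -> float:
    """Percentage overlap of two significant-voxel masks.

    ``method="jaccard"`` (default) is 100 * |A ∩ B| / |A ∪ B|;
    ``method="min"`` divides by the smaller mask instead.
    """
    a = np.asarray(mask_a, dtype=bool).ravel()
    b = np.asarray(mask_b, dtype=bool).ravel()
    if a.size != b.size:
        raise ValueError("masks live on different voxel universes")
    inter = np.sum(a & b)
    if method == "jaccard":
        denom = np.sum(a | b)
    elif method == "min":
        denom = min(a.sum(), b.sum())
    else:
        raise ValueError(f"unknown overlap method {method!r}")
    if denom == 0:
        raise EmptySelectionError("overlap undefined: both masks are empty")
    return float(100.0 * inter / denom)


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
) -> PartialCorrelation:
    """Correlation of x and y after removing covariates from both.

    Both variables are residualized by OLS on the covariates (plus an
    intercept), the residuals are Pearson-correlated, and the two-sided
    p-value comes from the t-transform with ``n - n_covariates - 2`` degrees
    of freedom.  With no covariates this reduces to the ordinary Pearson
    correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        k = covariates.shape[1]
        Z = np.column_stack([np.ones(n), covariates])
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(Z).all()):
        raise ValueError("inputs must be finite")
    if n <= k + 2:
        raise ValueError(f"need more than {k + 2} observations, got {n}")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if rx.std() <= 1e-12 * scale or ry.std() <= 1e-12 * scale:
        raise EmptySelectionError(
            "partial correlation undefined: residuals are (near-)constant"
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - k - 2
    r_clipped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clipped * np.sqrt(dof / (1.0 - r_clipped**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return PartialCorrelation(r=r, p=p)


def summarize_metrics(
    pe_maps: PEMaps,
    mask: TissueMask,
    spectra: BandSpectrumSet | None = None,
    external_cardiac: SpectralRegressors | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    window_hz: float = DEFAULT_WINDOW_HZ,
) -> MetricsReport:
    """Assemble the full per-tissue report from maps, mask and spectra.

    Weighted means are reported as None (rather than a fabricated number)
    when no voxel passes the joint thresholds; the pulsatility metric is
    computed twice — over all mask voxels and over the significantly
    cardiac-modulated subset — when spectra and an external cardiac spectrum
    are supplied.
    """
    means = {}
    for which in ("alpha", "beta_r", "beta_c"):
        try:
            means[which] = mean_pe(pe_maps, mask, which, p_threshold)
        except EmptySelectionError:
            means[which] = None
    puls_all = puls_sig = None
    if spectra is not None and external_cardiac is not None:
        members = mask.members
        puls_all = cardiac_pulsatility_metric(
            spectra, external_cardiac, voxel_subset=members, window_hz=window_hz
        )
        sig = members & (pe_maps.p_beta_c < p_threshold)
        if sig.any():
            puls_sig = cardiac_pulsatility_metric(
                spectra, external_cardiac, voxel_subset=sig, window_hz=window_hz
            )
    return MetricsReport(
        label=mask.label,
        mean_alpha=means["alpha"],
        mean_beta_r=means["beta_r"],
        mean_beta_c=means["beta_c"],
        extent_c=spatial_extent(pe_maps, mask, "beta_c", p_threshold),
        extent_r=spatial_extent(pe_maps, mask, "beta_r", p_threshold),
        n_significant_alpha=int(_selection(pe_maps, mask, "alpha", p_threshold).sum()),
        n_significant_beta_r=int(_selection(pe_maps, mask, "beta_r", p_threshold).sum()),
        n_significant_beta_c=int(_selection(pe_maps, mask, "beta_c", p_threshold).sum()),
        pulsatility_all_voxels=puls_all,
        pulsatility_significant_only=puls_sig,
        p_threshold=p_threshold,
        pve_threshold=mask.pve_threshold,
        window_hz=window_hz,
    )
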