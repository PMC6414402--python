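"""Readers/writers, mask construction, run configuration and orchestration.

Volumes are NIfTI-1 (time along the fourth dimension, TR from the header
with an explicit override); physiological traces are one-column (value) or
two-column (time, value) plain text with the sampling rate given either by
a ``<trace>.json`` sidecar or directly; refined spectra and iteration
traces are written as two-column text; the metrics report is JSON carrying
every threshold used, so any number in it can be regenerated from the
report alone.

Voxel extraction order is the C-order scan of the mask (``np.argwhere``),
which round-trips exactly back into volume space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import dualreg
from .dualreg import DualRegressionResult, run_dual_regression
from .glm import PEMaps
from .metrics import (
    MetricsReport,
    TissueMask,
    summarize_metrics,
)
from .simulate import GroundTruth, generate_epi_dataset
from .spectra import (
    FrequencyGrid,
    PhysioTrace,
    SpectralRegressors,
    VoxelTimeSeriesSet,
    band_normalize,
    compute_amplitude_spectrum,
)

__all__ = [
    "VolumeGeometry",
    "RunConfig",
    "load_epi",
    "load_pve",
    "build_mask",
    "read_trace",
    "write_trace",
    "write_volume",
    "write_epi",
    "write_spectrum",
    "read_spectrum",
    "run_pipeline",
]


@dataclass
class VolumeGeometry:
    """Grid shape and affine of the source volume, for writing maps back."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    tr_seconds: float | None = None


@dataclass
class RunConfig:
    """Every tunable of a pipeline run, with the standard defaults.

    The defaults are the fixed constants of the analysis: band floor
    fmin 0.2 Hz, data-driven split 0.6 Hz, convergence tolerance 0.01,
    significance threshold p < 0.01, tissue threshold PVE > 0.7 and a
    0.04 Hz pulsatility window.
    """

    epi_path: str
    pve_path: str
    out_dir: str
    mode: str = "informed"  # informed | data_driven
    cardiac_path: str | None = None
    resp_path: str | None = None
    trace_sampling_rate_hz: float | None = None
    tr_seconds: float | None = None
    fmin_hz: float = 0.2
    split_hz: float = 0.6
    tolerance: float = 0.01
    max_iter: int = 50
    p_threshold: float = 0.01
    pve_threshold: float = 0.7
    pulsatility_window_hz: float = 0.04
    alternative: str = "two-sided"
    seed: int = 0

    def validate(self, nyquist_hz: float | None = None) -> None:
        for name in ("fmin_hz", "split_hz", "tolerance", "p_threshold",
                     "pulsatility_window_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("informed", "data_driven"):
            raise ValueError(f"mode must be 'informed' or 'data_driven', got {self.mode!r}")
        if self.mode == "informed" and not (self.cardiac_path and self.resp_path):
            raise ValueError("informed mode requires cardiac and respiratory traces")
        if nyquist_hz is not None:
            if self.fmin_hz >= nyquist_hz:
                raise ValueError(
                    f"fmin {self.fmin_hz} Hz is not below Nyquist {nyquist_hz:.4g} Hz"
                )
            if self.mode == "data_driven" and not (
                self.fmin_hz < self.split_hz < nyquist_hz
            ):
                raise ValueError(
                    "data-driven mode requires fmin < split < Nyquist "
                    f"({self.fmin_hz} < {self.split_hz} < {nyquist_hz:.4g})"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def load_epi(
    path: str | Path,
    mask: np.ndarray | None = None,
    tr_seconds: float | None = None,
) -> tuple[VoxelTimeSeriesSet, VolumeGeometry]:
    """Load a 4D NIfTI into a masked voxel-by-time matrix.

    The TR is read from header pixdim[4] unless overridden.  Voxels are
    extracted in C-order scan of the mask, an order that round-trips
    exactly through ``write_volume``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got {data.ndim}D in {path}")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_seconds <= 0:
            raise ValueError(
                f"no usable TR in the header of {path}; pass tr_seconds explicitly"
            )
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume grid {data.shape[:3]}"
        )
    ts = VoxelTimeSeriesSet(
        data=data[mask], tr_seconds=tr_seconds, voxel_index=np.argwhere(mask)
    )
    geometry = VolumeGeometry(
        shape=data.shape[:3], affine=img.affine, tr_seconds=tr_seconds
    )
    return ts, geometry


def load_pve(path: str | Path) -> tuple[np.ndarray, VolumeGeometry]:
    """Load a 3D partial-volume-estimate map."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D PVE map, got {data.ndim}D in {path}")
    return data, VolumeGeometry(shape=data.shape, affine=img.affine)


def build_mask(
    pve: np.ndarray, threshold: float = 0.7, label: str = "other"
) -> TissueMask:
    """Tissue mask from a PVE map: membership where PVE is strictly above
    the threshold."""
    pve = np.asarray(pve, dtype=float)
    if np.any((pve < 0) | (pve > 1)):
        bad = pve[(pve < 0) | (pve > 1)]
        raise ValueError(f"PVE values outside [0, 1], e.g. {bad.ravel()[0]!r}")
    return TissueMask(pve=pve.ravel(), pve_threshold=threshold, label=label)


def _sidecar_rate(path: Path) -> float | None:
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        return float(meta["sampling_rate_hz"])
    return None


def read_trace(
    path: str | Path,
    sampling_rate_hz: float | None = None,
    modality: str = "cardiac",
) -> PhysioTrace:
    """Read a physiological trace from one- or two-column plain text.

    One column: waveform values, sampling rate from ``sampling_rate_hz`` or
    a ``<name>.json`` sidecar.  Two columns: (time_seconds, value), with the
    rate inferred from the time axis when not given.
    """
    path = Path(path)
    table = np.loadtxt(path, ndmin=2)
    if table.shape[1] == 1:
        rate = sampling_rate_hz or _sidecar_rate(path)
        if rate is None:
            raise ValueError(
                f"{path} is single-column; provide sampling_rate_hz or a "
                f"{path.name}.json sidecar"
            )
        samples = table[:, 0]
    elif table.shape[1] == 2:
        times, samples = table[:, 0], table[:, 1]
        rate = sampling_rate_hz or _sidecar_rate(path)
        if rate is None:
            dt = np.median(np.diff(times))
            if dt <= 0:
                raise ValueError(f"non-increasing time column in {path}")
            rate = 1.0 / dt
    else:
        raise ValueError(f"{path} must have 1 or 2 columns, found {table.shape[1]}")
    return PhysioTrace(samples=samples, sampling_rate_hz=rate, modality=modality)


def write_trace(trace: PhysioTrace, path: str | Path) -> None:
    """Write a trace as one-column text plus a sampling-rate sidecar."""
    path = Path(path)
    np.savetxt(path, trace.samples, fmt="%.8g")
    with open(path.with_name(path.name + ".json"), "w") as fh:
        json.dump(
            {"sampling_rate_hz": trace.sampling_rate_hz, "modality": trace.modality},
            fh, sort_keys=True,
        )


def write_volume(
    values: np.ndarray,
    voxel_index: np.ndarray,
    geometry: VolumeGeometry,
    path: str | Path,
    background: float = 0.0,
) -> None:
    """Scatter per-voxel values back into the volume grid and save NIfTI.

    Background voxels are written as ``background`` (default 0); consumers
    should use the accompanying mask file rather than test for NaN.
    """
    vol = np.full(geometry.shape, background, dtype=float)
    idx = np.asarray(voxel_index, dtype=int)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = np.asarray(values, dtype=float)
    nib.save(nib.Nifti1Image(vol, geometry.affine), str(path))


def read_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def write_epi(
    ts: VoxelTimeSeriesSet, grid_shape: tuple[int, int, int], path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Write a voxel-by-time matrix as 4D NIfTI with TR in the header."""
    vol = np.zeros((*grid_shape, ts.n_timepoints))
    idx = ts.voxel_index
    vol[idx[:, 0], idx[:, 1], idx[:, 2], :] = ts.data
    img = nib.Nifti1Image(vol, np.eye(4) if affine is None else affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = ts.tr_seconds
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def write_spectrum(
    frequencies_hz: np.ndarray, amplitude: np.ndarray, path: str | Path
) -> None:
    """Two-column (frequency_hz, amplitude) text file."""
    np.savetxt(
        path,
        np.column_stack([frequencies_hz, amplitude]),
        fmt="%.10g",
        header="frequency_hz amplitude",
    )


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    table = np.loadtxt(path, ndmin=2)
    return table[:, 0], table[:, 1]


def _write_dualreg_outputs(
    out: Path,
    result: DualRegressionResult,
    ts: VoxelTimeSeriesSet,
    geometry: VolumeGeometry,
    mask: TissueMask,
    config: RunConfig,
) -> None:
    regs = result.regressors
    write_spectrum(regs.band_frequencies_hz, regs.xc, out / "spectrum_cardiac.txt")
    write_spectrum(regs.band_frequencies_hz, regs.xr, out / "spectrum_respiratory.txt")
    np.savetxt(
        out / "iteration_trace.txt",
        result.change_trace,
        fmt="%.10g",
        header="l1_change_cardiac l1_change_respiratory",
    )
    pe = result.pe_maps
    for name, values in (
        ("alpha", pe.alpha), ("beta_r", pe.beta_r), ("beta_c", pe.beta_c),
        ("p_alpha", pe.p_alpha), ("p_beta_r", pe.p_beta_r), ("p_beta_c", pe.p_beta_c),
        ("residual_rms", pe.residual_rms),
    ):
        write_volume(values, ts.voxel_index, geometry, out / f"{name}.nii.gz")
    members = mask.members
    for name, sig in (
        ("mask_significant_cardiac", members & (pe.p_beta_c < config.p_threshold)),
        ("mask_significant_respiratory", members & (pe.p_beta_r < config.p_threshold)),
        ("mask_tissue", members),
    ):
        write_volume(sig.astype(float), ts.voxel_index, geometry, out / f"{name}.nii.gz")


def run_pipeline(
    config: RunConfig,
) -> tuple[MetricsReport, DualRegressionResult]:
    """End-to-end run: load, spectra, initialize, dual-regress, summarize.

    Writes coefficient/p/residual maps, significant-voxel masks, refined
    spectra, the iteration trace and a JSON report (metrics plus the full
    configuration and convergence record) into ``config.out_dir``.  The run
    is deterministic given the configuration.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        pve_vol, _ = load_pve(config.pve_path)
        tissue = build_mask(pve_vol, config.pve_threshold)
        analysis_mask = tissue.members.reshape(pve_vol.shape)
        ts, geometry = load_epi(
            config.epi_path, mask=analysis_mask, tr_seconds=config.tr_seconds
        )
        mask = TissueMask(
            pve=pve_vol[analysis_mask], pve_threshold=config.pve_threshold,
            label="tissue",
        )
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc

    grid = FrequencyGrid.from_sampling(ts.n_timepoints, ts.tr_seconds)
    config.validate(nyquist_hz=grid.nyquist_hz)

    try:
        spectrum, grid = compute_amplitude_spectrum(ts)
        spectra = band_normalize(spectrum, grid, config.fmin_hz)
    except Exception as exc:
        raise RuntimeError(f"[spectra] {exc}") from exc

    external_cardiac = None
    try:
        if config.mode == "informed":
            cardiac = read_trace(
                config.cardiac_path, config.trace_sampling_rate_hz, "cardiac"
            )
            resp = read_trace(
                config.resp_path, config.trace_sampling_rate_hz, "respiratory"
            )
            init = dualreg.informed_init(
                cardiac, resp, ts.tr_seconds, ts.n_timepoints, config.fmin_hz
            )
            external_cardiac = init
        else:
            init = dualreg.data_driven_init(spectra, config.split_hz)
            if config.cardiac_path:  # external spectrum only for the metric
                cardiac = read_trace(
                    config.cardiac_path, config.trace_sampling_rate_hz, "cardiac"
                )
                resp_like = cardiac  # pulsatility needs only the cardiac side
                external_cardiac = dualreg.informed_init(
                    cardiac, resp_like, ts.tr_seconds, ts.n_timepoints, config.fmin_hz
                )
    except Exception as exc:
        raise RuntimeError(f"[init:{config.mode}] {exc}") from exc

    try:
        result = run_dual_regression(
            spectra,
            init,
            tolerance=config.tolerance,
            max_iter=config.max_iter,
            alternative=config.alternative,
            init_mode=config.mode,
        )
    except Exception as exc:
        raise RuntimeError(f"[dual_regression] {exc}") from exc

    try:
        report = summarize_metrics(
            result.pe_maps,
            mask,
            spectra=spectra,
            external_cardiac=external_cardiac,
            p_threshold=config.p_threshold,
            window_hz=config.pulsatility_window_hz,
        )
        _write_dualreg_outputs(out, result, ts, geometry, mask, config)
        payload = {
            "config": config.to_dict(),
            "metrics": report.to_dict(),
            "dual_regression": {
                "mode": result.init_mode,
                "n_iterations": result.n_iterations,
                "converged": result.converged,
                "tolerance": result.tolerance,
                "final_change_cardiac": float(result.change_trace[-1, 0]),
                "final_change_respiratory": float(result.change_trace[-1, 1]),
            },
            "band": {
                "fmin_hz": config.fmin_hz,
                "nyquist_hz": grid.nyquist_hz,
                "n_bins": spectra.n_bins,
                "n_voxels": spectra.n_voxels,
            },
        }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
    except Exception as exc:
        raise RuntimeError(f"[metrics] {exc}") from exc

    return report, result


def write_synthetic_dataset(
    truth: GroundTruth, out_dir: str | Path, signal_scale: float = 100.0
) -> dict[str, str]:
    """Generate a synthetic dataset and write its standard files.

    Returns the paths of the EPI volume, PVE map, both traces and the
    ground-truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts, mask, (cardiac, resp) = generate_epi_dataset(truth, signal_scale=signal_scale)
    paths = {
        "epi": str(out / "epi.nii.gz"),
        "pve": str(out / "pve.nii.gz"),
        "cardiac": str(out / "cardiac.txt"),
        "resp": str(out / "resp.txt"),
        "truth": str(out / "ground_truth.json"),
    }
    write_epi(ts, truth.grid_shape, paths["epi"])
    geometry = VolumeGeometry(shape=truth.grid_shape, affine=np.eye(4))
    write_volume(mask.pve, ts.voxel_index, geometry, paths["pve"])
    write_trace(cardiac, paths["cardiac"])
    write_trace(resp, paths["resp"])
    truth_meta = {
        "grid_shape": list(truth.grid_shape),
        "tr_seconds": truth.tr_seconds,
        "n_volumes": truth.n_volumes,
        "fmin_hz": truth.fmin_hz,
        "cardiac_rate_hz": truth.cardiac_rate_hz,
        "resp_rate_hz": truth.resp_rate_hz,
        "rate_drift": truth.rate_drift,
        "n_harmonics": truth.n_harmonics,
        "noise_scale": truth.noise_scale,
        "seed": truth.seed,
        "alpha": truth.alpha.tolist(),
        "beta_r": truth.beta_r.tolist(),
        "beta_c": truth.beta_c.tolist(),
        "pve": truth.pve.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_meta, fh, sort_keys=True)
    return paths
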