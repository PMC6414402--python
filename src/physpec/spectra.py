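"""Band-limited amplitude spectra of voxel time series and physiological traces.

The signal model works on the one-sided discrete Fourier amplitude spectrum
of each voxel's BOLD time series.  A fast repetition time (TR of a few
hundred milliseconds) places the fundamental cardiac frequency below the
Nyquist frequency 1/(2*TR); higher cardiac harmonics fold back into the
sampled band at ``|f_true - n*f_sample|``.  All downstream modelling operates
on spectra restricted to the physiological band ``[fmin, nyquist]`` and
normalized to unit sum, so that voxels and subjects with different absolute
signal levels are comparable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelTimeSeriesSet",
    "FrequencyGrid",
    "BandSpectrumSet",
    "PhysioTrace",
    "SpectralRegressors",
    "compute_amplitude_spectrum",
    "band_normalize",
    "subsample_trace",
    "dominant_frequency",
    "alias_frequency",
]

#: minimum number of time points for a meaningful spectrum
MIN_TIMEPOINTS = 8

#: tolerance on unit-sum normalization checks
NORM_TOL = 1e-9


@dataclass
class VoxelTimeSeriesSet:
    """Masked voxel time series: a (voxels x timepoints) matrix sampled at TR.

    Parameters
    ----------
    data:
        Signal values, one row per voxel, in arbitrary scanner units.
    tr_seconds:
        Sampling interval (the repetition time) in seconds.
    voxel_index:
        (voxels x 3) integer coordinates of each row in the source volume
        grid, used to write results back into volume space.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_index: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.voxel_index = np.asarray(self.voxel_index, dtype=int).reshape(-1, 3)
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.data.shape[1] < MIN_TIMEPOINTS:
            raise ValueError(
                f"need at least {MIN_TIMEPOINTS} timepoints, got {self.data.shape[1]}"
            )
        bad = ~np.isfinite(self.data).all(axis=1)
        if bad.any():
            rows = np.flatnonzero(bad)
            raise ValueError(
                f"non-finite samples in voxel rows {rows[:10].tolist()}"
                + ("..." if rows.size > 10 else "")
            )
        if self.voxel_index.shape[0] != self.data.shape[0]:
            raise ValueError(
                f"voxel_index has {self.voxel_index.shape[0]} entries for "
                f"{self.data.shape[0]} voxel rows"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_timepoints * self.tr_seconds


@dataclass
class FrequencyGrid:
    """One-sided frequency axis f0=0 ... Nyquist of an N-point series at TR."""

    frequencies_hz: np.ndarray
    resolution_hz: float
    nyquist_hz: float

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        if self.frequencies_hz[0] != 0.0:
            raise ValueError("frequency grid must start at 0 Hz")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if abs(self.frequencies_hz[-1] - self.nyquist_hz) > self.resolution_hz:
            raise ValueError("last grid frequency must reach Nyquist within one bin")

    @classmethod
    def from_sampling(cls, n_timepoints: int, tr_seconds: float) -> "FrequencyGrid":
        freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
        return cls(
            frequencies_hz=freqs,
            resolution_hz=1.0 / (n_timepoints * tr_seconds),
            nyquist_hz=1.0 / (2.0 * tr_seconds),
        )


@dataclass
class BandSpectrumSet:
    """Voxel spectra restricted to the physiological band [fmin, Nyquist]."""

    power: np.ndarray
    band_frequencies_hz: np.ndarray
    fmin_hz: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        self.band_frequencies_hz = np.asarray(self.band_frequencies_hz, dtype=float)
        if self.power.shape[1] != self.band_frequencies_hz.size:
            raise ValueError("power columns must match band frequencies")
        if np.any(self.power < 0):
            raise ValueError("band spectra must be nonnegative")
        if self.normalized:
            sums = self.power.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("normalized flag set but row sums deviate from 1")

    @property
    def n_voxels(self) -> int:
        return self.power.shape[0]

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]


@dataclass
class PhysioTrace:
    """An externally recorded physiological waveform (pulse-ox or belt/pad)."""

    samples: np.ndarray
    sampling_rate_hz: float
    modality: str = "cardiac"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_seconds(self) -> float:
        return self.samples.size / self.sampling_rate_hz


@dataclass
class SpectralRegressors:
    """The three explanatory spectra of the band model.

    ``baseline`` is the constant-1 thermal-noise column; ``xr`` and ``xc``
    are the respiratory and cardiac amplitude spectra, each unit-sum over
    the band so that fitted coefficients are comparable across voxels.
    """

    baseline: np.ndarray
    xr: np.ndarray
    xc: np.ndarray
    band_frequencies_hz: np.ndarray

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.xr = np.asarray(self.xr, dtype=float)
        self.xc = np.asarray(self.xc, dtype=float)
        self.band_frequencies_hz = np.asarray(self.band_frequencies_hz, dtype=float)
        nb = self.band_frequencies_hz.size
        for name, vec in (("baseline", self.baseline), ("xr", self.xr), ("xc", self.xc)):
            if vec.shape != (nb,):
                raise ValueError(f"{name} must have one entry per band frequency")
        if not np.all(self.baseline == 1.0):
            raise ValueError("baseline must be the constant-1 vector")
        for name, vec in (("xr", self.xr), ("xc", self.xc)):
            if np.any(vec < 0):
                raise ValueError(f"{name} must be nonnegative")
            if abs(vec.sum() - 1.0) > NORM_TOL:
                raise ValueError(f"{name} must sum to 1 (got {vec.sum()!r})")

    @classmethod
    def from_raw(
        cls,
        xr: np.ndarray,
        xc: np.ndarray,
        band_frequencies_hz: np.ndarray,
    ) -> "SpectralRegressors":
        """Build regressors from raw nonnegative spectra by unit-sum scaling."""
        xr = np.asarray(xr, dtype=float)
        xc = np.asarray(xc, dtype=float)
        for name, vec in (("respiratory", xr), ("cardiac", xc)):
            if vec.sum() <= 0:
                raise ValueError(f"{name} spectrum has zero total amplitude")
        return cls(
            baseline=np.ones_like(xr),
            xr=xr / xr.sum(),
            xc=xc / xc.sum(),
            band_frequencies_hz=band_frequencies_hz,
        )

    @property
    def design_matrix(self) -> np.ndarray:
        """(bins x 3) design ``[1, Xr, Xc]`` for the per-voxel spatial GLM."""
        return np.column_stack([self.baseline, self.xr, self.xc])

    def copy(self) -> "SpectralRegressors":
        return dataclasses.replace(
            self,
            baseline=self.baseline.copy(),
            xr=self.xr.copy(),
            xc=self.xc.copy(),
        )


def compute_amplitude_spectrum(
    ts: VoxelTimeSeriesSet, output: str = "amplitude"
) -> tuple[np.ndarray, FrequencyGrid]:
    """One-sided Fourier spectrum of each voxel time series.

    Each row is demeaned and transformed; the returned matrix holds the
    Fourier-transform magnitude ``sqrt(Re^2 + Im^2)`` per voxel at the
    one-sided frequencies 0 ... Nyquist.  ``output="power"`` returns the
    squared magnitude instead (the magnitude is the default because the
    downstream band model is formulated on amplitudes).

    Returns
    -------
    spectrum : (voxels x n_freq) nonnegative matrix
    grid : FrequencyGrid
    """
    if output not in ("amplitude", "power"):
        raise ValueError(f"output must be 'amplitude' or 'power', got {output!r}")
    data = ts.data - ts.data.mean(axis=1, keepdims=True)
    coeffs = np.fft.rfft(data, axis=1)
    spectrum = np.abs(coeffs)
    if output == "power":
        spectrum = spectrum**2
    grid = FrequencyGrid.from_sampling(ts.n_timepoints, ts.tr_seconds)
    return spectrum, grid


def band_select(grid: FrequencyGrid, fmin_hz: float) -> np.ndarray:
    """Boolean index of grid frequencies inside [fmin, Nyquist]."""
    return (grid.frequencies_hz >= fmin_hz - 1e-12) & (
        grid.frequencies_hz <= grid.nyquist_hz + 1e-12
    )


def band_normalize(
    spectrum: np.ndarray, grid: FrequencyGrid, fmin_hz: float = 0.2
) -> BandSpectrumSet:
    """Restrict spectra to [fmin, Nyquist] and scale every row to unit sum.

    Raises if any voxel has zero power inside the band: such a voxel cannot
    be normalized and must be excluded from the analysis mask by the caller.
    """
    if fmin_hz >= grid.nyquist_hz:
        raise ValueError(
            f"fmin {fmin_hz} Hz must lie below the Nyquist frequency "
            f"{grid.nyquist_hz:.4g} Hz"
        )
    spectrum = np.atleast_2d(np.asarray(spectrum, dtype=float))
    keep = band_select(grid, fmin_hz)
    if keep.sum() < 4:
        raise ValueError(f"band [{fmin_hz}, {grid.nyquist_hz:.4g}] Hz has "
                         f"only {int(keep.sum())} bins; need at least 4")
    band = spectrum[:, keep]
    sums = band.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValueError(
            f"zero band power in voxel rows {bad[:10].tolist()}; "
            "exclude these voxels from the mask"
        )
    return BandSpectrumSet(
        power=band / sums[:, None],
        band_frequencies_hz=grid.frequencies_hz[keep],
        fmin_hz=fmin_hz,
        normalized=True,
    )


def subsample_trace(
    trace: PhysioTrace, tr_seconds: float, n_volumes: int
) -> VoxelTimeSeriesSet:
    """Sub-sample an external trace to one value per EPI volume.

    Takes the nearest trace sample at each volume onset time ``i * TR``.
    No anti-alias filtering is applied: folding of above-Nyquist cardiac
    harmonics into the sampled band is part of the modelled physics.
    """
    idx = np.rint(np.arange(n_volumes) * tr_seconds * trace.sampling_rate_hz).astype(int)
    if idx[-1] >= trace.samples.size:
        raise ValueError(
            f"trace too short: need {n_volumes * tr_seconds:.2f} s, "
            f"have {trace.duration_seconds:.2f} s"
        )
    return VoxelTimeSeriesSet(
        data=trace.samples[idx][None, :],
        tr_seconds=tr_seconds,
        voxel_index=np.zeros((1, 3), dtype=int),
    )


def dominant_frequency(power: np.ndarray, band_frequencies_hz: np.ndarray) -> float:
    """Band frequency carrying maximal power; ties break toward lower frequency."""
    power = np.asarray(power, dtype=float).ravel()
    band_frequencies_hz = np.asarray(band_frequencies_hz, dtype=float)
    if power.size == 0:
        raise ValueError("empty band spectrum")
    if power.size != band_frequencies_hz.size:
        raise ValueError("spectrum and frequency axis lengths differ")
    # argmax returns the first maximum; frequencies are increasing, so ties
    # resolve toward the lowest frequency
    return float(band_frequencies_hz[int(np.argmax(power))])


def alias_frequency(f_true_hz, f_sample_hz: float):
    """Fold a true frequency into the sampled band [0, f_sample/2].

    Implements ``f_alias = |f_true - n * f_sample|`` with the integer n that
    places the result at or below the Nyquist frequency.  Accepts scalars or
    arrays.
    """
    f_true = np.asarray(f_true_hz, dtype=float)
    if np.any(f_true < 0):
        raise ValueError("f_true_hz must be nonnegative")
    if f_sample_hz <= 0:
        raise ValueError("f_sample_hz must be positive")
    rem = np.mod(f_true, f_sample_hz)
    folded = np.where(rem > f_sample_hz / 2.0, f_sample_hz - rem, rem)
    if np.isscalar(f_true_hz) or folded.ndim == 0:
        return float(folded)
    return folded
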