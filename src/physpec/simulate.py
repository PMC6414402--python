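"""Synthetic fast-TR EPI datasets with known spectral ground truth.

The generator produces voxel time series whose band-limited amplitude
spectra satisfy the three-regressor model *by construction*: per voxel, the
band amplitudes are assembled as ``alpha + beta_r * Xr + beta_c * Xc``
(with the coefficients obeying the unit-sum coupling
``alpha * Nb + beta_r + beta_c = 1``), random phases are attached, and the
one-sided spectrum is inverse-transformed to a real time series.  A
low-frequency "neurovascular" component below 0.1 Hz exercises the band
cut, and complex Gaussian noise added to the frequency bins plays the role
of measurement variability.  Matched 1 kHz external traces (quasi-periodic
cardiac and respiratory waveforms with slowly drifting rates and decaying
harmonics) are generated from the same ground truth so that informed
initialization can be tested end to end, including aliasing of cardiac
harmonics above the EPI Nyquist frequency.

Frequency-domain synthesis keeps recovery tests sharp (the model holds
exactly at zero noise); a harder ``mode="time_domain"`` mixes the actual
trace waveforms into the voxel signals instead, in which case the recorded
coefficients are only approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import (
    FrequencyGrid,
    PhysioTrace,
    SpectralRegressors,
    VoxelTimeSeriesSet,
    band_normalize,
    band_select,
    compute_amplitude_spectrum,
    subsample_trace,
)
from .metrics import TissueMask

__all__ = [
    "GroundTruth",
    "generate_traces",
    "default_ground_truth",
    "generate_epi_dataset",
]

#: study-like scan geometry: fast-TR multiband EPI
DEFAULT_TR_SECONDS = 0.328
DEFAULT_N_VOLUMES = 2200
DEFAULT_FMIN_HZ = 0.2

#: physiological defaults: resting adult cardiac and respiratory rates
DEFAULT_CARDIAC_RATE_HZ = 1.1
DEFAULT_RESP_RATE_HZ = 0.3
DEFAULT_RATE_DRIFT = 0.03
DEFAULT_N_HARMONICS = 3

#: frequency-bin noise, as a fraction of the mean baseline amplitude
DEFAULT_NOISE_SCALE = 0.3

#: upper edge of the synthetic low-frequency neurovascular regime
LOW_FREQ_CUTOFF_HZ = 0.1


@dataclass
class GroundTruth:
    """Generating parameters and maps for one synthetic dataset."""

    regressors: SpectralRegressors
    alpha: np.ndarray
    beta_r: np.ndarray
    beta_c: np.ndarray
    pve: np.ndarray
    grid_shape: tuple[int, int, int]
    tr_seconds: float
    n_volumes: int
    fmin_hz: float
    cardiac_rate_hz: float
    rate_drift: float
    resp_rate_hz: float
    n_harmonics: int
    noise_scale: float
    seed: int

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.beta_r = np.asarray(self.beta_r, dtype=float).ravel()
        self.beta_c = np.asarray(self.beta_c, dtype=float).ravel()
        self.pve = np.asarray(self.pve, dtype=float).ravel()
        n_vox = int(np.prod(self.grid_shape))
        for name in ("alpha", "beta_r", "beta_c", "pve"):
            if getattr(self, name).size != n_vox:
                raise ValueError(f"{name} map does not match the grid shape")
        nb = self.regressors.band_frequencies_hz.size
        coupling = self.alpha * nb + self.beta_r + self.beta_c
        if not np.allclose(coupling, 1.0, atol=1e-9):
            raise ValueError(
                "generating coefficients must satisfy alpha*Nb + beta_r + beta_c = 1"
            )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


def _quasi_periodic_wave(
    n_samples: int,
    sampling_rate_hz: float,
    rate_hz: float,
    rate_drift: float,
    n_harmonics: int,
    rng: np.random.Generator,
    drift_freq_hz: float = 0.05,
) -> np.ndarray:
    """Fundamental plus decaying harmonics with a slowly drifting rate."""
    t = np.arange(n_samples) / sampling_rate_hz
    if rate_drift > 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        inst = rate_hz * (1.0 + rate_drift * np.sin(2 * np.pi * drift_freq_hz * t + phase0))
    else:
        inst = np.full(n_samples, rate_hz)
    phase = 2 * np.pi * np.cumsum(inst) / sampling_rate_hz
    wave = np.zeros(n_samples)
    for h in range(1, n_harmonics + 1):
        psi = rng.uniform(0, 2 * np.pi)
        wave += np.cos(h * phase + psi) / h
    return wave


def generate_traces(
    duration_s: float,
    sampling_rate_hz: float = 1000.0,
    cardiac_rate_hz: float = DEFAULT_CARDIAC_RATE_HZ,
    rate_drift: float = DEFAULT_RATE_DRIFT,
    resp_rate_hz: float = DEFAULT_RESP_RATE_HZ,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    seed: int = 0,
    epi_tr_seconds: float | None = None,
) -> tuple[PhysioTrace, PhysioTrace]:
    """Matched cardiac (pulse-ox-like) and respiratory (pad-like) waveforms.

    Quasi-periodic signals: a fundamental at the given rate plus
    ``n_harmonics - 1`` higher harmonics with 1/h amplitude decay and a
    slowly drifting instantaneous frequency (fractional amplitude
    ``rate_drift``).  Deterministic under ``seed``.  If ``epi_tr_seconds``
    is given, rates (or their harmonics) above the EPI Nyquist frequency
    trigger a warning — they are permitted, since aliasing is part of the
    modelled physics.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    for name, rate in (("cardiac", cardiac_rate_hz), ("respiratory", resp_rate_hz)):
        if rate <= 0:
            raise ValueError(f"{name} rate must be positive")
    if epi_tr_seconds is not None:
        epi_nyquist = 1.0 / (2.0 * epi_tr_seconds)
        for name, rate in (("cardiac", cardiac_rate_hz), ("respiratory", resp_rate_hz)):
            if rate * n_harmonics > epi_nyquist:
                warnings.warn(
                    f"{name} content up to {rate * n_harmonics:.2f} Hz exceeds the "
                    f"EPI Nyquist frequency {epi_nyquist:.2f} Hz and will alias",
                    stacklevel=2,
                )
    n_samples = int(round(duration_s * sampling_rate_hz))
    rng_c, rng_r = [np.random.default_rng(s) for s in
                    np.random.SeedSequence(seed).spawn(2)]
    cardiac = _quasi_periodic_wave(
        n_samples, sampling_rate_hz, cardiac_rate_hz, rate_drift, n_harmonics, rng_c
    )
    respiratory = _quasi_periodic_wave(
        n_samples, sampling_rate_hz, resp_rate_hz, rate_drift, n_harmonics, rng_r
    )
    return (
        PhysioTrace(cardiac, sampling_rate_hz, modality="cardiac"),
        PhysioTrace(respiratory, sampling_rate_hz, modality="respiratory"),
    )


def _trace_regressors(
    cardiac: PhysioTrace,
    respiratory: PhysioTrace,
    tr_seconds: float,
    n_volumes: int,
    fmin_hz: float,
) -> SpectralRegressors:
    xs = {}
    freqs = None
    for name, trace in (("xc", cardiac), ("xr", respiratory)):
        sub = subsample_trace(trace, tr_seconds, n_volumes)
        spec, grid = compute_amplitude_spectrum(sub)
        band = band_normalize(spec, grid, fmin_hz)
        xs[name] = band.power[0]
        freqs = band.band_frequencies_hz
    return SpectralRegressors.from_raw(xs["xr"], xs["xc"], freqs)


def default_ground_truth(
    grid_shape: tuple[int, int, int] = (12, 12, 4),
    tr_seconds: float = DEFAULT_TR_SECONDS,
    n_volumes: int = 512,
    fmin_hz: float = DEFAULT_FMIN_HZ,
    seed: int = 0,
    frac_cardiac: float = 0.35,
    frac_resp: float = 0.45,
    beta_c_range: tuple[float, float] = (0.05, 0.35),
    beta_r_range: tuple[float, float] = (0.05, 0.30),
    cardiac_rate_hz: float = DEFAULT_CARDIAC_RATE_HZ,
    resp_rate_hz: float = DEFAULT_RESP_RATE_HZ,
    rate_drift: float = DEFAULT_RATE_DRIFT,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    noise_scale: float = DEFAULT_NOISE_SCALE,
) -> GroundTruth:
    """Random but reproducible ground truth on a small grid.

    A fraction of voxels carries cardiac modulation (coefficients uniform in
    ``beta_c_range``), an independent fraction respiratory modulation; the
    thermal baseline absorbs the remainder of the unit sum.  PVE values are
    drawn Beta(5, 2)-distributed so that most voxels clear the 0.7 tissue
    threshold, as in a well-segmented tissue mask.  The generating cardiac
    and respiratory spectra are the band spectra of the matched external
    traces, so they carry realistic harmonic and alias structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    n_vox = int(np.prod(grid_shape))
    duration = n_volumes * tr_seconds + 2.0
    cardiac, respiratory = generate_traces(
        duration_s=duration,
        cardiac_rate_hz=cardiac_rate_hz,
        resp_rate_hz=resp_rate_hz,
        rate_drift=rate_drift,
        n_harmonics=n_harmonics,
        seed=seed,
    )
    regressors = _trace_regressors(cardiac, respiratory, tr_seconds, n_volumes, fmin_hz)
    nb = regressors.band_frequencies_hz.size

    beta_c = np.zeros(n_vox)
    beta_r = np.zeros(n_vox)
    card_active = rng.random(n_vox) < frac_cardiac
    resp_active = rng.random(n_vox) < frac_resp
    beta_c[card_active] = rng.uniform(*beta_c_range, card_active.sum())
    beta_r[resp_active] = rng.uniform(*beta_r_range, resp_active.sum())
    alpha = (1.0 - beta_r - beta_c) / nb
    pve = rng.beta(5.0, 2.0, n_vox)

    return GroundTruth(
        regressors=regressors,
        alpha=alpha,
        beta_r=beta_r,
        beta_c=beta_c,
        pve=pve,
        grid_shape=tuple(grid_shape),
        tr_seconds=tr_seconds,
        n_volumes=n_volumes,
        fmin_hz=fmin_hz,
        cardiac_rate_hz=cardiac_rate_hz,
        rate_drift=rate_drift,
        resp_rate_hz=resp_rate_hz,
        n_harmonics=n_harmonics,
        noise_scale=noise_scale,
        seed=seed,
    )


def generate_epi_dataset(
    truth: GroundTruth,
    signal_scale: float = 100.0,
    lf_amplitude: float = 1.0,
    mode: str = "frequency",
) -> tuple[VoxelTimeSeriesSet, TissueMask, tuple[PhysioTrace, PhysioTrace]]:
    """Voxel time series, tissue mask and matched traces from a ground truth.

    ``mode="frequency"`` (default) synthesizes each voxel's one-sided
    spectrum — low-frequency neurovascular amplitudes below 0.1 Hz, the
    three-regressor band amplitudes above ``fmin`` — attaches uniform random
    phases, adds complex Gaussian bin noise of standard deviation
    ``noise_scale`` times the mean baseline amplitude, and inverse
    transforms to a real time series.  ``mode="time_domain"`` instead mixes
    the actual trace waveforms into the voxel signals plus white noise; the
    ground-truth coefficients are then only approximate.
    """
    if mode not in ("frequency", "time_domain"):
        raise ValueError(f"unknown mode {mode!r}")
    tr, n_vol = truth.tr_seconds, truth.n_volumes
    grid = FrequencyGrid.from_sampling(n_vol, tr)
    keep = band_select(grid, truth.fmin_hz)
    if not np.array_equal(grid.frequencies_hz[keep], truth.regressors.band_frequencies_hz):
        raise ValueError("ground-truth regressors are not on this scan's band grid")
    n_vox = truth.n_voxels
    voxel_index = np.argwhere(np.ones(truth.grid_shape, dtype=bool))
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 29]))

    duration = n_vol * tr + 2.0
    traces = generate_traces(
        duration_s=duration,
        cardiac_rate_hz=truth.cardiac_rate_hz,
        resp_rate_hz=truth.resp_rate_hz,
        rate_drift=truth.rate_drift,
        n_harmonics=truth.n_harmonics,
        seed=truth.seed,
    )

    if mode == "time_domain":
        data = _time_domain_mix(truth, traces, signal_scale, rng)
    else:
        data = _frequency_domain_mix(truth, grid, keep, signal_scale, lf_amplitude, rng)

    ts = VoxelTimeSeriesSet(data=data, tr_seconds=tr, voxel_index=voxel_index)
    mask = TissueMask(pve=truth.pve, label="synthetic")
    return ts, mask, traces


def _frequency_domain_mix(truth, grid, keep, signal_scale, lf_amplitude, rng):
    freqs = grid.frequencies_hz
    n_freq = freqs.size
    n_vol = truth.n_volumes
    n_vox = truth.n_voxels
    regs = truth.regressors

    amp = np.zeros((n_vox, n_freq))
    # physiological band per the generating model
    band_amp = (
        truth.alpha[:, None]
        + np.outer(truth.beta_r, regs.xr)
        + np.outer(truth.beta_c, regs.xc)
    )
    amp[:, keep] = signal_scale * band_amp
    # 1/f-like neurovascular amplitudes strictly below 0.1 Hz
    lf = (freqs > 0) & (freqs < LOW_FREQ_CUTOFF_HZ)
    if lf.any() and lf_amplitude > 0:
        nb = regs.band_frequencies_hz.size
        amp[:, lf] = (
            signal_scale * lf_amplitude * (3.0 / nb) * (freqs[lf.argmax()] / freqs[lf])
        )

    phases = rng.uniform(0, 2 * np.pi, size=(n_vox, n_freq))
    phases[:, 0] = 0.0
    even = n_vol % 2 == 0
    if even:
        phases[:, -1] = 0.0  # Nyquist bin of a real series is real
    z = amp * np.exp(1j * phases)

    if truth.noise_scale > 0:
        sigma = truth.noise_scale * signal_scale * float(truth.alpha.mean())
        noise = sigma * (
            rng.standard_normal((n_vox, n_freq))
            + 1j * rng.standard_normal((n_vox, n_freq))
        )
        noise[:, 0] = 0.0
        if even:
            noise[:, -1] = noise[:, -1].real
        z = z + noise

    return np.fft.irfft(z, n=n_vol, axis=1)


def _time_domain_mix(truth, traces, signal_scale, rng):
    cardiac, respiratory = traces
    n_vol, tr = truth.n_volumes, truth.tr_seconds
    card = subsample_trace(cardiac, tr, n_vol).data[0]
    resp = subsample_trace(respiratory, tr, n_vol).data[0]
    card = card / max(np.abs(card).max(), 1e-12)
    resp = resp / max(np.abs(resp).max(), 1e-12)
    nb = truth.regressors.band_frequencies_hz.size
    noise_sd = truth.noise_scale * signal_scale * float(truth.alpha.mean()) + 1e-12
    data = (
        signal_scale * np.outer(truth.beta_c, card)
        + signal_scale * np.outer(truth.beta_r, resp)
        + noise_sd * np.sqrt(nb) * rng.standard_normal((truth.n_voxels, n_vol))
    )
    return data
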