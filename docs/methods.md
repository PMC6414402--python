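# Methods

## Signal model

A voxel's fast-TR EPI time series S(t₁…t_N) is demeaned and transformed to
its one-sided discrete Fourier spectrum; the quantity modelled is the FT
magnitude √(Re² + Im²) per frequency bin (an `output="power"` switch
returns the squared magnitude instead, but the amplitude is the default
throughout because the linear band model and its unit-sum normalization
are formulated on amplitudes). No apodization window and no detrending
beyond the mean are applied: the method's premise is that the raw spectral
content above the neurovascular regime is the signal of interest, and any
tapering would smear the narrow cardiac peaks that the model keys on.

The physiological band is [f_min, f_Nyq] with f_min = 0.2 Hz (inclusive at
both ends) and f_Nyq = 1/(2·TR). Band spectra and both physiological
regressors are normalized to unit sum over the band, making voxels and
subjects with different absolute signal levels comparable; the flat
baseline column is left at 1 per bin, so noiseless coefficients obey
α·N_b + β_r + β_c = 1. This coupling is intentional and is why the
complementary coefficient is offered as a covariate in group analyses.

External traces are decimated to the scan TR by taking the nearest trace
sample at each volume onset time, without anti-alias filtering: the
folding of above-Nyquist cardiac harmonics to |f − n·f_s| is part of the
physics being modelled, and the informed initializer must alias exactly as
the EPI sampling does. Volume onset (rather than centre) is the assumed
sampling phase; the two differ by a half-TR delay that leaves amplitude
spectra unchanged.

## Estimation

The spatial GLM is unweighted per-voxel OLS of the normalized band
spectrum on [1, X_r, X_c]; designs with condition number above 1e8 are
rejected. Significance per coefficient uses the two-sided t statistic with
N_b − 3 degrees of freedom; a one-sided (β > 0) option exists because
physiological power contributions are nonnegative, but two-sided is the
default since the fit itself is unconstrained and negative estimates are
possible. No correction across voxels is applied by default (a fixed
p < 0.01 per voxel is the convention mirrored here); a Benjamini–Hochberg
helper (`fdr_adjust`) is provided for users who want it.

The frequency GLM solves, jointly for the three spectrum rows, the
least-squares system P[s,f] ≈ α[s]·b[f] + β_r[s]·X_r[f] + β_c[s]·X_c[f]
across voxels. Three post-steps make the result a valid set of
regressors: the baseline row is reset to constant 1 (a non-flat thermal
baseline would contradict the white-noise premise), negative entries of
X_r and X_c are clipped to zero (amplitude spectra are physically
nonnegative), and each row is renormalized to unit band sum. The
renormalization is applied every iteration, not only at convergence: the
spatial-GLM coefficient scale is only stable if its regressors keep a
fixed normalization, and without it the coupled scales drift.

Convergence requires the L1 change of the cardiac **and** the respiratory
spectrum to fall below the tolerance (default 0.01) in the same iteration
— the strict reading of convergence for two refined spectra. Hitting
`max_iter` (default 50) yields a flagged, non-converged result rather than
an error, and the final coefficient maps are always refit against the
final spectra.

The data-driven initializer needs one shared spectrum per regressor, so it
uses the mask-average band spectrum, zeroed above (respiratory) or at and
below (cardiac) the 0.6 Hz split and renormalized; a bin exactly at the
split goes to the respiratory side. Ties in dominant-frequency searches
break toward the lower frequency.

## Metrics

Tissue masks binarize PVE maps at a strict pve > 0.7. The weighted mean
⟨β⟩ and spatial extent R follow the definitions in the README; an empty
joint selection (no voxel both in-mask and significant) raises a distinct
`EmptySelectionError` rather than returning 0, and the report serializes
it as null. Mask overlap defaults to Jaccard (100·|A∩B|/|A∪B|) with an
intersection-over-smaller option, since "overlap" is ambiguous; both can
be reported. The windowed pulsatility metric operates on the normalized
band spectrum (comparable across voxels and subjects) and clips its
0.04 Hz window at the band edges rather than failing; it is computed both
over all mask voxels and over the significantly cardiac-modulated subset.
Partial correlation residualizes both variables on the covariates (plus
intercept) by OLS and correlates the residuals, with n − k − 2 degrees of
freedom.

## Synthetic data generator

The generator emulates a fast-TR scan (TR 0.328 s; the full study length
is 2200 volumes, while tests and the acceptance script use 512 volumes and
grids of 72–2048 voxels to keep runs fast — problem sizes are stated with
each result). Per voxel, band amplitudes are assembled as
α + β_r·X_r + β_c·X_c, with maps satisfying the coupling identity; random
phases are attached and the one-sided spectrum inverse-transformed to a
real series. A 1/f-like component below 0.1 Hz exercises the f_min cut,
and complex Gaussian frequency-bin noise (standard deviation 0.3× the
mean baseline amplitude by default) plays the role of measurement
variability. Frequency-domain synthesis makes the GLM hold exactly at zero
noise, so recovery tests are sharp; a `mode="time_domain"` variant mixes
the actual trace waveforms plus white noise instead, at the cost of only
approximate ground-truth coefficients.

The matched external traces are quasi-periodic waveforms — fundamental
plus harmonics with 1/h amplitude decay and a slowly drifting
instantaneous rate — at resting-adult defaults: cardiac 1.1 Hz,
respiratory 0.3 Hz, 3 harmonics, 3% rate drift at 0.05 Hz. The generating
X_r/X_c are the band spectra of these traces, so they carry realistic
harmonic and alias structure (the cardiac second and third harmonics fold
to 0.85 and 0.25 Hz at this TR). Active-voxel fractions default to 35%
(cardiac) and 45% (respiratory) with coefficients uniform on 0.05–0.35 and
0.05–0.30; PVE values are Beta(5,2), so most voxels clear the 0.7 tissue
threshold as in a well-segmented mask.

What the generator does **not** emulate: motion, distortion, multiband
slice leakage, spatial autocorrelation, heart-rate variability beyond the
sinusoidal drift, or genuinely Rician voxel statistics at low SNR. Passing
tests therefore demonstrate correctness of the estimation machinery under
the stated model, not robustness to real-scanner artifacts.

## Numerical and design notes

* Rows with zero band power cannot be normalized and are rejected with
  their indices; callers exclude them from the mask.
* Rank checks use condition number 1e8 on both GLM directions; a
  coefficient map that is identically zero (e.g. β_c = 0 everywhere)
  rejects refinement rather than silently returning noise.
* Voxel extraction from volumes is the C-order scan of the mask and
  round-trips exactly; written maps use 0 as background with an explicit
  mask file, avoiding NaN-handling differences across NIfTI consumers.
* The magnitude of signal-plus-complex-noise is Rician, so the *effective*
  mean spectrum of noisy data has a slightly inflated floor relative to
  the generating spectra. The data-driven loop converges to that
  data-adapted fixed point while an informed start that already satisfies
  the tolerance stops closer to the generating spectra. At high spectral
  degrees of freedom (long scans) or small voxel samples this can shift
  borderline significance calls between the two modes; informed vs
  data-driven mask agreement is therefore assessed at a realistic
  tissue-mask size (~2000 voxels), where it is stable.
* The significant-only pulsatility metric retains a weak residual trend in
  extent-varying cohorts because p-thresholded masks include ~1%
  false-positive voxels whose near-floor power dilutes small masks more
  than large ones; the robust form of the extent/amplitude dissociation is
  that the all-voxel metric's trend loses significance once spatial extent
  is controlled for as a covariate, and both forms are computed.
* All randomness flows through numpy `SeedSequence`; regenerating with the
  same seed reproduces every downstream number bit-exactly.

## Limitations

Within-subject, per-tissue analysis only: no group-level dual regression,
no registration/motion machinery (delegated to standard preprocessing),
and no spatial smoothing or regularization of coefficient maps. The
convergence tolerance is an absolute L1 threshold on unit-sum spectra, so
its meaning scales with the number of band bins; very long scans may
warrant a proportionally tighter tolerance.
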