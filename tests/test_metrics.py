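"""Summary metrics: weighted means, extents, pulsatility, overlap, partials."""

import numpy as np
import pytest

from physpec import (
    BandSpectrumSet,
    EmptySelectionError,
    TissueMask,
    cardiac_pulsatility_metric,
    mask_overlap,
    mean_pe,
    partial_correlation,
    spatial_extent,
    summarize_metrics,
)
from physpec.glm import PEMaps

from conftest import make_regressors


def pe_maps_from(beta_c, p_beta_c, beta_r=None, p_beta_r=None):
    n = len(beta_c)
    ones = np.ones(n)
    zeros = np.zeros(n)
    return PEMaps(
        alpha=np.full(n, 0.01), beta_r=np.asarray(beta_r if beta_r is not None else zeros, float),
        beta_c=np.asarray(beta_c, float),
        se_alpha=ones, se_beta_r=ones, se_beta_c=ones,
        t_alpha=zeros, t_beta_r=zeros, t_beta_c=zeros,
        p_alpha=np.full(n, 0.5),
        p_beta_r=np.asarray(p_beta_r if p_beta_r is not None else np.full(n, 0.5), float),
        p_beta_c=np.asarray(p_beta_c, float),
        residual_rms=zeros, dof=10,
    )


class TestMeanPE:
    def test_hand_arithmetic(self):
        pe = pe_maps_from([2.0, 4.0], [0.001, 0.001])
        mask = TissueMask([0.8, 0.8])
        assert mean_pe(pe, mask, "beta_c") == pytest.approx(3.0)

    def test_single_significant_voxel_returns_its_value(self):
        pe = pe_maps_from([2.0, 4.0], [0.5, 0.001])
        mask = TissueMask([0.9, 0.75])
        assert mean_pe(pe, mask, "beta_c") == pytest.approx(4.0)

    def test_empty_selection_raises(self):
        pe = pe_maps_from([2.0, 4.0], [0.5, 0.02])
        mask = TissueMask([0.9, 0.9])
        with pytest.raises(EmptySelectionError):
            mean_pe(pe, mask, "beta_c")

    def test_invariant_to_duplicating_every_voxel(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(size=20)
        p = rng.uniform(0, 0.02, 20)
        pve = rng.uniform(0.5, 1.0, 20)
        pe1 = pe_maps_from(beta, p)
        pe2 = pe_maps_from(np.tile(beta, 2), np.tile(p, 2))
        m1 = mean_pe(pe1, TissueMask(pve), "beta_c")
        m2 = mean_pe(pe2, TissueMask(np.tile(pve, 2)), "beta_c")
        assert m1 == pytest.approx(m2)


class TestSpatialExtent:
    def test_all_and_none_significant(self):
        pve = [0.8, 0.9, 1.0]
        pe_all = pe_maps_from([1, 1, 1], [0.001] * 3)
        pe_none = pe_maps_from([1, 1, 1], [0.5] * 3)
        assert spatial_extent(pe_all, TissueMask(pve), "beta_c") == 1.0
        assert spatial_extent(pe_none, TissueMask(pve), "beta_c") == 0.0

    def test_hand_arithmetic(self):
        pe = pe_maps_from([1, 1, 1], [0.5, 0.5, 0.001])
        assert spatial_extent(pe, TissueMask([0.8, 0.9, 1.0]), "beta_c") == pytest.approx(
            1.0 / 2.7
        )

    def test_monotone_in_p_threshold(self):
        rng = np.random.default_rng(1)
        pe = pe_maps_from(rng.normal(size=50), rng.uniform(0, 1, 50))
        mask = TissueMask(rng.uniform(0.5, 1.0, 50))
        extents = [
            spatial_extent(pe, mask, "beta_c", p_threshold=p)
            for p in (0.001, 0.01, 0.05, 0.2, 1.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(extents, extents[1:]))

    def test_empty_tissue_mask_rejected(self):
        pe = pe_maps_from([1.0, 1.0], [0.001, 0.001])
        with pytest.raises(ValueError, match="empty tissue mask"):
            spatial_extent(pe, TissueMask([0.1, 0.2]), "beta_c")


class TestPulsatilityMetric:
    def test_flat_spectrum_gives_inverse_bin_count(self):
        rng = np.random.default_rng(2)
        regs = make_regressors(rng, 40)
        nb = 40
        rows = np.full((3, nb), 1.0 / nb)
        spectra = BandSpectrumSet(rows, regs.band_frequencies_hz, 0.2, normalized=True)
        assert cardiac_pulsatility_metric(spectra, regs) == pytest.approx(1.0 / nb)

    def test_single_tone_window_of_one_bin(self):
        freqs = np.array([0.2, 0.7, 1.2, 1.7])  # spacing 0.5 >> window
        xc = np.array([0.0, 0.0, 1.0, 0.0])
        xr = np.array([1.0, 0.0, 0.0, 0.0])
        from physpec import SpectralRegressors

        regs = SpectralRegressors(np.ones(4), xr, xc, freqs)
        row = np.array([0.1, 0.1, 0.7, 0.1])
        spectra = BandSpectrumSet(row[None], freqs, 0.2, normalized=True)
        assert cardiac_pulsatility_metric(spectra, regs) == pytest.approx(0.7)

    def test_window_clipped_at_band_edge(self):
        freqs = np.array([0.2, 0.21, 0.22, 0.23])
        xc = np.array([1.0, 0.0, 0.0, 0.0])  # dominant at the lower edge
        from physpec import SpectralRegressors

        regs = SpectralRegressors(np.ones(4), np.full(4, 0.25), xc, freqs)
        row = np.array([0.4, 0.3, 0.2, 0.1])
        spectra = BandSpectrumSet(row[None], freqs, 0.2, normalized=True)
        # window 0.04 Hz around 0.2 covers bins at 0.2, 0.21, 0.22
        expected = row[:3].mean()
        assert cardiac_pulsatility_metric(spectra, regs, window_hz=0.04) == pytest.approx(
            expected
        )

    def test_extent_growth_drives_all_voxel_metric_only(self):
        """A cohort whose active-voxel fraction grows (identical per-voxel
        amplitude) raises the all-voxel metric while the significant-only
        metric stays flat."""
        rng = np.random.default_rng(3)
        nb = 50
        regs = make_regressors(rng, nb)
        fractions = np.linspace(0.1, 0.6, 8)  # the "cohort variable"
        all_voxel, sig_only = [], []
        for frac in fractions:
            n = 200
            active = rng.random(n) < frac
            rows = np.full((n, nb), 1.0 / nb)
            rows[active] = 0.4 / nb + 0.6 * regs.xc  # same amplitude everywhere
            spectra = BandSpectrumSet(rows, regs.band_frequencies_hz, 0.2,
                                      normalized=True)
            all_voxel.append(cardiac_pulsatility_metric(spectra, regs))
            sig_only.append(cardiac_pulsatility_metric(spectra, regs, active))
        r_all = np.corrcoef(fractions, all_voxel)[0, 1]
        assert r_all > 0.9
        assert np.ptp(sig_only) < 1e-12


class TestMaskOverlap:
    def test_identical_and_disjoint(self):
        a = np.array([1, 1, 0, 0], bool)
        assert mask_overlap(a, a) == 100.0
        assert mask_overlap(a, ~a) == 0.0

    def test_nine_of_ten(self):
        a = np.zeros(20, bool)
        b = np.zeros(20, bool)
        a[:10] = True
        b[1:11] = True  # |A∩B| = 9, |A∪B| = 11... adjust to union 10
        b = a.copy()
        b[0] = False  # |A∩B| = 9, |A∪B| = 10
        assert mask_overlap(a, b) == pytest.approx(90.0)

    def test_min_denominator_option(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:6] = True
        b[:3] = True
        assert mask_overlap(a, b, method="min") == pytest.approx(100.0)
        assert mask_overlap(a, b, method="jaccard") == pytest.approx(50.0)

    def test_both_empty_undefined(self):
        z = np.zeros(5, bool)
        with pytest.raises(EmptySelectionError):
            mask_overlap(z, z)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 30))
        r, p = partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_six_point_two_stage_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        z = np.array([0.5, 1.5, 1.0, 3.0, 2.0, 4.0])
        Z = np.column_stack([np.ones(6), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        expected = np.corrcoef(rx, ry)[0, 1]
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x, y, c1, c2 = rng.normal(size=(4, 25))
        df = pd.DataFrame({"x": x, "y": y, "c1": c1, "c2": c2})
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        r, p = partial_correlation(x, y, np.column_stack([c1, c2]))
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_exact_linear_dependence_is_undefined(self):
        x = np.arange(10.0)
        z = np.arange(10.0) * 2 + 1
        y = 3 * z + 2  # y is exactly linear in the covariate
        with pytest.raises(EmptySelectionError):
            partial_correlation(x, y, z)


def test_summarize_reports_none_on_empty_selection():
    pe = pe_maps_from([1.0, 2.0], [0.5, 0.5], beta_r=[1.0, 1.0], p_beta_r=[0.001, 0.5])
    mask = TissueMask([0.9, 0.9])
    report = summarize_metrics(pe, mask)
    assert report.mean_beta_c is None
    assert report.mean_beta_r == pytest.approx(1.0)
    assert report.extent_c == 0.0
    assert report.n_significant_beta_r == 1
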