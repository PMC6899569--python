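"""Raman preprocessing, phosphate deconvolution, and fold conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimorphbone.phantom import RamanBand, RamanPhantomSpec, generate_raman_dataset
from dimorphbone.raman import (DeconvolutionConfig, RamanSpectrum,
                               deconvolve_phosphate, mineral_matrix_ratio,
                               normalize, preprocess, signed_fold_change)

BANDS = [
    RamanBand("ACP", 948.0, area=0.4, sigma_cm1=2.0, gaussian_fraction=0.85),
    RamanBand("OCP", 955.0, area=0.5, sigma_cm1=2.0, gaussian_fraction=0.85),
    RamanBand("CAP", 962.0, area=0.6, sigma_cm1=2.0, gaussian_fraction=0.85),
    RamanBand("PHE", 1004.0, area=1.0, sigma_cm1=2.5),
    RamanBand("amide3", 1280.0, area=0.6, sigma_cm1=10.0),
    RamanBand("CH2", 1450.0, area=0.8, sigma_cm1=4.0),
    RamanBand("amide1", 1660.0, area=1.0, sigma_cm1=8.0),
]


def _dataset(n=1, noise=0.01, spikes=0, jitter=0.0, seed=0, bands=BANDS,
             baseline=(5.0, 1.5, -0.8, 0.3)):
    spec = RamanPhantomSpec(bands=list(bands), baseline_coeffs=list(baseline),
                            noise_sigma_rel=noise, cosmic_spike_count=spikes,
                            area_jitter_cv=jitter, n_spectra=n, seed=seed)
    return generate_raman_dataset(spec)


class TestPreprocess:
    def test_pure_polynomial_baseline_removed(self):
        spectra, _ = _dataset(noise=0.0, bands=[])
        out = preprocess(spectra[0], despike=False, denoise=False)
        assert np.max(np.abs(out.intensity)) < 0.01 * np.max(spectra[0].intensity)

    def test_band_heights_preserved(self):
        spectra, truth = _dataset(noise=0.01, seed=2)
        out = preprocess(spectra[0])
        wn = out.wavenumbers
        for band in BANDS:
            from dimorphbone.phantom.raman import pseudo_voigt
            true_height = pseudo_voigt(np.array([band.center_cm1]),
                                       truth.iloc[0][f"area_{band.name}"],
                                       band.center_cm1, band.sigma_cm1,
                                       band.gaussian_fraction)[0]
            got = out.intensity[np.abs(wn - band.center_cm1) <= 2.0].max()
            assert got == pytest.approx(true_height, rel=0.05)

    def test_cosmic_spike_removed_without_disturbing_neighbors(self):
        clean, _ = _dataset(noise=0.01, spikes=0, seed=3)
        spiked, _ = _dataset(noise=0.01, spikes=1, seed=3)
        out_clean = preprocess(clean[0])
        out_spiked = preprocess(spiked[0])
        sigma = 0.01 * max(b.area for b in BANDS)  # order of the noise scale
        assert np.max(np.abs(out_spiked.intensity - out_clean.intensity)) < 5 * sigma

    def test_preprocessing_is_idempotent(self):
        # processing-state flags mean a second pass applies no stage again
        spectra, _ = _dataset(noise=0.01, seed=4)
        once = preprocess(spectra[0])
        again = preprocess(once)
        scale = np.max(np.abs(once.intensity))
        assert np.max(np.abs(again.intensity - once.intensity)) < 0.01 * scale
        np.testing.assert_allclose(again.intensity, once.intensity)

    def test_axis_must_cover_fingerprint(self):
        wn = np.linspace(800, 1600, 801)
        with pytest.raises(ValueError):
            preprocess(RamanSpectrum(wn, np.ones_like(wn)))


class TestNormalize:
    def test_phenylalanine_peak_scaled_to_one(self):
        spectra, _ = _dataset(seed=5)
        out = normalize(preprocess(spectra[0]))
        win = np.abs(out.wavenumbers - 1004.0) <= 5.0
        assert out.intensity[win].max() == pytest.approx(1.0)

    def test_intensity_scale_invariance(self):
        spectra, _ = _dataset(seed=6)
        s = preprocess(spectra[0])
        doubled = RamanSpectrum(s.wavenumbers, 2.0 * s.intensity,
                                baseline_corrected=True)
        np.testing.assert_allclose(normalize(s).intensity,
                                   normalize(doubled).intensity)

    def test_nonpositive_reference_rejected(self):
        wn = np.linspace(600, 1750, 1151)
        with pytest.raises(ValueError):
            normalize(RamanSpectrum(wn, np.zeros_like(wn)))


class TestDeconvolve:
    def test_zero_spectrum_gives_zero_areas(self):
        wn = np.linspace(600, 1750, 2301)
        fit = deconvolve_phosphate(RamanSpectrum(wn, np.zeros_like(wn)))
        assert fit.phosphate_envelope_area == pytest.approx(0.0, abs=1e-6)

    def test_two_overlapping_gaussians_resolved(self):
        # 1:3 area ratio, strongly overlapping: areas within 5 percent
        bands = [RamanBand("ACP", 948.0, area=1.0, sigma_cm1=2.0,
                           gaussian_fraction=0.85),
                 RamanBand("CAP", 962.0, area=3.0, sigma_cm1=2.0,
                           gaussian_fraction=0.85)]
        spectra, _ = _dataset(noise=0.0, bands=bands, baseline=(0.0,))
        fit = deconvolve_phosphate(spectra[0])
        assert fit.species_areas["ACP"] == pytest.approx(1.0, rel=0.05)
        assert fit.species_areas["CAP"] == pytest.approx(3.0, rel=0.05)

    def test_species_recovery_through_full_pipeline(self):
        spectra, truth = _dataset(noise=0.005, seed=7)
        out = preprocess(spectra[0])
        fit = deconvolve_phosphate(out)
        for name in ("ACP", "OCP", "CAP"):
            assert fit.species_areas[name] == pytest.approx(
                truth.iloc[0][f"area_{name}"], rel=0.10)

    def test_envelope_area_conservation(self):
        spectra, _ = _dataset(noise=0.005, seed=8)
        out = preprocess(spectra[0])
        fit = deconvolve_phosphate(out)
        wn, y = out.wavenumbers, out.intensity
        sel = (wn >= 940.0) & (wn <= 975.0)
        integral = np.trapezoid(y[sel], wn[sel])
        assert fit.phosphate_envelope_area == pytest.approx(integral, rel=0.10)


class TestRatiosAndFolds:
    def test_equal_areas_give_unit_ratio(self):
        bands = [RamanBand("CAP", 962.0, area=1.0, sigma_cm1=2.0),
                 RamanBand("amide1", 1660.0, area=1.0, sigma_cm1=8.0)]
        spectra, _ = _dataset(noise=0.0, bands=bands, baseline=(0.0,))
        fit = deconvolve_phosphate(spectra[0])
        assert mineral_matrix_ratio(fit) == pytest.approx(1.0, rel=0.05)

    def test_no_phosphate_gives_zero_ratio(self):
        bands = [RamanBand("amide1", 1660.0, area=1.0, sigma_cm1=8.0)]
        spectra, _ = _dataset(noise=0.0, bands=bands, baseline=(0.0,))
        fit = deconvolve_phosphate(spectra[0])
        assert mineral_matrix_ratio(fit) == pytest.approx(0.0, abs=1e-4)

    def test_hand_computed_folds(self):
        assert signed_fold_change(2.0, 3.0) == pytest.approx(-1.5)
        assert signed_fold_change(3.0, 2.0) == pytest.approx(1.5)
        assert signed_fold_change(1.0, 1.0) == 1.0

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(0.0, 1.0)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    def test_fold_antisymmetry(self, a, b):
        fab = signed_fold_change(a, b)
        fba = signed_fold_change(b, a)
        assert abs(fab) >= 1.0
        if a != b:
            assert fab == pytest.approx(-fba)
        else:
            assert fab == fba == 1.0
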