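"""Synthetic cell Raman spectra: baseline + pseudo-Voigt bands + noise.

A spectrum is a polynomial baseline (degree <= 9, coefficients in a domain
scaled to [-1, 1]) plus area-parameterised pseudo-Voigt bands, Gaussian
noise, and optional one-point cosmic-ray spikes. Band areas are jittered
per spectrum (log-normal, small CV) to emulate cell-to-cell variability;
the per-spectrum realised areas are stored in the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..raman import RamanSpectrum

__all__ = ["RamanBand", "RamanPhantomSpec", "pseudo_voigt", "generate_raman_dataset"]

FINGERPRINT = (600.0, 1750.0)


def pseudo_voigt(x: np.ndarray, area: float, center: float, sigma: float,
                 gaussian_fraction: float) -> np.ndarray:
    """Area-normalised pseudo-Voigt: shared-FWHM Gaussian/Lorentzian mix.

    ``sigma`` is the half width at half maximum of both components
    (FWHM = 2 sigma); ``gaussian_fraction`` weights the Gaussian component.
    """
    sg = sigma / np.sqrt(2.0 * np.log(2.0))
    g = np.exp(-((x - center) ** 2) / (2.0 * sg ** 2)) / (sg * np.sqrt(2.0 * np.pi))
    lor = (sigma / np.pi) / ((x - center) ** 2 + sigma ** 2)
    return area * (gaussian_fraction * g + (1.0 - gaussian_fraction) * lor)


@dataclass
class RamanBand:
    name: str
    center_cm1: float
    area: float
    sigma_cm1: float = 3.0
    gaussian_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not (FINGERPRINT[0] <= self.center_cm1 <= FINGERPRINT[1]):
            raise ValueError(f"band {self.name}: center {self.center_cm1} "
                             f"outside {FINGERPRINT}")
        if self.sigma_cm1 <= 0:
            raise ValueError(f"band {self.name}: width must be > 0")
        if self.area < 0:
            raise ValueError(f"band {self.name}: area must be >= 0")


@dataclass
class RamanPhantomSpec:
    bands: list[RamanBand] = field(default_factory=list)
    baseline_coeffs: list[float] = field(default_factory=lambda: [0.0])
    noise_sigma_rel: float = 0.01     # x reference peak height (see below)
    noise_reference_band: str | None = "PHE"
    area_jitter_cv: float = 0.05
    cosmic_spike_count: int = 0
    spike_amplitude_sigmas: float = 50.0
    n_spectra: int = 1
    wavenumber_step_cm1: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.baseline_coeffs) > 10:
            raise ValueError("baseline polynomial degree must be <= 9")
        if self.noise_sigma_rel < 0 or self.cosmic_spike_count < 0:
            raise ValueError("noise and spike parameters must be >= 0")

    def wavenumbers(self) -> np.ndarray:
        n = int(round((FINGERPRINT[1] - FINGERPRINT[0]) / self.wavenumber_step_cm1)) + 1
        return np.linspace(*FINGERPRINT, n)


def generate_raman_dataset(
    spec: RamanPhantomSpec,
) -> tuple[list[RamanSpectrum], pd.DataFrame]:
    """Generate ``n_spectra`` spectra plus a per-spectrum truth table.

    The truth table has one row per spectrum with the realised (jittered)
    area of every band, keyed ``area_<band name>``.
    """
    rng = np.random.default_rng(spec.seed)
    wn = spec.wavenumbers()
    x_scaled = 2.0 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1.0
    baseline = np.polynomial.polynomial.polyval(x_scaled,
                                                np.asarray(spec.baseline_coeffs))
    # noise is scaled to a reference peak height (the phenylalanine band when
    # present), emulating constant instrument noise across groups that differ
    # in their strongest mineral band
    ref_bands = [b for b in spec.bands
                 if b.name == spec.noise_reference_band] or spec.bands
    if ref_bands:
        clean_ref = sum((pseudo_voigt(wn, b.area, b.center_cm1, b.sigma_cm1,
                                      b.gaussian_fraction) for b in ref_bands),
                        np.zeros_like(wn))
        peak = float(clean_ref.max())
    else:
        peak = 1.0
    sigma = spec.noise_sigma_rel * peak

    spectra: list[RamanSpectrum] = []
    rows = []
    for i in range(spec.n_spectra):
        row = {"spectrum_id": i}
        signal = baseline.copy()
        for b in spec.bands:
            jitter = rng.lognormal(0.0, spec.area_jitter_cv) \
                if spec.area_jitter_cv > 0 else 1.0
            area = b.area * jitter
            row[f"area_{b.name}"] = area
            signal = signal + pseudo_voigt(wn, area, b.center_cm1, b.sigma_cm1,
                                           b.gaussian_fraction)
        if sigma > 0:
            signal = signal + rng.normal(0.0, sigma, size=wn.shape)
        for _ in range(spec.cosmic_spike_count):
            signal[rng.integers(0, len(wn))] += spec.spike_amplitude_sigmas * \
                max(sigma, 1e-3 * peak)
        spectra.append(RamanSpectrum(wavenumbers=wn.copy(), intensity=signal))
        rows.append(row)
    return spectra, pd.DataFrame(rows)
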