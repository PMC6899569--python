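"""Raman preprocessing and phosphate-band deconvolution.

The pipeline mirrors common practice for cell/bone spectra in the
fingerprint region (600-1750 cm^-1): cosmic-ray despiking, wavelet
soft-threshold denoising, iterative 9th-order polynomial baseline
subtraction, normalisation to the 1004 cm^-1 phenylalanine peak, then
least-squares pseudo-Voigt deconvolution of the v1 phosphate envelope
(940-975 cm^-1) into amorphous calcium phosphate (ACP ~950), octacalcium
phosphate (OCP ~955) and carbonated apatite (CAP ~961) sub-bands. Matrix
bands (amide I, CH2 at 1450, amide III) are fitted for the
mineral-to-matrix denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from lmfit.models import ConstantModel, PseudoVoigtModel

__all__ = [
    "RamanSpectrum",
    "BandConfig",
    "DeconvolutionConfig",
    "BandFit",
    "preprocess",
    "normalize",
    "deconvolve_phosphate",
    "mineral_matrix_ratio",
    "signed_fold_change",
]

FINGERPRINT = (600.0, 1750.0)


@dataclass
class RamanSpectrum:
    """One spectrum on a strictly increasing wavenumber axis (cm^-1)."""

    wavenumbers: np.ndarray
    intensity: np.ndarray
    despiked: bool = False
    denoised: bool = False
    baseline_corrected: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumbers.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    @classmethod
    def from_text(cls, path) -> "RamanSpectrum":
        """Read a two-column wavenumber/intensity text or CSV file."""
        data = np.loadtxt(path, delimiter=None if str(path).endswith(".txt") else ",")
        order = np.argsort(data[:, 0])
        return cls(data[order, 0], data[order, 1])

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavenumbers, self.intensity]),
                   fmt="%.6g", header="wavenumber_cm1 intensity")


@dataclass
class BandConfig:
    """One fitted sub-band: starting center, center window, width bounds."""

    center_cm1: float
    center_window_cm1: float = 2.0
    sigma_bounds_cm1: tuple[float, float] = (1.5, 5.0)


@dataclass
class DeconvolutionConfig:
    """Band assignments for phosphate species and matrix reference bands.

    Phosphate sub-band positions follow common bone-Raman usage; centers and
    windows are configuration, not constants, since assignments vary between
    instruments and references.
    """

    phosphate_region: tuple[float, float] = (940.0, 975.0)
    phosphate_bands: dict = field(default_factory=lambda: {
        "ACP": BandConfig(948.0, 1.0, (1.8, 2.2)),
        "OCP": BandConfig(955.0, 1.0, (1.8, 2.2)),
        "CAP": BandConfig(962.0, 1.0, (1.8, 2.2)),
    })
    matrix_bands: dict = field(default_factory=lambda: {
        "amide1": (BandConfig(1660.0, 10.0, (3.0, 25.0)), (1600.0, 1720.0)),
        "ch2": (BandConfig(1450.0, 5.0, (2.0, 12.0)), (1420.0, 1480.0)),
        "amide3": (BandConfig(1280.0, 20.0, (3.0, 30.0)), (1220.0, 1340.0)),
    })


@dataclass
class BandFit:
    """Fitted band areas for one spectrum.

    ``bands`` has one row per fitted band (name, center, sigma, fraction,
    area); ``species_areas`` maps ACP/OCP/CAP to areas; matrix areas are
    keyed by band name. Areas are in the (normalised) intensity units of the
    input spectrum times cm^-1.
    """

    bands: pd.DataFrame
    species_areas: dict
    matrix_areas: dict
    phosphate_envelope_area: float
    residual_rms: float


# ---------------------------------------------------------------------------
# preprocessing

def _despike(y: np.ndarray, z_max: float = 8.0) -> np.ndarray:
    """Remove isolated one-point positive outliers (cosmic rays).

    A sample is a spike only if it exceeds BOTH neighbours by ``z_max`` noise
    deviations — a smooth band apex never does, so genuine peaks are kept.
    """
    d = np.diff(y)
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    if sigma == 0 or len(y) < 3:
        return y.copy()
    left = np.concatenate([[y[1]], y[:-1]])
    right = np.concatenate([y[1:], [y[-2]]])
    spikes = (y - np.maximum(left, right)) > z_max * sigma
    out = y.copy()
    out[spikes] = 0.5 * (left + right)[spikes]
    return out


def _wavelet_denoise(y: np.ndarray, wavelet: str = "sym8",
                     level: int | None = None) -> np.ndarray:
    max_level = pywt.dwt_max_level(len(y), pywt.Wavelet(wavelet).dec_len)
    level = min(level or 5, max_level)
    if level < 1:
        return y.copy()
    coeffs = pywt.wavedec(y, wavelet, level=level)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    # BayesShrink: adaptive per-level threshold sigma^2/sigma_signal, far
    # gentler on genuine band coefficients than the universal threshold
    out = [coeffs[0]]
    for c in coeffs[1:]:
        sig_x = np.sqrt(max(float(np.var(c)) - sigma ** 2, 0.0))
        thr = sigma ** 2 / sig_x if sig_x > 0 else float(np.abs(c).max())
        out.append(pywt.threshold(c, thr, mode="soft"))
    return pywt.waverec(out, wavelet)[: len(y)]


def _iterative_polynomial_baseline(x: np.ndarray, y: np.ndarray,
                                   order: int = 9, max_iter: int = 100,
                                   tol: float = 1e-4) -> np.ndarray:
    """Iterative-polyfit baseline with noise-aware peak clipping.

    Refits while clipping intensities more than two noise deviations above the
    current fit: peak regions are progressively excluded while the fit keeps
    tracking the centre of the noise band (not its lower envelope), so
    subtraction is nearly unbiased and re-running it is close to a no-op.
    """
    xs = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    d = np.diff(y)
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    keep = np.ones_like(y, dtype=bool)
    fit = np.zeros_like(y)
    for _ in range(max_iter):
        coeffs = np.polynomial.polynomial.polyfit(xs[keep], y[keep], order)
        fit = np.polynomial.polynomial.polyval(xs, coeffs)
        new_keep = y <= fit + 2.0 * sigma
        if new_keep.sum() < 4 * (order + 1):
            break  # do not starve the fit of support points
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return fit


def preprocess(raw: RamanSpectrum, despike: bool = True, denoise: bool = True,
               baseline_order: int = 9) -> RamanSpectrum:
    """Despike, wavelet-denoise, subtract a polynomial baseline, and crop.

    The input axis must cover the fingerprint region (600-1750 cm^-1).
    Stages already recorded in the spectrum's processing-state flags are
    skipped, so re-processing a processed spectrum is a no-op.
    """
    wn, y = raw.wavenumbers, raw.intensity
    if wn[0] > FINGERPRINT[0] + 1.0 or wn[-1] < FINGERPRINT[1] - 1.0:
        raise ValueError(
            f"axis [{wn[0]:.0f}, {wn[-1]:.0f}] does not cover the "
            f"fingerprint region {FINGERPRINT}")
    if despike and not raw.despiked:
        y = _despike(y)
    if denoise and not raw.denoised:
        y = _wavelet_denoise(y)
    if not raw.baseline_corrected:
        y = y - _iterative_polynomial_baseline(wn, y, order=baseline_order)
    keep = (wn >= FINGERPRINT[0]) & (wn <= FINGERPRINT[1])
    return RamanSpectrum(wn[keep], y[keep],
                         despiked=despike or raw.despiked,
                         denoised=denoise or raw.denoised,
                         baseline_corrected=True,
                         normalized=raw.normalized)


def normalize(spectrum: RamanSpectrum, reference_cm1: float = 1004.0,
              half_window_cm1: float = 5.0) -> RamanSpectrum:
    """Scale so the local maximum near the phenylalanine peak equals 1."""
    wn = spectrum.wavenumbers
    win = np.abs(wn - reference_cm1) <= half_window_cm1
    if not win.any():
        raise ValueError(f"no samples within {half_window_cm1} cm^-1 of "
                         f"{reference_cm1} cm^-1")
    ref = float(spectrum.intensity[win].max())
    if ref <= 0:
        raise ValueError("non-positive normalisation reference intensity")
    return replace(spectrum, intensity=spectrum.intensity / ref, normalized=True)


# ---------------------------------------------------------------------------
# deconvolution

def _fit_bands(wn: np.ndarray, y: np.ndarray,
               bands: dict[str, BandConfig]) -> tuple[dict, pd.DataFrame, float]:
    """Least-squares pseudo-Voigt fit of named bands plus a constant offset."""
    model = ConstantModel(prefix="bl_")
    params = model.make_params(bl_c=0.0)
    for name, cfg in bands.items():
        pv = PseudoVoigtModel(prefix=f"{name}_")
        model = model + pv
        params.update(pv.make_params())
        params[f"{name}_center"].set(value=cfg.center_cm1,
                                     min=cfg.center_cm1 - cfg.center_window_cm1,
                                     max=cfg.center_cm1 + cfg.center_window_cm1)
        params[f"{name}_sigma"].set(value=np.mean(cfg.sigma_bounds_cm1),
                                    min=cfg.sigma_bounds_cm1[0],
                                    max=cfg.sigma_bounds_cm1[1])
        params[f"{name}_amplitude"].set(value=max(float(np.ptp(y)), 1e-6), min=0.0)
        params[f"{name}_fraction"].set(value=0.5, min=0.0, max=1.0)
    result = model.fit(y, params, x=wn)
    if not result.success:
        raise RuntimeError(
            f"band fit did not converge: {result.message}; "
            f"residual RMS {np.sqrt(np.mean(result.residual ** 2)):.3g}")
    areas = {name: float(result.params[f"{name}_amplitude"].value)
             for name in bands}
    rows = [{
        "name": name,
        "center_cm1": float(result.params[f"{name}_center"].value),
        "sigma_cm1": float(result.params[f"{name}_sigma"].value),
        "gaussian_fraction": 1.0 - float(result.params[f"{name}_fraction"].value),
        "area": areas[name],
    } for name in bands]
    rms = float(np.sqrt(np.mean(result.residual ** 2)))
    return areas, pd.DataFrame(rows), rms


def deconvolve_phosphate(spectrum: RamanSpectrum,
                         config: DeconvolutionConfig | None = None) -> BandFit:
    """Fit phosphate sub-bands (ACP/OCP/CAP) and matrix reference bands."""
    config = config or DeconvolutionConfig()
    wn, y = spectrum.wavenumbers, spectrum.intensity

    lo, hi = config.phosphate_region
    sel = (wn >= lo) & (wn <= hi)
    if sel.sum() < 4 * len(config.phosphate_bands):
        raise ValueError("too few samples in the phosphate region to fit")
    species, band_rows, rms = _fit_bands(wn[sel], y[sel], config.phosphate_bands)

    matrix_areas = {}
    frames = [band_rows]
    for name, (cfg, (mlo, mhi)) in config.matrix_bands.items():
        msel = (wn >= mlo) & (wn <= mhi)
        areas, rows, _ = _fit_bands(wn[msel], y[msel], {name: cfg})
        matrix_areas[name] = areas[name]
        frames.append(rows)

    return BandFit(
        bands=pd.concat(frames, ignore_index=True),
        species_areas=species,
        matrix_areas=matrix_areas,
        phosphate_envelope_area=float(sum(species.values())),
        residual_rms=rms,
    )


def mineral_matrix_ratio(fit: BandFit, matrix_band: str = "amide1") -> float:
    """Total v1 phosphate envelope area over the matrix (amide I) band area."""
    denom = fit.matrix_areas.get(matrix_band)
    if denom is None:
        raise KeyError(f"matrix band {matrix_band!r} was not fitted")
    if denom == 0:
        raise ZeroDivisionError("matrix band area is zero")
    return fit.phosphate_envelope_area / denom


def signed_fold_change(mean_a: float, mean_b: float) -> float:
    """Signed fold of A vs B: +A/B if A >= B, else -B/A (reciprocal for drops)."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("group means must be positive")
    return mean_a / mean_b if mean_a >= mean_b else -mean_b / mean_a
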