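"""Spectral pre-processing: Fourier smoothing, baseline correction, NADH normalization.

The processing chain applied to every recorded spectrum, in fixed order:

1. **Fourier smoothing** — FFT the intensities, zero the highest-frequency
   fraction of bins (the ``smoothing_fraction``), inverse FFT.  A
   raised-cosine taper over the outermost 10% of the retained band
   suppresses ringing.  The DC bin is always kept, so the spectral mean is
   preserved.
2. **Two-point baseline correction** — subtract the straight line through
   the intensities at two anchor wavelengths (default: first and last grid
   points).  Negative residuals are retained; clipping would bias the
   area-under-curve metric.
3. **Normalization** — divide by the global maximum.  In wound tissue
   autofluorescence the global maximum is the NADH emission peak
   (~455 nm); if the maximum falls outside the expected NADH window the
   spectrum is flagged rather than rejected, since freshly wounded tissue
   can deviate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .spectra import Spectrum, SpectrumError


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the three-stage chain.

    smoothing_fraction
        Fraction of the highest-frequency FFT bins zeroed (0 disables
        smoothing entirely; 0.80 is the study default).
    baseline_anchor_lo / baseline_anchor_hi
        Anchor wavelengths in nm, or ``None`` for the spectrum endpoints.
    nadh_window
        Wavelength interval (nm) where the global maximum (NADH peak) is
        expected to lie.
    """

    smoothing_fraction: float = 0.80
    baseline_anchor_lo: float | None = None
    baseline_anchor_hi: float | None = None
    nadh_window: tuple[float, float] = (440.0, 470.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.smoothing_fraction <= 1.0:
            raise PreprocessError("smoothing_fraction must be in [0, 1]")
        lo, hi = self.baseline_anchor_lo, self.baseline_anchor_hi
        if lo is not None and hi is not None and lo >= hi:
            raise PreprocessError("baseline_anchor_lo must be < baseline_anchor_hi")
        if self.nadh_window[0] >= self.nadh_window[1]:
            raise PreprocessError("nadh_window must be a proper interval")


@dataclass
class NormalizedSpectrum(Spectrum):
    """A preprocessed spectrum whose global maximum is exactly 1."""

    normalization_factor: float = 1.0
    nadh_peak_wavelength: float = float("nan")
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if abs(self.intensities.max() - 1.0) > 1e-12:
            raise PreprocessError("normalized spectrum must have max 1")


def fourier_smooth(spectrum: Spectrum, smoothing_fraction: float) -> Spectrum:
    """Low-pass filter via FFT bin truncation with a raised-cosine taper.

    Requires a uniform wavelength grid (the FFT frequency axis is only
    meaningful then); non-uniform spectra must go through
    :func:`collafluor.spectra.resample` first.
    """
    if not 0.0 <= smoothing_fraction <= 1.0:
        raise PreprocessError("smoothing_fraction must be in [0, 1]")
    if smoothing_fraction == 0.0:
        return spectrum
    if not spectrum.is_uniform():
        raise PreprocessError(
            "fourier_smooth requires a uniform wavelength grid; "
            "use collafluor.spectra.resample first"
        )
    y = spectrum.intensities
    coeffs = np.fft.rfft(y)
    n_bins = len(coeffs)
    # retain the lowest (1 - p) fraction of bins; DC always kept
    n_keep = max(1, int(round((1.0 - smoothing_fraction) * n_bins)))
    gain = np.zeros(n_bins)
    gain[:n_keep] = 1.0
    # raised-cosine rolloff over the outermost 10% of the retained band
    n_taper = int(np.floor(0.10 * n_keep))
    if n_taper > 0 and n_keep < n_bins:
        ramp = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, n_taper + 2)[1:-1]))
        gain[n_keep - n_taper : n_keep] = ramp
    gain[0] = 1.0
    smoothed = np.fft.irfft(coeffs * gain, n=len(y))
    return Spectrum(
        spectrum.wavelengths.copy(), smoothed, spectrum.meta, spectrum.ground_truth
    )


def smoothing_passband(n_samples: int, smoothing_fraction: float) -> tuple[int, int]:
    """(untapered_bins, kept_bins) of the filter for an n-sample signal.

    Useful to reason about which sinusoid frequencies pass unattenuated:
    rfft bin ``k`` corresponds to ``k`` cycles per record; bins strictly
    below ``untapered_bins - taper`` pass with unit gain.
    """
    n_bins = n_samples // 2 + 1
    n_keep = max(1, int(round((1.0 - smoothing_fraction) * n_bins)))
    n_taper = int(np.floor(0.10 * n_keep)) if n_keep < n_bins else 0
    return n_keep - n_taper, n_keep


def baseline_correct(
    spectrum: Spectrum,
    anchor_lo: float | None = None,
    anchor_hi: float | None = None,
) -> Spectrum:
    """Subtract the straight line through the two anchor-point intensities.

    Anchors default to the first and last wavelengths.  Each anchor reads
    the intensity at the single nearest grid point (no local averaging);
    the output is exactly zero at both anchor grid points.
    """
    wl = spectrum.wavelengths
    if anchor_lo is None:
        anchor_lo = wl[0]
    if anchor_hi is None:
        anchor_hi = wl[-1]
    if anchor_lo >= anchor_hi:
        raise PreprocessError("anchor_lo must be < anchor_hi")
    if anchor_lo < wl[0] or anchor_hi > wl[-1]:
        raise PreprocessError(
            f"anchors ({anchor_lo}, {anchor_hi}) outside coverage {spectrum.coverage}"
        )
    i_lo = int(np.argmin(np.abs(wl - anchor_lo)))
    i_hi = int(np.argmin(np.abs(wl - anchor_hi)))
    if i_lo == i_hi:
        raise PreprocessError("anchors resolve to the same grid point")
    x0, x1 = wl[i_lo], wl[i_hi]
    y0, y1 = spectrum.intensities[i_lo], spectrum.intensities[i_hi]
    line = y0 + (y1 - y0) * (wl - x0) / (x1 - x0)
    return Spectrum(
        wl.copy(), spectrum.intensities - line, spectrum.meta, spectrum.ground_truth
    )


def normalize_max(
    spectrum: Spectrum, nadh_window: tuple[float, float] = (440.0, 470.0)
) -> NormalizedSpectrum:
    """Scale intensities so the global maximum is exactly 1.

    Records the wavelength of the maximum (the presumed NADH peak; ties
    resolve to the lower wavelength) and flags a warning when it falls
    outside ``nadh_window`` instead of assuming the normalization target.
    """
    y = spectrum.intensities
    peak = float(y.max())
    # 1e-12 threshold catches the numerically-zero residue a perfectly
    # linear spectrum leaves after baseline correction
    if peak <= 1e-12:
        raise PreprocessError("normalization undefined: maximum intensity <= 0")
    i_max = int(np.argmax(y))  # argmax takes the first (lowest-wavelength) tie
    peak_wl = float(spectrum.wavelengths[i_max])
    warn: list[str] = []
    if not (nadh_window[0] <= peak_wl <= nadh_window[1]):
        warn.append(
            f"global maximum at {peak_wl:.1f} nm outside NADH window {nadh_window}"
        )
    return NormalizedSpectrum(
        wavelengths=spectrum.wavelengths.copy(),
        intensities=y / peak,
        meta=spectrum.meta,
        ground_truth=spectrum.ground_truth,
        normalization_factor=peak,
        nadh_peak_wavelength=peak_wl,
        warnings=warn,
    )


def preprocess(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> NormalizedSpectrum:
    """Full chain: smooth -> baseline-correct -> normalize, in that order."""
    cfg = config or PreprocessConfig()
    smoothed = fourier_smooth(spectrum, cfg.smoothing_fraction)
    corrected = baseline_correct(
        smoothed, cfg.baseline_anchor_lo, cfg.baseline_anchor_hi
    )
    nspec = normalize_max(corrected, cfg.nadh_window)
    nspec.provenance = {
        "smoothing_fraction": cfg.smoothing_fraction,
        "baseline_anchor_lo": cfg.baseline_anchor_lo or float(spectrum.wavelengths[0]),
        "baseline_anchor_hi": cfg.baseline_anchor_hi or float(spectrum.wavelengths[-1]),
        "nadh_window": list(cfg.nadh_window),
        "normalization_factor": nspec.normalization_factor,
    }
    return nspec
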