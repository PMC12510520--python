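"""Spectral preprocessing chain for PZT-PAS discrimination.

Fixed order: normalize the raw signal by laser power, min-max scale each
spectrum to [0, 1] using extrema from the 970-1162 cm^-1 window, then restrict
the feature vector to the 1022-1148 cm^-1 modeling band. All window endpoints
are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Spectrum, SpectrumKind

__all__ = ["PreprocessConfig", "normalize_by_power", "minmax_scale", "select_band",
           "preprocess_spectrum", "preprocess_dataset"]


@dataclass(frozen=True)
class PreprocessConfig:
    scale_lo: float = 970.0
    scale_hi: float = 1162.0
    band_lo: float = 1022.0
    band_hi: float = 1148.0
    smoothing_window: int = 3

    def __post_init__(self) -> None:
        if not self.scale_lo < self.scale_hi:
            raise ValueError("scale_lo must be < scale_hi")
        if not (self.scale_lo <= self.band_lo <= self.band_hi <= self.scale_hi):
            raise ValueError("modeling band must lie within the scaling window")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


def normalize_by_power(raw: Spectrum, power: Spectrum) -> Spectrum:
    """Divide the raw photoacoustic signal pointwise by the laser power."""
    if raw.kind is not SpectrumKind.PAS_SIGNAL:
        raise ValueError("raw spectrum must be a photoacoustic signal")
    if power.kind is not SpectrumKind.LASER_POWER:
        raise ValueError("power spectrum must be a laser-power spectrum")
    if not np.array_equal(raw.wavenumbers, power.wavenumbers):
        raise ValueError("raw and power spectra must share a wavenumber grid")
    if np.any(power.values <= 0):
        raise ValueError("laser power must be positive everywhere")
    return Spectrum(raw.wavenumbers, raw.values / power.values, SpectrumKind.PAS_SIGNAL)


def _window_mask(wavenumbers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (wavenumbers >= lo) & (wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] cm^-1 contains no grid points")
    return mask


def minmax_scale(spectrum: Spectrum, lo: float = 970.0, hi: float = 1162.0) -> Spectrum:
    """Min-max scale a spectrum to [0, 1] over the closed window [lo, hi].

    Extrema are computed only from points inside the window; the affine map
    is applied to the whole spectrum, so in-window values land in [0, 1] with
    both endpoints attained. A spectrum constant on the window is degenerate
    (an instrument fault) and raises.
    """
    mask = _window_mask(spectrum.wavenumbers, lo, hi)
    w = spectrum.values[mask]
    vmin, vmax = float(w.min()), float(w.max())
    if vmax == vmin:
        raise ValueError("spectrum is constant on the scaling window; cannot min-max scale")
    return spectrum.with_values((spectrum.values - vmin) / (vmax - vmin))


def select_band(spectrum: Spectrum, lo: float = 1022.0, hi: float = 1148.0) -> np.ndarray:
    """Feature vector: values at grid points within the closed band [lo, hi]."""
    mask = _window_mask(spectrum.wavenumbers, lo, hi)
    return spectrum.values[mask].copy()


def preprocess_spectrum(spectrum: Spectrum, config: PreprocessConfig | None = None,
                        power: Spectrum | None = None) -> np.ndarray:
    """Full chain on one spectrum: [power normalization] -> scale -> band select."""
    config = config or PreprocessConfig()
    if power is not None:
        spectrum = normalize_by_power(spectrum, power)
    scaled = minmax_scale(spectrum, config.scale_lo, config.scale_hi)
    return select_band(scaled, config.band_lo, config.band_hi)


def preprocess_dataset(dataset, config: PreprocessConfig | None = None):
    """Feature matrix, labels, smoothed reference glucose, band wavenumbers.

    Returns ``(X, y, glucose_smoothed, band_wavenumbers)`` where X is
    n_records x n_band_points.
    """
    config = config or PreprocessConfig()
    records = dataset.records
    if not records:
        raise ValueError("dataset has no records")
    X = np.vstack([preprocess_spectrum(r.spectrum, config) for r in records])
    y = np.asarray([r.label for r in records], dtype=int)
    glucose = np.asarray([r.glucose_smoothed for r in records], dtype=float)
    wn = records[0].spectrum.wavenumbers
    band_wn = wn[_window_mask(wn, config.band_lo, config.band_hi)]
    return X, y, glucose, band_wn
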