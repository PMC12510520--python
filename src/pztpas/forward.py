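"""Photoacoustic forward model: from layer optics to a PZT-PAS spectrum.

For optically thick aqueous samples (thickness beyond a few tens of
micrometres) the photoacoustic amplitude is inversely proportional to the
absorption coefficient: stronger absorption confines the deposited heat to a
thinner surface layer, shrinking the thermally expanding volume. Absorption
bands of the bulk therefore appear as *dips* in the signal. A thin top layer
(stratum corneum) attenuates the incident light once, by its decadic
transmitted fraction, and imprints additional dips at its own band centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acoustics import AcousticLayer
from .spectral import (
    LayerOptics,
    Spectrum,
    SpectrumKind,
    absorption_coefficient_spectrum,
    layer_absorbance,
    transmitted_fraction,
)

__all__ = ["LayeredSample", "LaserSpec", "pas_amplitude_thick", "pas_amplitude_thin",
           "synthesize_pas_spectrum", "average_irradiance"]


@dataclass(frozen=True)
class LayeredSample:
    """A bulk absorber under an optional thin top layer, with acoustic context."""

    bulk: LayerOptics
    top_layer: LayerOptics | None = None
    acoustic: AcousticLayer | None = None
    signal_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.signal_scale > 0:
            raise ValueError("signal_scale must be > 0")


@dataclass(frozen=True)
class LaserSpec:
    """Quantum cascade laser operating point."""

    power_mw: float = 12.0
    spot_diameter_mm: float = 1.0
    modulation_frequency_hz: float = 5.0e5
    pulse_width_ns: float = 100.0

    def __post_init__(self) -> None:
        for name in ("power_mw", "spot_diameter_mm", "modulation_frequency_hz", "pulse_width_ns"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def pas_amplitude_thick(mu_a, scale: float = 1.0):
    """Optically thick photoacoustic amplitude, S = scale / mu_a.

    Valid when the sample is thicker than the optical penetration depth, so
    that all light is absorbed and the heated volume scales as 1/mu_a.
    """
    mu = np.asarray(mu_a, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("pas_amplitude_thick requires mu_a > 0")
    out = scale / mu
    return float(out) if out.ndim == 0 else out


def pas_amplitude_thin(mu_a, thickness_um: float, scale: float = 1.0):
    """Optically thin limit, S = scale * mu_a * t: absorbed fraction ~ mu_a t.

    Provided for completeness; the study's samples are in the thick regime.
    """
    mu = np.asarray(mu_a, dtype=float)
    if np.any(mu < 0) or thickness_um < 0:
        raise ValueError("pas_amplitude_thin requires non-negative inputs")
    out = scale * mu * (thickness_um * 1e-4)
    return float(out) if out.ndim == 0 else out


def synthesize_pas_spectrum(sample: LayeredSample, grid: np.ndarray) -> Spectrum:
    """PZT-PAS spectrum of a layered sample on a wavenumber grid.

    S(nu) = signal_scale * T_top(nu) / mu_a_bulk(nu), where T_top is the
    one-way decadic transmitted fraction of the top layer (the returning wave
    is acoustic, not optical, so attenuation applies once). Bulk band centers
    are local minima; top-layer band centers add further minima.
    """
    grid = np.asarray(grid, dtype=float)
    mu_bulk = absorption_coefficient_spectrum(sample.bulk, grid)
    if np.any(mu_bulk <= 0):
        raise ValueError(
            "bulk absorption coefficient must be positive everywhere; "
            "add a small water background to the bulk layer"
        )
    signal = pas_amplitude_thick(mu_bulk, sample.signal_scale)
    if sample.top_layer is not None:
        a_top = layer_absorbance(
            absorption_coefficient_spectrum(sample.top_layer, grid),
            sample.top_layer.thickness_um,
        )
        signal = signal * transmitted_fraction(a_top)
    return Spectrum(grid, signal, SpectrumKind.PAS_SIGNAL)


def average_irradiance(power_mw: float, spot_diameter_mm: float) -> float:
    """Average irradiance in W/cm^2 of a beam over its 1/e^2 spot area.

    12 mW over a 1-mm spot gives 1.53 W/cm^2 (the instrument's stated
    1.5 W/cm^2 maximum).
    """
    if not power_mw > 0 or not spot_diameter_mm > 0:
        raise ValueError("power and spot diameter must be > 0")
    radius_cm = spot_diameter_mm / 2.0 * 0.1
    return (power_mw * 1e-3) / (math.pi * radius_cm**2)
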