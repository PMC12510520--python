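"""Optical model of thin tissue layers in the mid-infrared.

A layer (stratum corneum, epidermis phantom, glucose gel) is described by its
thickness, water content, and a list of Gaussian absorption bands. The water
background enters through an effective absorption coefficient
``water_fraction * mu_a_water``; bands add on top of it. Absorbance is decadic
(Bel): ``A = mu_a * t / ln 10`` with ``t`` in cm, so that one Bel attenuates
transmitted intensity by a factor of ten.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AbsorptionBand",
    "LayerOptics",
    "Spectrum",
    "SpectrumKind",
    "INSTRUMENT_RANGE",
    "WATER_MU_A",
    "effective_absorption_coefficient",
    "layer_absorbance",
    "penetration_depth",
    "absorption_coefficient_spectrum",
    "build_absorbance_spectrum",
    "transmitted_fraction",
    "default_grid",
]

#: Tunable range of the external-cavity quantum cascade laser source (cm^-1).
INSTRUMENT_RANGE = (930.0, 1200.0)

#: Mid-infrared absorption coefficient of liquid water near 1000 cm^-1 (cm^-1).
WATER_MU_A = 817.0


class SpectrumKind(str, enum.Enum):
    """What physical quantity a spectrum's values represent."""

    ABSORBANCE = "absorbance_Bel"
    PAS_SIGNAL = "pas_signal_au"
    LASER_POWER = "laser_power_au"


@dataclass(frozen=True)
class AbsorptionBand:
    """A Gaussian absorption band.

    Parameters
    ----------
    center : float
        Band center in cm^-1.
    width : float
        Gaussian standard deviation in cm^-1. Must be positive.
    amplitude : float
        Peak contribution to the absorption coefficient, in cm^-1.
    """

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Absorption-coefficient contribution (cm^-1) on a wavenumber grid."""
        x = (np.asarray(wavenumbers, dtype=float) - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * x * x)


@dataclass(frozen=True)
class LayerOptics:
    """Optical description of one tissue layer.

    thickness is in micrometres; ``water_fraction`` in [0, 1]; ``mu_a_water``
    is the pure-water absorption coefficient in cm^-1; ``bands`` are additional
    Gaussian absorbers (proteins, glucose, ...).
    """

    thickness_um: float
    water_fraction: float = 0.0
    mu_a_water: float = WATER_MU_A
    bands: tuple[AbsorptionBand, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.thickness_um > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness_um}")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError(f"water_fraction must be in [0, 1], got {self.water_fraction}")
        if self.mu_a_water < 0:
            raise ValueError(f"mu_a_water must be >= 0, got {self.mu_a_water}")
        object.__setattr__(self, "bands", tuple(self.bands))


@dataclass(frozen=True)
class Spectrum:
    """Values on a strictly ascending, uniform wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray
    values: np.ndarray
    kind: SpectrumKind

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wn.ndim != 1 or wn.size == 0:
            raise ValueError("wavenumber grid must be a non-empty 1-D array")
        if wn.size != vals.size:
            raise ValueError("wavenumbers and values must have equal length")
        if wn.size > 1 and not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", SpectrumKind(self.kind))

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None) -> "Spectrum":
        return Spectrum(self.wavenumbers, values, kind or self.kind)


def default_grid(lo: float = 930.0, hi: float = 1200.0, step: float = 2.0) -> np.ndarray:
    """The instrument wavenumber grid: 930-1200 cm^-1 at 2 cm^-1 spacing."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def effective_absorption_coefficient(water_fraction: float, mu_a_water: float = WATER_MU_A) -> float:
    """Water-background absorption coefficient of a partially hydrated layer.

    Returns ``water_fraction * mu_a_water`` in cm^-1: a layer with 30 % water
    content and the pure-water value 817 cm^-1 absorbs like a 245 cm^-1 medium.
    """
    if not 0.0 <= water_fraction <= 1.0:
        raise ValueError(f"water_fraction must be in [0, 1], got {water_fraction}")
    if mu_a_water < 0:
        raise ValueError(f"mu_a_water must be >= 0, got {mu_a_water}")
    return water_fraction * mu_a_water


def layer_absorbance(mu_a_eff: float | np.ndarray, thickness_um: float | np.ndarray):
    """Decadic absorbance (Bel) of a thin layer.

    ``A = mu_a_eff * t / ln 10`` with ``t`` converted from micrometres to cm.
    Broadcasts over arrays.
    """
    mu = np.asarray(mu_a_eff, dtype=float)
    t = np.asarray(thickness_um, dtype=float)
    if np.any(mu < 0) or np.any(t < 0):
        raise ValueError("layer_absorbance requires non-negative inputs")
    out = mu * (t * 1e-4) / math.log(10)
    return float(out) if out.ndim == 0 else out


def penetration_depth(mu_a_eff: float) -> float:
    """1/e optical penetration depth in micrometres, ``1e4 / mu_a_eff``.

    With the wettest stated stratum corneum (30 % water, 817 cm^-1) this gives
    ~41 um, the operating depth limit of the method.
    """
    if not mu_a_eff > 0:
        raise ValueError(f"penetration_depth requires mu_a_eff > 0, got {mu_a_eff}")
    return 1e4 / mu_a_eff


def absorption_coefficient_spectrum(layer: LayerOptics, grid: np.ndarray) -> np.ndarray:
    """Absorption coefficient mu_a(nu) in cm^-1: water background + bands."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wavenumber grid must be non-empty")
    mu = np.full(grid.shape, effective_absorption_coefficient(layer.water_fraction, layer.mu_a_water))
    for band in layer.bands:
        mu = mu + band.evaluate(grid)
    return mu


def build_absorbance_spectrum(layer: LayerOptics, grid: np.ndarray) -> Spectrum:
    """Decadic absorbance spectrum of a layer on a wavenumber grid.

    Local maxima sit at band centers (to grid resolution) when bands are
    separated by more than ~3 sigma.
    """
    mu = absorption_coefficient_spectrum(layer, grid)
    return Spectrum(grid, layer_absorbance(mu, layer.thickness_um), SpectrumKind.ABSORBANCE)


def transmitted_fraction(absorbance):
    """Fraction of light transmitted through a layer of given decadic absorbance."""
    a = np.asarray(absorbance, dtype=float)
    if np.any(a < 0):
        raise ValueError("absorbance must be >= 0")
    out = np.power(10.0, -a)
    return float(out) if out.ndim == 0 else out
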