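"""Synthetic OGTT photoacoustic datasets.

Real human spectra from this kind of trial are not publicly deposited, so the
package ships a generator that emulates their statistical structure: a 2-h
oral glucose tolerance test (OGTT) excursion sampled every ~5 min before and
after sugar ingestion, spectra synthesized by the layered photoacoustic
forward model with glucose bands at 990/1110 cm^-1 (appearing as dips) under a
protein-banded stratum-corneum layer (1030/1080 cm^-1), measurement noise that
is larger when the sample is repositioned between acquisitions than when it is
fixed, and additive day-to-day drift across a multi-day campaign.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .acoustics import AcousticLayer
from .chemometrics import label_by_threshold
from .forward import LayeredSample, synthesize_pas_spectrum
from .spectral import (
    INSTRUMENT_RANGE,
    AbsorptionBand,
    LayerOptics,
    Spectrum,
    SpectrumKind,
    default_grid,
)

__all__ = [
    "OGTTParams",
    "AcquisitionMode",
    "NoiseParams",
    "DatasetRecord",
    "Dataset",
    "GLUCOSE_BAND_CENTERS",
    "PROTEIN_BAND_CENTERS",
    "DEFAULT_GLUCOSE_BAND_COEFF",
    "ogtt_glucose_curve",
    "trailing_moving_average",
    "generate_dataset",
]

#: Glucose C-O stretch band centers (cm^-1), seen as dips in the PAS signal.
GLUCOSE_BAND_CENTERS = (990.0, 1110.0)
#: Protein amide/backbone bands of the stratum corneum (cm^-1).
PROTEIN_BAND_CENTERS = (1030.0, 1080.0)

# Band-amplitude coefficient (cm^-1 per mg/dL). Calibrated so that the
# 90 -> 180 mg/dL OGTT excursion changes the min-max-scaled dip depth at
# 1110 cm^-1 by ~5 % of the spectrum's dynamic range, which keeps the
# two-class problem nontrivial at realistic noise.
DEFAULT_GLUCOSE_BAND_COEFF = 0.142

_GLUCOSE_BAND_SIGMA = 10.0
_PROTEIN_BAND_SIGMA = 12.0
_PROTEIN_BAND_AMPLITUDE = 300.0  # cm^-1, dominant stratum-corneum absorber
_BULK_WATER_FRACTION = 0.8       # gelatin/interstitial-fluid-like bulk
_TOP_WATER_FRACTION = 0.2
_TOP_THICKNESS_UM = 15.0
_DEFAULT_SIGNAL_SCALE = 850.0    # puts the off-band signal near 1 a.u.

_EPIDERMIS = AcousticLayer(thickness_mm=2.0, sound_speed=1580.0, impedance=1.6)


class AcquisitionMode(str, enum.Enum):
    """Whether the sample stays clamped between acquisitions.

    Repositioning the sample for every measurement perturbs the probed spot on
    an inhomogeneous tissue, so its noise defaults dominate the fixed-mode
    ones.
    """

    FIXED = "fixed"
    REPOSITIONED = "repositioned"


@dataclass(frozen=True)
class OGTTParams:
    """Oral glucose tolerance test time-course parameters (minutes, mg/dL)."""

    baseline_glucose: float = 90.0
    peak_excess: float = 70.0
    time_to_peak: float = 45.0
    decay_time: float = 40.0
    sampling_interval: float = 5.0
    duration_before: float = 120.0
    duration_after: float = 120.0

    def __post_init__(self) -> None:
        for name in ("baseline_glucose", "peak_excess", "time_to_peak", "decay_time",
                     "sampling_interval", "duration_before", "duration_after"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise magnitudes for the spectral generator.

    additive_sd is in signal a.u. (off-band signal ~ 1 a.u. at the default
    scale); gain_jitter_sd and band_amplitude_jitter_sd are relative;
    baseline_drift_sd is a per-day additive offset; subject_band_shift_sd
    shifts every band center by one per-dataset draw (an intersubject knob).
    """

    additive_sd: float = 0.004
    gain_jitter_sd: float = 0.02
    band_amplitude_jitter_sd: float = 0.03
    baseline_drift_sd: float = 0.004
    subject_band_shift_sd: float = 0.0
    ref_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "gain_jitter_sd", "band_amplitude_jitter_sd",
                     "baseline_drift_sd", "subject_band_shift_sd", "ref_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def for_mode(cls, mode: AcquisitionMode, seed: int = 0) -> "NoiseParams":
        """Default noise for an acquisition mode; repositioning quadruples the
        gain jitter and more than triples the band-shape jitter."""
        mode = AcquisitionMode(mode)
        if mode is AcquisitionMode.FIXED:
            return cls(seed=seed)
        return cls(gain_jitter_sd=0.08, band_amplitude_jitter_sd=0.10, seed=seed)


@dataclass(frozen=True)
class DatasetRecord:
    timestamp_min: float
    glucose_ref: float
    glucose_smoothed: float
    label: int
    mode: AcquisitionMode
    day: int
    spectrum: Spectrum


@dataclass(frozen=True)
class Dataset:
    records: tuple[DatasetRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if records:
            grid = records[0].spectrum.wavenumbers
            for r in records[1:]:
                if not np.array_equal(r.spectrum.wavenumbers, grid):
                    raise ValueError("all records must share one wavenumber grid")
        object.__setattr__(self, "records", records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def grid(self) -> np.ndarray:
        return self.records[0].spectrum.wavenumbers


def _ogtt_shape(t: np.ndarray, params: OGTTParams) -> np.ndarray:
    """Noise-free excursion: baseline before ingestion (t <= 0), then a
    gamma-like rise/decay peaking exactly at time_to_peak."""
    x = np.maximum(np.asarray(t, dtype=float), 0.0) / params.time_to_peak
    return params.baseline_glucose + params.peak_excess * x * np.exp(1.0 - x)


def ogtt_glucose_curve(params: OGTTParams, seed: int = 0,
                       ref_noise_sd: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Sampled OGTT reference-glucose time course.

    Returns ``(times_min, glucose_mg_dl)`` on a uniform grid from
    -duration_before to +duration_after at the sampling interval; t = 0 is
    sugar ingestion. ``ref_noise_sd`` models fingerstick-meter repeatability.
    Deterministic for a given seed.
    """
    if not params.sampling_interval > 0:
        raise ValueError("sampling_interval must be > 0")
    n_before = int(round(params.duration_before / params.sampling_interval))
    n_after = int(round(params.duration_after / params.sampling_interval))
    t = params.sampling_interval * np.arange(-n_before, n_after + 1)
    g = _ogtt_shape(t, params)
    if ref_noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, ref_noise_sd, size=g.shape)
    return t, g


def trailing_moving_average(series, window: int = 3) -> np.ndarray:
    """Trailing moving average: each value averaged with the ``window - 1``
    immediately preceding points; leading windows are shortened."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if window < 1:
        raise ValueError("window must be >= 1")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    start = np.maximum(idx - window + 1, 0)
    return (csum[idx + 1] - csum[start]) / (idx + 1 - start)


def _record_sample(protein_amps: tuple[float, float],
                   glucose_amps: tuple[float, float], band_shift: float,
                   signal_scale: float) -> LayeredSample:
    top = LayerOptics(
        thickness_um=_TOP_THICKNESS_UM,
        water_fraction=_TOP_WATER_FRACTION,
        bands=tuple(
            AbsorptionBand(c + band_shift, _PROTEIN_BAND_SIGMA, a)
            for c, a in zip(PROTEIN_BAND_CENTERS, protein_amps)
        ),
    )
    bulk = LayerOptics(
        thickness_um=2000.0,
        water_fraction=_BULK_WATER_FRACTION,
        bands=tuple(
            AbsorptionBand(c + band_shift, _GLUCOSE_BAND_SIGMA, a)
            for c, a in zip(GLUCOSE_BAND_CENTERS, glucose_amps)
        ),
    )
    return LayeredSample(bulk=bulk, top_layer=top, acoustic=_EPIDERMIS,
                         signal_scale=signal_scale)


def generate_dataset(
    n_records: int,
    mode: AcquisitionMode = AcquisitionMode.FIXED,
    ogtt: OGTTParams | None = None,
    noise: NoiseParams | None = None,
    grid: np.ndarray | None = None,
    glucose_band_coeff: float = DEFAULT_GLUCOSE_BAND_COEFF,
    signal_scale: float = _DEFAULT_SIGNAL_SCALE,
    threshold: float = 140.0,
) -> Dataset:
    """Generate an OGTT spectral dataset.

    Each record's spectrum comes from the layered forward model with bulk
    glucose band amplitudes ``glucose_band_coeff * glucose_smoothed`` at 990
    and 1110 cm^-1, perturbed per ``noise``; the smoothed value is the
    analysis-scale glucose estimate that the labels also threshold, so a
    zero-noise dataset is separable by construction (the raw ``glucose_ref``
    models the fingerstick meter reading). Records beyond one OGTT day roll over
    to a fresh day with its own additive baseline drift (a multi-day
    campaign). Labels apply the threshold rule to the trailing-3-point
    smoothed reference. Fully reproducible from ``noise.seed``.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    mode = AcquisitionMode(mode)
    ogtt = ogtt or OGTTParams()
    noise = noise if noise is not None else NoiseParams.for_mode(mode)
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    lo, hi = INSTRUMENT_RANGE
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(f"grid must lie within the instrument range [{lo}, {hi}] cm^-1")

    rng = np.random.default_rng(noise.seed)
    band_shift = float(rng.normal(0.0, noise.subject_band_shift_sd)) \
        if noise.subject_band_shift_sd > 0 else 0.0

    records: list[DatasetRecord] = []
    day = 0
    while len(records) < n_records:
        day_seed = int(rng.integers(0, 2**31 - 1))
        t, g_ref = ogtt_glucose_curve(ogtt, seed=day_seed, ref_noise_sd=noise.ref_noise_sd)
        g_smooth = trailing_moving_average(g_ref, window=3)
        drift = float(rng.normal(0.0, noise.baseline_drift_sd)) \
            if noise.baseline_drift_sd > 0 else 0.0
        for ti, gi, gs in zip(t, g_ref, g_smooth):
            if len(records) >= n_records:
                break
            gi = max(gi, 1.0)
            gs = max(gs, 1.0)
            jit = (1.0 + rng.normal(0.0, noise.band_amplitude_jitter_sd, size=4)) \
                if noise.band_amplitude_jitter_sd > 0 else np.ones(4)
            jit = np.clip(jit, 0.0, None)
            protein_amps = (_PROTEIN_BAND_AMPLITUDE * jit[0], _PROTEIN_BAND_AMPLITUDE * jit[1])
            g_amp = glucose_band_coeff * gs
            glucose_amps = (g_amp * jit[2], g_amp * jit[3])
            sample = _record_sample(protein_amps, glucose_amps, band_shift, signal_scale)
            spec = synthesize_pas_spectrum(sample, grid)
            values = spec.values
            if noise.gain_jitter_sd > 0:
                values = values * (1.0 + rng.normal(0.0, noise.gain_jitter_sd))
            values = values + drift
            if noise.additive_sd > 0:
                values = values + rng.normal(0.0, noise.additive_sd, size=values.shape)
            records.append(DatasetRecord(
                timestamp_min=float(ti),
                glucose_ref=float(gi),
                glucose_smoothed=float(gs),
                label=label_by_threshold(gs, threshold),
                mode=mode,
                day=day,
                spectrum=Spectrum(grid, values, SpectrumKind.PAS_SIGNAL),
            ))
        day += 1
    return Dataset(tuple(records))
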