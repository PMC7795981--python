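"""Synthetic generator for time-resolved NIR spectra of a lactic fermentation.

The generator emulates an 8-hour yogurt fermentation monitored by an FT-NIR
instrument: 33 absorbance spectra taken every 15 min on a 12000-4000 cm^-1
grid (16 cm^-1 step, ~830-2500 nm), while the pH falls from ~6.7 to the casein
isoelectric point 4.6 along a descending logistic.

Model
-----
Each spectrum is the sum of three parts, evaluated on the wavelength grid
``lambda`` (nm) with normalized position ``u = (lambda - min) / (max - min)``:

``A(lambda, t) = [b0 + b1 * u] * (1 + s * g(t)) + sum_k a_k(t) * G_k(lambda) + eps``

* ``b0 + b1 * u`` is a linear scattering baseline; it is inflated by a factor
  ``1 + s * g(t)`` where ``g`` is an increasing logistic (the *growth sigmoid*)
  synchronized with the pH decline.  This reproduces the broadband absorbance
  rise caused by light scattering when casein micelles aggregate during
  coagulation.
* ``G_k`` are Gaussian absorbance bands (water and solute bands).  A band's
  amplitude ``a_k(t)`` is either constant or slides from ``amplitude_start``
  to ``amplitude_end`` along its own logistic driver, so that distinct band
  sets dominate the lag phase (early bands), the coagulation surge (bands
  tracking ``g``), and the late gel-setting phase (late bands).
* ``eps`` is i.i.d. Gaussian detector noise in absorbance units.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
configurations produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import SpectralSeries

__all__ = [
    "BandSpec",
    "PhProfile",
    "SimulationConfig",
    "default_bands",
    "default_config",
    "simulate_ph_profile",
    "growth_sigmoid",
    "band_shape",
    "band_amplitudes",
    "simulate_spectra",
    "FWHM_TO_SIGMA",
]

#: Conversion factor between a Gaussian FWHM and its standard deviation.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548

_PROFILES = ("constant", "growth", "early", "late")

# Default logistic-driver placement per amplitude profile, expressed relative
# to the pH logistic: midpoint shift in hours and rate multiplier.  "growth"
# always uses the scatter sigmoid g(t) itself.
_DEFAULT_SHIFT_H = {"early": -1.975, "late": 1.625}
_DEFAULT_RATE_MULT = {"early": 1.0, "late": 0.8}


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorbance band and its amplitude dynamics.

    ``profile`` selects the amplitude trajectory between ``amplitude_start``
    (early fermentation) and ``amplitude_end`` (fully fermented):

    - ``constant``: fixed at ``amplitude_start``;
    - ``growth``: slides along the scatter sigmoid ``g(t)``;
    - ``early``: slides along a logistic centred in the lag phase
      (decaying bands have ``amplitude_end < amplitude_start``);
    - ``late``: slides along a delayed logistic centred in the gel-setting
      phase.

    ``midpoint_shift_h`` and ``rate_multiplier`` override the driver placement
    (hours relative to the pH midpoint; multiple of the pH rate).
    """

    center_nm: float
    fwhm_nm: float
    amplitude_start: float
    amplitude_end: Optional[float] = None
    profile: str = "constant"
    midpoint_shift_h: Optional[float] = None
    rate_multiplier: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {_PROFILES}, got {self.profile!r}")
        if self.amplitude_end is None:
            object.__setattr__(self, "amplitude_end", self.amplitude_start)


@dataclass(frozen=True)
class PhProfile:
    """A pH-versus-time table (times in hours, ascending)."""

    times_h: np.ndarray
    ph: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", np.asarray(self.times_h, dtype=float))
        object.__setattr__(self, "ph", np.asarray(self.ph, dtype=float))
        if self.times_h.shape != self.ph.shape or self.times_h.ndim != 1:
            raise ValueError("times_h and ph must be 1-D arrays of equal length")
        if self.times_h.size == 0:
            raise ValueError("pH profile is empty")
        if np.any(np.diff(self.times_h) < 0):
            raise ValueError("times_h must be ascending")
        if np.any((self.ph <= 0.0) | (self.ph >= 14.0)):
            raise ValueError("pH values outside (0, 14)")


def default_bands() -> tuple[BandSpec, ...]:
    """The default fermentation band set.

    Static water bands (second overtone ~970 nm, combination-overtone
    ~1150 nm, first overtone ~1450 nm, combination band ~1910 nm) carry a
    small growth component on top of a constant base.  Early bands (998, 1090,
    1361, 1670, 1840 nm: lactic-acid production, solvated hydronium/proton
    hydrates, EPS-related features) accumulate during the lag phase, before
    coagulation drives the scattering baseline; late bands (1420, 1453 nm:
    hydration and adsorbed water in the set gel) rise once the gel forms.
    FWHMs and amplitudes are synthetic fixture choices, not measured values.
    """
    return (
        # static water bands with a mild growth component
        BandSpec(970.0, 55.0, 0.120, 0.140, "growth"),
        BandSpec(1150.0, 75.0, 0.250, 0.280, "growth"),
        BandSpec(1450.0, 95.0, 1.150, 1.270, "growth"),
        BandSpec(1910.0, 115.0, 1.850, 2.000, "growth"),
        # early (lag-phase) chemistry, fast group
        BandSpec(1361.0, 30.0, 0.004, 0.060, "early"),
        BandSpec(1670.0, 55.0, 0.008, 0.045, "early"),
        BandSpec(1840.0, 45.0, 0.006, 0.040, "early"),
        # early chemistry, slower group
        BandSpec(998.0, 25.0, 0.004, 0.012, "early", midpoint_shift_h=-1.275),
        BandSpec(1090.0, 40.0, 0.002, 0.012, "early", midpoint_shift_h=-1.275),
        # late (gel-setting) bands; slow driver so the gel keeps maturing
        # through the end of the monitored 8 h
        BandSpec(1420.0, 25.0, 0.002, 0.070, "late"),
        BandSpec(1453.0, 25.0, 0.002, 0.085, "late"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic fermentation generator.

    The spectral grid is specified in wavenumbers (cm^-1, descending from
    ``wavenumber_start`` to ``wavenumber_stop`` in steps of
    ``wavenumber_step``) and converted to a non-uniform ascending nm axis via
    ``lambda = 1e7 / nu``, matching an FT instrument.  A uniform nm grid can
    be requested instead through ``wavelengths_nm``.
    """

    wavenumber_start: float = 12000.0
    wavenumber_stop: float = 4000.0
    wavenumber_step: float = 16.0
    duration_h: float = 8.0
    interval_min: float = 15.0
    ph_start: float = 6.7
    ph_end: float = 4.6
    ph_rate: float = 1.5
    ph_midpoint_h: float = 3.875
    scatter_rate_multiplier: float = 4.5
    baseline_intercept: float = 0.30
    baseline_slope: float = 0.50
    scatter_gain: float = 0.12
    bands: tuple[BandSpec, ...] = field(default_factory=default_bands)
    noise_sd: float = 1e-4
    seed: int = 0
    wavelengths_nm: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.wavenumber_step <= 0:
            raise ValueError("wavenumber_step must be positive")
        if self.wavenumber_start <= self.wavenumber_stop:
            raise ValueError("wavenumber_start must exceed wavenumber_stop")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.ph_end >= self.ph_start:
            raise ValueError("ph_end must be below ph_start")
        if self.ph_rate <= 0:
            raise ValueError("ph_rate must be positive")
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.wavelengths_nm is not None:
            object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm))

    def times_h(self) -> np.ndarray:
        """Acquisition times in hours, including t=0."""
        n_steps = int(np.floor(self.duration_h * 60.0 / self.interval_min + 1e-9))
        return np.arange(n_steps + 1) * self.interval_min / 60.0

    def wavelength_grid_nm(self) -> np.ndarray:
        """Ascending wavelength axis in nm."""
        if self.wavelengths_nm is not None:
            grid = np.asarray(self.wavelengths_nm, dtype=float)
            if grid.size < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError("explicit wavelengths_nm must be ascending, length >= 2")
            return grid
        n_steps = int(np.floor((self.wavenumber_start - self.wavenumber_stop) / self.wavenumber_step + 1e-9))
        wavenumbers = self.wavenumber_start - np.arange(n_steps + 1) * self.wavenumber_step
        return np.sort(1e7 / wavenumbers)


def default_config(**overrides) -> SimulationConfig:
    """The default study conditions (convenience wrapper)."""
    return dataclasses.replace(SimulationConfig(), **overrides)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_ph_profile(config: SimulationConfig, times_h: Optional[Sequence[float]] = None) -> PhProfile:
    """Descending logistic pH profile.

    ``pH(t) = ph_end + (ph_start - ph_end) / (1 + exp(ph_rate * (t - ph_midpoint_h)))``

    The curve reproduces the three acidification phases of a LAB fermentation:
    lag (slow decrease), logarithmic (rapid decrease), and the slow-down
    toward the casein isoelectric point.
    """
    t = config.times_h() if times_h is None else np.asarray(times_h, dtype=float)
    if t.size == 0:
        raise ValueError("time grid is empty")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    if np.any((t < -1e-9) | (t > config.duration_h + 1e-9)):
        raise ValueError("times must lie within [0, duration_h]")
    ph = config.ph_end + (config.ph_start - config.ph_end) * _logistic(
        -config.ph_rate * (t - config.ph_midpoint_h)
    )
    return PhProfile(t, ph)


def growth_sigmoid(
    config: SimulationConfig,
    times_h: Optional[Sequence[float]] = None,
    midpoint_shift_h: float = 0.0,
    rate_multiplier: Optional[float] = None,
) -> np.ndarray:
    """Increasing logistic driver ``g(t)`` in [0, 1].

    With the default arguments this is the scattering driver: it shares the pH
    logistic's midpoint (so the fastest baseline rise coincides with the
    fastest pH drop) but is steeper by ``scatter_rate_multiplier``, because
    acid coagulation of casein is a threshold-like event compared with the
    smooth pH decline.  Band drivers reuse this function with their own
    midpoint shift and rate multiplier.
    """
    t = config.times_h() if times_h is None else np.asarray(times_h, dtype=float)
    mult = config.scatter_rate_multiplier if rate_multiplier is None else rate_multiplier
    rate = config.ph_rate * mult
    return _logistic(rate * (t - (config.ph_midpoint_h + midpoint_shift_h)))


def band_shape(
    center_nm: float,
    fwhm_nm: float,
    amplitude: float,
    wavelength_grid_nm: Sequence[float],
) -> np.ndarray:
    """Gaussian band profile evaluated on a wavelength grid.

    The Gaussian peaks at ``amplitude`` at ``center_nm`` and falls to half the
    amplitude at ``center_nm +/- fwhm_nm / 2``.
    """
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be positive")
    grid = np.asarray(wavelength_grid_nm, dtype=float)
    sigma = fwhm_nm / FWHM_TO_SIGMA
    return amplitude * np.exp(-0.5 * ((grid - center_nm) / sigma) ** 2)


def band_amplitudes(
    config: SimulationConfig, band: BandSpec, times_h: Optional[Sequence[float]] = None
) -> np.ndarray:
    """Amplitude trajectory ``a_k(t)`` for one band under its profile."""
    t = config.times_h() if times_h is None else np.asarray(times_h, dtype=float)
    if band.profile == "constant":
        return np.full(t.shape, band.amplitude_start)
    if band.profile == "growth":
        shift = band.midpoint_shift_h if band.midpoint_shift_h is not None else 0.0
        driver = growth_sigmoid(config, t, midpoint_shift_h=shift, rate_multiplier=band.rate_multiplier)
    else:  # early / late
        shift = (
            band.midpoint_shift_h
            if band.midpoint_shift_h is not None
            else _DEFAULT_SHIFT_H[band.profile]
        )
        mult = (
            band.rate_multiplier
            if band.rate_multiplier is not None
            else _DEFAULT_RATE_MULT[band.profile]
        )
        driver = growth_sigmoid(config, t, midpoint_shift_h=shift, rate_multiplier=mult)
    return band.amplitude_start + (band.amplitude_end - band.amplitude_start) * driver


def simulate_spectra(config: SimulationConfig) -> tuple[SpectralSeries, PhProfile]:
    """Generate the full synthetic fermentation data set.

    Returns the ``(m, n)`` spectral series (m time points including t=0, n
    wavelength channels, ascending nm axis) together with the paired pH
    profile sampled at the same times.  Identical configs (including the
    seed) give bit-identical outputs.
    """
    lam = config.wavelength_grid_nm()
    t = config.times_h()
    span = lam[-1] - lam[0]
    u = (lam - lam[0]) / span if span > 0 else np.zeros_like(lam)
    baseline = config.baseline_intercept + config.baseline_slope * u
    g = growth_sigmoid(config, t)
    absorbance = baseline[None, :] * (1.0 + config.scatter_gain * g[:, None])
    for band in config.bands:
        if not (lam[0] - 1e-9 <= band.center_nm <= lam[-1] + 1e-9):
            raise ValueError(
                f"band center {band.center_nm} nm outside the wavelength grid "
                f"[{lam[0]:.1f}, {lam[-1]:.1f}] nm"
            )
        shape = band_shape(band.center_nm, band.fwhm_nm, 1.0, lam)
        absorbance = absorbance + band_amplitudes(config, band, t)[:, None] * shape[None, :]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        absorbance = absorbance + rng.normal(0.0, config.noise_sd, absorbance.shape)
    series = SpectralSeries(
        wavelengths_nm=lam,
        times_h=t,
        absorbance=absorbance,
        meta={"generator": "fermnir.simulate", "seed": config.seed},
    )
    return series, simulate_ph_profile(config, t)
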