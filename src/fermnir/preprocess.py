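"""Spectral preprocessing: truncation, Savitzky-Golay filtering, baseline points.

The working region is truncated to 950-1880 nm before analysis (the detector
is noisy at the spectral edges and beyond ~1900 nm the sample absorbs too
strongly), then each spectrum is smoothed with a Savitzky-Golay filter
(second-order polynomial, 25 points by default).

Savitzky-Golay derivatives here are taken with respect to the *channel index*,
not nanometres: the FT-style wavelength grid is non-uniform in nm, and only
the sign structure (zero crossings) of the second derivative is used
downstream, for which the abscissa scale is immaterial.

Edge handling: by default the filtered series keeps interior channels only
((window_points - 1) / 2 channels trimmed per side), avoiding fabricated edge
values; a mirror-padding mode retaining the full axis is available.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectralSeries

__all__ = [
    "SgSettings",
    "TimeProfile",
    "BaselineCrossing",
    "truncate",
    "savgol",
    "find_baseline_wavelengths",
    "absorbance_time_profile",
]


@dataclass(frozen=True)
class SgSettings:
    """Savitzky-Golay filter settings (order 2, 25 points by default)."""

    polynomial_order: int = 2
    window_points: int = 25
    derivative_order: int = 0

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0 or self.window_points <= self.polynomial_order:
            raise ValueError("window_points must be odd and exceed polynomial_order")
        if not 0 <= self.derivative_order <= self.polynomial_order:
            raise ValueError("derivative_order must be in [0, polynomial_order]")

    @property
    def half_window(self) -> int:
        return (self.window_points - 1) // 2


@dataclass(frozen=True)
class TimeProfile:
    """Absorbance at one wavelength channel as a function of time."""

    wavelength_nm: float
    times_h: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", np.asarray(self.times_h, dtype=float))
        object.__setattr__(self, "absorbance", np.asarray(self.absorbance, dtype=float))
        if self.times_h.shape != self.absorbance.shape:
            raise ValueError("times_h and absorbance must have equal length")


@dataclass(frozen=True)
class BaselineCrossing:
    """A candidate baseline wavelength and the resolved zero crossing (or None)."""

    candidate_nm: float
    wavelength_nm: Optional[float]

    @property
    def resolved(self) -> bool:
        return self.wavelength_nm is not None


def truncate(series: SpectralSeries, lo_nm: float, hi_nm: float) -> SpectralSeries:
    """Restrict the series to channels with ``lo_nm <= lambda <= hi_nm``."""
    if lo_nm > hi_nm:
        raise ValueError("lo_nm must not exceed hi_nm")
    mask = (series.wavelengths_nm >= lo_nm) & (series.wavelengths_nm <= hi_nm)
    if not mask.any():
        raise ValueError(f"no channels in [{lo_nm}, {hi_nm}] nm")
    return series.select_channels(mask)


def savgol(
    series: SpectralSeries,
    settings: SgSettings = SgSettings(),
    edge_mode: str = "trim",
) -> SpectralSeries:
    """Savitzky-Golay filter each spectrum along the wavelength axis.

    ``edge_mode="trim"`` (default) returns interior channels only;
    ``edge_mode="mirror"`` keeps the full axis using mirror padding.
    Derivatives (``settings.derivative_order > 0``) are per channel-index
    step.
    """
    if series.n_channels < settings.window_points:
        raise ValueError(
            f"series has {series.n_channels} channels, fewer than the "
            f"{settings.window_points}-point filter window"
        )
    if edge_mode not in ("trim", "mirror"):
        raise ValueError("edge_mode must be 'trim' or 'mirror'")
    filtered = savgol_filter(
        series.absorbance,
        window_length=settings.window_points,
        polyorder=settings.polynomial_order,
        deriv=settings.derivative_order,
        delta=1.0,
        axis=1,
        mode="interp" if edge_mode == "trim" else "mirror",
    )
    meta = dict(series.meta)
    meta["savgol"] = dataclasses.asdict(settings)
    if edge_mode == "trim":
        h = settings.half_window
        return SpectralSeries(
            series.wavelengths_nm[h : series.n_channels - h],
            series.times_h.copy(),
            filtered[:, h : series.n_channels - h],
            meta,
        )
    return SpectralSeries(series.wavelengths_nm.copy(), series.times_h.copy(), filtered, meta)


def find_baseline_wavelengths(
    series: SpectralSeries,
    candidates_nm: Sequence[float] = (1050.0, 1245.0, 1760.0),
    settings: Optional[SgSettings] = None,
    search_nm: float = 25.0,
) -> list[BaselineCrossing]:
    """Locate baseline-monitoring wavelengths near the given candidates.

    A baseline point is a zero crossing of the time-averaged Savitzky-Golay
    second-derivative spectrum: there the absorbance is governed by the
    baseline slope alone, not by a band.  For each candidate the nearest sign
    change within ``+/- search_nm`` is returned; candidates with no sign
    change in range are reported unresolved.  If the second derivative is
    zero everywhere (pure linear baseline) every candidate resolves to
    itself.
    """
    if settings is None:
        settings = SgSettings(derivative_order=2)
    elif settings.derivative_order != 2:
        settings = dataclasses.replace(settings, derivative_order=2)
    deriv = savgol(series, settings, edge_mode="trim")
    d2 = deriv.absorbance.mean(axis=0)
    lam = deriv.wavelengths_nm
    scale = max(1.0, float(np.max(np.abs(series.absorbance))))
    if np.max(np.abs(d2)) <= 1e-10 * scale:
        return [BaselineCrossing(float(c), float(c)) for c in candidates_nm]
    sign_change = d2[:-1] * d2[1:] <= 0.0
    idx = np.nonzero(sign_change)[0]
    crossings = []
    for i in idx:
        y0, y1 = d2[i], d2[i + 1]
        if y0 == y1:
            crossings.append(0.5 * (lam[i] + lam[i + 1]))
        else:
            crossings.append(lam[i] - y0 * (lam[i + 1] - lam[i]) / (y1 - y0))
    crossings = np.asarray(crossings)
    out = []
    for cand in candidates_nm:
        if crossings.size:
            dist = np.abs(crossings - cand)
            k = int(np.argmin(dist))
            if dist[k] <= search_nm:
                out.append(BaselineCrossing(float(cand), float(crossings[k])))
                continue
        out.append(BaselineCrossing(float(cand), None))
    return out


def absorbance_time_profile(
    series: SpectralSeries,
    wavelengths_nm: Sequence[float],
    tolerance_nm: float = 8.0,
) -> list[TimeProfile]:
    """Extract absorbance-versus-time profiles at the requested wavelengths.

    Each profile is the exact matrix column of the grid channel nearest the
    requested wavelength; a request with no channel within ``tolerance_nm``
    raises, naming the offending wavelength.
    """
    profiles = []
    for w in wavelengths_nm:
        j = int(np.argmin(np.abs(series.wavelengths_nm - w)))
        if abs(series.wavelengths_nm[j] - w) > tolerance_nm:
            raise ValueError(
                f"no channel within {tolerance_nm} nm of requested {w} nm "
                f"(nearest: {series.wavelengths_nm[j]:.1f} nm)"
            )
        profiles.append(
            TimeProfile(
                wavelength_nm=float(series.wavelengths_nm[j]),
                times_h=series.times_h.copy(),
                absorbance=series.absorbance[:, j].copy(),
            )
        )
    return profiles
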