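"""Peak detection on variance spectra and absorbance-band annotation.

The shipped assignment table (``data/band_assignments.csv``) collects NIR
absorbance bands reported for milk/yogurt lactic fermentation: water species
bands (970/998/1450/1910 nm and relatives), protonated-water bands (1361,
1668-1675 nm), protein and lactic-acid bands near 1000-1032 nm, EPS bands
(1683-1752, 1840 nm), and the hydration/adsorbed-water pair 1420-1455 nm.
Annotation is a literature look-up, not chemical inference.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .mwpca import VarianceSpectrum

__all__ = [
    "BandTableEntry",
    "BandAnnotation",
    "load_band_table",
    "find_variance_peaks",
    "annotate_bands",
]

_TIE_TOL_NM = 1e-9


@dataclass(frozen=True)
class BandTableEntry:
    """One reference band: a wavelength (or range), its assignment, provenance."""

    reference_lo_nm: float
    reference_hi_nm: float
    assignment: str
    provenance: str

    @property
    def label(self) -> str:
        if self.reference_lo_nm == self.reference_hi_nm:
            return f"{self.reference_lo_nm:g}"
        return f"{self.reference_lo_nm:g}-{self.reference_hi_nm:g}"

    def distance_nm(self, wavelength_nm: float) -> float:
        """Distance from a wavelength to this entry (0 inside a range)."""
        if self.reference_lo_nm <= wavelength_nm <= self.reference_hi_nm:
            return 0.0
        return min(
            abs(wavelength_nm - self.reference_lo_nm),
            abs(wavelength_nm - self.reference_hi_nm),
        )


@dataclass(frozen=True)
class BandAnnotation:
    """A detected peak matched (or not) against the reference table."""

    detected_nm: float
    matched_entry: Optional[BandTableEntry]
    distance_nm: float
    tie: bool = False

    @property
    def matched(self) -> bool:
        return self.matched_entry is not None


def _parse_reference(text: str) -> tuple[float, float]:
    text = str(text).strip()
    if "-" in text[1:]:  # allow a leading minus, not that it should occur
        lo, hi = text.split("-", 1)
        lo_f, hi_f = float(lo), float(hi)
    else:
        lo_f = hi_f = float(text)
    if hi_f < lo_f:
        lo_f, hi_f = hi_f, lo_f
    return lo_f, hi_f


def load_band_table(path: Optional[str | Path] = None) -> list[BandTableEntry]:
    """Load the band-assignment table (the shipped default, or a custom CSV)."""
    if path is None:
        resource = importlib.resources.files("fermnir").joinpath("data/band_assignments.csv")
        with importlib.resources.as_file(resource) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    required = {"reference_nm", "assignment", "provenance"}
    if not required.issubset(frame.columns):
        raise ValueError(f"band table requires columns {sorted(required)}")
    entries = []
    for _, row in frame.iterrows():
        lo, hi = _parse_reference(row["reference_nm"])
        entries.append(
            BandTableEntry(
                reference_lo_nm=lo,
                reference_hi_nm=hi,
                assignment=str(row["assignment"]),
                provenance=str(row["provenance"]),
            )
        )
    return sorted(entries, key=lambda e: (e.reference_lo_nm, e.reference_hi_nm))


def find_variance_peaks(
    var_spectrum: VarianceSpectrum,
    min_prominence_fraction: float = 0.05,
) -> np.ndarray:
    """Wavelengths of local maxima in a variance spectrum.

    Local maxima with prominence at least ``min_prominence_fraction`` times
    the spectrum maximum, sorted by wavelength; an all-zero spectrum yields
    an empty array.
    """
    variance = np.asarray(var_spectrum.variance, dtype=float)
    if np.any(variance < 0):
        raise ValueError("variance spectrum must be nonnegative")
    peak_scale = float(variance.max(initial=0.0))
    if peak_scale <= 0.0:
        return np.empty(0)
    idx, _ = find_peaks(variance, prominence=min_prominence_fraction * peak_scale)
    return np.asarray(var_spectrum.wavelengths_nm, dtype=float)[idx]


def annotate_bands(
    peaks_nm: Sequence[float],
    tolerance_nm: float = 5.0,
    table: Optional[Sequence[BandTableEntry]] = None,
) -> list[BandAnnotation]:
    """Match detected peaks to the nearest reference entry within tolerance.

    Range entries match at distance 0 anywhere inside the range.  Two entries
    exactly equidistant from a peak are resolved toward the lower wavelength
    and flagged as a tie.  Unmatched peaks are reported with no entry.
    """
    entries = load_band_table() if table is None else list(table)
    annotations = []
    for peak in peaks_nm:
        peak = float(peak)
        if not entries:
            annotations.append(BandAnnotation(peak, None, np.inf))
            continue
        dists = np.array([e.distance_nm(peak) for e in entries])
        best = int(np.argmin(dists))  # entries sorted ascending -> ties go low
        tie = bool(np.sum(np.abs(dists - dists[best]) <= _TIE_TOL_NM) > 1)
        if dists[best] <= tolerance_nm:
            annotations.append(BandAnnotation(peak, entries[best], float(dists[best]), tie))
        else:
            annotations.append(BandAnnotation(peak, None, float(dists[best]), False))
    return annotations
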