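"""Readers and writers for spectral matrices, pH tables, and result tables.

All on-disk formats are plain CSV (UTF-8, ``.`` decimal separator, header row
mandatory).  The canonical spectral layout is *wide*: one row per wavelength
channel, first column ``wavelength_nm``, remaining columns one per acquisition
time labelled by minutes (``t0``, ``t15``, ...).  Times are stored in minutes
on disk and carried in hours in memory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .bands import BandAnnotation
    from .mwpca import MwpcaResult, StageSegmentation, VarianceSpectrum

__all__ = [
    "SpectralSeries",
    "read_spectra_wide",
    "write_spectra_wide",
    "read_spectra_long",
    "read_ph",
    "write_ph",
    "write_dissimilarity_csv",
    "write_loadings_csv",
    "write_stages_csv",
    "write_variance_csv",
    "read_variance_csv",
    "write_annotations_csv",
]

_FLOAT_FORMAT = "%.17g"  # full double precision -> exact round trips


@dataclass
class SpectralSeries:
    """A time series of absorbance spectra on a common wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing channel axis in nanometres, length ``n``.
    times_h
        Strictly increasing acquisition times in hours, length ``m``.
    absorbance
        ``(m, n)`` matrix of absorbance values (AU); rows are spectra.
    meta
        Free-form annotations propagated through processing steps.
    """

    wavelengths_nm: np.ndarray
    times_h: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.times_h.ndim != 1:
            raise ValueError("axes must be one-dimensional")
        if self.absorbance.shape != (self.times_h.size, self.wavelengths_nm.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{self.times_h.size} times x {self.wavelengths_nm.size} channels"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times_h must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_times(self) -> int:
        return self.times_h.size

    @property
    def n_channels(self) -> int:
        return self.wavelengths_nm.size

    def select_channels(self, mask: np.ndarray) -> "SpectralSeries":
        """Return a copy restricted to the channels selected by ``mask``."""
        return SpectralSeries(
            self.wavelengths_nm[mask],
            self.times_h.copy(),
            self.absorbance[:, mask],
            dict(self.meta),
        )

    def copy(self) -> "SpectralSeries":
        return SpectralSeries(
            self.wavelengths_nm.copy(),
            self.times_h.copy(),
            self.absorbance.copy(),
            dict(self.meta),
        )


def _format_time_label(time_h: float) -> str:
    minutes = time_h * 60.0
    rounded = round(minutes)
    if abs(minutes - rounded) < 1e-9:
        return f"t{int(rounded)}"
    return f"t{minutes:g}"


def _parse_time_label(label: str) -> float:
    """Parse a time column label (minutes) such as ``t15`` or ``15``."""
    text = label.strip()
    if text.lower().startswith("t"):
        text = text[1:]
    try:
        return float(text) / 60.0
    except ValueError as exc:
        raise ValueError(f"cannot parse time from column label {label!r}") from exc


def _coerce_numeric(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Convert all cells to float (round-trip exact), reporting bad cells."""
    try:
        numeric = frame.astype(float)  # numpy strtod: exact round trips
    except (ValueError, TypeError):
        numeric = None
    if numeric is None or numeric.isna().to_numpy().any():
        for col in frame.columns:
            for row_idx, value in enumerate(frame[col]):
                try:
                    if not np.isfinite(float(value)):
                        raise ValueError
                except (ValueError, TypeError):
                    raise ValueError(
                        f"{path}: non-numeric or missing value at data "
                        f"row {row_idx + 1}, column {col!r}"
                    ) from None
        raise ValueError(f"{path}: non-numeric content")  # pragma: no cover
    return numeric


def read_spectra_wide(path: str | Path) -> SpectralSeries:
    """Read a wide-format spectral CSV (wavelength rows, time columns).

    Axes are sorted ascending on return regardless of file order; the
    absorbance matrix is permuted consistently.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: need a wavelength column plus >= 2 time columns")
    if frame.columns[0].strip() != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm', got {frame.columns[0]!r}")
    numeric = _coerce_numeric(frame, path)
    wavelengths = numeric.iloc[:, 0].to_numpy(dtype=float)
    if np.unique(wavelengths).size != wavelengths.size:
        raise ValueError(f"{path}: duplicate wavelengths present")
    times_h = np.array([_parse_time_label(c) for c in frame.columns[1:]], dtype=float)
    if np.unique(times_h).size != times_h.size:
        raise ValueError(f"{path}: duplicate time columns present")
    matrix = numeric.iloc[:, 1:].to_numpy(dtype=float)  # (n_channels, m)
    chan_order = np.argsort(wavelengths)
    time_order = np.argsort(times_h)
    return SpectralSeries(
        wavelengths_nm=wavelengths[chan_order],
        times_h=times_h[time_order],
        absorbance=matrix[np.ix_(chan_order, time_order)].T,
        meta={"source": str(path)},
    )


def write_spectra_wide(series: SpectralSeries, path: str | Path) -> Path:
    """Write ``series`` in the canonical wide CSV layout."""
    path = Path(path)
    frame = pd.DataFrame({"wavelength_nm": series.wavelengths_nm})
    for j, t in enumerate(series.times_h):
        frame[_format_time_label(t)] = series.absorbance[j, :]
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_spectra_long(path: str | Path) -> SpectralSeries:
    """Read a long/tidy spectral CSV (``wavelength_nm,time_min,absorbance``)."""
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"wavelength_nm", "time_min", "absorbance"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: long format requires columns {sorted(required)}")
    pivot = frame.pivot_table(
        index="time_min", columns="wavelength_nm", values="absorbance", aggfunc="first"
    )
    if pivot.isna().to_numpy().any():
        raise ValueError(f"{path}: incomplete wavelength x time grid")
    return SpectralSeries(
        wavelengths_nm=pivot.columns.to_numpy(dtype=float),
        times_h=pivot.index.to_numpy(dtype=float) / 60.0,
        absorbance=pivot.to_numpy(dtype=float),
        meta={"source": str(path)},
    )


def read_ph(path: str | Path):
    """Read a pH table (``time_min,ph``); returns a :class:`~fermnir.simulate.PhProfile`.

    Rows are sorted by time; times are converted to hours.  pH values outside
    the open interval (0, 14) are rejected.
    """
    from .simulate import PhProfile  # local import avoids a cycle

    path = Path(path)
    frame = pd.read_csv(path)
    if not {"time_min", "ph"}.issubset(frame.columns):
        raise ValueError(f"{path}: pH table requires columns ['time_min', 'ph']")
    frame = _coerce_numeric(frame[["time_min", "ph"]], path)
    frame = frame.sort_values("time_min")
    ph = frame["ph"].to_numpy(dtype=float)
    if np.any((ph <= 0.0) | (ph >= 14.0)):
        raise ValueError(f"{path}: pH values outside (0, 14)")
    return PhProfile(frame["time_min"].to_numpy(dtype=float) / 60.0, ph)


def write_ph(profile, path: str | Path) -> Path:
    """Write a pH profile as ``time_min,ph``."""
    path = Path(path)
    frame = pd.DataFrame(
        {"time_min": np.round(profile.times_h * 60.0, 9), "ph": profile.ph}
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


# ---------------------------------------------------------------------------
# result tables


def write_dissimilarity_csv(result: "MwpcaResult", path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "window_index": result.window_starts,
            "start_time_min": np.round(result.window_start_times_h * 60.0, 9),
            "dissimilarity": result.dissimilarity,
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def write_loadings_csv(result: "MwpcaResult", path: str | Path) -> Path:
    """Wide table: one row per channel, one column per window loading."""
    path = Path(path)
    frame = pd.DataFrame({"wavelength_nm": result.wavelengths_nm})
    for k, start in enumerate(result.window_starts):
        frame[f"window_{start}"] = result.loadings[k, :]
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def write_stages_csv(
    segmentation: "StageSegmentation", result: "MwpcaResult", path: str | Path
) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "window_index": result.window_starts,
            "start_time_min": np.round(result.window_start_times_h * 60.0, 9),
            "stage": segmentation.labels,
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def write_variance_csv(spectrum: "VarianceSpectrum", path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths_nm, "variance": spectrum.variance}
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_variance_csv(path: str | Path, stage_id: int = 0):
    """Read a per-stage variance spectrum written by :func:`write_variance_csv`."""
    from .mwpca import VarianceSpectrum  # local import avoids a cycle

    path = Path(path)
    frame = pd.read_csv(path)
    if not {"wavelength_nm", "variance"}.issubset(frame.columns):
        raise ValueError(f"{path}: variance table requires columns ['wavelength_nm', 'variance']")
    frame = frame.sort_values("wavelength_nm")
    return VarianceSpectrum(
        stage_id=stage_id,
        wavelengths_nm=frame["wavelength_nm"].to_numpy(dtype=float),
        variance=frame["variance"].to_numpy(dtype=float),
        n_windows=0,
    )


def write_annotations_csv(annotations: Iterable["BandAnnotation"], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for ann in annotations:
        entry = ann.matched_entry
        rows.append(
            {
                "detected_nm": ann.detected_nm,
                "matched_reference": "" if entry is None else entry.label,
                "assignment": "" if entry is None else entry.assignment,
                "provenance": "" if entry is None else entry.provenance,
                "distance_nm": np.nan if entry is None else ann.distance_nm,
                "tie": ann.tie,
            }
        )
    pd.DataFrame(
        rows,
        columns=["detected_nm", "matched_reference", "assignment", "provenance", "distance_nm", "tie"],
    ).to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path
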