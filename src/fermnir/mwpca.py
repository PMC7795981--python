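"""Moving-window PCA over the time axis with a loading dissimilarity index.

A window of ``h_s`` consecutive spectra slides over the ``m x n`` series; the
first principal-component loading ``p(i)`` (unit right singular vector of the
column-mean-centred window submatrix) is computed for every window, and each
is compared with the loading of a reference window ``p(0)`` through the
dissimilarity index

    ``A_i = 1 - <p(i), p(0)>``

with ``p(i)`` sign-aligned so the inner product is nonnegative: ``A_i = 0``
when the window's dominant direction of change equals the reference's, and
``A_i = 1`` when it is orthogonal.  A fermentation run then segments into
stages from the shape of the ``A_i`` series, and per-stage variance spectra of
the loadings reveal the absorbance bands driving each stage.

Windows slide over TIME (consecutive spectra), not over wavelength: 33 spectra
at 15-min intervals with ``h_s = 5`` give 29 windows spanning the 8-h run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import SpectralSeries

__all__ = [
    "ZeroVarianceWindowError",
    "MwpcaResult",
    "StageSegmentation",
    "VarianceSpectrum",
    "extract_windows",
    "first_pc",
    "dissimilarity_index",
    "run_mwpca",
    "segment_stages",
    "loading_variance",
]

_UNIT_TOL = 1e-8


class ZeroVarianceWindowError(ValueError):
    """Raised when a window has no variance left after centring."""


@dataclass
class MwpcaResult:
    """Per-window first-PC loadings and the dissimilarity series.

    ``loadings`` rows are unit vectors stored with the sign convention that
    the largest-magnitude element is positive.  ``dissimilarity[i]`` compares
    window ``i`` with the reference window and lies in [0, 1].
    """

    window_size: int
    window_starts: np.ndarray  # 1-based start index of each window
    window_start_times_h: np.ndarray
    wavelengths_nm: np.ndarray
    loadings: np.ndarray  # (n_windows, n_channels)
    reference_window: int  # 1-based
    reference_loading: np.ndarray
    dissimilarity: np.ndarray
    scores: Optional[np.ndarray] = None  # (n_windows, window_size)

    @property
    def n_windows(self) -> int:
        return self.loadings.shape[0]


@dataclass
class StageSegmentation:
    """Assignment of each window to a contiguous process stage (1..k)."""

    labels: np.ndarray  # per-window stage id, nondecreasing
    breakpoints: tuple[int, ...]  # last window index (1-based) of each stage but the final
    method: str = "rise-fraction"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size == 0:
            raise ValueError("segmentation has no windows")
        if np.any(np.diff(self.labels) < 0):
            raise ValueError("stage labels must be nondecreasing over windows")

    @property
    def stage_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def windows_in_stage(self, stage_id: int) -> np.ndarray:
        """Zero-based window indices belonging to ``stage_id``."""
        return np.nonzero(self.labels == stage_id)[0]


@dataclass
class VarianceSpectrum:
    """Per-channel sample variance of the loadings across one stage's windows."""

    stage_id: int
    wavelengths_nm: np.ndarray
    variance: np.ndarray
    n_windows: int = 0


def extract_windows(series: SpectralSeries, h_s: int) -> list[np.ndarray]:
    """Submatrices ``X_i`` of ``h_s`` consecutive spectra (window i: rows i..i+h_s-1)."""
    m = series.n_times
    if h_s < 2:
        raise ValueError("window size must be at least 2")
    if h_s > m:
        raise ValueError(f"window size {h_s} exceeds the {m} available spectra")
    return [series.absorbance[i : i + h_s, :] for i in range(m - h_s + 1)]


def first_pc(window: np.ndarray, center: bool = True) -> np.ndarray:
    """First principal-component loading of one window submatrix.

    The unit right singular vector of the (column-mean-centred) window for its
    largest singular value, with the sign fixed so the largest-magnitude
    element is positive.  Raises :class:`ZeroVarianceWindowError` when the
    centred window is numerically zero.
    """
    X = np.asarray(window, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("window must be a 2-D matrix with at least 2 rows")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    scale = max(1.0, float(np.max(np.abs(window))))
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 1e-12 * scale:
        raise ZeroVarianceWindowError("window has zero variance after centring")
    v = vt[0]
    peak = int(np.argmax(np.abs(v)))
    if v[peak] < 0:
        v = -v
    return v


def dissimilarity_index(p_i: np.ndarray, p_0: np.ndarray) -> float:
    """``A_i = 1 - <p(i), p(0)>`` with sign alignment, in [0, 1].

    The loadings' SVD sign is arbitrary, so ``p(i)`` is aligned to make the
    inner product nonnegative before subtraction; identical directions give 0,
    orthogonal directions give 1.  Non-unit inputs are normalized with a
    warning.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_0 = np.asarray(p_0, dtype=float)
    if p_i.shape != p_0.shape or p_i.ndim != 1:
        raise ValueError("loadings must be 1-D vectors of equal length")
    norms = (float(np.linalg.norm(p_i)), float(np.linalg.norm(p_0)))
    if any(n == 0.0 for n in norms):
        raise ValueError("loadings must be nonzero")
    if any(abs(n - 1.0) > _UNIT_TOL for n in norms):
        warnings.warn("non-unit loading normalized before dissimilarity", stacklevel=2)
        p_i = p_i / norms[0]
        p_0 = p_0 / norms[1]
    return float(np.clip(1.0 - abs(float(p_i @ p_0)), 0.0, 1.0))


def run_mwpca(
    series: SpectralSeries,
    h_s: int = 5,
    reference_window: int = 1,
    center: bool = True,
    keep_scores: bool = False,
) -> MwpcaResult:
    """Moving-window PCA over the time axis of a (preprocessed) series.

    ``reference_window`` (1-based) selects which window's loading serves as
    ``p(0)``; its dissimilarity is exactly 0.
    """
    windows = extract_windows(series, h_s)
    n_windows = len(windows)
    if not 1 <= reference_window <= n_windows:
        raise ValueError(f"reference_window must be in [1, {n_windows}]")
    loadings = np.empty((n_windows, series.n_channels))
    scores = np.empty((n_windows, h_s)) if keep_scores else None
    for k, X in enumerate(windows):
        try:
            loadings[k] = first_pc(X, center=center)
        except ZeroVarianceWindowError as exc:
            raise ZeroVarianceWindowError(f"window {k + 1}: {exc}") from exc
        if keep_scores:
            Xc = X - X.mean(axis=0, keepdims=True) if center else X
            scores[k] = Xc @ loadings[k]
    p0 = loadings[reference_window - 1]
    dissimilarity = np.array([dissimilarity_index(row, p0) for row in loadings])
    dissimilarity[reference_window - 1] = 0.0  # exact by definition
    return MwpcaResult(
        window_size=h_s,
        window_starts=np.arange(1, n_windows + 1),
        window_start_times_h=series.times_h[:n_windows].copy(),
        wavelengths_nm=series.wavelengths_nm.copy(),
        loadings=loadings,
        reference_window=reference_window,
        reference_loading=p0.copy(),
        dissimilarity=dissimilarity,
        scores=scores,
    )


def segment_stages(
    result: MwpcaResult,
    method: str = "rise-fraction",
    f_lo: float = 0.1,
    f_hi: float = 0.9,
    breakpoints: Optional[Sequence[int]] = None,
) -> StageSegmentation:
    """Split the window sequence into contiguous stages.

    ``method="rise-fraction"`` (default) thresholds the dissimilarity series:
    stage 1 ends just before ``A`` first exceeds ``A_min + f_lo * range``,
    stage 3 begins where ``A`` first exceeds ``A_min + f_hi * range``.  A
    constant series yields a single stage with a warning.

    ``method="manual"`` applies user breakpoints verbatim: each breakpoint is
    the last window (1-based) of a stage; e.g. ``(10, 17)`` on 29 windows
    gives stages 1-10, 11-17, 18-29.
    """
    A = np.asarray(result.dissimilarity, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("dissimilarity series contains non-finite values")
    n = A.size
    if method == "manual":
        if breakpoints is None:
            raise ValueError("manual segmentation requires breakpoints")
        bp = [int(b) for b in breakpoints]
        if any(not 1 <= b < n for b in bp) or sorted(bp) != bp or len(set(bp)) != len(bp):
            raise ValueError("breakpoints must be strictly increasing window indices in [1, n)")
        labels = np.ones(n, dtype=int)
        for b in bp:
            labels[b:] += 1
        return StageSegmentation(labels=labels, breakpoints=tuple(bp), method="manual")
    if method != "rise-fraction":
        raise ValueError("method must be 'rise-fraction' or 'manual'")
    if not 0.0 < f_lo < f_hi < 1.0:
        raise ValueError("need 0 < f_lo < f_hi < 1")
    a_min, a_max = float(A.min()), float(A.max())
    span = a_max - a_min
    if span <= 1e-12:
        warnings.warn("dissimilarity series is constant; returning a single stage", stacklevel=2)
        return StageSegmentation(labels=np.ones(n, dtype=int), breakpoints=(), method=method)
    labels = np.ones(n, dtype=int)
    above_lo = np.nonzero(A > a_min + f_lo * span)[0]
    above_hi = np.nonzero(A > a_min + f_hi * span)[0]
    start2 = int(above_lo[0]) if above_lo.size else n
    start3 = int(above_hi[0]) if above_hi.size else n
    start3 = max(start3, start2)
    labels[start2:] = 2
    labels[start3:] = 3
    bp = []
    if start2 > 0 and start2 < n:
        bp.append(start2)  # last window of stage 1, 1-based == start2
    if start3 < n and start3 > start2:
        bp.append(start3)
    # relabel consecutively in case a stage came out empty
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels + 1
    return StageSegmentation(labels=labels, breakpoints=tuple(bp), method=method)


def loading_variance(
    result: MwpcaResult,
    segmentation: StageSegmentation,
    align: str = "sequential",
    stage_ids: Optional[Sequence[int]] = None,
) -> list[VarianceSpectrum]:
    """Per-stage, per-channel sample variance (ddof=1) of the loading values.

    Loadings are sign-aligned within each stage before the variance is taken
    (the SVD sign is arbitrary and an unlucky flip would otherwise inject
    spurious variance).  ``align="sequential"`` (default) chains each loading
    to its predecessor in the stage — robust even when a stage's loadings are
    nearly orthogonal to the reference loading; ``align="reference"`` aligns
    against ``p(0)``; ``align="none"`` uses the stored sign convention.
    Stages with a single window are rejected by name; ``stage_ids`` restricts
    the computation to a subset of stages.
    """
    if align not in ("sequential", "reference", "none"):
        raise ValueError("align must be 'sequential', 'reference', or 'none'")
    spectra = []
    for stage_id in (segmentation.stage_ids if stage_ids is None else stage_ids):
        idx = segmentation.windows_in_stage(stage_id)
        if idx.size < 2:
            raise ValueError(f"stage {stage_id} has fewer than 2 windows; variance undefined")
        block = result.loadings[idx, :].copy()
        if align == "reference":
            signs = np.sign(block @ result.reference_loading)
            signs[signs == 0] = 1.0
            block *= signs[:, None]
        elif align == "sequential":
            for k in range(1, block.shape[0]):
                if block[k] @ block[k - 1] < 0:
                    block[k] = -block[k]
        spectra.append(
            VarianceSpectrum(
                stage_id=int(stage_id),
                wavelengths_nm=result.wavelengths_nm.copy(),
                variance=np.var(block, axis=0, ddof=1),
                n_windows=int(idx.size),
            )
        )
    return spectra
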