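"""End-to-end orchestration: simulate/load -> preprocess -> MWPCA -> annotate.

``run_pipeline`` executes the full monitoring analysis from a single
:class:`PipelineConfig` and writes every artifact (CSV tables, a JSON summary,
optional plots) into an output directory.  Runs are deterministic for a fixed
config and seed; the summary contains no timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import io as fio
from . import simulate as fsim
from .bands import annotate_bands, find_variance_peaks
from .mwpca import loading_variance, run_mwpca, segment_stages
from .preprocess import SgSettings, savgol, truncate

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger("fermnir")


@dataclass
class PipelineConfig:
    """Configuration of the full monitoring pipeline.

    Exactly one input source must be set: a simulation config (synthetic run)
    or a spectra CSV path (real data), the latter optionally with a paired pH
    table.
    """

    out_dir: Path
    simulation: Optional[fsim.SimulationConfig] = None
    spectra_csv: Optional[Path] = None
    ph_csv: Optional[Path] = None
    truncate_lo_nm: float = 950.0
    truncate_hi_nm: float = 1880.0
    sg: SgSettings = field(default_factory=SgSettings)
    mwpca_lo_nm: float = 954.0
    mwpca_hi_nm: float = 1880.0
    window_size: int = 5
    reference_window: int = 1
    segmentation_method: str = "rise-fraction"
    f_lo: float = 0.1
    f_hi: float = 0.9
    breakpoints: Optional[tuple[int, ...]] = None
    annotation_tolerance_nm: float = 5.0
    peak_prominence_fraction: float = 0.05
    make_plots: bool = False
    log_level: str = "info"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.spectra_csv is not None:
            self.spectra_csv = Path(self.spectra_csv)
        if self.ph_csv is not None:
            self.ph_csv = Path(self.ph_csv)
        if (self.simulation is None) == (self.spectra_csv is None):
            raise ValueError("exactly one input source (simulation or spectra_csv) required")


@dataclass
class RunReport:
    """Paths of all artifacts written by a run, plus summary statistics."""

    out_dir: Path
    paths: dict[str, Path]
    summary: dict


def load_pipeline_config(path: str | Path, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (CLI flags override)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    sim_raw = raw.pop("simulation", None)
    if sim_raw is not None:
        bands_raw = sim_raw.pop("bands", None)
        if bands_raw is not None:
            sim_raw["bands"] = tuple(fsim.BandSpec(**b) for b in bands_raw)
        raw["simulation"] = fsim.SimulationConfig(**sim_raw)
    sg_raw = raw.pop("sg", None)
    if sg_raw is not None:
        raw["sg"] = SgSettings(**sg_raw)
    if raw.get("breakpoints") is not None:
        raw["breakpoints"] = tuple(int(b) for b in raw["breakpoints"])
    return PipelineConfig(**raw)


def _configure_logging(level: str) -> None:
    numeric = {"debug": logging.DEBUG, "info": logging.INFO, "warn": logging.WARNING}.get(
        level.lower(), logging.INFO
    )
    logging.basicConfig(level=numeric, format="%(name)s %(levelname)s: %(message)s")
    logger.setLevel(numeric)


def _summary_stage_table(segmentation, result) -> dict:
    stages = {}
    for stage_id in segmentation.stage_ids:
        idx = segmentation.windows_in_stage(stage_id)
        stages[str(int(stage_id))] = {
            "first_window": int(result.window_starts[idx[0]]),
            "last_window": int(result.window_starts[idx[-1]]),
            "n_windows": int(idx.size),
        }
    return stages


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis; returns artifact paths and a summary dict."""
    _configure_logging(config.log_level)
    paths: dict[str, Path] = {}

    # --- input stage (validate before writing anything)
    if config.spectra_csv is not None and not config.spectra_csv.exists():
        raise FileNotFoundError(f"input stage: spectra file not found: {config.spectra_csv}")
    if config.ph_csv is not None and not config.ph_csv.exists():
        raise FileNotFoundError(f"input stage: pH file not found: {config.ph_csv}")
    config.out_dir.mkdir(parents=True, exist_ok=True)

    ph_profile = None
    if config.simulation is not None:
        logger.info("simulating spectra (seed=%d)", config.simulation.seed)
        series, ph_profile = fsim.simulate_spectra(config.simulation)
        paths["spectra"] = fio.write_spectra_wide(series, config.out_dir / "spectra.csv")
        # pH is logged on the coarser 30-min protocol grid
        ph_times = np.arange(0.0, config.simulation.duration_h + 1e-9, 0.5)
        ph_out = fsim.simulate_ph_profile(config.simulation, ph_times)
        paths["ph"] = fio.write_ph(ph_out, config.out_dir / "ph.csv")
    else:
        logger.info("reading spectra from %s", config.spectra_csv)
        series = fio.read_spectra_wide(config.spectra_csv)
        if config.ph_csv is not None:
            ph_profile = fio.read_ph(config.ph_csv)

    n_spectra = series.n_times

    # --- preprocessing stage
    try:
        trimmed = truncate(series, config.truncate_lo_nm, config.truncate_hi_nm)
        smoothed = savgol(trimmed, config.sg)
        analysed = truncate(smoothed, config.mwpca_lo_nm, config.mwpca_hi_nm)
    except ValueError as exc:
        raise ValueError(f"preprocessing stage: {exc}") from exc
    logger.info(
        "preprocessed: %d spectra, %d channels (%.1f-%.1f nm)",
        analysed.n_times,
        analysed.n_channels,
        analysed.wavelengths_nm[0],
        analysed.wavelengths_nm[-1],
    )

    # --- MWPCA stage
    result = run_mwpca(
        analysed,
        h_s=config.window_size,
        reference_window=config.reference_window,
        keep_scores=True,
    )
    paths["dissimilarity"] = fio.write_dissimilarity_csv(result, config.out_dir / "dissimilarity.csv")
    paths["loadings"] = fio.write_loadings_csv(result, config.out_dir / "loadings.csv")
    segmentation = segment_stages(
        result,
        method=config.segmentation_method,
        f_lo=config.f_lo,
        f_hi=config.f_hi,
        breakpoints=config.breakpoints,
    )
    paths["stages"] = fio.write_stages_csv(segmentation, result, config.out_dir / "stages.csv")
    logger.info(
        "MWPCA: %d windows (h_s=%d), %d stages",
        result.n_windows,
        config.window_size,
        segmentation.stage_ids.size,
    )

    # --- variance + annotation stage
    multi_window_stages = [
        int(s) for s in segmentation.stage_ids if segmentation.windows_in_stage(s).size >= 2
    ]
    skipped = [int(s) for s in segmentation.stage_ids if int(s) not in multi_window_stages]
    for s in skipped:
        logger.warning("stage %d has a single window; variance spectrum skipped", s)
    variance_spectra = (
        loading_variance(result, segmentation, stage_ids=multi_window_stages)
        if multi_window_stages
        else []
    )
    top_bands: dict[str, list] = {}
    for vs in variance_spectra:
        paths[f"variance_stage{vs.stage_id}"] = fio.write_variance_csv(
            vs, config.out_dir / f"variance_stage{vs.stage_id}.csv"
        )
        peaks = find_variance_peaks(vs, config.peak_prominence_fraction)
        annotations = annotate_bands(peaks, config.annotation_tolerance_nm)
        paths[f"annotations_stage{vs.stage_id}"] = fio.write_annotations_csv(
            annotations, config.out_dir / f"annotations_stage{vs.stage_id}.csv"
        )
        ranked = sorted(
            (a for a in annotations),
            key=lambda a: -float(
                vs.variance[int(np.argmin(np.abs(vs.wavelengths_nm - a.detected_nm)))]
            ),
        )
        top_bands[str(vs.stage_id)] = [
            {
                "detected_nm": round(float(a.detected_nm), 2),
                "matched": a.matched_entry.label if a.matched_entry else None,
                "assignment": a.matched_entry.assignment if a.matched_entry else None,
            }
            for a in ranked[:3]
        ]

    if config.make_plots:
        _write_plots(result, variance_spectra, config.out_dir, paths)

    summary = {
        "n_spectra": int(n_spectra),
        "n_channels_analysed": int(analysed.n_channels),
        "analysed_range_nm": [
            round(float(analysed.wavelengths_nm[0]), 3),
            round(float(analysed.wavelengths_nm[-1]), 3),
        ],
        "window_size": int(config.window_size),
        "n_windows": int(result.n_windows),
        "reference_window": int(config.reference_window),
        "dissimilarity_max": float(result.dissimilarity.max()),
        "segmentation_method": segmentation.method,
        "stages": _summary_stage_table(segmentation, result),
        "top_bands_per_stage": top_bands,
        "seed": int(config.simulation.seed) if config.simulation is not None else None,
        "ph_start": float(ph_profile.ph[0]) if ph_profile is not None else None,
        "ph_end": float(ph_profile.ph[-1]) if ph_profile is not None else None,
    }
    summary_path = config.out_dir / "summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = summary_path
    logger.info("run complete: %s", summary_path)
    return RunReport(out_dir=config.out_dir, paths=paths, summary=summary)


def _write_plots(result, variance_spectra, out_dir: Path, paths: dict) -> None:
    """Optional diagnostic plots (never parsed by tests)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.window_starts, result.dissimilarity, "o-")
    ax.set_xlabel("window start position")
    ax.set_ylabel("dissimilarity index $A_i$")
    fig.tight_layout()
    p = out_dir / "dissimilarity.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["dissimilarity_plot"] = p
    for vs in variance_spectra:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(vs.wavelengths_nm, vs.variance)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("loading variance")
        ax.set_title(f"stage {vs.stage_id}")
        fig.tight_layout()
        p = out_dir / f"variance_stage{vs.stage_id}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"variance_stage{vs.stage_id}_plot"] = p
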