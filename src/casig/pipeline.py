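"""End-to-end runs: one config drives detection, extraction, zone analysis
and (optionally) spectra, with all outputs collected in a time-stamped
results directory and a run log recording every parameter actually used."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .frequency import dominant_frequency, power_spectrum
from .roi import RoiConfig, detect_rois, detect_rois_ratiometric, extract_traces, \
    reference_image
from .stack_io import ResultsDir, make_results_dir, read_stack, read_traces_csv, \
    write_traces_csv
from .traces import AnalysisConfig, StimulationZone, analyze_traceset, \
    write_metrics_csv

__all__ = [
    "RunConfig",
    "load_run_config",
    "run_single_wavelength",
    "run_ratiometric",
    "run_csv_analysis",
]

log = logging.getLogger("casig")

METRICS_CSV = "total_data_by_zone.csv"


@dataclasses.dataclass
class RunConfig:
    """Everything one run needs. ``stacks`` for single-wavelength input,
    ``pairs`` as (f340, ratio) path tuples for ratiometric input,
    ``traces_csv`` for CSV-only analysis; exactly the inputs matching the
    chosen entry point must be present."""

    out_base: str = "."
    dt: float | None = None
    stacks: list[str] = dataclasses.field(default_factory=list)
    pairs: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    traces_csv: str | None = None
    zones: list[StimulationZone] = dataclasses.field(default_factory=list)
    roi: RoiConfig | None = None
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)
    make_plots: bool = True
    spectrum_band: tuple[float, float] | None = None

    def validate(self, need: str) -> None:
        if not self.zones:
            raise ValueError("config error: no stimulation zones given")
        for prev, cur in zip(self.zones, self.zones[1:]):
            if cur.start < prev.end:
                raise ValueError("config error: zones overlap or are unsorted")
        if need == "stacks" and not self.stacks:
            raise ValueError("config error: no input stacks")
        if need == "pairs" and not self.pairs:
            raise ValueError("config error: no (f340, ratio) input pairs")
        if need == "csv" and not self.traces_csv:
            raise ValueError("config error: no traces CSV")
        if need in ("stacks", "pairs") and self.roi is None:
            raise ValueError("config error: missing roi section")


def load_run_config(path) -> RunConfig:
    """Load a YAML run config; keys mirror the dataclass fields, with
    ``roi`` and ``analysis`` as nested mappings and zones as
    ``[[start, end], ...]``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("out_base", "dt", "stacks", "traces_csv", "make_plots"):
        if key in raw:
            kwargs[key] = raw[key]
    if "pairs" in raw:
        kwargs["pairs"] = [tuple(p) for p in raw["pairs"]]
    if "zones" in raw:
        kwargs["zones"] = [StimulationZone(float(a), float(b)) for a, b in raw["zones"]]
    if "roi" in raw:
        roi = dict(raw["roi"])
        for rng in ("unstim_range", "stim_range"):
            if rng in roi:
                roi[rng] = tuple(roi[rng])
        kwargs["roi"] = RoiConfig(**roi)
    if "analysis" in raw:
        kwargs["analysis"] = AnalysisConfig(**raw["analysis"])
    if "spectrum_band" in raw and raw["spectrum_band"] is not None:
        kwargs["spectrum_band"] = tuple(raw["spectrum_band"])
    return RunConfig(**kwargs)


def _start_run(cfg: RunConfig, tag: str) -> ResultsDir:
    results = make_results_dir(cfg.out_base, tag)
    handler = logging.FileHandler(Path(results.path) / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("casig %s run '%s' -> %s", __version__, tag, results.path)
    log.info("config: %s", cfg)
    return results


def _end_run(results: ResultsDir) -> None:
    for handler in list(log.handlers):
        if isinstance(handler, logging.FileHandler) and \
                handler.baseFilename.startswith(str(results.path)):
            handler.close()
            log.removeHandler(handler)


def _analyze_and_save(traces, cfg: RunConfig, out: Path) -> pd.DataFrame:
    df = analyze_traceset(traces, cfg.zones, cfg.analysis)
    write_metrics_csv(df, out / METRICS_CSV)
    log.info("stage analysis: wrote %s (%d rows)", out / METRICS_CSV, len(df))
    if cfg.make_plots:
        from .plotting import plot_roi_traces

        plot_roi_traces(traces, cfg.zones, cfg.analysis, df, out / "plots")
    if cfg.spectrum_band is not None:
        rows = []
        for k, rid in enumerate(traces.roi_ids):
            spec = power_spectrum(traces.times, traces.values[:, k])
            freq, pwr = dominant_frequency(spec, cfg.spectrum_band)
            rows.append({"roi_id": int(rid), "dominant_freq_hz": freq,
                         "power": pwr})
        pd.DataFrame(rows).to_csv(out / "dominant_frequency.csv", index=False)
        log.info("stage spectrum: wrote dominant_frequency.csv")
    return df


def run_single_wavelength(cfg: RunConfig) -> ResultsDir:
    """Detect ROIs, extract traces and quantify each single-wavelength
    stack; one subdirectory per input stack."""
    cfg.validate("stacks")
    results = _start_run(cfg, "single")
    try:
        for stack_path in cfg.stacks:
            name = Path(stack_path).stem
            sub = Path(results.path) / name
            sub.mkdir(exist_ok=True)
            try:
                stack = read_stack(stack_path, dt=cfg.dt)
                labels = detect_rois(stack, cfg.roi)
                log.info("stage detect [%s]: %d ROIs", name, labels.max())
                tifffile.imwrite(sub / "labels.tif", labels.astype(np.uint16))
                traces = extract_traces(stack, labels)
                write_traces_csv(traces, sub / "traces.csv")
                if cfg.make_plots:
                    from .plotting import plot_label_overlay

                    ref = reference_image(stack, cfg.roi.stim_range,
                                          cfg.roi.statistic)
                    plot_label_overlay(ref, labels, sub / "roi_overlay.png")
                _analyze_and_save(traces, cfg, sub)
            except Exception:
                log.exception("run aborted in stack %s", name)
                raise
    finally:
        _end_run(results)
    return results


def run_ratiometric(cfg: RunConfig) -> ResultsDir:
    """Ratiometric batch: anatomy ROIs from each 340 nm stack, traces from
    the paired ratio stack, then zone analysis in the configured mode."""
    cfg.validate("pairs")
    results = _start_run(cfg, "ratio")
    try:
        for f340_path, ratio_path in cfg.pairs:
            name = Path(ratio_path).stem
            sub = Path(results.path) / name
            sub.mkdir(exist_ok=True)
            try:
                f340 = read_stack(f340_path, dt=cfg.dt)
                ratio = read_stack(ratio_path, dt=cfg.dt)
                labels = detect_rois_ratiometric(f340, ratio, cfg.roi)
                log.info("stage detect [%s]: %d ROIs", name, labels.max())
                tifffile.imwrite(sub / "labels.tif", labels.astype(np.uint16))
                traces = extract_traces(ratio, labels)
                write_traces_csv(traces, sub / "traces.csv")
                if cfg.make_plots:
                    from .plotting import plot_label_overlay

                    plot_label_overlay(f340.frames.mean(axis=0), labels,
                                       sub / "roi_overlay.png")
                _analyze_and_save(traces, cfg, sub)
            except Exception:
                log.exception("run aborted in experiment %s", name)
                raise
    finally:
        _end_run(results)
    return results


def run_csv_analysis(cfg: RunConfig) -> ResultsDir:
    """Analyze an existing traces CSV; numerically identical to analyzing
    the traces straight after extraction."""
    cfg.validate("csv")
    results = _start_run(cfg, "csv")
    try:
        traces = read_traces_csv(cfg.traces_csv)
        _analyze_and_save(traces, cfg, Path(results.path))
    except Exception:
        log.exception("run aborted in csv analysis")
        raise
    finally:
        _end_run(results)
    return results
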