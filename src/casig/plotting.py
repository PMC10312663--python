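"""Annotated result plots: per-ROI traces with shaded stimulation zones,
detected peaks as black dots and onsets as red dots, plus ROI-boundary
overlays on a reference image."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stack_io import TraceSet
from .traces import AnalysisConfig, StimulationZone, compute_baseline, detect_peaks

__all__ = ["plot_roi_traces", "plot_label_overlay"]


def plot_roi_traces(traces: TraceSet, zones: list[StimulationZone],
                    cfg: AnalysisConfig, metrics: pd.DataFrame,
                    out_dir) -> list[Path]:
    """One PNG per ROI: trace, shaded zones, black peak dots, red onset
    dots. Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, rid in enumerate(traces.roi_ids):
        v = traces.values[:, k]
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(traces.times, v, lw=0.8, color="tab:blue")
        rows = metrics[metrics["roi_id"] == rid]
        for zone in zones:
            ax.axvspan(zone.start, zone.end, color="0.92", zorder=0)
        for zi, zone in enumerate(zones):
            base, _ = compute_baseline(traces.times, v, zone, cfg.baseline_window)
            work = 2 * base - v if cfg.mode == "inhibitor" else v
            peaks = detect_peaks(traces.times, work, zone, base, cfg)
            if len(peaks):
                vals = 2 * base - peaks.peak_values if cfg.mode == "inhibitor" \
                    else peaks.peak_values
                ax.plot(peaks.peak_times, vals, "ko", ms=4)
            row = rows[rows["zone_index"] == zi]
            if len(row):
                onset = row["onset_time_s"].iloc[0]
                if np.isfinite(onset):
                    idx = int(np.argmin(np.abs(traces.times - onset)))
                    ax.plot(onset, v[idx], "ro", ms=5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("intensity")
        ax.set_title(f"ROI {rid} ({cfg.mode})")
        fig.tight_layout()
        path = out_dir / f"roi_{rid}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_label_overlay(reference: np.ndarray, labels: np.ndarray,
                       path) -> Path:
    """Reference image with ROI boundaries and label numbers."""
    from skimage.segmentation import find_boundaries

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(reference, cmap="gray", interpolation="nearest")
    boundaries = find_boundaries(labels, mode="outer")
    overlay = np.zeros((*labels.shape, 4))
    overlay[boundaries] = (1.0, 0.2, 0.2, 1.0)
    ax.imshow(overlay, interpolation="nearest")
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rr, cc = np.nonzero(labels == lab)
        ax.text(cc.mean(), rr.mean(), str(lab), color="yellow",
                ha="center", va="center", fontsize=8)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
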