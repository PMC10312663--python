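"""Zone-based quantification of per-ROI calcium traces.

Every metric is computed per stimulation zone — a half-open time interval
``[start, end)`` during which the stimulus (agonist, SERCA-pump inhibitor,
Ca²⁺ readmission, channel blocker, ...) is applied. A baseline and its noise
level come from the window immediately preceding the zone; the response
threshold is baseline ± k·sd; latency is the delay from zone start to the
first threshold crossing.

Three modes share one upward analysis core:

* ``agonist`` — the response point is the first detected peak; reported
  heights are baseline-subtracted, and peaks are found on a lightly smoothed
  trace by topographic prominence with a minimum peak spacing.
* ``soce`` — store-operated entry rises too gradually for peak detection to
  be reliable, so the response point is the maximum sample within the zone.
* ``inhibitor`` — the exact mirror: the trace is reflected about its
  baseline and analyzed upward, so the onset is the first crossing *below*
  threshold, the response point is the zone *minimum*, and slopes come back
  negated (a downward slope). This mirroring makes the two directions
  structurally identical.

Smoothing (a centered moving average of odd width) is applied only where
noise hurts — peak finding and slope estimation; baselines, AUC and the zone
extremum use the raw trace.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .stack_io import TraceSet

__all__ = [
    "StimulationZone",
    "AnalysisConfig",
    "PeakSet",
    "ZoneMetrics",
    "METRICS_COLUMNS",
    "smooth_trace",
    "compute_baseline",
    "compute_threshold",
    "detect_onset",
    "detect_peaks",
    "first_peak_metrics",
    "compute_auc",
    "zone_extremum",
    "analyze_zone",
    "analyze_traceset",
    "write_metrics_csv",
    "parse_zones",
]

MODES = ("agonist", "soce", "inhibitor")


@dataclasses.dataclass(frozen=True)
class StimulationZone:
    """Half-open stimulation interval [start, end) in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    def contains(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t)
        return (t >= self.start) & (t < self.end)


def parse_zones(text: str) -> list[StimulationZone]:
    """Parse ``"200:800,900:1074"`` into a validated, sorted zone list."""
    zones = []
    for chunk in text.split(","):
        a, _, b = chunk.partition(":")
        zones.append(StimulationZone(float(a), float(b)))
    _validate_zones(zones)
    return zones


def _validate_zones(zones: list[StimulationZone]) -> None:
    for prev, cur in zip(zones, zones[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"zones must be sorted and non-overlapping: "
                f"[{prev.start}, {prev.end}) then [{cur.start}, {cur.end})"
            )


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the zone analysis.

    baseline_window
        Seconds immediately preceding each zone used for the baseline mean
        and noise sd (clipped at the start of the trace, with a warning).
    threshold_k
        Response threshold offset in units of the baseline noise sd; the
        offset never drops below ``abs_min`` trace units (the floor matters
        for noise-free data, where sd = 0).
    min_prominence
        Peaks must have topographic prominence of at least this fraction of
        (zone maximum − baseline).
    min_peak_distance
        Minimum spacing between surviving peaks, seconds; higher peaks win,
        ties go to the earlier peak.
    smoothing_width
        Width (odd number of frames) of the centered moving average applied
        before peak finding and slope estimation. 1 disables smoothing.
    """

    mode: str = "agonist"
    baseline_window: float = 30.0
    threshold_k: float = 3.0
    abs_min: float = 0.0
    min_prominence: float = 0.1
    min_peak_distance: float = 10.0
    smoothing_width: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not self.baseline_window > 0:
            raise ValueError("baseline_window must be > 0")
        if self.smoothing_width < 1 or self.smoothing_width % 2 == 0:
            raise ValueError("smoothing_width must be odd and >= 1")
        if self.min_prominence < 0:
            raise ValueError("min_prominence must be >= 0")
        if self.min_peak_distance < 0:
            raise ValueError("min_peak_distance must be >= 0")


@dataclasses.dataclass(frozen=True)
class PeakSet:
    """Detected peaks within one zone (times ascending)."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    prominences: np.ndarray

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclasses.dataclass
class ZoneMetrics:
    """One row of the per-(ROI, zone) metrics table.

    Missing values (e.g. no threshold crossing, hence no latency) are NaN
    and render as empty CSV cells. In inhibitor mode ``rise_time_s`` holds
    the fall time, slopes are negative, and peak heights are trough depths
    (≤ 0); ``extremum_*`` is the zone maximum in agonist/soce modes and the
    zone minimum in inhibitor mode.
    """

    roi_id: int
    zone_index: int
    zone_start_s: float
    zone_end_s: float
    baseline: float
    threshold: float
    onset_time_s: float
    latency_s: float
    rise_time_s: float
    max_slope_per_s: float
    secant_slope_per_s: float
    auc: float
    peak_count: int
    first_peak_height: float
    max_peak_height: float
    extremum_time_s: float
    extremum_value: float


METRICS_COLUMNS = [f.name for f in dataclasses.fields(ZoneMetrics)]


def smooth_trace(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average of odd ``width``; near the ends the window
    shrinks to the available samples. ``width == 1`` returns a copy."""
    values = np.asarray(values, dtype=np.float64)
    if width < 1 or width % 2 == 0:
        raise ValueError("smoothing width must be odd and >= 1")
    if width == 1:
        return values.copy()
    kernel = np.ones(width)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def _zone_indices(times: np.ndarray, zone: StimulationZone) -> np.ndarray:
    idx = np.nonzero(zone.contains(times))[0]
    if idx.size == 0:
        raise ValueError(
            f"zone [{zone.start}, {zone.end}) contains no samples "
            f"(trace spans [{times[0]}, {times[-1]}])"
        )
    return idx


def compute_baseline(times: np.ndarray, values: np.ndarray,
                     zone: StimulationZone, baseline_window: float,
                     ) -> tuple[float, float]:
    """Baseline mean and noise sd (ddof 1) over the ``baseline_window``
    seconds immediately preceding the zone, clipped at the trace start."""
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    lo = zone.start - baseline_window
    if lo < times[0]:
        warnings.warn(
            f"baseline window [{lo}, {zone.start}) clipped to trace start "
            f"{times[0]}", stacklevel=2,
        )
        lo = times[0]
    sel = (times >= lo) & (times < zone.start)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(
            f"baseline window before zone start {zone.start} has only {n} "
            f"samples (need >= 3)"
        )
    window = values[sel]
    return float(window.mean()), float(window.std(ddof=1))


def compute_threshold(baseline: float, noise_sd: float, threshold_k: float,
                      mode: str = "agonist", abs_min: float = 0.0) -> float:
    """Response threshold: baseline ± max(k·sd, abs_min); the sign follows
    the mode (below baseline for inhibitor)."""
    offset = max(threshold_k * noise_sd, abs_min)
    if mode == "inhibitor":
        return baseline - offset
    return baseline + offset


def detect_onset(times: np.ndarray, values: np.ndarray, zone: StimulationZone,
                 threshold: float, direction: str = "above") -> float | None:
    """Time of the first sample in the zone strictly beyond the threshold,
    or None if the trace never crosses."""
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    idx = _zone_indices(times, zone)
    if direction == "above":
        hits = idx[values[idx] > threshold]
    elif direction == "below":
        hits = idx[values[idx] < threshold]
    else:
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    if hits.size == 0:
        return None
    return float(times[hits[0]])


def _local_maxima(seg: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau reports its left-most
    index. Segment endpoints are never maxima."""
    n = seg.size
    peaks = []
    i = 1
    while i < n - 1:
        if seg[i] > seg[i - 1]:
            j = i
            while j < n - 1 and seg[j + 1] == seg[i]:
                j += 1
            if j < n - 1 and seg[j + 1] < seg[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=np.intp)


def detect_peaks(times: np.ndarray, values: np.ndarray, zone: StimulationZone,
                 baseline: float, cfg: AnalysisConfig) -> PeakSet:
    """Prominent peaks on the smoothed trace within one zone.

    Candidates are strict local maxima (plateaus take the left-most index).
    A candidate survives if its topographic prominence within the zone is at
    least ``min_prominence · (zone max − baseline)``; the survivors are then
    thinned greedily, keeping higher peaks first (ties: earlier peak), so
    that the final peaks are at least ``min_peak_distance`` seconds apart.
    """
    times = np.asarray(times, dtype=np.float64)
    smoothed = smooth_trace(np.asarray(values, dtype=np.float64),
                            cfg.smoothing_width)
    idx = _zone_indices(times, zone)
    seg = smoothed[idx]
    seg_t = times[idx]
    cand = _local_maxima(seg)
    empty = PeakSet(np.empty(0), np.empty(0), np.empty(0))
    if cand.size == 0:
        return empty
    prom = sps.peak_prominences(seg, cand)[0]
    min_prom = cfg.min_prominence * (seg.max() - baseline)
    keep = prom >= min_prom
    cand, prom = cand[keep], prom[keep]
    if cand.size == 0:
        return empty
    order = sorted(range(cand.size), key=lambda i: (-seg[cand[i]], cand[i]))
    selected: list[int] = []
    for i in order:
        t_i = seg_t[cand[i]]
        if all(abs(t_i - seg_t[cand[j]]) >= cfg.min_peak_distance for j in selected):
            selected.append(i)
    selected.sort(key=lambda i: cand[i])
    picked = cand[selected]
    return PeakSet(
        peak_times=seg_t[picked],
        peak_values=seg[picked],
        prominences=prom[selected],
    )


def first_peak_metrics(times: np.ndarray, values: np.ndarray,
                       onset_time: float, first_peak_time: float,
                       smoothing_width: int = 1) -> tuple[float, float]:
    """Rise time and maximum slope from stimulation onset to the first peak.

    The slope is the largest consecutive-sample finite difference of the
    smoothed trace over [onset, peak], divided by dt. A degenerate interval
    (onset == peak) has rise time 0 and no slope (NaN).
    """
    if onset_time > first_peak_time:
        raise ValueError(
            f"onset ({onset_time}) after first peak ({first_peak_time})"
        )
    times = np.asarray(times, dtype=np.float64)
    smoothed = smooth_trace(np.asarray(values, dtype=np.float64), smoothing_width)
    rise_time = float(first_peak_time - onset_time)
    sel = (times >= onset_time) & (times <= first_peak_time)
    seg = smoothed[sel]
    if seg.size < 2:
        return rise_time, float("nan")
    dt = float(times[1] - times[0])
    max_slope = float(np.max(np.diff(seg)) / dt)
    return rise_time, max_slope


def compute_auc(times: np.ndarray, values: np.ndarray, zone: StimulationZone,
                baseline: float) -> float:
    """Trapezoidal area of max(trace − baseline, 0) over the zone.

    Integration runs over samples from ``zone.start`` up to and including a
    sample landing exactly on ``zone.end``, so areas over adjacent zones add
    up exactly to the area over their union.
    """
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    sel = (times >= zone.start) & (times <= zone.end)
    if sel.sum() < 2:
        return 0.0
    excess = np.maximum(values[sel] - baseline, 0.0)
    return float(np.trapezoid(excess, times[sel]))


def zone_extremum(times: np.ndarray, values: np.ndarray, zone: StimulationZone,
                  direction: str = "max") -> tuple[float, float]:
    """Arg-extremum over the samples in the zone; ties go to the earliest
    time."""
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    idx = _zone_indices(times, zone)
    seg = values[idx]
    if direction == "max":
        k = int(np.argmax(seg))
    elif direction == "min":
        k = int(np.argmin(seg))
    else:
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    return float(times[idx[k]]), float(seg[k])


def analyze_zone(times: np.ndarray, values: np.ndarray, zone: StimulationZone,
                 cfg: AnalysisConfig, roi_id: int = 0,
                 zone_index: int = 0) -> ZoneMetrics:
    """Quantify one trace over one zone in the configured mode.

    Inhibitor mode reflects the trace about its baseline and runs the
    upward analysis, then flips the sign-bearing outputs; this guarantees
    that downward responses are measured by exactly the same rules as
    upward ones.
    """
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    baseline, noise_sd = compute_baseline(times, values, zone, cfg.baseline_window)
    mirrored = cfg.mode == "inhibitor"
    work = 2.0 * baseline - values if mirrored else values

    thr_up = compute_threshold(baseline, noise_sd, cfg.threshold_k,
                               "agonist", cfg.abs_min)
    onset = detect_onset(times, work, zone, thr_up, "above")
    peaks = detect_peaks(times, work, zone, baseline, cfg)
    ext_t, ext_v = zone_extremum(times, work, zone, "max")
    auc = compute_auc(times, work, zone, baseline)

    nan = float("nan")
    latency = rise_time = max_slope = secant = nan
    first_ph = max_ph = nan
    if len(peaks):
        first_ph = float(peaks.peak_values[0] - baseline)
        max_ph = float(peaks.peak_values.max() - baseline)
    if onset is not None:
        latency = onset - zone.start
        if cfg.mode == "agonist":
            response_t = float(peaks.peak_times[0]) if len(peaks) else None
        else:  # soce / inhibitor: zone extremum, robust to gradual rises
            response_t = ext_t
        if response_t is not None and response_t >= onset:
            rise_time, max_slope = first_peak_metrics(
                times, work, onset, response_t, cfg.smoothing_width
            )
        if cfg.mode in ("soce", "inhibitor") and ext_t > onset:
            secant = (ext_v - thr_up) / (ext_t - onset)

    if mirrored:
        threshold_out = 2.0 * baseline - thr_up
        max_slope = -max_slope
        secant = -secant
        first_ph = -first_ph
        max_ph = -max_ph
        ext_v = 2.0 * baseline - ext_v
    else:
        threshold_out = thr_up

    return ZoneMetrics(
        roi_id=roi_id,
        zone_index=zone_index,
        zone_start_s=zone.start,
        zone_end_s=zone.end,
        baseline=baseline,
        threshold=threshold_out,
        onset_time_s=nan if onset is None else onset,
        latency_s=latency,
        rise_time_s=rise_time,
        max_slope_per_s=max_slope,
        secant_slope_per_s=secant,
        auc=auc,
        peak_count=len(peaks),
        first_peak_height=first_ph,
        max_peak_height=max_ph,
        extremum_time_s=ext_t,
        extremum_value=ext_v,
    )


def analyze_traceset(traces: TraceSet, zones: list[StimulationZone],
                     cfg: AnalysisConfig) -> pd.DataFrame:
    """One metrics row per (ROI, zone); stable column order."""
    _validate_zones(zones)
    for zone in zones:
        if zone.start > traces.times[-1]:
            raise ValueError(
                f"zone [{zone.start}, {zone.end}) lies outside the trace "
                f"time span (ends at {traces.times[-1]})"
            )
    rows = []
    for k, rid in enumerate(traces.roi_ids):
        for zi, zone in enumerate(zones):
            m = analyze_zone(traces.times, traces.values[:, k], zone, cfg,
                             roi_id=int(rid), zone_index=zi)
            rows.append(dataclasses.asdict(m))
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    """Write the metrics table; missing values become empty cells."""
    df.to_csv(path, index=False)
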