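"""I/O for the formats the pipeline touches.

Multi-page grayscale TIFF movies come in and out through :func:`read_stack` /
:func:`write_stack`; per-ROI traces travel as plain CSV with a ``time`` column
and one ``roi_<id>`` column per region; results of a run land in a
time-stamped directory created by :func:`make_results_dir`.

Intensities are held as float64 internally regardless of the on-disk integer
type so that ratio stacks and frame averages stay exact.
"""

from __future__ import annotations

import dataclasses
import re
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "TraceSet",
    "ResultsDir",
    "read_stack",
    "write_stack",
    "read_traces_csv",
    "write_traces_csv",
    "make_results_dir",
]

_ROI_COL = re.compile(r"^roi_(\d+)$")


@dataclasses.dataclass(frozen=True)
class ImageStack:
    """A movie: ``frames`` with shape (T, H, W), frame interval ``dt`` in
    seconds, and the acquisition time ``t0`` of frame 0.

    Frame ``i`` is acquired at ``t0 + i * dt``.
    """

    frames: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (T, H, W), got shape {frames.shape}")
        if frames.shape[0] < 1 or frames.shape[1] < 1 or frames.shape[2] < 1:
            raise ValueError(f"empty stack dimension: {frames.shape}")
        if not np.all(np.isfinite(frames)):
            raise ValueError("stack contains non-finite intensities")
        if not (self.dt > 0):
            raise ValueError(f"dt must be > 0, got {self.dt}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of every frame, in seconds."""
        return self.t0 + self.dt * np.arange(self.n_frames, dtype=np.float64)


@dataclasses.dataclass(frozen=True)
class TraceSet:
    """K aligned per-ROI time series on a shared uniform time grid.

    ``values`` has shape (T, K); column ``k`` belongs to ``roi_ids[k]``.
    ROI ids are distinct positive integers, kept sorted ascending.
    """

    times: np.ndarray
    values: np.ndarray
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        roi_ids = np.asarray(self.roi_ids, dtype=np.int64)
        if times.ndim != 1:
            raise ValueError("times must be 1-D")
        if values.ndim != 2 or values.shape[0] != times.shape[0]:
            raise ValueError(
                f"values must be (T, K) with T == len(times); got {values.shape}"
            )
        if roi_ids.ndim != 1 or roi_ids.shape[0] != values.shape[1]:
            raise ValueError("roi_ids length must equal number of trace columns")
        if roi_ids.size:
            if np.any(roi_ids <= 0):
                raise ValueError("roi_ids must be positive")
            if np.unique(roi_ids).size != roi_ids.size:
                raise ValueError("roi_ids must be distinct")
            order = np.argsort(roi_ids)
            roi_ids = roi_ids[order]
            values = values[:, order]
        if not np.all(np.isfinite(values)):
            raise ValueError("trace values must be finite")
        _check_uniform_times(times)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_ids", roi_ids)

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_rois(self) -> int:
        return self.roi_ids.shape[0]

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for a single-sample trace set")
        return float(self.times[1] - self.times[0])

    def trace(self, roi_id: int) -> np.ndarray:
        """Return the series for one ROI id."""
        idx = np.nonzero(self.roi_ids == roi_id)[0]
        if idx.size == 0:
            raise KeyError(f"no ROI with id {roi_id}")
        return self.values[:, idx[0]]


@dataclasses.dataclass(frozen=True)
class ResultsDir:
    """An existing output directory whose name ends in a creation timestamp."""

    path: Path

    def __fspath__(self) -> str:
        return str(self.path)


def _check_uniform_times(times: np.ndarray, rtol: float = 1e-6) -> None:
    if times.size >= 2:
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > rtol * max(abs(dt), 1e-300)):
            raise ValueError("non-uniform time steps")


def read_stack(path, dt: float | None = None, t0: float = 0.0) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    ``dt`` given explicitly wins over any frame interval recorded in the
    file's metadata; with neither available the read fails, because a movie
    without a time base cannot be analyzed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        if len(pages) == 0:
            raise ValueError(f"{path}: TIFF has no pages")
        first = pages[0]
        if first.samplesperpixel != 1:
            raise ValueError(
                f"{path}: unsupported layout (multi-sample/RGB TIFF, "
                f"{first.samplesperpixel} samples per pixel)"
            )
        shape0 = first.shape
        if len(shape0) != 2:
            raise ValueError(f"{path}: pages are not 2-D grayscale (shape {shape0})")
        frames = np.empty((len(pages), *shape0), dtype=np.float64)
        for i, page in enumerate(pages):
            if page.shape != shape0:
                raise ValueError(
                    f"{path}: pages of unequal shape ({page.shape} vs {shape0})"
                )
            frames[i] = page.asarray()
        if dt is None:
            dt = _dt_from_metadata(tif)
    if dt is None:
        raise ValueError(
            f"{path}: no frame interval: pass dt explicitly (none found in metadata)"
        )
    return ImageStack(frames=frames, dt=float(dt), t0=float(t0))


def _dt_from_metadata(tif: tifffile.TiffFile) -> float | None:
    meta = tif.imagej_metadata
    if meta and meta.get("finterval"):
        return float(meta["finterval"])
    shaped = tif.shaped_metadata
    if shaped:
        dt = shaped[0].get("dt")
        if dt:
            return float(dt)
    return None


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF.

    Integer-valued data within the 16-bit range is written as uint16
    (bit-exact round trip); anything else is written as float64. The frame
    interval is stored in the file's JSON description and recovered by
    :func:`read_stack`.
    """
    path = Path(path)
    frames = stack.frames
    integral = np.all(frames == np.round(frames))
    if integral and frames.min() >= 0 and frames.max() <= np.iinfo(np.uint16).max:
        data = frames.astype(np.uint16)
    else:
        data = frames  # float64
    tifffile.imwrite(path, data, photometric="minisblack",
                     metadata={"dt": stack.dt, "t0": stack.t0})


def write_traces_csv(traces: TraceSet, path) -> None:
    """Write a trace set as CSV: header ``time,roi_<id>,...``, one row per
    frame, numbers at full (round-trippable) precision."""
    df = pd.DataFrame({"time": traces.times})
    for k, rid in enumerate(traces.roi_ids):
        df[f"roi_{rid}"] = traces.values[:, k]
    df.to_csv(path, index=False)


def read_traces_csv(path) -> TraceSet:
    """Read a CSV in the dialect written by :func:`write_traces_csv`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\r\n").split(",")
    if not header or header[0] != "time":
        raise ValueError(f"{path}: first column must be 'time', got {header[:1]}")
    roi_ids = []
    for col in header[1:]:
        m = _ROI_COL.match(col)
        if not m:
            raise ValueError(f"{path}: unexpected column header {col!r}")
        roi_ids.append(int(m.group(1)))
    if len(set(roi_ids)) != len(roi_ids):
        raise ValueError(f"{path}: duplicate ROI headers")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric cells in column {col!r}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cells")
    times = df["time"].to_numpy(dtype=np.float64)
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return TraceSet(times=times, values=values, roi_ids=np.array(roi_ids, dtype=np.int64))


def make_results_dir(base, tag: str) -> ResultsDir:
    """Create ``base/<tag>_<YYYYMMDD-HHMMSS>``; on collision within the same
    second, append ``-1``, ``-2``, ... so an existing directory is never
    reused."""
    base = Path(base)
    if not base.is_dir():
        raise NotADirectoryError(f"base directory does not exist: {base}")
    stamp = time.strftime("%Y%m%d-%H%M%S")
    candidate = base / f"{tag}_{stamp}"
    suffix = 0
    while True:
        try:
            candidate.mkdir()
            return ResultsDir(path=candidate)
        except FileExistsError:
            suffix += 1
            candidate = base / f"{tag}_{stamp}-{suffix}"
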