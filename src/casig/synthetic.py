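"""Synthetic calcium-imaging data with known ground truth.

A field of elliptical "cells" is laid out at random (seeded, with a minimum
boundary gap); each cell carries a piecewise-linear / exponential response
model so every downstream quantity — latency, rise time, slope, peak height,
area under the curve — has a closed form. Stacks are rendered as
baseline + stimulus-locked transient + additive Gaussian noise, both for a
single-wavelength indicator (one movie) and for a ratiometric indicator
(an anatomy movie at 340 nm excitation plus a 340/380 ratio movie).

Everything is a pure function of its arguments and the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .stack_io import ImageStack, TraceSet

__all__ = [
    "TraceModel",
    "CellSpec",
    "Layout",
    "GroundTruth",
    "eval_trace",
    "ellipse_mask",
    "make_layout",
    "render_stack",
    "render_ratiometric",
    "make_trace_set",
]

KINDS = ("flat", "agonist", "soce", "inhibitor")


@dataclasses.dataclass(frozen=True)
class TraceModel:
    """Response of one cell, relative to its baseline.

    kind
        ``flat`` — no response. ``agonist`` — linear rise from 0 at
        ``onset_time`` to ``amplitude`` at ``peak_time``, then exponential
        decay with time constant ``decay_tau``. ``soce`` — same rise, then a
        plateau at ``amplitude`` (store-operated entry keeps cytosolic Ca²⁺
        elevated while external Ca²⁺ is present). ``inhibitor`` — linear fall
        from 0 at ``onset_time`` to ``amplitude`` (negative) at
        ``peak_time``, then hold.
    """

    kind: str
    onset_time: float = 0.0
    peak_time: float = 1.0
    amplitude: float = 0.0
    decay_tau: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.kind != "flat":
            if not self.onset_time < self.peak_time:
                raise ValueError("onset_time must precede peak_time")
        if self.amplitude < 0 and self.kind not in ("inhibitor", "flat"):
            raise ValueError("negative amplitude is only meaningful for inhibitor kind")
        if self.kind == "agonist" and not self.decay_tau > 0:
            raise ValueError("decay_tau must be > 0")


def eval_trace(model: TraceModel, times: np.ndarray) -> np.ndarray:
    """Evaluate a response model on a time grid (baseline-relative values)."""
    t = np.asarray(times, dtype=np.float64)
    out = np.zeros_like(t)
    if model.kind == "flat":
        return out
    rising = (t >= model.onset_time) & (t < model.peak_time)
    out[rising] = (
        model.amplitude
        * (t[rising] - model.onset_time)
        / (model.peak_time - model.onset_time)
    )
    after = t >= model.peak_time
    if model.kind == "agonist":
        out[after] = model.amplitude * np.exp(-(t[after] - model.peak_time) / model.decay_tau)
    else:  # soce plateau / inhibitor hold
        out[after] = model.amplitude
    return out


@dataclasses.dataclass(frozen=True)
class CellSpec:
    """One elliptical cell: center (row, col), semi-axes (a, b) in pixels,
    resting fluorescence, and its response model."""

    center: tuple[float, float]
    axes: tuple[float, float]
    baseline_intensity: float
    response: TraceModel


@dataclasses.dataclass(frozen=True)
class Layout:
    """A placed field of cells plus the ground-truth label image
    (0 background, 1..K cells, label k+1 is ``cells[k]``)."""

    cells: tuple[CellSpec, ...]
    label_image: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def mask(self, label: int) -> np.ndarray:
        return self.label_image == label


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Everything needed to verify a detection or a metric: the label image,
    the per-cell specs, and the noise/seed used for rendering."""

    layout: Layout
    noise_sd: float
    seed: int
    dt: float
    n_frames: int
    t0: float = 0.0

    @property
    def label_image(self) -> np.ndarray:
        return self.layout.label_image

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames, dtype=np.float64)

    def expected_trace(self, label: int) -> np.ndarray:
        """Noise-free cell-mean trace of cell ``label`` (baseline included)."""
        cell = self.layout.cells[label - 1]
        return cell.baseline_intensity + eval_trace(cell.response, self.times)


def ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                 axes: tuple[float, float]) -> np.ndarray:
    """Boolean mask of a filled ellipse: ((r-r0)/a)² + ((c-c0)/b)² ≤ 1."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = axes
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


_MAX_TRIES = 10_000


def make_layout(
    n_cells: int,
    image_shape: tuple[int, int] = (128, 128),
    min_gap: float = 3.0,
    seed: int = 0,
    *,
    axes_range: tuple[float, float] = (4.0, 8.0),
    baseline_range: tuple[float, float] = (60.0, 120.0),
    response: TraceModel | None = None,
) -> Layout:
    """Place ``n_cells`` non-overlapping ellipses by rejection sampling.

    With ``min_gap > 0`` every pair of cell boundaries is at least
    ``min_gap`` pixels apart (Euclidean); ``min_gap = 0`` permits touching
    cells, which is what the watershed-splitting tests need. Placement is
    bounded at 10⁴ draws and fails loudly if the packing is infeasible.

    All cells share ``response`` (default: an agonist transient rising from
    t = 30 s to amplitude 30 at t = 45 s, decaying with τ = 20 s) so trace
    metrics have a single closed form; pass a model per experiment type.
    """
    H, W = image_shape
    if response is None:
        response = TraceModel(
            kind="agonist", onset_time=30.0, peak_time=45.0, amplitude=30.0,
            decay_tau=20.0,
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros((H, W), dtype=np.int32)
    occupied = np.zeros((H, W), dtype=bool)
    cells: list[CellSpec] = []
    tries = 0
    while len(cells) < n_cells:
        if tries >= _MAX_TRIES:
            raise RuntimeError(
                f"could not place {n_cells} cells in {image_shape} with "
                f"min_gap={min_gap} after {_MAX_TRIES} tries"
            )
        tries += 1
        a = rng.uniform(*axes_range)
        b = rng.uniform(*axes_range)
        r0 = rng.uniform(a + 1, H - a - 2)
        c0 = rng.uniform(b + 1, W - b - 2)
        cand = ellipse_mask((H, W), (r0, c0), (a, b))
        if not cand.any():
            continue
        if occupied.any():
            if (cand & occupied).any():
                continue
            if min_gap > 0:
                # distance from each candidate pixel to the nearest placed pixel
                dist = ndi.distance_transform_edt(~occupied)
                if dist[cand].min() < min_gap:
                    continue
        baseline = rng.uniform(*baseline_range)
        cells.append(CellSpec(center=(r0, c0), axes=(a, b),
                              baseline_intensity=baseline, response=response))
        labels[cand] = len(cells)
        occupied |= cand
    return Layout(cells=tuple(cells), label_image=labels)


def render_stack(
    layout: Layout,
    dt: float = 1.0,
    n_frames: int = 120,
    noise_sd: float = 0.0,
    seed: int = 0,
    t0: float = 0.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-wavelength movie from a layout.

    Pixel (r, c) of frame i is ``baseline_intensity + eval_trace(model, tᵢ)``
    for its cell (background baseline 0), plus N(0, noise_sd²) noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    H, W = layout.label_image.shape
    times = t0 + dt * np.arange(n_frames, dtype=np.float64)
    frames = np.zeros((n_frames, H, W), dtype=np.float64)
    for k, cell in enumerate(layout.cells, start=1):
        mask = layout.label_image == k
        sig = cell.baseline_intensity + eval_trace(cell.response, times)
        frames[:, mask] += sig[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    truth = GroundTruth(layout=layout, noise_sd=noise_sd, seed=seed, dt=dt,
                        n_frames=n_frames, t0=t0)
    return ImageStack(frames=frames, dt=dt, t0=t0), truth


def render_ratiometric(
    layout: Layout,
    dt: float = 1.0,
    n_frames: int = 120,
    noise_sd: float = 0.0,
    seed: int = 0,
    t0: float = 0.0,
    *,
    ratio_baseline: float = 1.0,
    f340_noise_sd: float | None = None,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Render a Fura-2-style experiment: an anatomy stack (340 nm excitation,
    per-cell baseline fluorescence, no stimulus signal) and a 340/380 ratio
    stack carrying the response models on a flat baseline of
    ``ratio_baseline`` (default 1.0, inside and outside cells).

    ``noise_sd`` applies to the ratio stack; the anatomy stack gets
    ``f340_noise_sd`` (default: ``noise_sd`` scaled by the mean cell
    baseline, since raw fluorescence counts are ~100× the ratio scale).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    H, W = layout.label_image.shape
    times = t0 + dt * np.arange(n_frames, dtype=np.float64)
    anatomy = np.zeros((H, W), dtype=np.float64)
    ratio = np.full((n_frames, H, W), ratio_baseline, dtype=np.float64)
    for k, cell in enumerate(layout.cells, start=1):
        mask = layout.label_image == k
        anatomy[mask] = cell.baseline_intensity
        ratio[:, mask] += eval_trace(cell.response, times)[:, None]
    f340 = np.broadcast_to(anatomy, (n_frames, H, W)).copy()
    if f340_noise_sd is None:
        scale = np.mean([c.baseline_intensity for c in layout.cells]) if layout.cells else 1.0
        f340_noise_sd = noise_sd * scale
    rng = np.random.default_rng(seed)
    if f340_noise_sd > 0:
        f340 += rng.normal(0.0, f340_noise_sd, size=f340.shape)
    if noise_sd > 0:
        ratio += rng.normal(0.0, noise_sd, size=ratio.shape)
    truth = GroundTruth(layout=layout, noise_sd=noise_sd, seed=seed, dt=dt,
                        n_frames=n_frames, t0=t0)
    return (
        ImageStack(frames=f340, dt=dt, t0=t0),
        ImageStack(frames=ratio, dt=dt, t0=t0),
        truth,
    )


def make_trace_set(
    models: list[TraceModel],
    dt: float = 1.0,
    n_frames: int = 120,
    noise_sd: float = 0.0,
    seed: int = 0,
    baselines: list[float] | float = 1.0,
    t0: float = 0.0,
) -> TraceSet:
    """Build a TraceSet directly from response models (no imaging step);
    ROI ids are 1..K in model order."""
    times = t0 + dt * np.arange(n_frames, dtype=np.float64)
    K = len(models)
    if np.isscalar(baselines):
        baselines = [float(baselines)] * K
    if len(baselines) != K:
        raise ValueError("need one baseline per model")
    values = np.empty((n_frames, K), dtype=np.float64)
    for k, (model, base) in enumerate(zip(models, baselines)):
        values[:, k] = base + eval_trace(model, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values += rng.normal(0.0, noise_sd, size=values.shape)
    return TraceSet(times=times, values=values,
                    roi_ids=np.arange(1, K + 1, dtype=np.int64))
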