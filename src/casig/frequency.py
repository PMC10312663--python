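"""Frequency-domain summaries of per-ROI traces.

A plain one-sided periodogram (optionally Hann-windowed) and the dominant
frequency within a band. Oscillatory calcium signals are usually easier to
read as peak trains, but a spectral summary is useful for comparing pacing
rates across conditions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["Spectrum", "power_spectrum", "dominant_frequency"]


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum: ``freqs`` in Hz ascending from 0 to the
    Nyquist frequency 1/(2·dt); ``power`` is |FFT|²/n per bin."""

    freqs: np.ndarray
    power: np.ndarray
    n_samples: int
    dt: float


def power_spectrum(times: np.ndarray, values: np.ndarray,
                   detrend: str = "mean", window: str = "none") -> Spectrum:
    """One-sided periodogram of a uniformly sampled series.

    ``detrend="mean"`` subtracts the series mean (removes the DC bin, which
    otherwise dwarfs everything in a fluorescence trace). ``window="hann"``
    applies a Hann taper before the transform.
    """
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    steps = np.diff(times)
    if np.any(steps <= 0) or np.any(np.abs(steps - steps[0]) > 1e-6 * steps[0]):
        raise ValueError("non-uniform sampling")
    dt = float(steps[0])
    if detrend == "mean":
        values = values - values.mean()
    elif detrend != "none":
        raise ValueError(f"unknown detrend {detrend!r}")
    if window == "hann":
        values = values * np.hanning(n)
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    spectrum = np.fft.rfft(values)
    power = np.abs(spectrum) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=dt)
    return Spectrum(freqs=freqs, power=power, n_samples=n, dt=dt)


def dominant_frequency(spec: Spectrum, band: tuple[float, float]
                       ) -> tuple[float, float]:
    """(frequency, power) of the strongest bin within ``band`` (Hz,
    inclusive); ties go to the lower frequency. ``band[0]`` must be > 0 so
    the DC bin is excluded."""
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi):
        raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    sel = np.nonzero((spec.freqs >= f_lo) & (spec.freqs <= f_hi))[0]
    if sel.size == 0:
        raise ValueError(f"band ({f_lo}, {f_hi}) Hz contains no spectral bins")
    k = sel[int(np.argmax(spec.power[sel]))]  # argmax returns first max: low-f tie rule
    return float(spec.freqs[k]), float(spec.power[k])
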