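# Methods

## The analysis model

The package treats a calcium-imaging experiment as a movie `F(t, r, c)` of
fluorescence intensity (or 340/380 excitation ratio), a set of cell regions
in the image plane, and one or more *stimulation zones* — half-open time
intervals `[start, end)` in seconds during which a stimulus is applied.
Frame `i` is acquired at `t0 + i·dt`; `dt` (seconds per frame) must be
supplied by the user or the file metadata, with an explicit value always
taking precedence over metadata, since acquisition metadata is unreliable
across microscope vendors.

### ROI detection (single wavelength)

1. Reference images: per-pixel mean (or population sd, ddof 0) over an
   unstimulated frame range and over a stimulated frame range. The two
   ranges must be disjoint.
2. Difference image `D = max(S − U, 0)`. Subtracting removes static
   anatomy; negatives are clamped because a pixel that got dimmer carries no
   activation signal, and a signed difference would force sign handling in
   every downstream step.
3. Threshold: `D > cutoff`, strictly. In percentile mode the cutoff is the
   requested percentile of the *nonzero* pixels; difference images are
   mostly zero, so a percentile over all pixels would sit at zero and be
   meaningless. A degenerate (constant) image yields an empty mask with a
   warning rather than an arbitrary split.
4. Optional outline mask: Canny edges at a configurable sigma/hysteresis,
   closed contours filled; the mask keeps each contour's interior plus the
   one ring of edge pixels adjacent to it. The Canny edge straddles the
   true boundary: interiors alone under-cover a disk by ~10 %, interiors
   plus the full (possibly 2-px-thick) edge over-cover by a similar margin,
   and the one-ring rule lands within a few percent of the enclosed area.
   Open edge fragments enclose nothing and are dropped. The outline mask is
   *intersected* with the threshold mask and is off by default — plain
   thresholding of the difference image is the primary path; the edge path
   helps when cells respond weakly but have crisp outlines.
5. Cleanup: `erode_iter` erosions then `dilate_iter` dilations with a fixed
   3×3 cross (4-connectivity), then removal of 8-connected components
   smaller than `min_area` pixels. Note that an opening with the cross
   element shaves single corner pixels off rectangular regions and does not
   remove 1-pixel bumps that are flush with a larger body (the dilation
   regrows them); this is the exact behavior of the stated element, not an
   approximation.
6. Labeling: 8-connected components, or — when `split_touching` is set —
   watershed on the negated distance transform with markers at
   distance-transform maxima separated by ≥ `min_marker_distance` pixels.
   Labels are renumbered 1..K by decreasing area, ties broken by the
   row-major position of the first pixel, so label identity is
   deterministic.

For ratiometric (Fura-2 style) input the anatomy mask comes from the
time-averaged 340 nm stack — that channel shows the cells regardless of
calcium level — thresholded directly (no difference image), and traces are
extracted from the ratio stack. A batch wrapper maps one configuration over
many experiment pairs.

Traces are per-label means of each frame. Intensities are held as float64
throughout regardless of the on-disk integer type, so ratios and means are
exact.

### Zone quantification

Per trace and zone, in trace units and seconds:

* **baseline / noise**: mean and sd (ddof 1) over the `baseline_window`
  seconds immediately preceding the zone, clipped at the trace start with a
  warning; fewer than 3 samples is an error.
* **threshold**: `b ± max(k·σ, abs_min)`. The `abs_min` floor (default 0)
  exists because noise-free traces have σ = 0 and a pure `k·σ` offset would
  put the threshold exactly at baseline.
* **onset / latency**: first sample in the zone strictly beyond the
  threshold (no sub-frame interpolation — the simplest defensible rule;
  latency is therefore quantized to the frame interval and biased late by
  at most one frame). Latency is referenced to the zone start. A trace that
  never crosses has no onset; all onset-dependent fields are then missing
  (empty CSV cells, never sentinel numbers).
* **peaks** (agonist mode): strict local maxima of the smoothed trace
  restricted to the zone, plateaus taking the left-most index, with
  topographic prominence ≥ `min_prominence · (zone max − b)`, then greedy
  suppression keeping higher peaks (ties: earlier) until survivors are
  ≥ `min_peak_distance` apart. Prominences come from `scipy.signal`; the
  test suite checks the whole chain against an independent brute-force
  enumeration.
* **response point**: agonist — the first detected peak; soce — the zone
  maximum, because store-operated entry can rise too gradually for any
  peak-prominence rule; inhibitor — the zone minimum.
* **rise time / max slope**: response time minus onset time; largest
  consecutive-sample finite difference of the smoothed trace between onset
  and response, per second. For soce/inhibitor a *secant* slope
  `(extremum − threshold)/(extremum time − onset)` is also reported, which
  is the natural "rate of entry/inhibition" number; the threshold (not the
  baseline) anchors it, mirroring the onset rule.
* **AUC**: trapezoidal integral of `max(trace − b, 0)`. Integration
  includes a sample landing exactly on the zone end, so AUCs over adjacent
  zones add exactly to the AUC over their union.
* **extremum**: earliest arg-max (arg-min for inhibitor) over the zone's
  samples.

**Mirroring.** Inhibitor mode reflects the trace about its baseline
(`2b − trace`) and runs the upward analysis, then negates the sign-bearing
outputs. This is not a shortcut but the definition: a downward response is
measured by exactly the same rules as an upward one, which makes the
up/down symmetry property (`inhibitor(T) ≡ −soce(2b − T)`, field for field)
hold by construction and keeps the two directions from drifting apart as
parameters change. Equality against *agonist* mode on reflected traces
additionally requires the first peak and the zone extremum to coincide,
which is the case for transient (rise-and-decay) responses.

Smoothing is a centered moving average of odd width (shrinking at the trace
ends), applied only to peak finding and slope estimation; baselines, AUC and
extrema use the raw trace. Slopes and peak positions are noise-sensitive,
integrals and means are not, and smoothing an integrand would bias the AUC.

### Frequency analysis

A plain one-sided periodogram (`|rfft|²/n`, optional mean detrend and Hann
window) and the arg-max bin within a user band excluding DC, ties to the
lower frequency. No Welch averaging by default: the traces are short and
the output is used comparatively, so the simplest deterministic estimator
is preferred.

## Synthetic data: what it emulates and what it does not

The generator places elliptical "cells" (semi-axes 4–8 px by default,
rejection-sampled with a minimum Euclidean boundary gap, bounded at 10⁴
draws) on a dark background, with per-cell resting intensity drawn from
60–120 counts. Each cell carries a piecewise-linear/exponential response:
agonist — linear rise from onset to peak, exponential decay; soce — rise
then plateau; inhibitor — linear fall to a negative amplitude, then hold.
These shapes give every metric a closed form, which is what makes exactness
testable. Rendering adds i.i.d. Gaussian noise (sd configurable; the
validation suite uses 0 and 5 % of the response amplitude). Defaults
elsewhere in the suite: 128×128 px, 120 frames at 1 s/frame, 5 cells,
amplitude 30 on baselines of ~60–120, onset 30 s, peak 45 s, τ = 20 s —
chosen as a realistic single-field recording of a sparse preparation.

The ratiometric generator emits an anatomy stack (per-cell baseline counts,
no stimulus signal) and a ratio stack with baseline 1.0 everywhere and the
response riding on the cells, with independent noise scales for the two.

Deliberately not modeled: photobleaching, focal drift and motion,
Poisson photon statistics, spatially correlated noise, intra-cell response
heterogeneity, and overlapping cells in depth. Passing tests therefore
demonstrate the correctness of the algorithms under the stated model, not
robustness to every artifact of real microscopy; on real data the
user-adjustable thresholds and morphology iterations exist precisely to
absorb what the model leaves out.

## Numerical choices

* Strict `>` comparisons at thresholds; boundary-valued pixels/samples are
  *not* selected.
* Ties: extremum — earliest time; peak suppression — higher wins, then
  earlier; label numbering — larger area, then row-major first pixel;
  dominant frequency — lower frequency.
* CSVs are written at full round-trip precision and read back with
  `float_precision="round_trip"`, so analyzing an exported CSV reproduces
  the metrics file byte for byte.
* 16-bit-integer-valued stacks are written as uint16 (bit-exact round
  trip); anything else as float64.
* Missing metric values are NaN internally and empty CSV cells on disk.
* Time stamps in results-directory names get a numeric suffix on collision
  within the same second; a directory is never reused.

## Validation problem sizes

The shipped validation (`scripts/acceptance.py` and the test suite) uses
5-cell 128×128×120 stacks (clean and 5 % noise, 3 seeds), 10–20 randomized
closed-form traces per metric family, 100 random-walk traces of 50–500
samples for the peak-detection oracle comparison, and 240–257-sample series
for the spectral checks. These sizes give sub-pixel/sub-frame sensitivity
for every assertion while keeping the whole suite near-instant.

## Known limitations

* Onset detection is sample-resolution; latencies inherit a one-frame
  quantization.
* The percentile threshold is undefined on an all-equal image (warned,
  empty mask).
* Watershed splitting relies on distance-transform maxima: cells joined by
  a bridge wider than the cell radius will not be split.
* The frequency module is a minimal periodogram summary, not a
  time–frequency analysis; bursting/irregular oscillations are better
  served by the peak metrics.
* No motion correction or manual ROI editing; inputs are assumed
  pre-registered (vendor software or ImageJ).
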