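# casig

Quantitative analysis of Ca²⁺-signaling imaging data: automated
region-of-interest (ROI) detection on fluorescence time-series image stacks,
per-ROI trace extraction, and zone-based quantification of responses, with a
synthetic ground-truth generator so every stage can be validated without any
experimental dataset.

It is written for physiologists analyzing movies from calcium-imaging
experiments — single-wavelength indicators (gCaMP-style, brighter at higher
[Ca²⁺]) recorded in vivo or in vitro, and ratiometric Fura-2 experiments
where the 340/380 nm excitation ratio tracks [Ca²⁺] — covering the common
experiment types: agonist stimulation (e.g. carbachol or trypsin),
store-operated calcium entry (SOCE, e.g. CPA in Ca²⁺-free buffer followed by
Ca²⁺ readmission), and inhibitor experiments (e.g. ORAI blockers), plus a
periodogram-based frequency summary.

## Method

**ROI detection.** For a single-wavelength movie, an *unstimulated* reference
image `U` and a *stimulated* reference image `S` are formed as per-pixel
means (or standard deviations) over user-chosen frame ranges. The difference
image `D = max(S − U, 0)` removes static background structure and leaves the
responding cell regions, which are segmented by intensity thresholding
(absolute or percentile of the nonzero pixels), optionally intersected with a
Canny-edge/flood-fill outline mask, cleaned by erosion/dilation (3×3 cross)
and small-region filtering, and labeled — with optional watershed splitting
of touching cells using distance-transform maxima as markers. For
ratiometric data the anatomy comes from the time-averaged 340 nm stack and
traces are extracted from the ratio stack. Trace *k* at frame *i* is the mean
of frame *i* over the pixels of label *k*.

**Zone metrics.** Each trace is quantified per *stimulation zone* `[start,
end)` (seconds). From the window immediately preceding the zone: baseline
`b` (mean) and noise `σ` (sd, ddof 1). Threshold `θ = b ± max(k·σ,
abs_min)`. Latency is `t_onset − start`, where `t_onset` is the first sample
strictly beyond `θ`. In **agonist** mode the response point is the first
detected peak — peaks are strict local maxima of the (optionally smoothed)
trace with topographic prominence ≥ `min_prominence · (zone max − b)`,
thinned to a minimum spacing; in **soce** mode it is the zone *maximum*
(gradual SOCE rises defeat peak detection); in **inhibitor** mode the trace
is reflected about its baseline and analyzed upward, so onset is the first
crossing *below* `θ`, the response point is the zone *minimum*, and slopes
come back negative. Reported per (ROI, zone): baseline, threshold, latency,
rise (or fall) time, maximum slope (largest finite difference between onset
and the response point, per second), secant slope (soce/inhibitor), AUC
(trapezoidal area of `max(trace − b, 0)`), peak count, first/maximum peak
height (baseline-subtracted) and the zone extremum — the
`total_data_by_zone.csv` table.

## Worked example

```python
from casig import (make_layout, render_stack, RoiConfig, detect_rois,
                   extract_traces, AnalysisConfig, StimulationZone,
                   analyze_traceset)

# 5 synthetic cells, 128x128, 120 frames at 1 s/frame, 5% noise;
# each cell: baseline + linear rise 30->45 s to amplitude 30, tau 20 s decay
layout = make_layout(5, (128, 128), min_gap=3.0, seed=11)
stack, truth = render_stack(layout, dt=1.0, n_frames=120, noise_sd=1.5, seed=11)

roi_cfg = RoiConfig(unstim_range=(0, 25), stim_range=(40, 55), threshold_value=10.0)
labels = detect_rois(stack, roi_cfg)
print("detected ROIs:", labels.max())

traces = extract_traces(stack, labels)
cfg = AnalysisConfig(mode="agonist", baseline_window=15.0, threshold_k=3.0)
df = analyze_traceset(traces, [StimulationZone(20, 100)], cfg)
```

Output:

```
detected ROIs: 5
 roi_id  baseline  latency_s  rise_time_s  max_slope_per_s     auc  peak_count  first_peak_height
      1    92.940       11.0         14.0            2.334 787.890           1             30.128
      2    81.219       11.0         14.0            2.233 785.713           1             29.928
      ...
```

All five cells are recovered. Latency 11 s means the trace first exceeded
baseline + 3σ eleven seconds after the zone opened at t = 20 s (the true
ramp starts at t = 30 s, i.e. latency 10 s, and the first sample strictly
above threshold is one frame later). Rise time 14 s and max slope ≈ 2.3/s
recover the generated ramp (15 s to amplitude 30, slope 2/s, steepened
slightly by noise), and first-peak height ≈ 30 is the generated amplitude
above baseline.

The same analyses run from the shell:

```sh
casig synth --cells 5 --shape 128x128 --frames 120 --noise 1.5 --seed 11 --out data/
casig detect --stack data/stack.tif --config roi.yaml --dt 1.0 --out det/
casig analyze --traces det/traces.csv --zones "20:100" --mode agonist --out results/
casig spectrum --traces det/traces.csv --band 0.05:0.4 --out results/
casig run --config run.yaml --workflow single   # full pipeline, timestamped results dir
```

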