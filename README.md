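# halotrace

Analysis pipeline for one-photon **miniscope calcium imaging** of neurons in
freely moving animals, built around the study design of recording
hypothalamic orexin/hypocretin neurons during mating behaviors. It takes a
fluorescence movie, hand-drawn ROIs and a behavioral annotation table, and
produces per-cell z-scored ΔF/F₀ traces plus the population statistics that
summarize them across behavior epochs. A first-class synthetic-data
generator produces movies, LED synchronization traces, behavior scripts and
ground truth with the statistical structure the analysis assumes, so every
stage can be validated against a known answer.

## What the pipeline computes

For each cell *i* with ROI mask *Rᵢ* and neuropil halo *Hᵢ* (the pixels at
chessboard distance 3–6 outside the ROI that belong to no ROI):

1. **Trace extraction** — F_roi(t), F_halo(t): mean fluorescence over *Rᵢ*
   and *Hᵢ* per frame (10 frames/s).
2. **Lowpass** — 3-frame centered moving average of both traces.
3. **Neuropil subtraction** — F(t) = F_roi(t) − F_halo(t), removing the
   shared out-of-focus contamination that dominates one-photon imaging.
4. **Photobleaching correction** — ΔF/F₀(t) = (F(t) − F₀(t)) / F₀(t) with
   F₀(t) the mean of F over a 120 s moving window centered on t.
5. **z-score** — z(t) = (ΔF/F₀ − mean) / sd per cell over the recording.

Downstream analyses: per-epoch means and variabilities of z (all bouts of a
behavior pooled), Pearson correlation of the per-epoch **population
vectors** across behaviors with r² as the coefficient of determination,
**event-triggered averages** in a ±10 s window around bout onsets/offsets,
behavioral **bout statistics** (mean ± sample std, cumulative time, pooled
Student's t-tests), and a **fluorescence-to-firing-rate calibration**
(steady-state fluorescence of 10 s constant-rate steps regressed on the
commanded rate). Imaging (10 frames/s) and behavior video (65 frames/s)
timelines are aligned via an LED that blinks once per imaging frame in the
behavior camera's view.

## Worked example

`examples/epoch_statistics.py` simulates a session in which cells carry an
intromission-up/-down pattern, its sign-flipped pattern during anterior
thrusting (AT), and an amplified pattern during ejaculation, then runs the
full pipeline:

```
population-vector correlations:
              intromission     AT  ejaculation
intromission          1.00 -0.960        0.990
AT                   -0.96  1.000       -0.929
ejaculation           0.99 -0.929        1.000

mean r2 of intromission with the other mating behaviors: 0.951

AT bouts: [2.4, 4.6, 1.1] s -> 2.7 +/- 1.8 s
intromission cumulative: 73.1 s across 2 bouts
AT vs intromission durations: t = -8.49, df = 3, p = 0.003
```

The correlation matrix shows the recovered structure: AT anticorrelated
with intromission, ejaculation positively correlated with it. The bout
statistics come from the built-in `male_day10` behavioral timeline (three
AT bouts of 2.4/4.6/1.1 s between intromission bouts of 41.6 and 31.5 s);
mean ± sample std and cumulative durations are computed from the table, and
the t-test compares AT and intromission bout durations with pooled
variance.

The other scripts in `examples/` each demonstrate one capability:
simulation and file I/O, stage-by-stage trace processing, LED
synchronization, event-triggered averages, and the calibration fit.

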