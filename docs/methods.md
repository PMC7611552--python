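# Methods

## The measurement model

The pipeline assumes the standard one-photon miniscope imaging model: each
pixel records a bleach-scaled sum of local cellular fluorescence, a
spatially broad neuropil background, and sensor noise,

    movie(t, x) = B(t) · ( Σ_i c_i(t) · footprint_i(x) + n(t) ) + ε(t, x),

where `c_i(t)` is cell *i*'s fluorescence (a baseline level plus spikes
convolved with the indicator kernel), `n(t)` the neuropil, `B(t)` a
monotone photobleach factor and `ε` i.i.d. Gaussian noise. The analysis
chain is designed so that each stage removes one nuisance term: halo
subtraction removes `n`, the moving-window ΔF/F₀ removes `B` (and the
units), and the z-score removes per-cell gain and offset. Consequently the
z-scored output is exactly invariant to positive affine rescaling of the
raw movie, which the test suite asserts end to end.

Fluorescence is treated as a low-passed proxy for firing rate, not
deconvolved into spikes. The calibration module justifies this reading:
steady-state fluorescence of constant-rate steps is linear in rate across
the physiological 0–30 Hz range (r² ≈ 1 in the noise-free fit), so
z-scored ΔF/F₀ is interpretable as relative firing rate.

## Halo geometry

The neuropil halo of an ROI is the union of chessboard-distance rings 3–6
outside the ROI, minus every ROI's pixels, clipped at the image border.
Rings are computed with an exact chamfer distance transform
(`scipy.ndimage.distance_transform_cdt`), equivalent to iterated
8-connected dilation; an exhaustive per-pixel distance enumeration serves
as the independent oracle in the tests (200 random geometries). "Nearest
pixels" has no unique metric on a grid; a Euclidean variant (band
(2, 6] of `distance_transform_edt`) is available via `metric="euclidean"`.
A cell whose halo comes out empty (crowded field of view) is flagged and
passes through neuropil subtraction unchanged rather than failing the run.

## Trace processing: parameters and numerical choices

| parameter | default | meaning |
|---|---|---|
| lowpass width | 3 frames (0.3 s) | centered moving average; edge windows truncate to the available frames |
| F₀ window | 120 s | moving-window baseline for ΔF/F₀ |
| z-score denominator | sample std (ddof=1) | population std available via `ddof=0` |
| halo rings | 3–6, chessboard | config-exposed |
| processing order | lowpass → subtraction → ΔF/F₀ → z | fixed |

**F₀ edge handling.** F₀(t) is the mean of the trace over a centered 120 s
window. Within half a window of either recording end a centered window
does not exist; truncating it one-sidedly biases F₀ against slow drift by
up to (window/4)/τ — about +5% ΔF/F₀ at the first frame for τ = 600 s
bleaching — which is the dominant error of the whole bleach correction.
`compute_dff` therefore truncates **symmetrically**: at distance d from an
end the window is [t−d, t+d], so its time-center always coincides with t
and the first-order bias cancels for any smooth trend (bleach and slow
signal alike). A window at least as long as the recording yields the grand
mean. Alternatives tried and rejected: odd-reflection padding and linear
extrapolation of F₀, both of which leak transient/epoch structure into the
baseline when the drift is multiplicative. With symmetric truncation,
noise-free recordings simulated with and without τ = 600 s bleaching give
z-scored traces agreeing to better than 0.1 z (max absolute difference,
measured ≈ 0.07–0.09 across seeds).

**Degenerate inputs.** A zero F₀ anywhere raises (division by zero, with
cell and frame named); a zero-variance cell cannot be z-scored and raises;
a flat LED trace at positive level is treated as an always-on LED (single
onset at index 0) while a flat trace at zero raises "no blinks detectable";
a bout label covering fewer than two frames is dropped from epoch
statistics with a warning; the two-sample t-test with zero pooled variance
returns (0, df, 1) for equal means and (±inf, df, 0) otherwise.

**Tie-breaks.** The inverse synchronization lookup assigns a behavior frame
equidistant between two blink onsets to the earlier imaging frame; cell
sorting breaks equal epoch means by cell id; even-width moving-average
windows place their extra sample on the left. Interval endpoints are
half-open `[start, stop)` in frame indices throughout.

## The synthetic-data generator

The generator emulates the study conditions: 10 frames/s imaging, a
65 frames/s behavior camera with an LED blinking once per imaging frame,
GCaMP6s-like kinetics as a peak-normalized difference of exponentials
(rise 0.2 s, decay 1.5 s — the indicator's kinetics are not published for
this preparation, so these are config-exposed choices typical of a slow
indicator), spikes as a thinned Poisson process whose rate is a per-epoch
multiple of a 3 Hz baseline clipped to the physiological 0–30 Hz range,
single-exponential photobleaching with τ = 600 s (slow enough that the
120 s F₀ window must demonstrably remove it), a neuropil field that is
spatially uniform and temporally smooth, and i.i.d. Gaussian sensor noise.
Movies are float in memory and 16-bit unsigned TIFF on disk.

`mating_modulation` encodes the reported population structure: per-cell
signed patterns make the anterior-thrusting rate pattern the sign-flip of
the intromission pattern and the ejaculation pattern an amplified copy of
it, driving cells toward the extremes of the 0–30 Hz range. The
`male_day10` script preset reproduces the printed second-recording
timeline: intromission 41.6 s, a 22.5 s gap, AT bouts of 2.4/4.6/1.1 s
separated by 11.9 and 11.4 s, a 10.9 s gap, then 31.5 s of intromission
ending in ejaculation. Pre/chasing/ejaculation/post durations are not
printed in the source report; the preset fixes them at 60/10/5/60 s.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: motion artifacts (recordings are assumed
motion-corrected upstream), spatially structured neuropil (a spatially
varying background would make halo subtraction approximate rather than
exact), indicator nonlinearity and saturation, cell-shape irregularity and
overlapping somata, slow drifts other than single-exponential bleaching,
and behavioral annotation noise. The spatially uniform neuropil in
particular means the noise-free subtraction identity (`roi − halo`
recovers the cell signal exactly) is a property of the simulation, not a
guarantee for tissue.

## Problem sizes

Simulated recordings used by the tests and the acceptance script are
desk-scale by choice: 48–80 px square fields of view, 4–10 cells, 280 s
sessions (2800 frames). The correlation-structure recovery check uses 100
seeded end-to-end runs at 48×48 px with 8 cells; halo geometry is checked
against the brute-force oracle on 200 random ≤32×32 px layouts with up to
4 ROIs.

## Known limitations

* Halo subtraction with unit weight assumes the halo sees the same
  contamination amplitude as the ROI; no scaling factor is fitted.
* The ΔF/F₀ baseline window (120 s) must be much shorter than the bleach
  time constant and much longer than behavioral epochs; epochs approaching
  the window length would be partly absorbed into F₀.
* Epoch statistics pool all bouts of a label; per-bout statistics are
  available only through the bout table.
* The population correlation uses per-epoch mean vectors; a
  concatenated-time-series mode is not implemented.
* The calibration fit is a straight line; it quantifies (via r²) but does
  not model departures from linearity.
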