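"""From raw ROI/halo traces to z-scored ΔF/F0.

The fixed processing order is: 3-frame moving-average lowpass of both the
ROI and halo traces, neuropil subtraction (ROI minus halo), photobleaching
correction via ΔF/F0 with a 120 s moving-window baseline F0, and finally a
per-cell z-score over the whole recording. The moving-window F0 tracks
slow multiplicative drift (bleaching) while leaving second-scale calcium
transients intact, and the z-score puts cells with different expression
levels on a common scale.
"""

from __future__ import annotations

import numpy as np

from .containers import TraceMatrix

__all__ = [
    "moving_average",
    "lowpass_moving_average",
    "subtract_neuropil",
    "compute_dff",
    "zscore",
    "process_traces",
]


def _windowed_mean(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving mean with edge truncation along the last axis.

    The window covers ``width`` samples centered on each output sample
    (one extra on the left for even widths); where it sticks out past
    either end it shrinks to the available samples, so widths larger than
    the trace give the grand mean everywhere.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[-1]
    half_l, half_r = width // 2, (width - 1) // 2
    idx = np.arange(n)
    starts = np.clip(idx - half_l, 0, n)
    stops = np.clip(idx + half_r + 1, 0, n)
    cs = np.concatenate(
        [np.zeros(values.shape[:-1] + (1,)), np.cumsum(values, axis=-1)], axis=-1
    )
    sums = cs[..., stops] - cs[..., starts]
    return sums / (stops - starts)


def _baseline_mean(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving mean with *symmetric* edge truncation.

    Inside the recording each output sample is the mean of a centered
    window of ``2*(width//2) + 1`` samples. Near the edges the window
    shrinks symmetrically — at distance d from either end it covers
    ``[t-d, t+d]`` — so the window's time-center always coincides with t.
    A one-sidedly truncated window would lag slow drift (an exponential
    photobleach biases it by up to half a window times the drift slope);
    the symmetric window cancels that first-order bias for any smooth
    trend. When the window is at least as long as the trace the grand
    mean is returned everywhere.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[-1]
    if width >= n:
        return np.repeat(values.mean(axis=-1, keepdims=True), n, axis=-1)
    t = np.arange(n)
    r = np.minimum(width // 2, np.minimum(t, n - 1 - t))
    starts = t - r
    stops = t + r + 1
    cs = np.concatenate(
        [np.zeros(values.shape[:-1] + (1,)), np.cumsum(values, axis=-1)], axis=-1
    )
    return (cs[..., stops] - cs[..., starts]) / (stops - starts)


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average, truncated at the edges (see _windowed_mean)."""
    if width < 1:
        raise ValueError("width must be >= 1")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if width > values.shape[-1]:
        raise ValueError(
            f"window of {width} frames exceeds trace length {values.shape[-1]}"
        )
    if width == 1:
        return values.copy()
    return _windowed_mean(values, width)


def lowpass_moving_average(traces: TraceMatrix, width_frames: int = 3) -> TraceMatrix:
    """Lowpass each trace with a centered moving average (default 3 frames)."""
    if traces.stage not in ("raw_roi", "raw_halo"):
        raise ValueError(f"cannot lowpass traces at stage {traces.stage!r}")
    return traces.advance(moving_average(traces.values, width_frames), "lowpassed")


def subtract_neuropil(roi_traces: TraceMatrix,
                      halo_traces: TraceMatrix) -> TraceMatrix:
    """Elementwise ROI minus halo.

    Cells flagged as having an empty halo pass through unchanged (their
    halo trace carries no neuropil estimate) and keep the flag.
    """
    if roi_traces.values.shape != halo_traces.values.shape:
        raise ValueError(
            f"shape mismatch: roi {roi_traces.values.shape} vs "
            f"halo {halo_traces.values.shape}"
        )
    if roi_traces.stage != halo_traces.stage:
        raise ValueError(
            f"stage mismatch: roi {roi_traces.stage!r} vs "
            f"halo {halo_traces.stage!r}"
        )
    out = roi_traces.values - halo_traces.values
    keep = roi_traces.empty_halo
    if keep.any():
        out[keep] = roi_traces.values[keep]
    return roi_traces.advance(out, "neuropil_subtracted")


def compute_dff(traces: TraceMatrix, window_s: float = 120.0,
                frame_rate: float | None = None) -> TraceMatrix:
    """ΔF/F0 with a centered moving-window baseline.

    F0(t) is the mean of the trace over a window of ``window_s`` seconds
    centered on t; in the half-window edge zones, where no centered window
    exists, F0 is linearly extrapolated (see :func:`_baseline_mean`). A
    window at least as long as the recording makes F0 the grand mean. The
    output is ``(F - F0) / F0``; a zero F0 anywhere is an error (division
    by zero), reported with the offending cell and frame.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if traces.n_frames < 2:
        raise ValueError("trace must be longer than one frame")
    fs = frame_rate if frame_rate is not None else traces.frame_rate
    width = max(int(round(window_s * fs)), 1)
    f0 = _baseline_mean(traces.values, width)
    zero = f0 == 0
    if zero.any():
        c, t = np.argwhere(zero)[0]
        raise ZeroDivisionError(
            f"F0 is zero for cell {traces.cell_ids[c]!r} at frame {t}; "
            "cannot form ΔF/F0"
        )
    return traces.advance((traces.values - f0) / f0, "dff")


def zscore(traces: TraceMatrix, ddof: int = 1) -> TraceMatrix:
    """Per-cell z-score over the full recording (sample std by default)."""
    mean = traces.values.mean(axis=1, keepdims=True)
    std = traces.values.std(axis=1, ddof=ddof, keepdims=True)
    flat = np.nonzero(std.ravel() == 0)[0]
    if flat.size:
        raise ValueError(
            f"cell {traces.cell_ids[flat[0]]!r} has zero variance; "
            "cannot z-score"
        )
    return traces.advance((traces.values - mean) / std, "zscored")


def process_traces(roi_traces: TraceMatrix, halo_traces: TraceMatrix | None,
                   lowpass_width: int = 3, window_s: float = 120.0,
                   ddof: int = 1) -> TraceMatrix:
    """Run the full stage sequence and return z-scored ΔF/F0.

    With ``halo_traces=None`` the neuropil-subtraction stage is skipped
    (every cell is treated as if its halo were empty).
    """
    lp = lowpass_moving_average(roi_traces, lowpass_width)
    if halo_traces is not None:
        lp_halo = lowpass_moving_average(halo_traces, lowpass_width)
        sub = subtract_neuropil(lp, lp_halo)
    else:
        sub = lp.advance(lp.values.copy(), "neuropil_subtracted")
    dff = compute_dff(sub, window_s=window_s)
    return zscore(dff, ddof=ddof)
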