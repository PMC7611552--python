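"""Movie repair, spatial downsampling and imaging/behavior synchronization.

Imaging runs at 10 frames/s while the behavior camera runs at 65 frames/s;
an LED facing the behavior camera blinks once per imaging frame. Blink
onsets detected in the LED trace pair behavior frames to imaging frames,
and behavioral annotations (made on the behavior-video timeline) are then
mapped onto the imaging timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .containers import EpochTable, LedTrace, MovieStack, warn

__all__ = [
    "RepairReport",
    "SyncMap",
    "read_movie",
    "write_movie",
    "read_led_trace",
    "write_led_trace",
    "repair_movie",
    "downsample_spatial",
    "detect_blinks",
    "build_sync_map",
    "map_intervals",
]


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def write_movie(movie: MovieStack, path) -> None:
    """Save as a multi-page 16-bit unsigned TIFF (values rounded/clipped)."""
    data = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16), photometric="minisblack")


def read_movie(path, frame_rate: float) -> MovieStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return MovieStack(frames=frames.astype(float), frame_rate=frame_rate)


def write_led_trace(led: LedTrace, path) -> None:
    """Single-column CSV; the rate goes in a comment header line."""
    with open(path, "w") as fh:
        fh.write(f"# rate: {led.rate}\n")
        np.savetxt(fh, led.samples, fmt="%.6g")


def read_led_trace(path) -> LedTrace:
    with open(path) as fh:
        header = fh.readline()
        rate = float(header.split(":", 1)[1])
        samples = np.loadtxt(fh, ndmin=1)
    return LedTrace(samples=samples, rate=rate)


# --------------------------------------------------------------------------
# repair & downsampling
# --------------------------------------------------------------------------

@dataclass
class RepairReport:
    n_frames_repaired: int
    n_pixels_repaired: int


def repair_movie(movie: MovieStack) -> tuple[MovieStack, RepairReport]:
    """Repair dropped frames and dead pixels.

    A frame is invalid if flagged in ``frame_valid`` or entirely zero; it
    is replaced by linear interpolation between the nearest valid frames
    (nearest-valid copy at the ends). A dead pixel has zero variance
    across time; each is replaced, frame by frame, with the mean of its
    non-dead 8-neighbors. If every pixel is static (e.g. a constant test
    movie) pixel repair is skipped, since "dead" is then undefined.
    """
    frames = movie.frames.copy()
    valid = movie.frame_valid & ~np.all(frames == 0, axis=(1, 2))
    if not valid.any():
        raise ValueError("all frames invalid; nothing to interpolate from")

    n_bad_frames = int((~valid).sum())
    if n_bad_frames:
        idx = np.arange(movie.n_frames)
        good = idx[valid]
        for axis_flat in [frames.reshape(movie.n_frames, -1)]:
            interp = np.empty_like(axis_flat)
            for j in range(axis_flat.shape[1]):
                interp[:, j] = np.interp(idx, good, axis_flat[valid, j])
            frames = interp.reshape(movie.frames.shape)

    n_bad_pixels = 0
    var = frames.var(axis=0)
    dead = var == 0
    if dead.any() and not dead.all():
        ys, xs = np.nonzero(dead)
        h, w = frames.shape[1:]
        for y, x in zip(ys, xs):
            ny0, ny1 = max(y - 1, 0), min(y + 2, h)
            nx0, nx1 = max(x - 1, 0), min(x + 2, w)
            block_dead = dead[ny0:ny1, nx0:nx1].copy()
            block_dead[y - ny0, x - nx0] = True  # exclude the pixel itself
            if block_dead.all():
                continue  # no live neighbor to borrow from
            neigh = frames[:, ny0:ny1, nx0:nx1]
            live = ~block_dead
            frames[:, y, x] = neigh[:, live].mean(axis=1)
            n_bad_pixels += 1
    elif dead.all():
        warn("movie is static everywhere; dead-pixel repair skipped")

    repaired = MovieStack(frames=frames, frame_rate=movie.frame_rate)
    return repaired, RepairReport(n_bad_frames, n_bad_pixels)


def downsample_spatial(movie: MovieStack, factor: int) -> MovieStack:
    """Non-overlapping ``factor x factor`` block mean.

    Trailing rows/columns that do not fill a block are discarded;
    ``factor=1`` returns the input unchanged.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    if factor == 1:
        return movie
    t, h, w = movie.frames.shape
    hh, ww = h // factor, w // factor
    if hh < 1 or ww < 1:
        raise ValueError("factor larger than image")
    cropped = movie.frames[:, : hh * factor, : ww * factor]
    blocks = cropped.reshape(t, hh, factor, ww, factor)
    return MovieStack(
        frames=blocks.mean(axis=(2, 4)),
        frame_rate=movie.frame_rate,
        frame_valid=movie.frame_valid.copy(),
    )


# --------------------------------------------------------------------------
# synchronization
# --------------------------------------------------------------------------

def detect_blinks(led: LedTrace, threshold_fraction: float = 0.5) -> np.ndarray:
    """Indices where the LED trace crosses its threshold from below.

    The threshold is ``min + threshold_fraction * range``. A flat trace at
    a positive level is treated as an always-on LED (single onset at 0);
    a flat trace at or below zero has no detectable blinks.
    """
    x = led.samples
    if x.size < 1:
        raise ValueError("LED trace is empty")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        if lo > 0:
            return np.array([0], dtype=int)
        raise ValueError("no blinks detectable: LED trace is flat")
    thr = lo + threshold_fraction * (hi - lo)
    above = x >= thr
    onsets = np.nonzero(above & ~np.concatenate(([False], above[:-1])))[0]
    return onsets.astype(int)


@dataclass
class SyncMap:
    """Pairing of imaging frames with behavior-frame LED blink onsets.

    ``onsets[i]`` is the behavior frame at which imaging frame ``i``
    started. The inverse lookup assigns each behavior frame to the imaging
    frame with the nearest onset, ties going to the earlier frame.
    """

    onsets: np.ndarray            # (n_pairs,) behavior-frame indices
    n_imaging_frames: int
    surplus_blinks: int = 0
    surplus_frames: int = 0
    n_behavior_frames: int | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if (np.diff(self.onsets) <= 0).any():
            raise ValueError("onsets must be strictly increasing")
        if self.n_behavior_frames is None:
            self.n_behavior_frames = int(self.onsets[-1]) + 1

    @property
    def n_pairs(self) -> int:
        return self.onsets.size

    def imaging_to_behavior(self, i) -> np.ndarray:
        return self.onsets[np.asarray(i, dtype=int)]

    def behavior_to_imaging(self, b) -> np.ndarray:
        """Nearest-onset imaging frame (ties -> earlier imaging frame)."""
        b = np.atleast_1d(np.asarray(b, dtype=float))
        right = np.searchsorted(self.onsets, b, side="left")
        right = np.clip(right, 0, self.n_pairs - 1)
        left = np.clip(right - 1, 0, self.n_pairs - 1)
        d_left = np.abs(b - self.onsets[left])
        d_right = np.abs(self.onsets[right] - b)
        out = np.where(d_left <= d_right, left, right)
        return out.astype(int)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "imaging_frame": np.arange(self.n_pairs),
            "behavior_frame": self.onsets,
        })
        with open(path, "w") as fh:
            fh.write(f"# n_imaging_frames: {self.n_imaging_frames}\n")
            fh.write(f"# surplus_blinks: {self.surplus_blinks}\n")
            fh.write(f"# surplus_frames: {self.surplus_frames}\n")
            fh.write(f"# n_behavior_frames: {self.n_behavior_frames}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SyncMap":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = int(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        return cls(onsets=df["behavior_frame"].to_numpy(), **{
            k: meta[k] for k in ("n_imaging_frames", "surplus_blinks",
                                 "surplus_frames", "n_behavior_frames")
        })


def build_sync_map(blinks: np.ndarray, n_imaging_frames: int,
                   n_behavior_frames: int | None = None) -> SyncMap:
    """Pair the i-th blink onset with imaging frame i (greedy from start).

    A count mismatch is tolerated: pairing stops at the shorter list and
    the surplus is reported on the SyncMap.
    """
    blinks = np.asarray(blinks, dtype=int)
    if blinks.size == 0:
        raise ValueError("zero blinks; cannot build a sync map")
    n_pairs = min(blinks.size, n_imaging_frames)
    surplus_blinks = blinks.size - n_pairs
    surplus_frames = n_imaging_frames - n_pairs
    if surplus_blinks or surplus_frames:
        warn(
            f"blink/frame count mismatch: {surplus_blinks} surplus blinks, "
            f"{surplus_frames} surplus imaging frames"
        )
    return SyncMap(
        onsets=blinks[:n_pairs],
        n_imaging_frames=n_imaging_frames,
        surplus_blinks=surplus_blinks,
        surplus_frames=surplus_frames,
        n_behavior_frames=n_behavior_frames,
    )


def map_intervals(intervals: EpochTable, sync: SyncMap, behavior_rate: float,
                  imaging_rate: float) -> EpochTable:
    """Convert a behavior-timeline epoch table onto the imaging timeline.

    Endpoints are converted behavior seconds -> behavior frame -> nearest
    imaging frame (via the sync map's inverse lookup) -> imaging seconds.
    Zero-length results are retained and flagged.
    """
    if intervals.timeline != "behavior":
        raise ValueError("intervals must be on the behavior timeline")
    if len(intervals) == 0:
        return EpochTable(timeline="imaging")
    rows = []
    flags = []
    for _, row in intervals.df.iterrows():
        b0 = int(round(row["start_s"] * behavior_rate))
        b1 = int(round(row["stop_s"] * behavior_rate))
        if b0 < 0 or b1 > sync.n_behavior_frames:
            raise ValueError(
                f"interval {row['label']!r} [{row['start_s']}, {row['stop_s']}) s "
                "lies outside the behavior-trace span"
            )
        f0 = int(sync.behavior_to_imaging(b0)[0])
        f1 = int(sync.behavior_to_imaging(b1)[0])
        zero_len = f0 == f1
        if zero_len:
            warn(f"interval {row['label']!r} maps to zero imaging frames")
        rows.append((row["label"], f0 / imaging_rate, f1 / imaging_rate))
        flags.append(zero_len)
    out = EpochTable.from_records(rows, timeline="imaging")
    out.df["zero_length"] = flags
    return out
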