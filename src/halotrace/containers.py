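"""Core in-memory containers shared across the pipeline.

The pipeline moves data through a fixed set of shapes: a fluorescence
movie (``MovieStack``), cell/halo geometry (``RoiSet``), per-cell time
series at successive processing stages (``TraceMatrix``), labeled
behavioral intervals (``EpochTable``) and the behavior-camera LED trace
used for synchronization (``LedTrace``).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MovieStack",
    "LedTrace",
    "RoiSet",
    "TraceMatrix",
    "EpochTable",
    "STAGES",
]

#: Processing stages of a TraceMatrix, in their only allowed order.
STAGES = (
    "raw_roi",
    "raw_halo",
    "lowpassed",
    "neuropil_subtracted",
    "dff",
    "zscored",
)


@dataclass
class MovieStack:
    """A grayscale fluorescence movie: time x height x width.

    Parameters
    ----------
    frames
        Float array of shape ``(n_frames, height, width)``.
    frame_rate
        Acquisition rate in frames/s.
    frame_valid
        Optional per-frame boolean; frames flagged False are treated as
        dropped and repaired by :func:`halotrace.io_sync.repair_movie`.
    """

    frames: np.ndarray
    frame_rate: float
    frame_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (time, height, width)")
        if self.frames.shape[0] < 1 or min(self.frames.shape[1:]) < 1:
            raise ValueError("movie must have at least one frame and one pixel")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frame_valid is None:
            self.frame_valid = np.ones(self.frames.shape[0], dtype=bool)
        else:
            self.frame_valid = np.asarray(self.frame_valid, dtype=bool)
            if self.frame_valid.shape != (self.frames.shape[0],):
                raise ValueError("frame_valid must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate


@dataclass
class LedTrace:
    """Per-behavior-frame intensity of the synchronization LED."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class RoiSet:
    """Per-cell pixel masks plus (optionally) their neuropil halos.

    ``roi_masks`` is boolean with shape ``(n_cells, height, width)``; ROI
    masks must be pairwise disjoint and each halo must be disjoint from
    every ROI. ``halo_empty`` flags cells whose halo ended up with no
    pixels (crowded fields of view); such cells skip neuropil
    subtraction downstream.
    """

    roi_masks: np.ndarray
    cell_ids: list | None = None
    halo_masks: np.ndarray | None = None
    halo_empty: np.ndarray | None = None
    halo_metric: str | None = None  # set by compute_halo

    def __post_init__(self) -> None:
        self.roi_masks = np.asarray(self.roi_masks, dtype=bool)
        if self.roi_masks.ndim != 3:
            raise ValueError("roi_masks must be (n_cells, height, width)")
        if self.cell_ids is None:
            self.cell_ids = list(range(self.n_cells))
        if len(self.cell_ids) != self.n_cells:
            raise ValueError("cell_ids length must match number of masks")
        if self.n_cells > 1 and (self.roi_masks.sum(axis=0) > 1).any():
            raise ValueError("ROI masks must be pairwise disjoint")
        if self.halo_masks is not None:
            self.halo_masks = np.asarray(self.halo_masks, dtype=bool)
            if self.halo_masks.shape != self.roi_masks.shape:
                raise ValueError("halo_masks shape must match roi_masks")
            union_roi = self.roi_masks.any(axis=0)
            if (self.halo_masks & union_roi[None]).any():
                raise ValueError("halo masks must not contain ROI pixels")
            if self.halo_empty is None:
                self.halo_empty = ~self.halo_masks.any(axis=(1, 2))

    @property
    def n_cells(self) -> int:
        return self.roi_masks.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.roi_masks.shape[1], self.roi_masks.shape[2]


@dataclass
class TraceMatrix:
    """Per-cell time series at one processing stage (cells x frames)."""

    values: np.ndarray
    stage: str
    frame_rate: float
    cell_ids: list | None = None
    empty_halo: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; must be one of {STAGES}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.cell_ids is None:
            self.cell_ids = list(range(self.n_cells))
        if self.empty_halo is None:
            self.empty_halo = np.zeros(self.n_cells, dtype=bool)
        else:
            self.empty_halo = np.asarray(self.empty_halo, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def advance(self, values: np.ndarray, stage: str) -> "TraceMatrix":
        """Return a copy at a later processing stage (order enforced)."""
        if STAGES.index(stage) <= STAGES.index(self.stage) and not (
            self.stage in ("raw_roi", "raw_halo") and stage == "lowpassed"
        ):
            if not (self.stage == "raw_roi" and stage == "raw_halo"):
                raise ValueError(
                    f"stage may only advance along {STAGES}: "
                    f"{self.stage!r} -> {stage!r} is not allowed"
                )
        return TraceMatrix(
            values=values,
            stage=stage,
            frame_rate=self.frame_rate,
            cell_ids=list(self.cell_ids),
            empty_halo=self.empty_halo.copy(),
        )

    def to_csv(self, path) -> None:
        """Write traces as CSV (rows = cells) with a metadata header."""
        with open(path, "w") as fh:
            fh.write(f"# stage: {self.stage}\n")
            fh.write(f"# frame_rate: {self.frame_rate}\n")
            df = pd.DataFrame(self.values, index=self.cell_ids)
            df.index.name = "cell_id"
            df.to_csv(fh)

    @classmethod
    def from_csv(cls, path) -> "TraceMatrix":
        with open(path) as fh:
            stage = fh.readline().split(":", 1)[1].strip()
            frame_rate = float(fh.readline().split(":", 1)[1].strip())
            df = pd.read_csv(fh, index_col=0)
        return cls(values=df.to_numpy(), stage=stage, frame_rate=frame_rate,
                   cell_ids=list(df.index))


class EpochTable:
    """Labeled behavioral intervals on a common timeline.

    Rows carry ``label``, ``start_s`` and ``stop_s`` (seconds on the
    timeline given by :attr:`timeline`, one of ``"behavior"`` or
    ``"imaging"``). Intervals are half-open ``[start, stop)``; rows are
    kept sorted by start.
    """

    COLUMNS = ("label", "start_s", "stop_s")

    def __init__(self, df: pd.DataFrame | None = None, timeline: str = "behavior"):
        if timeline not in ("behavior", "imaging"):
            raise ValueError("timeline must be 'behavior' or 'imaging'")
        if df is None:
            df = pd.DataFrame({c: [] for c in self.COLUMNS})
        df = df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"EpochTable requires column {col!r}")
        if len(df) and (df["stop_s"] < df["start_s"]).any():
            bad = df[df["stop_s"] < df["start_s"]].iloc[0]
            raise ValueError(
                f"interval {bad['label']!r} [{bad['start_s']}, {bad['stop_s']}) "
                "has stop < start"
            )
        df = df.sort_values("start_s", kind="stable").reset_index(drop=True)
        self.df = df
        self.timeline = timeline

    @classmethod
    def from_records(cls, records, timeline: str = "behavior") -> "EpochTable":
        """Build from an iterable of ``(label, start_s, stop_s)`` tuples."""
        df = pd.DataFrame(records, columns=list(cls.COLUMNS))
        return cls(df, timeline=timeline)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"EpochTable({len(self)} intervals, timeline={self.timeline!r})"

    @property
    def labels(self) -> list[str]:
        """Unique labels in order of first appearance."""
        return list(dict.fromkeys(self.df["label"]))

    def bouts(self, label: str) -> np.ndarray:
        """(n_bouts, 2) array of [start, stop) for one label."""
        sel = self.df[self.df["label"] == label]
        return sel[["start_s", "stop_s"]].to_numpy(dtype=float)

    def durations(self, label: str) -> np.ndarray:
        b = self.bouts(label)
        return b[:, 1] - b[:, 0] if len(b) else np.empty(0)

    @property
    def span(self) -> float:
        """Stop of the latest interval (0 for an empty table)."""
        return float(self.df["stop_s"].max()) if len(self.df) else 0.0

    def check_disjoint(self) -> None:
        """Raise if any two intervals overlap (half-open semantics)."""
        d = self.df
        if len(d) < 2:
            return
        starts = d["start_s"].to_numpy()
        stops = d["stop_s"].to_numpy()
        overlap = starts[1:] < stops[:-1]
        if overlap.any():
            i = int(np.argmax(overlap))
            raise ValueError(
                f"intervals overlap: {d.iloc[i]['label']!r} and "
                f"{d.iloc[i + 1]['label']!r}"
            )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# timeline: {self.timeline}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "EpochTable":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                timeline = first.split(":", 1)[1].strip()
                body = fh.read()
            else:
                timeline = "behavior"
                body = first + fh.read()
        df = pd.read_csv(_io.StringIO(body))
        return cls(df, timeline=timeline)

    def copy(self) -> "EpochTable":
        return EpochTable(self.df.copy(), timeline=self.timeline)


def warn(msg: str) -> None:
    """Single funnel for pipeline warnings (eases testing)."""
    warnings.warn(msg, stacklevel=3)
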