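"""Event-triggered averages (ETAs) of cell fluorescence.

Trace segments are aligned to repeated behavioral event onsets (or
offsets — e.g. tumescence begins, detumescence begins) and averaged per
cell; the population mean across cells summarizes the group response.
Traces are already globally z-scored, so no within-window baseline is
removed by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EpochTable, TraceMatrix, warn

__all__ = ["EtaResult", "extract_event_onsets", "compute_eta"]


@dataclass
class EtaResult:
    """Per-cell mean trace around event onsets, plus the population mean."""

    cell_etas: np.ndarray      # (n_cells, n_lags)
    lags_s: np.ndarray         # (n_lags,), 0 at the event
    n_events: int
    population_mean: np.ndarray
    cell_ids: list

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.cell_etas, index=self.cell_ids,
                          columns=np.round(self.lags_s, 6))
        df.index.name = "cell_id"
        df.loc["population_mean"] = self.population_mean
        df.to_csv(path)


def extract_event_onsets(epochs: EpochTable, label: str,
                         edge: str = "onset") -> np.ndarray:
    """Start (or stop) times of every bout of ``label``, sorted, in seconds."""
    if edge not in ("onset", "offset"):
        raise ValueError("edge must be 'onset' or 'offset'")
    bouts = epochs.bouts(label)
    if len(bouts) == 0:
        raise ValueError(f"label {label!r} has no bouts")
    col = 0 if edge == "onset" else 1
    return np.sort(bouts[:, col])


def compute_eta(traces: TraceMatrix, events: np.ndarray, w_pre: float = 10.0,
                w_post: float = 10.0,
                baseline_subtract: bool = False) -> EtaResult:
    """Average trace segments in ``[-w_pre, +w_post]`` around each event.

    Events whose window does not fit entirely inside the recording are
    dropped with a warning rather than zero-padded. With
    ``baseline_subtract`` each segment has its pre-event mean removed
    before averaging.
    """
    fs = traces.frame_rate
    n_pre = int(round(w_pre * fs))
    n_post = int(round(w_post * fs))
    events = np.asarray(events, dtype=float)
    frames = np.round(events * fs).astype(int)
    ok = (frames - n_pre >= 0) & (frames + n_post < traces.n_frames)
    if (~ok).any():
        warn(f"{int((~ok).sum())} event(s) dropped: window exceeds recording")
    frames = np.sort(frames[ok])  # order-independent averaging
    if frames.size == 0:
        raise ValueError("zero usable events: no full window fits the recording")

    lags = np.arange(-n_pre, n_post + 1)
    segs = np.stack([traces.values[:, f + lags] for f in frames])  # ev x cell x lag
    if baseline_subtract:
        segs = segs - segs[:, :, lags < 0].mean(axis=2, keepdims=True)
    cell_etas = segs.mean(axis=0)
    return EtaResult(
        cell_etas=cell_etas,
        lags_s=lags / fs,
        n_events=int(frames.size),
        population_mean=cell_etas.mean(axis=0),
        cell_ids=list(traces.cell_ids),
    )
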