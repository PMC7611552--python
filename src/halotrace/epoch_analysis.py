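"""Epoch-wise population statistics and behavioral bout statistics.

Per behavior category this module computes each cell's mean and variability
of z-scored ΔF/F0 (pooling all bouts of the category), correlates the
resulting population vectors across categories (Pearson r, with r² as the
coefficient of determination), and summarizes the behavioral bouts
themselves (durations as mean ± sample std, cumulative time, pooled-variance
Student's t-tests between categories).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .containers import EpochTable, TraceMatrix, warn

__all__ = [
    "EpochStats",
    "BehaviorSummary",
    "derive_pre_post",
    "epoch_stats",
    "population_correlation",
    "mean_r2",
    "sort_cells",
    "bout_statistics",
    "two_sample_ttest",
    "MATING_LABELS",
]

#: Default categories entering the cross-behavior correlation analysis.
MATING_LABELS = ("intromission", "AT", "ejaculation")


@dataclass
class EpochStats:
    """Per-cell, per-label mean and sample std of the z-scored signal."""

    means: pd.DataFrame   # index = cell ids, columns = labels
    stds: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.means.columns)

    @property
    def cell_ids(self) -> list:
        return list(self.means.index)

    def to_csv(self, path) -> None:
        out = pd.concat({"mean": self.means, "std": self.stds}, axis=1)
        out.to_csv(path)


def derive_pre_post(epochs: EpochTable, recording_span: float,
                    meeting_label: str = "meeting") -> EpochTable:
    """Add the 'pre' and 'post' control epochs.

    'pre' runs from the recording start to the first meeting of the
    animals; 'post' is an equal period starting where the ejaculation
    epoch ends (clipped to the recording end with a warning). The first
    meeting is an explicit marker row (``meeting_label``) if present,
    otherwise the start of the earliest annotated social bout.
    """
    df = epochs.df
    social = df[~df["label"].isin(("pre", "post"))]
    if meeting_label in set(df["label"]):
        meet = float(df.loc[df["label"] == meeting_label, "start_s"].min())
    elif len(social):
        meet = float(social["start_s"].min())
    else:
        raise ValueError("missing first-meeting marker: no social epochs found")
    rows = [("pre", 0.0, meet)]
    if "ejaculation" in set(df["label"]):
        ej_end = float(df.loc[df["label"] == "ejaculation", "stop_s"].max())
        post_stop = ej_end + meet
        if post_stop > recording_span:
            warn(
                f"post epoch clipped from {post_stop:.1f} to "
                f"{recording_span:.1f} s (end of recording)"
            )
            post_stop = recording_span
        rows.append(("post", ej_end, post_stop))
    keep = df[~df["label"].isin(("pre", "post", meeting_label))]
    body = [(r["label"], r["start_s"], r["stop_s"]) for _, r in keep.iterrows()]
    return EpochTable.from_records(rows + body, timeline=epochs.timeline)


def _frames_of_label(epochs: EpochTable, label: str, frame_rate: float,
                     n_frames: int) -> np.ndarray:
    """Pooled frame indices of all bouts of one label, half-open [start, stop)."""
    chunks = []
    for start, stop in epochs.bouts(label):
        a = max(int(round(start * frame_rate)), 0)
        b = min(int(round(stop * frame_rate)), n_frames)
        if b > a:
            chunks.append(np.arange(a, b))
    return np.concatenate(chunks) if chunks else np.empty(0, dtype=int)


def epoch_stats(traces: TraceMatrix, epochs: EpochTable) -> EpochStats:
    """Mean and sample std of each cell's signal within each behavior label.

    All bouts of a label are pooled before computing the statistics.
    Labels covering fewer than two frames are dropped with a warning.
    """
    if traces.stage != "zscored":
        raise ValueError("epoch_stats expects z-scored traces")
    means: dict[str, np.ndarray] = {}
    stds: dict[str, np.ndarray] = {}
    for label in epochs.labels:
        idx = _frames_of_label(epochs, label, traces.frame_rate, traces.n_frames)
        if idx.size < 2:
            warn(f"label {label!r} covers {idx.size} frame(s); dropped")
            continue
        seg = traces.values[:, idx]
        means[label] = seg.mean(axis=1)
        stds[label] = seg.std(axis=1, ddof=1)
    return EpochStats(
        means=pd.DataFrame(means, index=traces.cell_ids),
        stds=pd.DataFrame(stds, index=traces.cell_ids),
    )


def population_correlation(stats: EpochStats,
                           labels: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation between per-label population vectors.

    The population vector of a label is the vector of per-cell epoch
    means. The result is symmetric with a unit diagonal; a label whose
    vector has zero variance gets NaN off-diagonals with a warning.
    """
    labels = list(labels) if labels is not None else stats.labels
    missing = [l for l in labels if l not in stats.means.columns]
    if missing:
        raise ValueError(f"labels not in stats: {missing}")
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    vecs = stats.means[labels].to_numpy()   # cells x labels
    if vecs.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vecs.T)
    np.fill_diagonal(corr, 1.0)
    flat = np.nonzero(vecs.std(axis=0) == 0)[0]
    for j in flat:
        warn(f"population vector of {labels[j]!r} has zero variance")
        corr[j, :] = np.nan
        corr[:, j] = np.nan
        corr[j, j] = 1.0
    return pd.DataFrame(corr, index=labels, columns=labels)


def mean_r2(corr: pd.DataFrame, label: str,
            exclude: tuple[str, ...] = ("pre", "post")) -> float:
    """Mean coefficient of determination of one behavior with the others.

    Averages r² between ``label`` and every other mating-behavior label in
    the matrix (``exclude`` drops the control epochs).
    """
    if label not in corr.index:
        raise ValueError(f"label {label!r} not in correlation matrix")
    others = [l for l in corr.index if l != label and l not in exclude]
    if not others:
        raise ValueError("fewer than 2 mating labels in the matrix")
    return float((corr.loc[label, others] ** 2).mean())


def sort_cells(stats: EpochStats, key_label: str) -> list:
    """Cell ids ordered by descending epoch mean for ``key_label``.

    Ties are broken by cell id, so the order is deterministic.
    """
    if key_label not in stats.means.columns:
        raise ValueError(f"label {key_label!r} not in stats")
    col = stats.means[key_label]
    order = sorted(col.index, key=lambda cid: (-col[cid], cid))
    return list(order)


@dataclass
class BehaviorSummary:
    """Per-label bout statistics plus the raw durations."""

    table: pd.DataFrame              # index = label
    durations: dict[str, np.ndarray]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def bout_statistics(epochs: EpochTable) -> BehaviorSummary:
    """Durations, count, mean ± sample std, cumulative time per label.

    The sample std of a single bout is undefined (NaN). Inter-bout
    intervals (onset-to-onset gaps minus bout length) are included when a
    label has more than one bout.
    """
    if len(epochs) == 0:
        raise ValueError("epoch table is empty")
    rows = {}
    durations = {}
    for label in epochs.labels:
        b = epochs.bouts(label)
        d = b[:, 1] - b[:, 0]
        durations[label] = d
        gaps = b[1:, 0] - b[:-1, 1] if len(b) > 1 else np.empty(0)
        rows[label] = {
            "count": len(d),
            "mean_s": d.mean(),
            "std_s": d.std(ddof=1) if len(d) > 1 else np.nan,
            "cumulative_s": d.sum(),
            "mean_interbout_s": gaps.mean() if gaps.size else np.nan,
        }
    table = pd.DataFrame(rows).T
    table["count"] = table["count"].astype(int)
    table.index.name = "label"
    return BehaviorSummary(table=table, durations=durations)


def two_sample_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided Student's t-test with pooled variance.

    Returns ``(t, df, p)`` with ``df = n_a + n_b - 2``. If the pooled
    variance is zero the test is degenerate: equal means give
    ``(0, df, 1)``, different means are reported as ``(±inf, df, 0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    t, p = _stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)
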