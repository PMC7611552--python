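"""ROI and neuropil-halo geometry, and per-cell trace extraction.

Each hand-drawn ROI gets a neuropil "halo": the ring of pixels at
chessboard distance 3 to 6 outside the ROI outline, excluding pixels that
belong to any ROI. The mean fluorescence over the halo estimates the
out-of-focus contamination that one-photon miniscope imaging adds to every
cell's signal; it is subtracted from the ROI trace downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import distance_transform_cdt, distance_transform_edt
from skimage.draw import polygon as _sk_polygon

from .containers import MovieStack, RoiSet, TraceMatrix, warn

__all__ = [
    "compute_halo",
    "extract_traces",
    "read_label_mask",
    "write_label_mask",
    "rois_from_polygons",
]


def compute_halo(rois: RoiSet, ring_min: int = 3, ring_max: int = 6,
                 metric: str = "chessboard") -> RoiSet:
    """Attach a neuropil halo to each ROI.

    With the default chessboard metric, ring ``k`` is the set of pixels at
    8-connected dilation distance exactly ``k`` from the ROI, and the halo
    is the union of rings ``ring_min..ring_max`` minus every ROI's pixels,
    clipped at the image border. An isolated single-pixel ROI with rings
    3-6 therefore has ``8*(3+4+5+6) = 144`` halo pixels.

    ``metric="euclidean"`` instead takes the band of Euclidean distances
    in ``(ring_min - 1, ring_max]``.
    """
    if ring_min < 1:
        raise ValueError("ring_min must be >= 1")
    if ring_min > ring_max:
        raise ValueError("ring_min must be <= ring_max")
    if metric not in ("chessboard", "euclidean"):
        raise ValueError("metric must be 'chessboard' or 'euclidean'")

    union = rois.roi_masks.any(axis=0)
    halos = np.zeros_like(rois.roi_masks)
    for i in range(rois.n_cells):
        roi = rois.roi_masks[i]
        if not roi.any():
            raise ValueError(f"ROI {rois.cell_ids[i]!r} is empty")
        if metric == "chessboard":
            dist = distance_transform_cdt(~roi, metric="chessboard")
            band = (dist >= ring_min) & (dist <= ring_max)
        else:
            dist = distance_transform_edt(~roi)
            band = (dist > ring_min - 1) & (dist <= ring_max)
        halos[i] = band & ~union
    empty = ~halos.any(axis=(1, 2))
    for i in np.nonzero(empty)[0]:
        warn(f"halo of ROI {rois.cell_ids[i]!r} is empty")
    return RoiSet(
        roi_masks=rois.roi_masks.copy(),
        cell_ids=list(rois.cell_ids),
        halo_masks=halos,
        halo_empty=empty,
        halo_metric=metric,
    )


def extract_traces(movie: MovieStack,
                   rois: RoiSet) -> tuple[TraceMatrix, TraceMatrix]:
    """Mean fluorescence per frame over each ROI and over its halo.

    Returns ``(raw_roi, raw_halo)`` trace matrices. A cell whose halo is
    empty gets an all-zero halo trace and carries the ``empty_halo`` flag
    so that neuropil subtraction can skip it.
    """
    if rois.image_shape != movie.image_shape:
        raise ValueError(
            f"ROI image shape {rois.image_shape} does not match movie "
            f"shape {movie.image_shape}"
        )
    if rois.halo_masks is None:
        raise ValueError("RoiSet has no halos; call compute_halo first")
    flat = movie.frames.reshape(movie.n_frames, -1)
    roi_vals = np.empty((rois.n_cells, movie.n_frames))
    halo_vals = np.zeros((rois.n_cells, movie.n_frames))
    for i in range(rois.n_cells):
        m = rois.roi_masks[i].ravel()
        if not m.any():
            raise ValueError(f"ROI {rois.cell_ids[i]!r} is empty")
        roi_vals[i] = flat[:, m].mean(axis=1)
        hm = rois.halo_masks[i].ravel()
        if hm.any():
            halo_vals[i] = flat[:, hm].mean(axis=1)
    kwargs = dict(frame_rate=movie.frame_rate, cell_ids=list(rois.cell_ids),
                  empty_halo=rois.halo_empty.copy())
    return (
        TraceMatrix(values=roi_vals, stage="raw_roi", **kwargs),
        TraceMatrix(values=halo_vals, stage="raw_halo", **kwargs),
    )


# --------------------------------------------------------------------------
# ROI file formats
# --------------------------------------------------------------------------

def write_label_mask(rois: RoiSet, path) -> None:
    """16-bit label-mask TIFF: 0 = background, k = k-th cell (1-based)."""
    label = np.zeros(rois.image_shape, dtype=np.uint16)
    for i in range(rois.n_cells):
        label[rois.roi_masks[i]] = i + 1
    tifffile.imwrite(path, label)


def read_label_mask(path) -> RoiSet:
    label = tifffile.imread(path)
    ids = np.unique(label)
    ids = ids[ids > 0]
    masks = np.stack([label == k for k in ids]) if ids.size else \
        np.zeros((0,) + label.shape, dtype=bool)
    return RoiSet(roi_masks=masks, cell_ids=[int(k) for k in ids])


def rois_from_polygons(path_or_df, image_shape: tuple[int, int]) -> RoiSet:
    """Rasterize a polygon CSV (columns cell_id, x, y) into ROI masks.

    ``x`` is the column coordinate and ``y`` the row coordinate; vertices
    of each cell are taken in file order.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) \
        else pd.read_csv(path_or_df)
    masks, ids = [], []
    for cid, grp in df.groupby("cell_id", sort=True):
        rr, cc = _sk_polygon(grp["y"].to_numpy(), grp["x"].to_numpy(),
                             shape=image_shape)
        m = np.zeros(image_shape, dtype=bool)
        m[rr, cc] = True
        masks.append(m)
        ids.append(cid)
    if not masks:
        raise ValueError("polygon table contains no cells")
    return RoiSet(roi_masks=np.stack(masks), cell_ids=ids)
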