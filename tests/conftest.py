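import numpy as np
import pytest

import halotrace as ht


@pytest.fixture
def small_session():
    """One small noise-free simulated session for oracle comparisons."""
    cfg = ht.SimConfig(image_shape=(48, 48), n_cells=4, duration=60.0,
                       noise_sd=0.0, bleach_tau=None, seed=11)
    script = ht.generate_epoch_script(cfg, bouts=[("intromission", 10.0)],
                                      pre_s=10.0)
    movie, truth = ht.simulate_movie(cfg, script)
    return cfg, script, movie, truth


def brute_force_halo(roi_masks: np.ndarray, index: int, ring_min: int,
                     ring_max: int) -> np.ndarray:
    """Exhaustive chessboard-distance halo: the independent geometry oracle.

    For every pixel, the chessboard distance to ROI ``index`` is the
    minimum over the ROI's pixels of max(|dy|, |dx|); the halo is the set
    of pixels with distance in [ring_min, ring_max] that belong to no ROI.
    """
    h, w = roi_masks.shape[1:]
    pts = np.argwhere(roi_masks[index])
    union = roi_masks.any(axis=0)
    halo = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            d = np.abs(pts - (y, x)).max(axis=1).min()
            halo[y, x] = ring_min <= d <= ring_max and not union[y, x]
    return halo


def random_roi_set(rng: np.random.Generator, max_side: int = 32,
                   max_rois: int = 4) -> ht.RoiSet:
    """Random small disjoint rectangular ROIs for geometry property tests."""
    h = int(rng.integers(8, max_side + 1))
    w = int(rng.integers(8, max_side + 1))
    n = int(rng.integers(1, max_rois + 1))
    masks = []
    occupied = np.zeros((h, w), dtype=bool)
    for _ in range(n):
        for _attempt in range(50):
            rh = int(rng.integers(1, 4))
            rw = int(rng.integers(1, 4))
            y = int(rng.integers(0, h - rh + 1))
            x = int(rng.integers(0, w - rw + 1))
            m = np.zeros((h, w), dtype=bool)
            m[y:y + rh, x:x + rw] = True
            if not (m & occupied).any():
                occupied |= m
                masks.append(m)
                break
    return ht.RoiSet(roi_masks=np.stack(masks))
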