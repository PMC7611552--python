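"""End-to-end convenience wrappers for the common simulate-then-analyze flow."""

from __future__ import annotations

from dataclasses import dataclass

from .containers import EpochTable, MovieStack, RoiSet, TraceMatrix
from .epoch_analysis import EpochStats, epoch_stats, population_correlation
from .roi_geometry import compute_halo, extract_traces
from .simulate import (GroundTruth, SimConfig, generate_epoch_script,
                       mating_modulation, simulate_movie)
from .trace_processing import process_traces

__all__ = ["Session", "process_movie", "run_mating_session"]


@dataclass
class Session:
    """One simulated recording with everything the analyses consume."""

    config: SimConfig
    script: EpochTable
    movie: MovieStack
    truth: GroundTruth
    rois: RoiSet
    zscored: TraceMatrix

    def epoch_statistics(self) -> EpochStats:
        return epoch_stats(self.zscored, self.truth.epoch_script)

    def behavior_correlation(self, labels=None):
        return population_correlation(self.epoch_statistics(), labels)


def process_movie(movie: MovieStack, rois: RoiSet, ring_min: int = 3,
                  ring_max: int = 6, lowpass_width: int = 3,
                  window_s: float = 120.0) -> TraceMatrix:
    """Extract ROI/halo traces and run the full processing chain."""
    if rois.halo_masks is None:
        rois = compute_halo(rois, ring_min=ring_min, ring_max=ring_max)
    raw_roi, raw_halo = extract_traces(movie, rois)
    return process_traces(raw_roi, raw_halo,
                          lowpass_width=lowpass_width, window_s=window_s)


def run_mating_session(seed: int = 0, preset: str = "male_day10",
                       **config_overrides) -> Session:
    """Simulate a mating session with the reported modulation structure.

    Cells get an intromission-up/-down pattern, its sign-flipped anterior
    thrusting pattern and an amplified ejaculation pattern (see
    :func:`halotrace.simulate.mating_modulation`), the movie is rendered
    on the preset behavioral timeline, and ROI+halo traces are processed
    to z-scored ΔF/F0 using the simulator's true footprints as ROIs.
    """
    cfg = SimConfig(seed=seed, **config_overrides)
    if cfg.modulation_map is None:
        cfg.modulation_map = mating_modulation(cfg.n_cells, seed=seed)
    script = generate_epoch_script(cfg, preset=preset)
    movie, truth = simulate_movie(cfg, script)
    rois = compute_halo(RoiSet(roi_masks=truth.footprints.copy()))
    zscored = process_movie(movie, rois)
    return Session(config=cfg, script=script, movie=movie, truth=truth,
                   rois=rois, zscored=zscored)
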