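"""Synthetic miniscope data with the statistical structure the pipeline assumes.

The generator emulates a one-photon miniscope recording of GCaMP6s-labeled
hypothalamic neurons during a social-interaction session: each cell fires
as an inhomogeneous Poisson process whose rate is set per behavioral epoch
(clipped to the physiological 0-30 Hz range), spikes are convolved with a
slow difference-of-exponentials indicator kernel, cells are painted onto
disk footprints, a spatially uniform neuropil field contaminates every
pixel, a single-exponential photobleach multiplies the whole frame, and
i.i.d. Gaussian sensor noise is added last:

    movie(t, x) = bleach(t) * (sum_c cell_c(t) * footprint_c(x) + neuropil(t)) + noise

Everything is deterministic given ``SimConfig.seed``. Ground truth (rates,
spike times, footprints, per-cell fluorescence, neuropil and bleach
curves) is returned alongside the movie so recovery tests can compare the
pipeline's output against what was actually simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import EpochTable, LedTrace, MovieStack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gcamp_kernel",
    "generate_epoch_script",
    "mating_modulation",
    "rate_traces_from_script",
    "simulate_movie",
    "simulate_led_trace",
    "PRESET_NAMES",
]

#: Labels the epoch scripts draw from.
EPOCH_VOCABULARY = (
    "pre",
    "chasing",
    "intromission",
    "AT",
    "ejaculation",
    "tumescence",
    "detumescence",
    "post",
)

PRESET_NAMES = ("male_day10",)


@dataclass
class SimConfig:
    """Parameters of one synthetic recording.

    Defaults describe a desk-scale session: 10 frames/s imaging and a
    65 frames/s behavior camera, cells firing around 3 Hz at baseline and
    clipped to 0-30 Hz after epoch modulation, a GCaMP6s-like kernel
    (0.2 s rise, 1.5 s decay), photobleaching with a 600 s time constant,
    and a neuropil field whose amplitude dominates single-cell baseline
    fluorescence, as is typical for one-photon imaging.
    """

    image_shape: tuple[int, int] = (80, 80)
    n_cells: int = 10
    imaging_rate: float = 10.0
    behavior_rate: float = 65.0
    duration: float = 280.0
    cell_radius: int = 3
    baseline_rate: float = 3.0
    modulation_map: dict | None = None
    gcamp_tau_rise: float = 0.2
    gcamp_tau_decay: float = 1.5
    bleach_tau: float | None = 600.0
    neuropil_amplitude: float = 150.0
    noise_sd: float = 5.0
    cell_baseline_fluor: float = 60.0
    spike_amplitude: float = 40.0
    rate_clip: tuple[float, float] = (0.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.imaging_rate <= 0:
            raise ValueError("imaging_rate must be > 0")
        if self.behavior_rate < self.imaging_rate:
            raise ValueError("behavior_rate must be >= imaging_rate")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.rate_clip[0] < 0 or self.rate_clip[1] <= self.rate_clip[0]:
            raise ValueError("rate_clip must be a non-negative, increasing pair")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.imaging_rate))

    @property
    def n_behavior_frames(self) -> int:
        return int(round(self.duration * self.behavior_rate))

    def to_file(self, path) -> None:
        """Write as a flat key = value text file."""
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if f.name == "modulation_map":
                    if v is None:
                        continue
                    v = json.dumps({k: np.asarray(m).tolist() for k, m in v.items()})
                elif isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        kwargs: dict = {}
        casts = {f.name: f for f in fields(cls)}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in casts:
                raise ValueError(f"unknown config key {key!r}")
            if key == "modulation_map":
                kwargs[key] = {k: np.asarray(v) for k, v in json.loads(raw).items()}
            elif key == "image_shape":
                kwargs[key] = tuple(int(x) for x in raw.split(","))
            elif key == "rate_clip":
                kwargs[key] = tuple(float(x) for x in raw.split(","))
            elif key in ("n_cells", "cell_radius", "seed"):
                kwargs[key] = int(raw)
            elif key == "bleach_tau":
                kwargs[key] = None if raw == "None" else float(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    rate_traces: np.ndarray          # (n_cells, n_frames), Hz
    spike_times: list                # per cell, sorted event times in s
    cell_centers: np.ndarray         # (n_cells, 2) as (row, col)
    epoch_script: EpochTable
    bleach_curve: np.ndarray         # (n_frames,), multiplicative
    footprints: np.ndarray           # (n_cells, H, W) bool
    cell_fluor: np.ndarray           # (n_cells, n_frames), unbleached, noise-free
    neuropil_trace: np.ndarray       # (n_frames,), unbleached

    def __post_init__(self) -> None:
        if (self.rate_traces < 0).any():
            raise ValueError("rate_traces must be non-negative")
        if (np.diff(self.bleach_curve) > 1e-12).any():
            raise ValueError("bleach_curve must be monotonically non-increasing")

    def save(self, outdir) -> None:
        """Write the ground truth as plain CSV files into ``outdir``."""
        import pandas as pd
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.rate_traces).to_csv(outdir / "rate_traces.csv",
                                              index_label="cell")
        rows = [(c, t) for c, st in enumerate(self.spike_times) for t in st]
        pd.DataFrame(rows, columns=["cell", "time_s"]).to_csv(
            outdir / "spike_times.csv", index=False)
        pd.DataFrame(self.cell_centers, columns=["row", "col"]).to_csv(
            outdir / "cell_centers.csv", index_label="cell")
        pd.DataFrame({"bleach": self.bleach_curve}).to_csv(
            outdir / "bleach_curve.csv", index_label="frame")
        self.epoch_script.to_csv(outdir / "epoch_script.csv")


def gcamp_kernel(tau_rise: float, tau_decay: float, frame_rate: float) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak-normalized to 1.

    Sampled at ``frame_rate`` and truncated at five decay constants.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    t = np.arange(0.0, 5.0 * tau_decay, 1.0 / frame_rate)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("kernel is degenerate at this frame rate")
    return k / peak


# --------------------------------------------------------------------------
# behavior scripts
# --------------------------------------------------------------------------

def _male_day10_rows(pre_s: float = 60.0, chase_s: float = 10.0,
                     ejaculation_s: float = 5.0) -> list[tuple[str, float, float]]:
    """The published second-recording timeline of the male subject.

    Intromission of 41.6 s, a 22.5 s gap, three anterior-thrusting (AT)
    bouts of 2.4 / 4.6 / 1.1 s separated by 11.9 and 11.4 s, a 10.9 s gap,
    then a 31.5 s intromission ending in ejaculation. Pre/chasing/
    ejaculation/post durations are not printed in the source report and
    are fixed choices here.
    """
    rows = [("pre", 0.0, pre_s)]
    t = pre_s
    rows.append(("chasing", t, t + chase_s)); t += chase_s
    rows.append(("intromission", t, t + 41.6)); t += 41.6
    t += 22.5
    for dur, gap in ((2.4, 11.9), (4.6, 11.4), (1.1, 10.9)):
        rows.append(("AT", t, t + dur))
        t += dur + gap
    rows.append(("intromission", t, t + 31.5)); t += 31.5
    rows.append(("ejaculation", t, t + ejaculation_s)); t += ejaculation_s
    rows.append(("post", t, t + pre_s))
    return [(lab, round(a, 6), round(b, 6)) for lab, a, b in rows]


def generate_epoch_script(
    config: SimConfig,
    bouts: list[tuple[str, float]] | None = None,
    preset: str | None = None,
    pre_s: float = 30.0,
    gap_range: tuple[float, float] = (5.0, 15.0),
) -> EpochTable:
    """Build a non-overlapping behavioral script on the behavior timeline.

    Parameters
    ----------
    bouts
        Ordered ``(label, duration_s)`` requests, placed after the ``pre``
        epoch with random gaps drawn from ``gap_range``. With no bouts the
        table holds only ``pre`` and ``post``.
    preset
        ``"male_day10"`` reproduces the published second-recording
        timeline (see :func:`_male_day10_rows`); ``bouts`` is then ignored.

    Raises
    ------
    ValueError
        If an interval does not fit in ``config.duration`` (the first
        offending interval is named).
    """
    if preset is not None:
        if preset not in PRESET_NAMES:
            raise ValueError(f"unknown preset {preset!r}; available: {PRESET_NAMES}")
        rows = _male_day10_rows()
    else:
        rng = np.random.default_rng(config.seed)
        rows = [("pre", 0.0, pre_s)]
        t = pre_s
        for label, dur in (bouts or []):
            if label not in EPOCH_VOCABULARY:
                raise ValueError(f"label {label!r} not in {EPOCH_VOCABULARY}")
            t += float(rng.uniform(*gap_range))
            rows.append((label, t, t + dur))
            t += dur
        post_start = t if bouts else max(pre_s, config.duration - pre_s)
        rows.append(("post", post_start, min(post_start + pre_s, config.duration)))

    for label, start, stop in rows:
        if stop > config.duration + 1e-9:
            raise ValueError(
                f"duration {config.duration} s too short: epoch {label!r} "
                f"[{start}, {stop}) does not fit"
            )
    table = EpochTable.from_records(rows, timeline="behavior")
    table.check_disjoint()
    return table


def mating_modulation(
    n_cells: int,
    seed: int = 0,
    base: float = 6.0,
    ejaculation_gain: float = 1.5,
    chasing: float = 1.5,
) -> dict:
    """Per-cell epoch rate multipliers with the reported mating structure.

    Cells get a signed pattern p in [-1, 1]; the intromission multiplier is
    ``base**p`` (some cells strongly up, some strongly down), anterior
    thrusting is the sign-flipped pattern ``base**(-p)``, and ejaculation is
    the amplified pattern ``base**(ejaculation_gain * p)`` so that after
    clipping cells reach the extremes of their 0-30 Hz range. Chasing gets
    a uniform modest increase.
    """
    rng = np.random.default_rng(seed)
    p = np.linspace(-1.0, 1.0, n_cells) if n_cells > 1 else np.ones(max(n_cells, 1))
    p = p + rng.uniform(-0.05, 0.05, size=p.size)
    return {
        "intromission": base ** p,
        "AT": base ** (-p),
        "ejaculation": base ** (ejaculation_gain * p),
        "chasing": np.full(p.size, chasing),
    }


def rate_traces_from_script(config: SimConfig, script: EpochTable) -> np.ndarray:
    """Per-cell firing rate (Hz) at imaging resolution, clipped to rate_clip."""
    n_frames, n_cells = config.n_frames, config.n_cells
    rates = np.full((n_cells, n_frames), config.baseline_rate, dtype=float)
    mod = config.modulation_map or {}
    fs = config.imaging_rate
    for _, row in script.df.iterrows():
        m = mod.get(row["label"])
        if m is None:
            continue
        m = np.broadcast_to(np.asarray(m, dtype=float).ravel()
                            if np.ndim(m) else np.full(n_cells, float(m)),
                            (n_cells,))
        a = int(round(row["start_s"] * fs))
        b = int(round(row["stop_s"] * fs))
        a, b = max(a, 0), min(b, n_frames)
        if b > a:
            rates[:, a:b] = config.baseline_rate * m[:, None]
    return np.clip(rates, *config.rate_clip)


# --------------------------------------------------------------------------
# movie synthesis
# --------------------------------------------------------------------------

def _place_cells(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.image_shape
    r = config.cell_radius
    margin = r + 1
    if config.n_cells == 0:
        return np.empty((0, 2), dtype=int)
    if h - 2 * margin < 0 or w - 2 * margin < 0:
        raise ValueError(
            f"cells of radius {r} do not fit in image of shape {(h, w)}"
        )
    min_sep = 2 * r + 3  # keeps footprints disjoint with a gap for halos
    centers: list[tuple[int, int]] = []
    for _ in range(20000):
        if len(centers) == config.n_cells:
            break
        cy = int(rng.integers(margin, h - margin + 1))
        cx = int(rng.integers(margin, w - margin + 1))
        if all(max(abs(cy - y), abs(cx - x)) >= min_sep for y, x in centers):
            centers.append((cy, cx))
    else:
        raise ValueError(
            f"could not place {config.n_cells} cells of radius {r} "
            f"in image of shape {(h, w)}"
        )
    return np.asarray(centers, dtype=int)


def _disk_footprints(centers: np.ndarray, radius: int,
                     shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    fp = np.zeros((len(centers), h, w), dtype=bool)
    for i, (cy, cx) in enumerate(centers):
        fp[i] = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
    return fp


def _thinned_poisson(rate_per_frame: np.ndarray, fs: float, duration: float,
                     cap: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spike times via thinning against rate cap."""
    if cap <= 0:
        return np.empty(0)
    n = rng.poisson(cap * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    idx = np.minimum((t * fs).astype(int), rate_per_frame.size - 1)
    keep = rng.uniform(size=n) < rate_per_frame[idx] / cap
    return t[keep]


def simulate_movie(config: SimConfig,
                   script: EpochTable) -> tuple[MovieStack, GroundTruth]:
    """Render a synthetic movie and its ground truth (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    h, w = config.image_shape
    fs = config.imaging_rate

    centers = _place_cells(config, rng)
    footprints = _disk_footprints(centers, config.cell_radius, (h, w))
    rates = rate_traces_from_script(config, script)
    kernel = gcamp_kernel(config.gcamp_tau_rise, config.gcamp_tau_decay, fs)
    cap = float(rates.max(initial=0.0))

    spike_times: list[np.ndarray] = []
    cell_fluor = np.zeros((config.n_cells, n_frames))
    for c in range(config.n_cells):
        st = _thinned_poisson(rates[c], fs, config.duration, cap, rng)
        spike_times.append(st)
        counts = np.bincount(
            np.minimum((st * fs).astype(int), n_frames - 1), minlength=n_frames
        )[:n_frames]
        cell_fluor[c] = (config.cell_baseline_fluor
                         + config.spike_amplitude
                         * np.convolve(counts, kernel)[:n_frames])

    if config.neuropil_amplitude > 0:
        g = gaussian_filter1d(rng.standard_normal(n_frames), sigma=max(fs, 1.0))
        sd = g.std()
        if sd > 0:
            g = g / sd
        neuropil = config.neuropil_amplitude * np.clip(1.0 + 0.3 * g, 0.0, None)
    else:
        neuropil = np.zeros(n_frames)

    t = np.arange(n_frames) / fs
    if config.bleach_tau is None or not np.isfinite(config.bleach_tau):
        bleach = np.ones(n_frames)
    else:
        bleach = np.exp(-t / config.bleach_tau)

    frames = np.zeros((n_frames, h, w))
    for c in range(config.n_cells):
        frames[:, footprints[c]] += cell_fluor[c][:, None]
    frames += neuropil[:, None, None]
    frames *= bleach[:, None, None]
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape)

    movie = MovieStack(frames=frames, frame_rate=fs)
    truth = GroundTruth(
        rate_traces=rates,
        spike_times=spike_times,
        cell_centers=centers,
        epoch_script=script,
        bleach_curve=bleach,
        footprints=footprints,
        cell_fluor=cell_fluor,
        neuropil_trace=neuropil,
    )
    return movie, truth


def simulate_led_trace(config: SimConfig) -> LedTrace:
    """Binary LED trace at behavior rate: one blink per imaging frame.

    Blink onsets fall at the behavior frame nearest each imaging-frame
    start; at 65/10 frames/s this yields the familiar 6/7-frame alternating
    spacing. When the two rates are equal the LED is on in every frame.
    """
    ratio = config.behavior_rate / config.imaging_rate
    onsets = np.round(np.arange(config.n_frames) * ratio).astype(int)
    if (np.diff(onsets) < 1).any():
        raise ValueError("blink onsets not strictly increasing; check rates")
    n_beh = max(config.n_behavior_frames, int(onsets[-1]) + 1 if onsets.size else 1)
    # blink must end before the next onset or consecutive blinks merge
    blink_len = max(1, int(ratio // 2))
    if onsets.size > 1:
        blink_len = max(1, min(blink_len, int(np.diff(onsets).min()) - 1))
    samples = np.zeros(n_beh)
    for o in onsets:
        samples[o:o + blink_len] = 1.0
    return LedTrace(samples=samples, rate=config.behavior_rate)
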