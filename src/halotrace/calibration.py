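"""Fluorescence-to-firing-rate calibration.

Emulates the slice validation experiment: 10 s current steps drive a cell
at commanded firing rates (within the physiological 0-30 Hz range), the
resulting spikes are convolved with the same GCaMP kernel the movie
generator uses, and a straight line of steady-state fluorescence versus
commanded rate quantifies how faithfully fluorescence reports rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .simulate import gcamp_kernel

__all__ = [
    "StepProtocol",
    "CalibrationFit",
    "simulate_step_recording",
    "fit_calibration",
    "kernel_slope",
]


@dataclass
class StepProtocol:
    """A sequence of constant-rate steps separated by silent intervals."""

    firing_rates: tuple = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    step_duration: float = 10.0
    inter_step_interval: float = 10.0
    sample_rate: float = 10.0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.firing_rates):
            raise ValueError("firing rates must be >= 0")
        if self.step_duration <= 0 or self.inter_step_interval < 0:
            raise ValueError("durations must be positive")

    @property
    def duration(self) -> float:
        n = len(self.firing_rates)
        return (n * self.step_duration + (n + 1) * self.inter_step_interval)

    def step_window(self, i: int) -> tuple[float, float]:
        """[start, stop) of the i-th step in seconds."""
        start = (i + 1) * self.inter_step_interval + i * self.step_duration
        return start, start + self.step_duration


def simulate_step_recording(
    protocol: StepProtocol,
    tau_rise: float = 0.2,
    tau_decay: float = 1.5,
    spike_amplitude: float = 40.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    spike_process: str = "poisson",
) -> tuple[np.ndarray, np.ndarray]:
    """Fluorescence trace and spike times for a step protocol.

    ``spike_process="poisson"`` draws spikes stochastically at each
    commanded rate; ``"regular"`` spaces them evenly (the fully
    deterministic, noise-free case). Deterministic given ``seed``.
    """
    if spike_process not in ("poisson", "regular"):
        raise ValueError("spike_process must be 'poisson' or 'regular'")
    rng = np.random.default_rng(seed)
    fs = protocol.sample_rate
    n = int(round(protocol.duration * fs))
    spikes: list[np.ndarray] = []
    for i, rate in enumerate(protocol.firing_rates):
        start, stop = protocol.step_window(i)
        if rate <= 0:
            continue
        if spike_process == "regular":
            st = start + (np.arange(int(np.floor(rate * protocol.step_duration)))
                          + 0.5) / rate
        else:
            k = rng.poisson(rate * protocol.step_duration)
            st = np.sort(rng.uniform(start, stop, size=k))
        spikes.append(st[st < stop])
    spike_times = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)

    counts = np.bincount(
        np.minimum((spike_times * fs).astype(int), n - 1), minlength=n
    )[:n]
    kernel = gcamp_kernel(tau_rise, tau_decay, fs)
    trace = spike_amplitude * np.convolve(counts, kernel)[:n]
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    return trace, spike_times


@dataclass
class CalibrationFit:
    """Least-squares line of steady-state fluorescence vs commanded rate."""

    slope: float          # fluorescence units per Hz
    intercept: float
    r2: float
    pairs: pd.DataFrame   # columns: rate_hz, mean_fluorescence

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# slope: {self.slope}\n")
            fh.write(f"# intercept: {self.intercept}\n")
            fh.write(f"# r2: {self.r2}\n")
            self.pairs.to_csv(fh, index=False)


def fit_calibration(trace: np.ndarray, protocol: StepProtocol,
                    steady_state_fraction: float = 0.5) -> CalibrationFit:
    """Fit fluorescence vs rate from the steady-state tail of each step.

    The per-step fluorescence is averaged over the last
    ``steady_state_fraction`` of the step (default: last half, letting the
    slow indicator settle), then regressed on the commanded rate.
    """
    rates = np.asarray(protocol.firing_rates, dtype=float)
    if np.unique(rates).size < 2:
        raise ValueError("need at least 2 distinct commanded rates")
    fs = protocol.sample_rate
    trace = np.asarray(trace, dtype=float)
    means = []
    for i in range(rates.size):
        start, stop = protocol.step_window(i)
        a = int(round((stop - steady_state_fraction * protocol.step_duration) * fs))
        b = int(round(stop * fs))
        means.append(trace[a:b].mean())
    means = np.asarray(means)
    pairs = pd.DataFrame({"rate_hz": rates, "mean_fluorescence": means})
    if np.ptp(means) == 0:  # flat response: no rate dependence at all
        return CalibrationFit(slope=0.0, intercept=float(means[0]), r2=0.0,
                              pairs=pairs)
    fit = _stats.linregress(rates, means)
    return CalibrationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2),
        pairs=pairs,
    )


def kernel_slope(tau_rise: float = 0.2, tau_decay: float = 1.5,
                 sample_rate: float = 10.0,
                 spike_amplitude: float = 40.0) -> float:
    """Generator-truth slope: steady-state fluorescence per Hz.

    At a sustained rate r the expected fluorescence is
    ``r * spike_amplitude * sum(kernel) / sample_rate``, so the slope of
    fluorescence vs rate is ``spike_amplitude * sum(kernel) / sample_rate``.
    """
    k = gcamp_kernel(tau_rise, tau_decay, sample_rate)
    return spike_amplitude * float(k.sum()) / sample_rate
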