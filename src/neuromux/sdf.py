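"""Spike-density functions via an exponentially modified Gaussian (EMG) kernel.

Raw spike trains are convolved with the density of X + Y where
X ~ Normal(0, sigma^2) and Y ~ Exponential(mean tau), with the exponential
tail oriented toward positive time (the standard causal-skew convention for
spike smoothing). Defaults: sigma = tau = 100 ms. The kernel is built by
discrete convolution of the Gaussian and exponential densities, truncated at
+/- (5 sigma + 5 tau) and renormalized to unit mass, so each spike
contributes exactly one unit of integrated rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from neuromux.io import SpikeTrainSet


@dataclass
class SDF:
    """A trial-averaged firing-rate estimate on a uniform time grid."""

    time_grid: np.ndarray  # seconds, uniform spacing
    rate: np.ndarray  # spikes/s per grid point
    n_trials: int

    def __post_init__(self):
        dt = np.diff(self.time_grid)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("time grid must be uniform")
        if np.any(self.rate < -1e-12):
            raise ValueError("rate must be nonnegative")

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.time_grid, self.rate]),
                   header="time_s rate_hz", comments="#")


def emg_kernel(dt: float, sigma: float = 0.1, tau: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Discrete EMG kernel samples on a symmetric grid.

    Returns (offsets, kernel) where offsets run from -(5 sigma + 5 tau) to
    +(5 sigma + 5 tau) in steps of dt (odd length, 0 at the center) and
    sum(kernel) * dt == 1 exactly after renormalization.
    """
    if dt <= 0 or sigma <= 0 or tau <= 0:
        raise ValueError("dt, sigma and tau must all be > 0")
    span = 5.0 * sigma + 5.0 * tau
    if dt >= span:
        raise ValueError(f"dt={dt} is not smaller than the truncation span {span}")
    half = int(np.ceil(span / dt))
    offsets = np.arange(-half, half + 1) * dt

    gauss = np.exp(-0.5 * (offsets / sigma) ** 2)
    expo = np.where(offsets >= 0, np.exp(-np.maximum(offsets, 0.0) / tau), 0.0)
    kernel = np.convolve(gauss, expo, mode="same")
    kernel /= kernel.sum() * dt
    return offsets, kernel


def smooth(
    spikes: SpikeTrainSet,
    neuron_id: str,
    trial_indices,
    time_grid: np.ndarray,
    sigma: float = 0.1,
    tau: float = 0.1,
) -> SDF:
    """Trial-averaged SDF of one neuron over the given trials.

    Each trial's spike point process is binned at the grid resolution,
    convolved with the EMG kernel, and the per-trial rates are averaged.
    The grid should extend beyond the analysis interval (e.g. by 0.25 s) so
    that edge attenuation stays outside the interval of interest; no edge
    correction is applied.
    """
    trial_indices = list(trial_indices)
    if not trial_indices:
        raise ValueError("trial subset must be non-empty")
    time_grid = np.asarray(time_grid, dtype=float)
    dt = float(time_grid[1] - time_grid[0])
    _, kernel = emg_kernel(dt, sigma=sigma, tau=tau)

    # bin edges centered on grid points
    edges = np.concatenate([time_grid - dt / 2, [time_grid[-1] + dt / 2]])
    acc = np.zeros_like(time_grid)
    half = (len(kernel) - 1) // 2
    for ti in trial_indices:
        t = spikes.spike_times(neuron_id, int(ti))
        counts, _ = np.histogram(t, bins=edges)
        full = np.convolve(counts.astype(float), kernel)
        acc += full[half:half + len(time_grid)]
    return SDF(time_grid=time_grid, rate=np.maximum(acc / len(trial_indices), 0.0),
               n_trials=len(trial_indices))
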