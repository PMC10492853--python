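"""Burst-spike selection and spike-density (firing-rate) estimation.

Spikes contributing to a gaze shift are those falling in a window of the
same length as the movement, shifted earlier by the neural lead
(default 20 ms): [onset - lead, offset - lead].  Prelude spikes (before
the window) and post-saccadic spikes are discarded.

The spike-density function SD(t) is the sum of unit-area Gaussian kernels
centred on the selected spike times.  Two kernel rules are provided: a
fixed width (sigma_K = 4 ms, the default throughout the analyses) and an
adaptive rule where each spike's kernel width equals the local
inter-spike interval (clipped below at 1 ms; the final spike reuses the
preceding interval).  Kernels are not truncated or renormalized at the
window edges: the density is evaluated on an extended grid so that the
cumulative density reaches exactly N_spk, and profiles are reported from
the window start.  SD is in spikes/ms; multiply by 1000 for spikes/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinematics import GazeShiftEvent

__all__ = [
    "SpikeBurst",
    "DensityProfile",
    "select_burst_spikes",
    "spike_density_fixed",
    "spike_density_adaptive",
    "isi_rate",
]

# padding (in kernel SDs) of the extended integration grid beyond the
# outermost spikes; 6 SDs keep >1 - 1e-9 of each kernel's mass
_PAD_SDS = 6.0


@dataclass
class SpikeBurst:
    """Spikes selected within the (lead-shifted) gaze-shift window."""

    spike_times: np.ndarray  # ms, sorted
    window: tuple  # (start_ms, end_ms)

    def __post_init__(self) -> None:
        s = np.asarray(self.spike_times, dtype=float)
        if s.size and np.any(np.diff(s) < 0):
            raise ValueError("SpikeBurst: spike times must be sorted")
        lo, hi = self.window
        if s.size and (s[0] < lo or s[-1] > hi):
            raise ValueError("SpikeBurst: spikes outside the selection window")
        self.spike_times = s

    @property
    def n_spk(self) -> int:
        return int(len(self.spike_times))


@dataclass
class DensityProfile:
    """Continuous spike-density estimate on a 1-ms time grid.

    ``sd`` is in spikes/ms, ``csd`` is the running integral (spikes,
    nondecreasing, reaching N_spk at the end of the extended support).
    """

    t: np.ndarray
    sd: np.ndarray
    csd: np.ndarray
    method: str
    sigma_K: np.ndarray  # per-spike kernel widths (ms); scalar broadcast for fixed

    def window_slice(self, start_ms: float, end_ms: float):
        """Return (t, sd, csd) restricted to [start_ms, end_ms]."""
        m = (self.t >= start_ms - 1e-9) & (self.t <= end_ms + 1e-9)
        return self.t[m], self.sd[m], self.csd[m]


def select_burst_spikes(spikes, event: GazeShiftEvent, lead: float = 20.0) -> SpikeBurst:
    """Select the saccade-related burst spikes for a gaze shift.

    Keeps spikes in [onset - lead, offset - lead] ms; the window has the
    gaze-shift duration and leads it by ``lead`` ms (default 20).
    """
    if event.offset_ms <= event.onset_ms:
        raise ValueError("gaze-shift offset must be after onset")
    spikes = np.asarray(spikes, dtype=float)
    lo = event.onset_ms - lead
    hi = event.offset_ms - lead
    kept = spikes[(spikes >= lo) & (spikes <= hi)]
    return SpikeBurst(spike_times=np.sort(kept), window=(lo, hi))


def _density_on_grid(spike_times, sigmas, grid) -> np.ndarray:
    """Sum of unit-area Gaussians at spike_times with per-spike widths."""
    grid = np.asarray(grid, dtype=float)
    sd = np.zeros_like(grid)
    for tau, sig in zip(spike_times, sigmas):
        z = (grid - tau) / sig
        sd += np.exp(-0.5 * z * z) / (sig * np.sqrt(2.0 * np.pi))
    return sd


def _make_profile(burst: SpikeBurst, sigmas, grid, method: str) -> DensityProfile:
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (burst.n_spk,))
    if grid is None:
        lo, hi = burst.window
        pad = _PAD_SDS * (float(np.max(sigmas)) if burst.n_spk else 4.0)
        grid = np.arange(np.floor(lo - pad), np.ceil(hi + pad) + 1.0, 1.0)
    else:
        grid = np.asarray(grid, dtype=float)
    sd = _density_on_grid(burst.spike_times, sigmas, grid)
    dt = np.diff(grid, prepend=grid[0] - (grid[1] - grid[0]) if len(grid) > 1 else 1.0)
    csd = np.cumsum(sd * dt)
    return DensityProfile(t=grid, sd=sd, csd=csd, method=method, sigma_K=sigmas)


def spike_density_fixed(burst: SpikeBurst, sigma: float = 4.0,
                        grid=None) -> DensityProfile:
    """Spike density with a fixed Gaussian kernel (default sigma_K = 4 ms)."""
    if sigma <= 0:
        raise ValueError("kernel width must be positive")
    return _make_profile(burst, sigma, grid, method="fixed")


def spike_density_adaptive(burst: SpikeBurst, grid=None,
                           min_sigma: float = 1.0) -> DensityProfile:
    """Spike density with kernel widths equal to the local inter-spike interval.

    sigma_K(i) = tau_{i+1} - tau_i, clipped below at 1 ms; the last spike
    (which has no following interval) uses the preceding interval.  With
    fewer than two spikes the interval is undefined and the fixed 4-ms
    kernel is used instead (with a warning).
    """
    if burst.n_spk < 2:
        warnings.warn("adaptive kernel needs >= 2 spikes; falling back to fixed 4 ms")
        return _make_profile(burst, 4.0, grid, method="adaptive")
    isi = np.diff(burst.spike_times)
    sigmas = np.concatenate([isi, isi[-1:]])
    sigmas = np.maximum(sigmas, min_sigma)
    return _make_profile(burst, sigmas, grid, method="adaptive")


def isi_rate(burst: SpikeBurst):
    """Discrete instantaneous firing rate from inter-spike intervals.

    Returns ``(interval_starts_ms, rates)`` where
    rate(i) = 1000 / (tau_{i+1} - tau_i) spikes/s is attributed to the
    interval [tau_i, tau_{i+1}).
    """
    if burst.n_spk < 2:
        raise ValueError("ISI rate needs at least 2 spikes")
    isi = np.diff(burst.spike_times)
    if np.any(isi <= 0):
        raise ValueError("duplicate spike times give an infinite rate")
    return burst.spike_times[:-1], 1000.0 / isi
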