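"""Forward simulator of the linear ensemble-coding model.

Generates complete synthetic recording sessions: per-trial gaze and head
traces (1 kHz, degrees), the recorded cell's spike train, and initial
conditions, under the same assumptions the analyses test —

* the recorded cell's expected burst count follows the static gain-field
  movement field; trial-to-trial count variability is multiplicative
  (shared coefficient of variation C_V) plus optional additive noise;
* burst profiles are synchronized to the gaze kinematics: every cell's
  rate is the straight-line gaze-velocity profile (advanced by the 20-ms
  neural lead) scaled to its expected count, so cumulative counts track
  straight-line displacement;
* gaze kinematics depend on initial eye-in-head position E0: ipsilateral
  deviations (E0 > 0) prolong the movement and lower its peak velocity,
  and the head contributes more for larger amplitudes and ipsilateral E0
  (a phenomenological ramp model, not a head plant);
* the desired trajectory is decoded by summing mini spike-vectors of the
  recruited population (each spike of cell k moves the eye by its site's
  efferent gaze vector over a calibration constant eta), optionally
  truncated when the cumulative population count reaches a fixed
  threshold, and the downstream system is the delayed linear feedback
  loop  e(s)/c(s) = B / (s*(s + B*exp(-s*dT))).

The experimental paradigm is emulated with E0 in {-15, 0, +15} deg and
the head initially deviated oppositely (H0 = -E0) so the initial gaze is
straight ahead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as _stats

from .kinematics import Trial
from .movement_field import (MovementFieldParams, NoiseParams,
                             predict_static_count)
from .sc_map import MapParams, afferent_map, efferent_map

__all__ = [
    "KinematicsConfig",
    "SimConfig",
    "SessionFile",
    "make_velocity_profile",
    "make_population_rates",
    "sample_population_spikes",
    "decode_desired_trajectory",
    "apply_count_threshold",
    "simulate_plant",
    "generate_session",
    "default_cell_params",
]

# Velocity profiles are Beta densities on the normalized movement time.
# The shape depends on E0: contralateral eye positions give sharp, early
# peaks; ipsilateral ones give flat, late-peaked profiles (the profile
# variability that the shuffle-null analysis relies on).
_PEAK_X0 = 0.32  # normalized peak time, E0 = 0
_PEAK_X_PER_DEG = 0.007
_CONC0 = 4.0  # profile concentration (sharpness), E0 = 0
_CONC_PER_DEG = -0.04


def _beta_shape(E0: float) -> tuple:
    """Beta-density shape for the velocity profile at eye position E0.

    Mode at x_m = 0.32 + 0.007*E0 with concentration 4 - 0.04*E0:
    contralateral (E0 < 0) profiles peak early and sharply, ipsilateral
    ones late and flat (cf. the E0-split velocity profiles of real gaze
    shifts).  a, b > 1 so the profile vanishes at both endpoints.
    """
    x_m = float(np.clip(_PEAK_X0 + _PEAK_X_PER_DEG * E0, 0.1, 0.6))
    conc = max(_CONC0 + _CONC_PER_DEG * E0, 2.0)
    return 1.0 + conc * x_m, 1.0 + conc * (1.0 - x_m)


def default_cell_params(map_params: MapParams = MapParams()) -> MovementFieldParams:
    """The reference recorded cell: peak 25 spikes, weak positive gain
    field (0.003/deg), field centre at 36.0 deg amplitude, 23.3 deg
    direction, extent 0.6 mm."""
    u0, v0 = afferent_map(36.0, 23.3, map_params)
    return MovementFieldParams(N0=25.0, eps=0.003, u0=u0, v0=v0, sigmaP=0.6)


@dataclass(frozen=True)
class KinematicsConfig:
    """Phenomenological gaze/head kinematics of the generator.

    Durations: T = (T0 + Ts*dG + Tk*max(0, dG - head_knee_deg))
    * (1 + gE*E0) * lognormal jitter.  The extra slope above the knee
    reproduces the drop of peak gaze velocity once the head contributes;
    the E0 gain prolongs (slows) movements for ipsilateral eye positions.
    Head contribution: dH = max(0, k_head*(dG + E0 - head_margin_deg)),
    ramping up from a delayed onset (earlier for ipsilateral E0).
    """

    T0_ms: float = 45.0
    Ts_ms_per_deg: float = 1.8
    Tk_ms_per_deg: float = 1.5
    head_knee_deg: float = 35.0  # oculomotor-range soft limit
    gE_per_deg: float = 0.014
    duration_jitter_sd: float = 0.08  # lognormal sigma; 0 disables
    k_head: float = 0.6
    head_margin_deg: float = 20.0
    head_delay0_ms: float = 30.0
    head_delay_E0_ms_per_deg: float = 1.5


@dataclass
class SimConfig:
    """Full parameterization of the synthetic session generator."""

    mf: MovementFieldParams = field(default_factory=default_cell_params)
    noise: NoiseParams = field(default_factory=lambda: NoiseParams(C_V=0.15))
    map_params: MapParams = field(default_factory=MapParams)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    n_trials: int = 600
    E0_levels: tuple = (-15.0, 0.0, 15.0)
    seed: int = 0
    # population / decoder / plant
    n_pop: int = 225
    pop_sigma: float = 0.5  # population extent on the map (mm)
    B: float = 70.0  # burst-generator gain (1/s)
    delta_T: float = 20.0  # SC lead (ms)
    theta_fixed: Optional[float] = None  # population spike-count threshold
    # session layout
    fs: float = 1000.0
    pre_ms: float = 300.0
    post_ms: float = 200.0
    # target sampling spread on the map around the cell's field centre (mm)
    target_spread_u: float = 0.7
    target_spread_v: float = 0.7
    # recorded-cell spike generation: 'conditioned' draws the count from the
    # multiplicative-noise model and places times from the rate envelope;
    # 'poisson' is an inhomogeneous Poisson process; 'quantile' places
    # round(N_STMF) spikes deterministically at envelope quantiles (the
    # noiseless-envelope limit)
    spike_mode: str = "conditioned"

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("burst gain B must be positive")
        if self.delta_T < 0:
            raise ValueError("delta_T must be nonnegative")
        if self.B * self.delta_T / 1000.0 >= np.pi / 2:
            raise ValueError("delay loop unstable: need B*delta_T < pi/2")
        if self.spike_mode not in ("conditioned", "poisson", "quantile"):
            raise ValueError(f"unknown spike_mode {self.spike_mode!r}")


@dataclass
class SessionFile:
    """A generated session: trials plus cell metadata and provenance."""

    trials: list
    mf: MovementFieldParams
    config: SimConfig

    def __len__(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# kinematics


def _duration_ms(dG: float, E0: float, kin: KinematicsConfig,
                 jitter: float = 1.0) -> float:
    base = (kin.T0_ms + kin.Ts_ms_per_deg * dG
            + kin.Tk_ms_per_deg * max(0.0, dG - kin.head_knee_deg))
    return base * (1.0 + kin.gE_per_deg * E0) * jitter


def make_velocity_profile(dG: float, E0: float,
                          kin: KinematicsConfig = KinematicsConfig(),
                          fs: float = 1000.0, jitter: float = 1.0):
    """Straight-line gaze-velocity profile for one gaze shift.

    Returns ``(gdot, duration_ms)``: a Beta-shaped velocity trace
    (deg/s, E0-dependent shape) on a 1-ms grid over [0, duration], zero
    at both ends, whose
    trapezoid integral equals ``dG`` exactly.  Duration grows with
    amplitude (extra slope above the head knee) and with ipsilateral E0;
    peak velocity correspondingly falls for ipsilateral eye positions.
    """
    if dG <= 0:
        raise ValueError("gaze amplitude must be positive")
    T = _duration_ms(dG, E0, kin, jitter)
    n = max(int(round(T * fs / 1000.0)), 8)
    x = np.linspace(0.0, 1.0, n + 1)
    a, b = _beta_shape(E0)
    prof = _stats.beta.pdf(x, a, b)
    dt_s = 1.0 / fs
    area = np.trapezoid(prof, dx=dt_s)
    gdot = prof * (dG / area)
    return gdot, n * 1000.0 / fs


def _displacement_from_velocity(gdot: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative trapezoid integral of a velocity trace (endpoint exact)."""
    dt_s = 1.0 / fs
    dg = np.concatenate([[0.0], np.cumsum(0.5 * (gdot[1:] + gdot[:-1]) * dt_s)])
    return dg


# ---------------------------------------------------------------------------
# population rates, spikes, decoding, plant


def _population_sites(target_u: float, target_v: float, config: SimConfig):
    """Square grid of recruited-cell sites centred on the target's image."""
    n_side = max(int(np.ceil(np.sqrt(config.n_pop))), 3)
    half = 2.5 * config.pop_sigma
    g = np.linspace(-half, half, n_side)
    uu, vv = np.meshgrid(target_u + g, target_v + g, indexing="ij")
    return uu.ravel(), vv.ravel()


def make_population_rates(dG: float, phi_deg: float, E0: float,
                          config: SimConfig, n_mul: float = 0.0,
                          jitter: float = 1.0):
    """Expected per-cell rate profiles for one gaze shift.

    Every recruited cell shares the normalized straight-line velocity
    profile (synchronized bursts), scaled to its expected count: a
    Gaussian of map distance from the target's image, gain-modulated by
    (1 + eps*E0), times the shared per-trial multiplicative factor
    ``(1 + n_mul)`` that implements signal-dependent noise.

    Returns ``(rates, sites_u, sites_v, gdot, duration_ms)`` where
    ``rates`` is (n_cells, n_t) in spikes/ms on the 1-ms burst grid
    (advanced relative to the movement by ``config.delta_T``).
    """
    if dG <= 0:
        raise ValueError("target amplitude must be positive")
    tu, tv = afferent_map(dG, phi_deg, config.map_params)
    su, sv = _population_sites(tu, tv, config)
    d2 = (su - tu) ** 2 + (sv - tv) ** 2
    gain = 1.0 + config.mf.eps * E0
    if gain <= 0:
        raise ValueError("nonpositive eye-position gain")
    N_k = config.mf.N0 * gain * np.exp(-d2 / (2.0 * config.pop_sigma ** 2))
    gdot, T = make_velocity_profile(dG, E0, config.kinematics, config.fs, jitter)
    envelope = gdot / (dG * config.fs)  # spikes/ms per expected spike; sums to 1
    rates = np.outer(N_k * (1.0 + n_mul), envelope) * config.fs / 1000.0
    return rates, su, sv, gdot, T


def sample_population_spikes(rates: np.ndarray, rng: np.random.Generator,
                             dt_ms: float = 1.0):
    """Inhomogeneous-Poisson spike trains from per-cell rate profiles.

    ``rates`` is (n_cells, n_t) in spikes/ms; returns a list of arrays of
    spike times (ms, relative to the grid start), independent across
    cells given the shared envelope.
    """
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    n_cells, n_t = rates.shape
    trains = []
    for k in range(n_cells):
        counts = rng.poisson(rates[k] * dt_ms)
        idx = np.repeat(np.arange(n_t), counts)
        times = (idx + rng.uniform(0.0, 1.0, size=len(idx))) * dt_ms
        trains.append(np.sort(times))
    return trains


def calibrate_eta(config: SimConfig, dG: Optional[float] = None,
                  phi_deg: Optional[float] = None) -> float:
    """Decoder calibration: expected |vector sum| over amplitude for the
    centred target (the cell's optimal vector by default)."""
    if dG is None:
        dG, phi_deg = efferent_map(config.mf.u0, config.mf.v0, config.map_params)
    tu, tv = afferent_map(dG, phi_deg, config.map_params)
    su, sv = _population_sites(tu, tv, config)
    d2 = (su - tu) ** 2 + (sv - tv) ** 2
    N_k = config.mf.N0 * np.exp(-d2 / (2.0 * config.pop_sigma ** 2))
    mG, mphi = efferent_map(su, sv, config.map_params)
    sx = np.sum(N_k * mG * np.cos(np.deg2rad(mphi)))
    sy = np.sum(N_k * mG * np.sin(np.deg2rad(mphi)))
    return float(np.hypot(sx, sy) / dG)


def decode_desired_trajectory(spike_trains, sites_u, sites_v,
                              config: SimConfig, eta: float,
                              t_grid: np.ndarray):
    """Cumulative mini spike-vector sum: the desired gaze trajectory.

    Each spike of cell k adds its site's efferent gaze vector divided by
    the calibration constant ``eta``, at the spike time plus the SC lead.
    Returns an (n_t, 2) running vector sum (deg) on ``t_grid`` (ms).
    """
    if not np.isfinite(eta) or eta <= 0:
        raise ValueError("decoder requires a calibrated eta > 0")
    mG, mphi = efferent_map(np.asarray(sites_u), np.asarray(sites_v),
                            config.map_params)
    mx = mG * np.cos(np.deg2rad(mphi))
    my = mG * np.sin(np.deg2rad(mphi))
    out = np.zeros((len(t_grid), 2))
    dt = t_grid[1] - t_grid[0] if len(t_grid) > 1 else 1.0
    for k, train in enumerate(spike_trains):
        if len(train) == 0:
            continue
        idx = np.searchsorted(t_grid, np.asarray(train) + config.delta_T,
                              side="right") - 1
        idx = idx[(idx >= 0) & (idx < len(t_grid))]
        np.add.at(out[:, 0], idx, mx[k] / eta)
        np.add.at(out[:, 1], idx, my[k] / eta)
    return np.cumsum(out, axis=0)


def apply_count_threshold(spike_trains, theta: float):
    """Discard all population spikes after the cumulative count reaches theta.

    Models the downstream mechanism that stops the burst generator once
    the total number of population spikes exceeds a fixed threshold.
    """
    if theta <= 0:
        raise ValueError("threshold must be positive")
    all_times = np.sort(np.concatenate([np.asarray(t) for t in spike_trains])) \
        if spike_trains else np.array([])
    if len(all_times) <= theta:
        return [np.asarray(t, float).copy() for t in spike_trains]
    t_cut = all_times[int(np.ceil(theta)) - 1]
    return [np.asarray(t, float)[np.asarray(t, float) <= t_cut]
            for t in spike_trains]


def simulate_plant(command: np.ndarray, B: float = 70.0, delta_T: float = 20.0,
                   fs: float = 1000.0, t_end_ms: Optional[float] = None):
    """Integrate the delayed linear feedback loop driven by a velocity command.

    Realizes  vdot(t) = B*(c(t) - v(t - dT)),  e(t) = integral of v,  by
    explicit Euler stepping at the grid resolution.  For a command of
    finite area dG the final position converges to dG (unit DC gain).
    Raises if the closed loop is unstable (B*dT >= pi/2) or a growing
    oscillation is detected.

    Returns ``(t_ms, e, v)``.
    """
    if B * delta_T / 1000.0 >= np.pi / 2:
        raise ValueError("delay loop unstable: need B*delta_T < pi/2")
    c = np.asarray(command, float)
    dt_s = 1.0 / fs
    if t_end_ms is None:
        # the delayed loop rings at B*dT = 1.4 with slow decay; allow the
        # oscillation to settle so the endpoint reflects the DC gain
        t_end_ms = len(c) * 1000.0 / fs + 3000.0
    n = int(round(t_end_ms * fs / 1000.0))
    d = int(round(delta_T * fs / 1000.0))
    cc = np.zeros(n)
    cc[:min(len(c), n)] = c[:min(len(c), n)]
    v = np.zeros(n)
    for i in range(n - 1):
        v_del = v[i - d] if i - d >= 0 else 0.0
        v[i + 1] = v[i] + dt_s * B * (cc[i] - v_del)
    peak = np.max(np.abs(v))
    if peak > 0 and np.max(np.abs(v[-max(n // 10, d + 1):])) > peak * 1.01:
        raise RuntimeError("plant simulation diverging (growing oscillation)")
    e = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt_s)])[:n]
    t = np.arange(n) * 1000.0 / fs
    return t, e, v


# ---------------------------------------------------------------------------
# recorded-cell spike generation


def _recorded_cell_spikes(dG: float, N_exp: float, gdot: np.ndarray,
                          onset_ms: float, config: SimConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Burst spike times (ms) of the recorded cell for one trial.

    Spikes occupy [onset - dT, offset - dT]; their cumulative count
    follows the normalized displacement profile so that, after the
    20-ms shift, it tracks the straight-line gaze displacement.
    """
    dg = _displacement_from_velocity(gdot, config.fs)
    F = dg / dg[-1]  # normalized displacement CDF on the movement grid
    t_rel = np.arange(len(F)) * 1000.0 / config.fs
    start = onset_ms - config.delta_T

    if config.spike_mode == "quantile":
        N = int(round(N_exp))
        if N <= 0:
            return np.array([])
        q = (np.arange(N) + 0.5) / N
        return start + np.interp(q, F, t_rel)

    if config.spike_mode == "conditioned":
        n_mul = rng.normal(0.0, config.noise.C_V) if config.noise.C_V > 0 else 0.0
        n_add = (rng.normal(0.0, config.noise.sigma_ADD)
                 if config.noise.sigma_ADD > 0 else 0.0)
        N = int(max(np.rint((1.0 + n_mul) * N_exp + n_add), 0))
        if N == 0:
            return np.array([])
        # stratified placement: one spike per envelope quantile stratum with
        # within-stratum jitter — a tightly synchronized burst whose timing
        # dispersion is sub-Poisson, as implied by the synchronized-population
        # assumption, while the count carries the multiplicative noise
        u = (np.arange(N) + rng.uniform(0.0, 1.0, size=N)) / N
        return start + np.interp(u, F, t_rel)

    # poisson
    n_mul = rng.normal(0.0, config.noise.C_V) if config.noise.C_V > 0 else 0.0
    rate = np.maximum(N_exp * (1.0 + n_mul), 0.0) * gdot / (dG * config.fs)
    counts = rng.poisson(rate)
    idx = np.repeat(np.arange(len(rate)), counts)
    times = start + (idx + rng.uniform(0.0, 1.0, size=len(idx)))
    return np.sort(times)


# ---------------------------------------------------------------------------
# session generation


def _head_ramp(x: np.ndarray) -> np.ndarray:
    """Smooth 0->1 ramp (Beta(2,3) CDF) for the head trajectory."""
    return _stats.beta.cdf(x, 2.0, 3.0)


def generate_session(config: SimConfig) -> SessionFile:
    """Generate a full synthetic session (reproducible from config.seed).

    Targets are drawn on the SC map around the recorded cell's field
    centre; E0 is drawn uniformly from the configured levels with the
    head initially deviated oppositely (initial gaze straight ahead).
    Gaze traces integrate the straight-line velocity profile along the
    target direction; head traces ramp up a contribution that grows with
    amplitude and ipsilateral E0, starting earlier for ipsilateral eye
    positions.  The recorded cell's spikes follow ``config.spike_mode``.
    """
    rng = np.random.default_rng(config.seed)
    kin = config.kinematics
    trials = []
    for i in range(config.n_trials):
        u = rng.normal(config.mf.u0, config.target_spread_u)
        v = rng.normal(config.mf.v0, config.target_spread_v)
        dG, phi_deg = efferent_map(max(u, 0.0), v, config.map_params)
        dG = float(np.clip(dG, 2.0, 100.0))
        phi_deg = float(np.clip(phi_deg, -80.0, 80.0))
        E0 = float(rng.choice(config.E0_levels))
        H0 = -E0

        jitter = (np.exp(rng.normal(0.0, kin.duration_jitter_sd))
                  if kin.duration_jitter_sd > 0 else 1.0)
        gdot, T = make_velocity_profile(dG, E0, kin, config.fs, jitter)
        dg = _displacement_from_velocity(gdot, config.fs)

        n_pre = int(round(config.pre_ms * config.fs / 1000.0))
        n_post = int(round(config.post_ms * config.fs / 1000.0))
        n_mov = len(dg)
        n_tot = n_pre + n_mov + n_post
        t = np.arange(n_tot) * 1000.0 / config.fs
        onset_ms = n_pre * 1000.0 / config.fs

        full_dg = np.concatenate([np.zeros(n_pre), dg, np.full(n_post, dg[-1])])
        cphi, sphi = np.cos(np.deg2rad(phi_deg)), np.sin(np.deg2rad(phi_deg))
        gaze_h = full_dg * cphi
        gaze_v = full_dg * sphi

        # head: delayed smooth ramp along the gaze direction from H0
        dH = max(0.0, kin.k_head * (dG + E0 - kin.head_margin_deg))
        delay = max(kin.head_delay0_ms - kin.head_delay_E0_ms_per_deg * E0, 0.0)
        h_start = onset_ms + delay
        h_end = onset_ms + T
        if h_end <= h_start:  # degenerate short movement
            h_end = h_start + 1.0
        xh = np.clip((t - h_start) / (h_end - h_start), 0.0, 1.0)
        head_ramp = dH * _head_ramp(xh)
        head_h = H0 + head_ramp * cphi
        head_v = head_ramp * sphi

        N_exp = predict_static_count(dG, phi_deg, E0, config.mf,
                                     config.map_params)
        spikes = _recorded_cell_spikes(dG, N_exp, gdot, onset_ms, config, rng)
        spikes = spikes[(spikes >= t[0]) & (spikes <= t[-1])]

        trials.append(Trial(t=t, gaze_h=gaze_h, gaze_v=gaze_v,
                            head_h=head_h, head_v=head_v, spikes=spikes,
                            E0=E0, H0=H0,
                            target=(dG * cphi, dG * sphi), trial_id=i))
    return SessionFile(trials=trials, mf=config.mf, config=config)
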