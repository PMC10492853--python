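"""Dynamic movement-field analyses: phase trajectories, rate-velocity
correlations, shuffle nulls and supporting statistics.

The dynamic ensemble-coding prediction is that the cumulative spike count
of a recruited SC cell, delayed by the neural lead dT (20 ms), grows
linearly with the instantaneous straight-line gaze displacement:

    n_CS(t - dT) = (N_STMF / dG) * delta_g(t)

so each trial's phase trajectory (delta_g, n_CS) should be a straight
line of slope alpha = N_STMF/dG, and, by differentiation, the spike
density SD(t - dT) should covary with the straight-line gaze velocity.
The per-trial Pearson correlations between SD and velocity are compared
against a shuffle null obtained by randomly re-pairing velocity profiles
with spike densities across the session; the population histogram of
correlations is summarized by a beta-family density on (-0.5, 1):

    P(r) = P0 * (r + 0.5)**alpha * (1 - r)**beta,
    mode at r = (alpha - 0.5*beta) / (alpha + beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinematics import GazeShiftEvent
from .movement_field import MovementFieldParams, predict_static_count
from .sc_map import MapParams
from .spike_tools import DensityProfile

__all__ = [
    "PhaseTrajectory",
    "CorrelationRecord",
    "BetaFit",
    "predict_cumulative_count",
    "phase_fit_and_deviation",
    "sd_velocity_correlation",
    "shuffle_null",
    "fit_beta_distribution",
    "cluster_gaze_shifts",
    "peak_regressions",
    "zscore_partial_regression",
    "head_amplitude_effect",
    "histogram_binwidth",
    "ks_one_tailed",
]


@dataclass
class PhaseTrajectory:
    """Samples of one trial's (displacement, cumulative-count) curve.

    ``dg`` is the straight-line gaze displacement (deg, 0..dG) and ``ncs``
    the cumulative spike density at the same 1-ms samples, already
    time-shifted by the 20-ms neural lead.
    """

    dg: np.ndarray
    ncs: np.ndarray
    n_spk: int
    event: Optional[GazeShiftEvent] = None

    def __post_init__(self) -> None:
        self.dg = np.asarray(self.dg, float)
        self.ncs = np.asarray(self.ncs, float)
        if len(self.dg) != len(self.ncs):
            raise ValueError("phase trajectory samples must have equal length")


@dataclass
class CorrelationRecord:
    """Per-trial spike-density vs gaze-velocity correlation and peaks."""

    trial_id: int
    r: float
    n_spk: int
    peak_sd: float = np.nan  # spikes/s
    peak_sd_time: float = np.nan  # ms
    peak_velocity: float = np.nan  # deg/s
    peak_velocity_time: float = np.nan  # ms
    head_contribution: float = np.nan  # deg
    E0: float = np.nan
    valid: bool = True


@dataclass
class BetaFit:
    """Least-squares beta-family fit to a correlation histogram."""

    P0: float
    alpha: float
    beta: float
    bin_centers: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_density: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mode_r(self) -> float:
        """Analytic mode of P(r) on (-0.5, 1)."""
        return (self.alpha - 0.5 * self.beta) / (self.alpha + self.beta)

    def pdf_shape(self, r) -> np.ndarray:
        r = np.asarray(r, float)
        out = np.zeros_like(r)
        m = (r > -0.5) & (r < 1.0)
        out[m] = self.P0 * (r[m] + 0.5) ** self.alpha * (1.0 - r[m]) ** self.beta
        return out


# ---------------------------------------------------------------------------
# phase-trajectory analysis


def predict_cumulative_count(event: GazeShiftEvent, mf: MovementFieldParams,
                             map_params: MapParams, dg,
                             ) -> np.ndarray:
    """Predicted cumulative spike count along the straight-line displacement.

    n_CS(t - dT) = (N_STMF/dG) * delta_g(t); the endpoint equals N_STMF.
    """
    if not np.isfinite(event.dG) or event.dG <= 0:
        raise ValueError("event amplitude dG must be positive")
    N = predict_static_count(event.dG, event.phi_deg, event.E0, mf, map_params)
    return (N / event.dG) * np.asarray(dg, float)


def phase_fit_and_deviation(traj: PhaseTrajectory):
    """Straight-line fit of a phase trajectory and its deviation SD.

    Ordinary least squares of n_CS on delta_g; returns
    ``(slope_a, offset_b, dev_sd)`` with dev_sd the SD of the residuals
    (spikes).  Trials with N_spk < 10 are conventionally excluded upstream.
    """
    if np.ptp(traj.dg) == 0:
        raise ValueError("degenerate phase trajectory: constant displacement")
    fit = stats.linregress(traj.dg, traj.ncs)
    resid = traj.ncs - (fit.slope * traj.dg + fit.intercept)
    return float(fit.slope), float(fit.intercept), float(np.std(resid))


# ---------------------------------------------------------------------------
# spike density vs gaze velocity


def sd_velocity_correlation(sd_profile: DensityProfile, gdot_lin,
                            event: GazeShiftEvent, lead: float = 20.0,
                            n_spk: Optional[int] = None) -> CorrelationRecord:
    """Correlate the lead-shifted spike density with straight-line velocity.

    The spike density (estimated on the lead-shifted window) is shifted
    forward by ``lead`` ms and sampled at 1 kHz over [onset, offset],
    aligning SD(t - dT) with Gdot_lin(t).  Also records the peak spike
    density (spikes/s), peak velocity and their times.  Zero-variance
    signals yield a flagged (``valid=False``) record.
    """
    gdot = np.asarray(gdot_lin, float)
    t_move = event.onset_ms + np.arange(len(gdot)) * 1.0
    # SD(t - lead) evaluated at movement times t
    sd = np.interp(t_move - lead, sd_profile.t, sd_profile.sd)
    if n_spk is None:
        n_spk = int(round(sd_profile.csd[-1]))
    rec = CorrelationRecord(trial_id=getattr(event, "trial_id", 0), r=np.nan,
                            n_spk=n_spk, E0=event.E0,
                            head_contribution=event.head_contribution)
    if np.std(sd) == 0 or np.std(gdot) == 0:
        rec.valid = False
        return rec
    rec.r = float(stats.pearsonr(sd, gdot).statistic)
    ipk_sd = int(np.argmax(sd))
    ipk_v = int(np.argmax(gdot))
    rec.peak_sd = float(sd[ipk_sd] * 1000.0)  # spikes/ms -> spikes/s
    rec.peak_sd_time = float(t_move[ipk_sd] - lead)  # time of the SD peak itself
    rec.peak_velocity = float(gdot[ipk_v])
    rec.peak_velocity_time = float(t_move[ipk_v])
    return rec


def shuffle_null(sd_profiles: Sequence[DensityProfile],
                 gdots: Sequence[np.ndarray],
                 events: Sequence[GazeShiftEvent],
                 rng: np.random.Generator,
                 lead: float = 20.0,
                 mode: str = "truncate") -> list[CorrelationRecord]:
    """Null correlations from randomly re-paired velocity profiles.

    The assignment of gaze-velocity profiles to spike-density profiles is
    permuted across the session (self-pairings allowed).  Each re-paired
    correlation is computed over the interval set by the pairing: with
    ``mode='truncate'`` (default) both signals are truncated to the
    shorter of the two durations; ``mode='resample'`` linearly time-warps
    the velocity profile onto the spike trial's duration instead.
    """
    n = len(sd_profiles)
    if n < 2:
        raise ValueError("shuffle null needs at least 2 trials")
    if len(gdots) != n or len(events) != n:
        raise ValueError("inputs must have one entry per trial")
    perm = rng.permutation(n)
    out: list[CorrelationRecord] = []
    for i, j in enumerate(perm):
        ev_spk = events[i]
        gdot = np.asarray(gdots[j], float)
        if mode == "truncate":
            n_t = min(int(round(ev_spk.duration)) + 1, len(gdot))
            t_move = ev_spk.onset_ms + np.arange(n_t) * 1.0
            sd = np.interp(t_move - lead, sd_profiles[i].t, sd_profiles[i].sd)
            g = gdot[:n_t]
        elif mode == "resample":
            n_t = int(round(ev_spk.duration)) + 1
            t_move = ev_spk.onset_ms + np.arange(n_t) * 1.0
            sd = np.interp(t_move - lead, sd_profiles[i].t, sd_profiles[i].sd)
            g = np.interp(np.linspace(0, len(gdot) - 1, n_t),
                          np.arange(len(gdot)), gdot)
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        rec = CorrelationRecord(trial_id=getattr(ev_spk, "trial_id", i), r=np.nan,
                                n_spk=int(round(sd_profiles[i].csd[-1])),
                                E0=ev_spk.E0)
        if np.std(sd) == 0 or np.std(g) == 0:
            rec.valid = False
        else:
            rec.r = float(stats.pearsonr(sd, g).statistic)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# distribution of correlations


def histogram_binwidth(value_range: float, n: int) -> float:
    """Histogram bin width BW = range / sqrt(N)."""
    if n < 1:
        raise ValueError("need at least one data point")
    if value_range < 0:
        raise ValueError("range must be nonnegative")
    if value_range == 0:
        return 0.0  # degenerate: a single bin
    return value_range / np.sqrt(n)


def fit_beta_distribution(correlations, bin_width: Optional[float] = None,
                          method: str = "histogram") -> BetaFit:
    """Fit P(r) = P0*(r+0.5)^alpha*(1-r)^beta to a sample of correlations.

    ``method='histogram'`` (default) least-squares fits the binned density
    (bin width range/sqrt(N) unless given); ``method='mle'`` fits by
    maximum likelihood of the equivalent rescaled Beta law instead.
    Values outside the support (-0.5, 1) are excluded with a warning.
    """
    r = np.asarray(correlations, float)
    r = r[np.isfinite(r)]
    inside = (r > -0.5) & (r < 1.0)
    if not np.all(inside):
        import warnings
        warnings.warn(f"excluding {int((~inside).sum())} correlations outside (-0.5, 1)")
        r = r[inside]
    if len(r) < 50:
        raise ValueError("need at least 50 correlations for a stable beta fit")

    if method == "mle":
        # r = -0.5 + 1.5*x with x ~ Beta(alpha+1, beta+1)
        a, b, _, _ = stats.beta.fit((r + 0.5) / 1.5, floc=0.0, fscale=1.0)
        alpha, beta = a - 1.0, b - 1.0
        P0 = len(r) * 1.0 / stats.beta(a, b).pdf(0.5)  # nominal scale only
        return BetaFit(P0=float(P0), alpha=float(alpha), beta=float(beta))

    if bin_width is None:
        bin_width = histogram_binwidth(1.5, len(r))
    n_bins = max(int(round(1.5 / bin_width)), 4)
    edges = np.linspace(-0.5, 1.0, n_bins + 1)  # centers stay inside (-0.5, 1)
    counts, edges = np.histogram(r, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def shape(x, P0, alpha, beta):
        return P0 * (x + 0.5) ** alpha * (1.0 - x) ** beta

    p0 = [counts.max() if counts.max() > 0 else 1.0, 1.0, 1.0]
    popt, _ = optimize.curve_fit(shape, centers, counts, p0=p0,
                                 bounds=([0, 1e-6, 1e-6], [np.inf, 50, 50]),
                                 maxfev=20000)
    return BetaFit(P0=float(popt[0]), alpha=float(popt[1]), beta=float(popt[2]),
                   bin_centers=centers, bin_density=counts.astype(float))


def sample_beta_correlations(alpha: float, beta: float, size: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw correlations from P(r) ∝ (r+0.5)^alpha (1-r)^beta on (-0.5, 1)."""
    x = rng.beta(alpha + 1.0, beta + 1.0, size=size)
    return -0.5 + 1.5 * x


# ---------------------------------------------------------------------------
# cluster / peak / regression analyses


def cluster_gaze_shifts(events: Sequence[GazeShiftEvent],
                        center_dG: float, center_phi_deg: float,
                        bin_deg: float = 2.0, radius_deg: float = 10.0,
                        min_per_cluster: int = 3) -> list[list[int]]:
    """Group gaze shifts whose endpoints fall in the same 2x2 deg bin.

    Endpoints within ``radius_deg`` of the movement-field centre (in
    Cartesian gaze coordinates) are binned on a ``bin_deg`` grid anchored
    at the centre; bins holding at least ``min_per_cluster`` events form
    clusters.  Returns lists of event indices.
    """
    cx = center_dG * np.cos(np.deg2rad(center_phi_deg))
    cy = center_dG * np.sin(np.deg2rad(center_phi_deg))
    bins: dict[tuple, list[int]] = {}
    for idx, ev in enumerate(events):
        ex, ey = ev.dG_h, ev.dG_v
        if np.hypot(ex - cx, ey - cy) > radius_deg:
            continue
        key = (int(np.floor((ex - cx) / bin_deg)), int(np.floor((ey - cy) / bin_deg)))
        bins.setdefault(key, []).append(idx)
    return [members for members in bins.values() if len(members) >= min_per_cluster]


def _bootstrap_slope(x, y, n_boot, rng, fit_fn):
    n = len(x)
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        out[b] = fit_fn(x[idx], y[idx])
    return out


def peak_regressions(records: Sequence[CorrelationRecord],
                     n_boot: int = 1000,
                     rng: Optional[np.random.Generator] = None,
                     ci_alpha: float = 0.01) -> dict:
    """Peak-based regressions and spike-density timing lead.

    Univariate regressions of peak spike density (spikes/s) and of spike
    count on peak gaze velocity (deg/s), with bootstrap confidence
    intervals (1000 resamples), plus the mean timing difference
    ``peak_sd_time - peak_velocity_time`` in ms (negative = the spike
    density peaks before the gaze velocity).
    """
    recs = [r for r in records if r.valid and np.isfinite(r.peak_velocity)]
    if len(recs) < 10:
        raise ValueError("need at least 10 valid records for peak regressions")
    if rng is None:
        rng = np.random.default_rng()
    v = np.array([r.peak_velocity for r in recs])
    f = np.array([r.peak_sd for r in recs])
    n = np.array([float(r.n_spk) for r in recs])
    dt_peak = np.array([r.peak_sd_time - r.peak_velocity_time for r in recs])

    def slope(x, y):
        return stats.linregress(x, y).slope

    out = {}
    for name, y in (("peak_sd_vs_velocity", f), ("n_spk_vs_velocity", n)):
        boots = _bootstrap_slope(v, y, n_boot, rng, slope)
        lo, hi = np.percentile(boots, [100 * ci_alpha / 2, 100 * (1 - ci_alpha / 2)])
        out[name] = {"slope": float(slope(v, y)), "ci": (float(lo), float(hi))}
    out["mean_timing_lead_ms"] = float(np.mean(dt_peak))
    out["n"] = len(recs)
    return out


def zscore_partial_regression(V_PK, F_PK, N_SPK, n_boot: int = 1000,
                              rng: Optional[np.random.Generator] = None,
                              ci_alpha: float = 0.01) -> dict:
    """Multiple regression of peak velocity on z-scored predictors.

    All three variables are standardized to zero mean / unit SD and the
    no-intercept model V = p_SD*F + p_NS*N is fitted by least squares;
    bootstrap confidence intervals at the given alpha.
    """
    V = np.asarray(V_PK, float)
    F = np.asarray(F_PK, float)
    N = np.asarray(N_SPK, float)
    if not (len(V) == len(F) == len(N)) or len(V) < 20:
        raise ValueError("need >= 20 matched observations")
    for x in (V, F, N):
        if np.std(x) == 0:
            raise ValueError("zero-variance variable in partial regression")
    if abs(stats.pearsonr(F, N).statistic) > 0.999:
        raise ValueError("collinear predictors")

    def zs(x):
        return (x - x.mean()) / x.std()

    def coefs(idx=None):
        if idx is None:
            v, f_, n_ = zs(V), zs(F), zs(N)
        else:
            v, f_, n_ = zs(V[idx]), zs(F[idx]), zs(N[idx])
        X = np.column_stack([f_, n_])
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        return beta

    p_sd, p_ns = coefs()
    if rng is None:
        rng = np.random.default_rng()
    boots = np.array([coefs(rng.integers(0, len(V), size=len(V)))
                      for _ in range(n_boot)])
    qs = [100 * ci_alpha / 2, 100 * (1 - ci_alpha / 2)]
    ci_sd = np.percentile(boots[:, 0], qs)
    ci_ns = np.percentile(boots[:, 1], qs)
    return {"p_SD": float(p_sd), "p_NS": float(p_ns),
            "ci_SD": (float(ci_sd[0]), float(ci_sd[1])),
            "ci_NS": (float(ci_ns[0]), float(ci_ns[1]))}


def head_amplitude_effect(records: Sequence[CorrelationRecord],
                          min_n_spk: int = 15) -> dict:
    """Regression of the per-trial SD-velocity correlation on head amplitude.

    Tests whether the rate-velocity coupling degrades as the head
    contributes more to the gaze shift.  Returns offset r0, slope
    (per deg), Pearson r and r^2.
    """
    recs = [r for r in records
            if r.valid and r.n_spk >= min_n_spk and np.isfinite(r.head_contribution)]
    if len(recs) < 10:
        raise ValueError("need at least 10 records with head contributions")
    dh = np.array([r.head_contribution for r in recs])
    rr = np.array([r.r for r in recs])
    fit = stats.linregress(dh, rr)
    return {"offset": float(fit.intercept), "slope": float(fit.slope),
            "r": float(fit.rvalue), "r2": float(fit.rvalue ** 2), "n": len(recs)}


# ---------------------------------------------------------------------------
# hypothesis testing


def ks_one_tailed(sample_a, sample_b, alpha: float = 0.005):
    """One-sided two-sample KS test that A is shifted to HIGHER values than B.

    Returns ``(ks_statistic, p_value, reject)`` with ``reject`` True when
    the null (A not higher) is rejected at the given alpha.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    # A stochastically larger <=> CDF of A lies below CDF of B
    res = stats.ks_2samp(a, b, alternative="less")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)
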