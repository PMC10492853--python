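"""Static gain-field movement-field model of SC spike counts.

An SC cell's movement field gives the expected number of spikes in the
saccade-related burst as a Gaussian of anatomical distance on the motor
map, multiplicatively modulated by the initial eye-in-head position E0
(the gain field):

    N_STMF(dG, phi, E0) = N0 * (1 + eps*E0)
                          * exp(-((u-u0)^2 + (v-v0)^2) / (2*sigmaP^2))

with (u, v) the complex-log image of the gaze vector, (u0, v0) the field
centre (mm), sigmaP the field extent (mm), N0 the peak count (spikes) and
eps the eye-position sensitivity (fractional modulation per degree).

The five parameters are estimated by unweighted least squares on the
measured burst counts, minimized with the Nelder-Mead simplex from a
data-driven initialization.  Fit quality is summarized by the Pearson
correlation between predicted and measured counts.

Trial-to-trial spike-count variability is modelled as multiplicative
(signal-dependent) plus additive noise:

    N_SPKS = (1 + n_MUL) * N_STMF + n_ADD,
    n_MUL ~ Normal(0, C_V),  n_ADD ~ Normal(0, sigma_ADD),

rounded to the nearest integer and clipped at zero.  The mean-SD
regression (:func:`noise_regression`) characterizes this noise from data:
trials are ordered by predicted count, grouped in sliding bins 2 spikes
wide stepped by 1 spike, and the per-bin SD of the measured counts is
regressed linearly on the per-bin mean — the slope estimates C_V and the
offset the additive floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sc_map import MapParams, afferent_map

__all__ = [
    "MovementFieldParams",
    "NoiseParams",
    "MovementFieldModel",
    "MovementFieldResults",
    "predict_static_count",
    "fit_static_field",
    "sample_spike_count",
    "noise_regression",
]


@dataclass(frozen=True)
class MovementFieldParams:
    """Parameters of the static gain-field movement field."""

    N0: float  # peak spike count (spikes)
    eps: float  # eye-position sensitivity (fractional modulation per deg)
    u0: float  # field centre, rostral-caudal (mm)
    v0: float  # field centre, medial-lateral (mm)
    sigmaP: float  # field extent (mm)

    def __post_init__(self) -> None:
        if not self.N0 > 0:
            raise ValueError("N0 must be positive")
        if not self.sigmaP > 0:
            raise ValueError("sigmaP must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative plus additive spike-count noise."""

    C_V: float = 0.0  # coefficient of variation of the multiplicative term
    sigma_ADD: float = 0.0  # additive noise SD (spikes)

    def __post_init__(self) -> None:
        if self.C_V < 0 or self.sigma_ADD < 0:
            raise ValueError("noise parameters must be nonnegative")


def predict_static_count(dG, phi_deg, E0, mf: MovementFieldParams,
                         map_params: MapParams = MapParams()):
    """Expected burst spike count for gaze shifts (dG, phi) at eye position E0.

    Real-valued; raises if the gain factor (1 + eps*E0) is not positive
    anywhere (a pathological eye-position sensitivity).
    """
    gain = 1.0 + mf.eps * np.asarray(E0, dtype=float)
    if np.any(gain <= 0):
        raise ValueError("gain factor (1 + eps*E0) must be positive")
    u, v = afferent_map(dG, phi_deg, map_params)
    d2 = (np.asarray(u) - mf.u0) ** 2 + (np.asarray(v) - mf.v0) ** 2
    out = mf.N0 * gain * np.exp(-d2 / (2.0 * mf.sigmaP ** 2))
    return float(out) if np.ndim(out) == 0 else out


def sample_spike_count(N_STMF, noise: NoiseParams, rng: np.random.Generator):
    """Draw noisy integer spike counts from the multiplicative-noise model."""
    N_STMF = np.asarray(N_STMF, dtype=float)
    if np.any(N_STMF < 0):
        raise ValueError("expected counts must be nonnegative")
    n_mul = rng.normal(0.0, noise.C_V, size=N_STMF.shape) if noise.C_V > 0 else 0.0
    n_add = rng.normal(0.0, noise.sigma_ADD, size=N_STMF.shape) if noise.sigma_ADD > 0 else 0.0
    n = np.rint((1.0 + n_mul) * N_STMF + n_add)
    n = np.maximum(n, 0.0)
    return int(n) if n.ndim == 0 else n.astype(int)


class MovementFieldModel:
    """Static gain-field movement-field model for one cell.

    Parameters
    ----------
    counts : array_like
        Measured burst spike counts, one per gaze shift.
    dG, phi_deg, E0 : array_like
        Gaze-shift amplitude (deg), direction (deg) and initial eye
        position (deg) per trial.
    map_params : MapParams
        SC map calibration.

    Use :meth:`from_dataframe` to build from an event table with columns
    ``n_spk, dG, phi_deg, E0``.
    """

    def __init__(self, counts, dG, phi_deg, E0,
                 map_params: MapParams = MapParams()):
        self.counts = np.asarray(counts, dtype=float)
        self.dG = np.asarray(dG, dtype=float)
        self.phi_deg = np.asarray(phi_deg, dtype=float)
        self.E0 = np.asarray(E0, dtype=float)
        self.map_params = map_params
        n = len(self.counts)
        if not (len(self.dG) == len(self.phi_deg) == len(self.E0) == n):
            raise ValueError("all inputs must have equal length")
        if n < 10:
            raise ValueError("need at least 10 gaze shifts to fit a movement field")
        self.u, self.v = afferent_map(self.dG, self.phi_deg, map_params)
        if (np.ptp(np.round(self.u, 9)) == 0 and np.ptp(np.round(self.v, 9)) == 0):
            raise ValueError("all gaze vectors identical: movement field unidentifiable")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame,
                       map_params: MapParams = MapParams()) -> "MovementFieldModel":
        return cls(table["n_spk"].to_numpy(), table["dG"].to_numpy(),
                   table["phi_deg"].to_numpy(), table["E0"].to_numpy(),
                   map_params=map_params)

    # -- fitting -----------------------------------------------------------

    def _initial_params(self) -> np.ndarray:
        w = np.maximum(self.counts, 0.0)
        if w.sum() == 0:
            w = np.ones_like(w)
        u0 = float(np.average(self.u, weights=w))
        v0 = float(np.average(self.v, weights=w))
        N0 = float(max(np.percentile(self.counts, 95), 1.0))
        return np.array([N0, 0.0, u0, v0, 0.5])

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        N0, eps, u0, v0, sigmaP = theta
        gain = 1.0 + eps * self.E0
        d2 = (self.u - u0) ** 2 + (self.v - v0) ** 2
        return N0 * gain * np.exp(-d2 / (2.0 * sigmaP ** 2))

    def _sse(self, theta: np.ndarray) -> float:
        if theta[0] <= 0 or theta[4] <= 0:
            return np.inf
        if np.any(1.0 + theta[1] * self.E0 <= 0):
            return np.inf
        r = self.counts - self._predict(theta)
        return float(r @ r)

    def fit(self, start_params=None, maxiter: int = 5000,
            xatol: float = 1e-6, fatol: float = 1e-6) -> "MovementFieldResults":
        """Least-squares fit by the Nelder-Mead simplex.

        Returns a :class:`MovementFieldResults`; non-convergence after
        ``maxiter`` iterations is flagged on the result, not raised.
        """
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self._initial_params()
        res = optimize.minimize(self._sse, x0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": xatol,
                                         "fatol": fatol})
        theta = res.x
        params = MovementFieldParams(N0=float(theta[0]), eps=float(theta[1]),
                                     u0=float(theta[2]), v0=float(theta[3]),
                                     sigmaP=float(abs(theta[4])))
        predicted = self._predict(theta)
        if np.std(predicted) > 0 and np.std(self.counts) > 0:
            r = float(stats.pearsonr(predicted, self.counts).statistic)
        else:
            r = np.nan
        return MovementFieldResults(model=self, params=params, pearson_r=r,
                                    sse=float(res.fun), converged=bool(res.success),
                                    n_iter=int(res.nit))


@dataclass
class MovementFieldResults:
    """Fitted static gain-field movement field."""

    model: MovementFieldModel
    params: MovementFieldParams
    pearson_r: float
    sse: float
    converged: bool
    n_iter: int

    @property
    def nobs(self) -> int:
        return len(self.model.counts)

    @property
    def center_gaze(self):
        """Field centre as a gaze vector (amplitude deg, direction deg)."""
        from .sc_map import efferent_map
        return efferent_map(self.params.u0, self.params.v0, self.model.map_params)

    def predict(self, dG=None, phi_deg=None, E0=None) -> np.ndarray:
        """Predicted counts for new gaze shifts (defaults: the fitted data)."""
        if dG is None:
            dG, phi_deg, E0 = self.model.dG, self.model.phi_deg, self.model.E0
        return predict_static_count(dG, phi_deg, E0, self.params,
                                    self.model.map_params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.counts - self.predict()

    def to_record(self) -> dict:
        """One JSON/CSV-ready record per cell (mirrors a fit-table row)."""
        Rc, Phic = self.center_gaze
        return {
            "N0": self.params.N0, "eps": self.params.eps,
            "u0": self.params.u0, "v0": self.params.v0,
            "sigmaP": self.params.sigmaP,
            "center_amplitude_deg": Rc, "center_direction_deg": Phic,
            "r": self.pearson_r, "n_trials": self.nobs,
            "converged": self.converged,
        }

    def summary(self) -> str:
        p = self.params
        Rc, Phic = self.center_gaze
        lines = [
            "Static gain-field movement field",
            "=" * 48,
            f"Trials:             {self.nobs}",
            f"N0 (peak count):    {p.N0:10.3f} spikes",
            f"eps (gain field):   {p.eps:10.5f} /deg",
            f"u0, v0 (centre):    {p.u0:7.3f}, {p.v0:7.3f} mm",
            f"  as gaze vector:   {Rc:7.2f} deg @ {Phic:6.2f} deg",
            f"sigmaP (extent):    {p.sigmaP:10.3f} mm",
            f"Pearson r (pred vs measured): {self.pearson_r:6.3f}",
            f"Converged:          {self.converged} ({self.n_iter} iterations)",
        ]
        return "\n".join(lines)


def fit_static_field(table: pd.DataFrame,
                     map_params: MapParams = MapParams(),
                     start_params=None):
    """Fit the static gain-field model to an event+count table.

    ``table`` needs columns ``n_spk, dG, phi_deg, E0``.  Returns
    ``(MovementFieldParams, pearson_r)``; use :class:`MovementFieldModel`
    directly for the full results object.
    """
    res = MovementFieldModel.from_dataframe(table, map_params).fit(
        start_params=start_params)
    return res.params, res.pearson_r


def noise_regression(table: pd.DataFrame, mf: MovementFieldParams,
                     map_params: MapParams = MapParams(),
                     bin_width: float = 2.0, step: float = 1.0,
                     min_per_bin: int = 5):
    """Mean-SD regression of measured counts in sliding predicted-count bins.

    Trials are ordered by the model-predicted count; sliding bins
    ``bin_width`` predicted spikes wide, stepped by ``step``, collect the
    measured counts; bins with fewer than ``min_per_bin`` trials are
    dropped.  A line SD = a + b*mean is fitted through the binned points.

    Returns ``(offset_a, slope_b, pearson_r, bins)`` where ``bins`` is a
    DataFrame of the binned means and SDs.
    """
    predicted = predict_static_count(table["dG"].to_numpy(),
                                     table["phi_deg"].to_numpy(),
                                     table["E0"].to_numpy(), mf, map_params)
    measured = table["n_spk"].to_numpy(dtype=float)
    order = np.argsort(predicted)[::-1]
    predicted, measured = predicted[order], measured[order]

    lo_edge = np.floor(predicted.min())
    hi_edge = predicted.max()
    means, sds, centers, counts = [], [], [], []
    start = hi_edge
    while start - bin_width >= lo_edge - step:
        m = (predicted <= start) & (predicted > start - bin_width)
        if m.sum() >= min_per_bin:
            means.append(measured[m].mean())
            sds.append(measured[m].std(ddof=1))
            centers.append(start - bin_width / 2.0)
            counts.append(int(m.sum()))
        start -= step
    if len(means) < 10:
        raise ValueError(
            f"only {len(means)} populated bins (need >= 10) for the mean-SD regression"
        )
    means = np.asarray(means)
    sds = np.asarray(sds)
    fit = stats.linregress(means, sds)
    bins = pd.DataFrame({"bin_center_predicted": centers, "mean": means,
                         "sd": sds, "n": counts})
    return float(fit.intercept), float(fit.slope), float(fit.rvalue), bins
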