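"""Diagnostic figures for fitted movement fields and dynamic analyses.

All functions take an existing ``matplotlib`` Axes (or create one) and
return it, so they compose into multi-panel session reports.
"""

from __future__ import annotations

import numpy as np

from .dynamics import BetaFit, histogram_binwidth
from .movement_field import MovementFieldResults


def plot_movement_field(results: MovementFieldResults, ax=None):
    """Predicted vs measured burst counts with the identity line."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    pred = results.predict()
    ax.plot(pred, results.model.counts, "k.", ms=3, alpha=0.5)
    lim = max(float(np.max(pred)), float(np.max(results.model.counts))) * 1.05
    ax.plot([0, lim], [0, lim], "r-", lw=1)
    ax.set_xlabel("predicted count (spikes)")
    ax.set_ylabel("measured count (spikes)")
    ax.set_title(f"static movement field (r = {results.pearson_r:.2f}, "
                 f"n = {results.nobs})")
    return ax


def plot_correlation_histogram(correlations, null_correlations=None,
                               beta_fit: BetaFit | None = None, ax=None):
    """Histogram of per-trial SD-velocity correlations, optionally with the
    shuffle-null histogram and a fitted beta-family curve."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    r = np.asarray(correlations, float)
    bw = histogram_binwidth(1.5, len(r)) or 0.1
    bins = np.linspace(-0.5, 1.0, max(int(round(1.5 / bw)), 4) + 1)
    ax.hist(r, bins=bins, color="C0", alpha=0.6, label="original")
    if null_correlations is not None:
        ax.hist(np.asarray(null_correlations, float), bins=bins, color="C1",
                alpha=0.5, label="shuffled")
    if beta_fit is not None:
        grid = np.linspace(-0.499, 0.999, 400)
        ax.plot(grid, beta_fit.pdf_shape(grid), "r--", lw=1.5,
                label=f"beta fit (mode {beta_fit.mode_r:.2f})")
    ax.set_xlabel("correlation r")
    ax.set_ylabel("trials")
    ax.legend(frameon=False)
    return ax


def plot_phase_trajectories(trajectories, ax=None, max_trials: int = 50):
    """Cumulative spike count against straight-line displacement, one line
    per trial (the fan of phase trajectories)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for traj in trajectories[:max_trials]:
        ax.plot(traj.dg, traj.ncs, lw=0.7, alpha=0.6)
    ax.set_xlabel("straight-line gaze displacement (deg)")
    ax.set_ylabel("cumulative spike density (spikes)")
    return ax
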