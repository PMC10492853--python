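"""Orchestration of the full analysis chain on one session.

Stages: gaze-shift detection -> burst-spike selection -> static gain-field
fit -> mean-SD noise regression -> phase-trajectory fits -> spike-density
vs gaze-velocity correlations -> shuffle null + one-tailed KS ->
beta-distribution fit -> peak/partial/head-effect regressions.  Stage
failures are reported per stage without aborting independent downstream
stages; all randomness flows from a single seeded generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, kinematics, movement_field, spike_tools
from .sc_map import MapParams
from .synthetic_data import SessionFile

log = logging.getLogger("scgaze")

__all__ = ["AnalysisConfig", "run_full_analysis", "write_report"]


@dataclass
class AnalysisConfig:
    """Selection thresholds and statistical settings of the pipeline.

    Defaults mirror the conventions used throughout the analyses: burst
    window leading the gaze shift by 20 ms, fixed 4-ms Gaussian kernel,
    phase fits for bursts of >= 10 spikes, correlation histograms for
    >= 15 spikes, 1000 bootstrap resamples, KS significance 0.005.
    """

    lead_ms: float = 20.0
    kernel: str = "fixed"  # 'fixed' | 'adaptive'
    sigma_K: float = 4.0
    min_n_spk_phase: int = 10
    min_n_spk_corr: int = 15
    onset_threshold: float = 30.0
    offset_threshold: float = 20.0
    min_duration_ms: float = 15.0
    n_bootstrap: int = 1000
    ks_alpha: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lead_ms", "sigma_K", "min_n_spk_phase", "min_n_spk_corr",
                     "onset_threshold", "offset_threshold", "min_duration_ms",
                     "n_bootstrap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All tables and fit records produced by one pipeline run."""

    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    bursts: pd.DataFrame = field(default_factory=pd.DataFrame)
    mf_fit: dict = field(default_factory=dict)
    noise_fit: dict = field(default_factory=dict)
    phase_fits: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    shuffled_correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    ks: dict = field(default_factory=dict)
    beta_fit: dict = field(default_factory=dict)
    peak_fit: dict = field(default_factory=dict)
    partial_fit: dict = field(default_factory=dict)
    head_fit: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def run_full_analysis(session: SessionFile,
                      config: AnalysisConfig = AnalysisConfig()) -> ReportBundle:
    """Run the full analysis chain on a session; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    bundle = ReportBundle()
    t_start = time.time()

    map_params = (session.config.map_params if session.config is not None
                  else MapParams())

    # --- stage 1: detection + metrics + burst selection -------------------
    events, bursts, profiles, gdots = [], [], [], []
    for trial in session.trials:
        ev = kinematics.largest_gaze_shift(
            trial.gaze_h, trial.gaze_v, t0=float(trial.t[0]),
            onset_threshold=config.onset_threshold,
            offset_threshold=config.offset_threshold,
            min_duration_ms=config.min_duration_ms)
        if ev is None:
            continue
        try:
            ev = kinematics.event_metrics(trial, ev)
        except ValueError:
            continue
        burst = spike_tools.select_burst_spikes(trial.spikes, ev,
                                                lead=config.lead_ms)
        if config.kernel == "adaptive" and burst.n_spk >= 2:
            prof = spike_tools.spike_density_adaptive(burst)
        else:
            prof = spike_tools.spike_density_fixed(burst, sigma=config.sigma_K)
        _, _, gdot = kinematics.straight_line_displacement(
            trial.gaze_h, trial.gaze_v, ev, t0=float(trial.t[0]))
        events.append(ev)
        bursts.append(burst)
        profiles.append(prof)
        gdots.append(gdot)
    log.info("detection: %d/%d trials with a gaze shift",
             len(events), len(session.trials))
    if not events:
        bundle.warnings.append("no detectable gaze shifts")
        return bundle

    bundle.events = pd.DataFrame([{
        "trial_id": ev.trial_id, "onset_ms": ev.onset_ms,
        "offset_ms": ev.offset_ms, "duration_ms": ev.duration,
        "dG": ev.dG, "phi_deg": ev.phi_deg,
        "peak_gaze_velocity": ev.peak_gaze_velocity,
        "peak_velocity_time": ev.peak_velocity_time,
        "head_contribution": ev.head_contribution, "E0": ev.E0,
        "n_spk": b.n_spk,
    } for ev, b in zip(events, bursts)])
    bundle.bursts = pd.DataFrame([{
        "trial_id": ev.trial_id, "n_spk": b.n_spk,
        "window_start_ms": b.window[0], "window_end_ms": b.window[1],
    } for ev, b in zip(events, bursts)])

    # --- stage 2: static movement-field fit -------------------------------
    mf_params = None
    try:
        res = movement_field.MovementFieldModel.from_dataframe(
            bundle.events, map_params).fit()
        mf_params = res.params
        bundle.mf_fit = res.to_record()
    except Exception as exc:  # noqa: BLE001 - reported, not fatal
        bundle.warnings.append(f"static fit failed: {exc}")

    # --- stage 3: noise regression ----------------------------------------
    if mf_params is not None:
        try:
            a, b, r, _bins = movement_field.noise_regression(
                bundle.events, mf_params, map_params)
            bundle.noise_fit = {"offset": a, "slope_CV": b, "r": r}
        except Exception as exc:  # noqa: BLE001
            bundle.warnings.append(f"noise regression failed: {exc}")

    # --- stage 4: phase-trajectory fits -----------------------------------
    phase_rows = []
    if mf_params is not None:
        for ev, burst, prof, trial in zip(events, bursts, profiles,
                                          session.trials):
            if burst.n_spk < config.min_n_spk_phase:
                continue
            t, dg, _ = kinematics.straight_line_displacement(
                trial.gaze_h, trial.gaze_v, ev, t0=float(trial.t[0]))
            ncs = np.interp(t - config.lead_ms, prof.t, prof.csd)
            traj = dynamics.PhaseTrajectory(dg=dg, ncs=ncs, n_spk=burst.n_spk,
                                            event=ev)
            a, b_off, dev = dynamics.phase_fit_and_deviation(traj)
            pred = dynamics.predict_cumulative_count(ev, mf_params, map_params,
                                                     np.array([ev.dG]))[0]
            phase_rows.append({"trial_id": ev.trial_id, "slope": a,
                               "offset": b_off, "dev_sd": dev,
                               "predicted_slope": pred / ev.dG,
                               "n_spk": burst.n_spk})
    bundle.phase_fits = pd.DataFrame(phase_rows)
    if not phase_rows:
        bundle.warnings.append("no trials met the phase-fit spike criterion")

    # --- stage 5: SD-velocity correlations + shuffle null + KS + beta ------
    records = [dynamics.sd_velocity_correlation(prof, gdot, ev,
                                                lead=config.lead_ms,
                                                n_spk=b.n_spk)
               for prof, gdot, ev, b in zip(profiles, gdots, events, bursts)]
    bundle.correlations = _records_to_frame(records)
    strong = [r for r in records if r.valid and r.n_spk >= config.min_n_spk_corr]
    if len(events) >= 2:
        null = dynamics.shuffle_null(profiles, gdots, events, rng,
                                     lead=config.lead_ms)
        bundle.shuffled_correlations = _records_to_frame(null)
        null_strong = [r for r in null
                       if r.valid and r.n_spk >= config.min_n_spk_corr]
        if len(strong) >= 20 and len(null_strong) >= 20:
            ks, p, reject = dynamics.ks_one_tailed(
                [r.r for r in strong], [r.r for r in null_strong],
                alpha=config.ks_alpha)
            bundle.ks = {"ks": ks, "p": p, "reject": reject,
                         "alpha": config.ks_alpha,
                         "n": len(strong), "n_null": len(null_strong)}
        else:
            bundle.warnings.append("too few high-count trials for the KS test")
        try:
            fit = dynamics.fit_beta_distribution([r.r for r in null_strong])
            bundle.beta_fit = {"P0": fit.P0, "alpha": fit.alpha,
                               "beta": fit.beta, "mode_r": fit.mode_r}
        except Exception as exc:  # noqa: BLE001
            bundle.warnings.append(f"beta fit failed: {exc}")

    # --- stage 6: peak / partial / head regressions ------------------------
    if len(strong) >= 20:
        try:
            bundle.peak_fit = dynamics.peak_regressions(
                strong, n_boot=config.n_bootstrap, rng=rng)
            bundle.partial_fit = dynamics.zscore_partial_regression(
                [r.peak_velocity for r in strong],
                [r.peak_sd for r in strong],
                [r.n_spk for r in strong],
                n_boot=config.n_bootstrap, rng=rng)
        except Exception as exc:  # noqa: BLE001
            bundle.warnings.append(f"peak regressions failed: {exc}")
        try:
            bundle.head_fit = dynamics.head_amplitude_effect(
                strong, min_n_spk=config.min_n_spk_corr)
        except Exception as exc:  # noqa: BLE001
            bundle.warnings.append(f"head-effect regression failed: {exc}")
    else:
        bundle.warnings.append("too few high-count trials for peak analyses")

    from . import __version__
    bundle.meta = {"config_hash": config.config_hash,
                   "package_version": __version__,
                   "n_trials": len(session.trials),
                   "n_events": len(events),
                   "elapsed_s": round(time.time() - t_start, 2)}
    log.info("analysis finished in %.1f s (%d warnings)",
             time.time() - t_start, len(bundle.warnings))
    return bundle


def write_report(bundle: ReportBundle, out_dir: str) -> None:
    """Write the report bundle as CSV tables and JSON summaries."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.events.to_csv(out / "events.csv", index=False)
    bundle.bursts.to_csv(out / "bursts.csv", index=False)
    bundle.phase_fits.to_csv(out / "phase_fits.csv", index=False)
    bundle.correlations.to_csv(out / "correlations.csv", index=False)
    bundle.shuffled_correlations.to_csv(out / "shuffled_correlations.csv",
                                        index=False)
    for name in ("mf_fit", "noise_fit", "ks", "beta_fit", "peak_fit",
                 "partial_fit", "head_fit", "meta"):
        with open(out / f"{name}.json", "w") as fh:
            json.dump(getattr(bundle, name), fh, indent=2, default=float)
    with open(out / "warnings.json", "w") as fh:
        json.dump(bundle.warnings, fh, indent=2)
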