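"""Gaze-trace differentiation, gaze-shift detection and kinematic metrics.

Position traces (gaze and head, horizontal and vertical, in degrees) are
sampled at 1 kHz.  Velocities are computed with the two-point central
difference followed by zero-phase FIR low-pass filtering with an 80 Hz
bandwidth (order 50); the zero-phase (forward-backward) application avoids
introducing a group delay that would contaminate the 20-ms lead between SC
activity and the movement.

A gaze shift is detected from the vectorial gaze speed
``sqrt(g_h'^2 + g_v'^2)`` with a conventional two-threshold rule: the
event starts where speed crosses an onset threshold (default 30 deg/s),
is extended outward while speed stays above an offset threshold (default
20 deg/s), and must last a minimum duration (default 15 ms).

The straight-line displacement of an event projects the instantaneous
(possibly curved) gaze trajectory, re-referenced to the onset position,
onto the overall gaze-shift direction Phi = atan2(dG_v, dG_h):

    dg(t) = g_h(t)*cos(Phi) + g_v(t)*sin(Phi)

so that dg(offset) equals the vectorial amplitude dG exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

__all__ = [
    "Trial",
    "GazeShiftEvent",
    "differentiate_trace",
    "detect_gaze_shift",
    "straight_line_displacement",
    "event_metrics",
]


@dataclass
class Trial:
    """One behavioral trial: gaze/head traces, spike times, initial conditions.

    Traces are in degrees on a uniform 1-kHz time grid ``t`` (ms).  Spike
    event times are in ms, sorted ascending, within the trial.  ``E0`` is
    the initial eye-in-head position (deg, positive = deviated toward the
    ipsilateral side of the upcoming gaze shift), ``H0`` the initial head
    position (deg).  The eye-in-head trace is gaze minus head,
    componentwise.
    """

    t: np.ndarray
    gaze_h: np.ndarray
    gaze_v: np.ndarray
    head_h: np.ndarray
    head_v: np.ndarray
    spikes: np.ndarray
    E0: float = 0.0
    H0: float = 0.0
    target: tuple = (0.0, 0.0)
    trial_id: int = 0

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("gaze_h", "gaze_v", "head_h", "head_v"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"Trial: trace {name!r} length != time grid")
        s = np.asarray(self.spikes, dtype=float)
        if s.size and (np.any(np.diff(s) < 0) or s[0] < self.t[0] or s[-1] > self.t[-1]):
            raise ValueError("Trial: spikes must be sorted and within the time grid")

    @property
    def eye_h(self) -> np.ndarray:
        """Eye-in-head horizontal trace (deg): gaze minus head."""
        return self.gaze_h - self.head_h

    @property
    def eye_v(self) -> np.ndarray:
        return self.gaze_v - self.head_v


@dataclass
class GazeShiftEvent:
    """A detected saccadic gaze shift and its kinematic metrics."""

    onset_ms: float
    offset_ms: float
    dG_h: float = np.nan
    dG_v: float = np.nan
    dG: float = np.nan
    phi: float = np.nan  # rad
    peak_gaze_velocity: float = np.nan  # deg/s
    peak_velocity_time: float = np.nan  # ms
    head_contribution: float = np.nan  # deg, projected on phi
    E0: float = 0.0
    trial_id: int = 0

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValueError("GazeShiftEvent: offset must be after onset")

    @property
    def duration(self) -> float:
        """Gaze-shift duration T_DUR (ms)."""
        return self.offset_ms - self.onset_ms

    @property
    def phi_deg(self) -> float:
        return float(np.rad2deg(self.phi))


def differentiate_trace(position, fs: float = 1000.0, cutoff_hz: float = 80.0,
                        order: int = 50) -> np.ndarray:
    """Differentiate a position trace (deg) into velocity (deg/s).

    Two-point central difference (one-sided at the endpoints) followed by
    zero-phase FIR low-pass filtering, 80 Hz cutoff, order 50.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 1:
        raise ValueError("differentiate_trace expects a 1-D trace")
    if len(position) <= order:
        raise ValueError(
            f"trace of length {len(position)} is shorter than the filter order {order}"
        )
    dt = 1.0 / fs
    vel = np.gradient(position, dt)
    taps = signal.firwin(order + 1, cutoff_hz, fs=fs)
    return signal.filtfilt(taps, [1.0], vel)


def _vectorial_speed(gaze_h, gaze_v, fs: float) -> np.ndarray:
    vh = differentiate_trace(gaze_h, fs)
    vv = differentiate_trace(gaze_v, fs)
    return np.hypot(vh, vv)


def detect_gaze_shift(gaze_h, gaze_v, fs: float = 1000.0,
                      onset_threshold: float = 30.0,
                      offset_threshold: float = 20.0,
                      min_duration_ms: float = 15.0,
                      t0: float = 0.0) -> list[GazeShiftEvent]:
    """Detect gaze shifts from the vectorial gaze speed.

    Returns events in time order; empty list if the speed never crosses the
    onset threshold.  Times are in ms relative to ``t0`` (the time of the
    first sample).
    """
    speed = _vectorial_speed(np.asarray(gaze_h, float), np.asarray(gaze_v, float), fs)
    dt_ms = 1000.0 / fs
    above_on = speed >= onset_threshold
    above_off = speed >= offset_threshold
    events: list[GazeShiftEvent] = []
    n = len(speed)
    i = 0
    while i < n:
        if above_on[i]:
            start = i
            while start > 0 and above_off[start - 1]:
                start -= 1
            end = i
            while end < n - 1 and above_off[end + 1]:
                end += 1
            if (end - start) * dt_ms >= min_duration_ms:
                events.append(GazeShiftEvent(onset_ms=t0 + start * dt_ms,
                                             offset_ms=t0 + end * dt_ms))
            i = end + 1
        else:
            i += 1
    return events


def largest_gaze_shift(gaze_h, gaze_v, fs: float = 1000.0,
                       **kwargs) -> Optional[GazeShiftEvent]:
    """Return the largest-amplitude detected gaze shift, or None."""
    events = detect_gaze_shift(gaze_h, gaze_v, fs=fs, **kwargs)
    if not events:
        return None
    gh = np.asarray(gaze_h, float)
    gv = np.asarray(gaze_v, float)
    t0 = kwargs.get("t0", 0.0)

    def _amp(ev):
        i0 = int(round((ev.onset_ms - t0) * fs / 1000.0))
        i1 = int(round((ev.offset_ms - t0) * fs / 1000.0))
        return np.hypot(gh[i1] - gh[i0], gv[i1] - gv[i0])

    return max(events, key=_amp)


def straight_line_displacement(gaze_h, gaze_v, event: GazeShiftEvent,
                               t0: float = 0.0, fs: float = 1000.0):
    """Project the gaze trajectory onto the overall gaze-shift direction.

    Returns ``(t, dg, gdot_lin)``: the time grid of the event (ms), the
    straight-line displacement dg(t) (deg, 0 at onset, dG at offset), and
    its filtered derivative Gdot_lin(t) (deg/s).  The derivative is taken
    on the full-trial projected trace and then windowed, so the low-pass
    filter sees enough context on both sides.
    """
    gh = np.asarray(gaze_h, float)
    gv = np.asarray(gaze_v, float)
    i0 = int(round((event.onset_ms - t0) * fs / 1000.0))
    i1 = int(round((event.offset_ms - t0) * fs / 1000.0))
    if i0 < 0 or i1 >= len(gh):
        raise ValueError("event lies outside the trace")
    dgh = gh[i1] - gh[i0]
    dgv = gv[i1] - gv[i0]
    dG = float(np.hypot(dgh, dgv))
    if dG == 0.0:
        raise ValueError("zero-amplitude gaze shift: direction undefined")
    phi = np.arctan2(dgv, dgh)
    proj_full = (gh - gh[i0]) * np.cos(phi) + (gv - gv[i0]) * np.sin(phi)
    gdot_full = differentiate_trace(proj_full, fs)
    t = np.arange(i0, i1 + 1) * (1000.0 / fs) + t0
    return t, proj_full[i0:i1 + 1], gdot_full[i0:i1 + 1]


def event_metrics(trial: Trial, event: GazeShiftEvent,
                  fs: float = 1000.0,
                  head_contribution_mode: str = "projected") -> GazeShiftEvent:
    """Complete a detected event with amplitude, direction, peak velocity
    and head contribution.

    The head contribution is the head displacement over [onset, offset]
    projected on the gaze-shift direction Phi by default
    (``head_contribution_mode='vectorial'`` uses the unprojected magnitude).
    """
    t0 = float(trial.t[0])
    i0 = int(round((event.onset_ms - t0) * fs / 1000.0))
    i1 = int(round((event.offset_ms - t0) * fs / 1000.0))
    gh, gv = trial.gaze_h, trial.gaze_v
    event.dG_h = float(gh[i1] - gh[i0])
    event.dG_v = float(gv[i1] - gv[i0])
    event.dG = float(np.hypot(event.dG_h, event.dG_v))
    if event.dG == 0.0:
        raise ValueError("zero-amplitude gaze shift")
    event.phi = float(np.arctan2(event.dG_v, event.dG_h))

    speed = _vectorial_speed(gh, gv, fs)[i0:i1 + 1]
    ipk = int(np.argmax(speed))  # argmax -> earliest sample on ties
    event.peak_gaze_velocity = float(speed[ipk])
    event.peak_velocity_time = event.onset_ms + ipk * (1000.0 / fs)

    dhh = float(trial.head_h[i1] - trial.head_h[i0])
    dhv = float(trial.head_v[i1] - trial.head_v[i0])
    if head_contribution_mode == "projected":
        event.head_contribution = dhh * np.cos(event.phi) + dhv * np.sin(event.phi)
    elif head_contribution_mode == "vectorial":
        event.head_contribution = float(np.hypot(dhh, dhv))
    else:
        raise ValueError(f"unknown head_contribution_mode {head_contribution_mode!r}")
    event.E0 = trial.E0
    event.trial_id = trial.trial_id
    return event
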