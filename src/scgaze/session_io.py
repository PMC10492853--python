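"""HDF5 session storage.

Layout (version 1):

    /                       attrs: format_version, package_version
    /config                 attrs: serialized generator config (YAML), seed
    /cell                   attrs: N0, eps, u0, v0, sigmaP (movement field)
    /trials/NNNNNN/         attrs: E0, H0, target_h, target_v, trial_id
        t, gaze_h, gaze_v, head_h, head_v   float64 datasets (deg, 1 kHz)
        spikes                               float64 dataset (ms)

Traces round-trip losslessly as float64.  Files without /config load with
a warning and ``session.config = None``.
"""

from __future__ import annotations

import dataclasses
import warnings

import h5py
import numpy as np
import yaml

from .kinematics import Trial
from .movement_field import MovementFieldParams, NoiseParams
from .sc_map import MapParams

FORMAT_VERSION = 1

__all__ = ["read_session", "write_session", "FORMAT_VERSION"]


def _config_to_yaml(config) -> str:
    from .synthetic_data import SimConfig  # local import to avoid cycle
    d = dataclasses.asdict(config)
    return yaml.safe_dump(d)


def _config_from_yaml(text: str):
    from .synthetic_data import SimConfig, KinematicsConfig
    d = yaml.safe_load(text)
    d["mf"] = MovementFieldParams(**d["mf"])
    d["noise"] = NoiseParams(**d["noise"])
    d["map_params"] = MapParams(**d["map_params"])
    d["kinematics"] = KinematicsConfig(**d["kinematics"])
    d["E0_levels"] = tuple(d["E0_levels"])
    return SimConfig(**d)


def write_session(session, path: str) -> None:
    """Write a SessionFile to HDF5 (documented, versioned layout)."""
    from . import __version__
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["package_version"] = __version__
        if session.config is not None:
            g = f.create_group("config")
            g.attrs["yaml"] = _config_to_yaml(session.config)
            g.attrs["seed"] = int(session.config.seed)
        c = f.create_group("cell")
        for k, v in dataclasses.asdict(session.mf).items():
            c.attrs[k] = float(v)
        tg = f.create_group("trials")
        for trial in session.trials:
            g = tg.create_group(f"{trial.trial_id:06d}")
            for name in ("t", "gaze_h", "gaze_v", "head_h", "head_v", "spikes"):
                g.create_dataset(name, data=np.asarray(getattr(trial, name),
                                                       dtype=np.float64))
            g.attrs["E0"] = float(trial.E0)
            g.attrs["H0"] = float(trial.H0)
            g.attrs["target_h"] = float(trial.target[0])
            g.attrs["target_v"] = float(trial.target[1])
            g.attrs["trial_id"] = int(trial.trial_id)


def read_session(path: str):
    """Read a session written by :func:`write_session`.

    Raises a descriptive error naming the first missing group/dataset.
    """
    from .synthetic_data import SessionFile
    with h5py.File(path, "r") as f:
        for group in ("cell", "trials"):
            if group not in f:
                raise KeyError(f"corrupt session file: missing group '/{group}'")
        if "config" in f:
            config = _config_from_yaml(f["config"].attrs["yaml"])
        else:
            warnings.warn("legacy session layout without /config; "
                          "generator config unknown")
            config = None
        mf = MovementFieldParams(**{k: float(v)
                                    for k, v in f["cell"].attrs.items()})
        trials = []
        for key in sorted(f["trials"]):
            g = f["trials"][key]
            for name in ("t", "gaze_h", "gaze_v", "head_h", "head_v", "spikes"):
                if name not in g:
                    raise KeyError(
                        f"corrupt session file: missing dataset "
                        f"'/trials/{key}/{name}'")
            trials.append(Trial(
                t=g["t"][()], gaze_h=g["gaze_h"][()], gaze_v=g["gaze_v"][()],
                head_h=g["head_h"][()], head_v=g["head_v"][()],
                spikes=g["spikes"][()],
                E0=float(g.attrs["E0"]), H0=float(g.attrs["H0"]),
                target=(float(g.attrs["target_h"]), float(g.attrs["target_v"])),
                trial_id=int(g.attrs["trial_id"])))
    return SessionFile(trials=trials, mf=mf, config=config)
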