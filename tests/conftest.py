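import numpy as np
import pandas as pd
import pytest

from scgaze import kinematics, spike_tools
from scgaze.synthetic_data import SimConfig, generate_session


def analyze_events(session, lead: float = 20.0) -> pd.DataFrame:
    """Detect gaze shifts and count burst spikes for every trial."""
    rows = []
    for tr in session.trials:
        ev = kinematics.largest_gaze_shift(tr.gaze_h, tr.gaze_v, t0=float(tr.t[0]))
        if ev is None:
            continue
        ev = kinematics.event_metrics(tr, ev)
        burst = spike_tools.select_burst_spikes(tr.spikes, ev, lead=lead)
        rows.append({"n_spk": burst.n_spk, "dG": ev.dG, "phi_deg": ev.phi_deg,
                     "E0": ev.E0, "event": ev, "burst": burst, "trial": tr})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_session():
    """A 120-trial synthetic session under the default study conditions."""
    return generate_session(SimConfig(n_trials=120, seed=11))


@pytest.fixture(scope="session")
def small_events(small_session):
    return analyze_events(small_session)
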