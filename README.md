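# scgaze

Ensemble-coding analysis of superior-colliculus (SC) single-unit activity
during saccadic eye–head gaze shifts.

## The problem

The midbrain SC contains a topographic motor map for rapid gaze shifts:
where a recruited population sits on the map encodes the amplitude and
direction of the upcoming movement. A long-standing question is whether the
*firing-rate dynamics* of these neurons also encode the movement's detailed
kinematics. Under the linear ensemble-coding hypothesis, each spike of each
recruited cell contributes a fixed "mini" gaze vector determined by its map
location, so the desired trajectory is the running sum of all population
spike vectors, and for tightly synchronized bursts the cumulative spike
count of any single cell grows linearly with the instantaneous gaze
displacement along the straight line to the goal.

This package implements the complete single-unit analysis chain for that
hypothesis, and a forward simulator of the model that generates complete
synthetic recording sessions (gaze/head traces at 1 kHz, spike trains,
initial conditions) on which every stage is validated end to end. It is
aimed at sensorimotor neurophysiologists who want to run, extend, or
stress-test these analyses without access to the original recordings.

## The model

**SC motor map.** A gaze vector (ΔG, Φ) maps to anatomical coordinates
(u, v) in mm by the complex-logarithmic afferent map

    u = B_u · ln( √(ΔG² + 2·A·ΔG·cosΦ + A²) / A )
    v = B_v · atan2( ΔG·sinΦ, ΔG·cosΦ + A )

with B_u = 1.4 mm, B_v = 1.8 mm/rad, A = 3.0 deg. The analytic inverse
(efferent map) assigns each recorded site its mini spike-vector.

**Static gain-field movement field.** The expected number of burst spikes
for a gaze shift at initial eye-in-head position E₀ is

    N_STMF(ΔG, Φ, E₀) = N₀ · (1 + ε·E₀) · exp( −((u−u₀)² + (v−v₀)²) / 2σ_P² )

fitted by Nelder–Mead least squares over [N₀, ε, u₀, v₀, σ_P].

**Dynamics.** With a fixed 20-ms neural lead ΔT, the cumulative spike
count obeys n_CS(t−ΔT) = (N_STMF/ΔG)·Δg(t), where Δg(t) is the projection
of the instantaneous gaze trajectory onto the overall movement direction;
differentiating, the spike density SD(t−ΔT) covaries with straight-line
gaze velocity. Per-trial correlations are compared against a shuffle null
(velocity profiles randomly re-paired across trials) with a one-tailed
two-sample KS test, and correlation histograms are summarized by
P(r) = P₀·(r+0.5)^α·(1−r)^β on (−0.5, 1).

**Noise.** Trial-to-trial count variability is multiplicative:
N_SPKS = (1+n_MUL)·N_STMF + n_ADD with n_MUL ~ N(0, C_V); the mean–SD
regression in sliding 2-spike bins recovers C_V as its slope.

## Worked example

```python
from scgaze.synthetic_data import SimConfig, generate_session
from scgaze.pipeline import AnalysisConfig, run_full_analysis
from scgaze.movement_field import MovementFieldModel

session = generate_session(SimConfig(n_trials=300, seed=42))
bundle = run_full_analysis(session, AnalysisConfig(seed=42))
res = MovementFieldModel.from_dataframe(bundle.events,
                                        session.config.map_params).fit()
print(res.summary())
```

prints

```
Static gain-field movement field
================================================
Trials:             300
N0 (peak count):        25.178 spikes
eps (gain field):      0.00289 /deg
u0, v0 (centre):      3.603,   0.670 mm
  as gaze vector:     36.56 deg @  23.02 deg
sigmaP (extent):         0.597 mm
Pearson r (pred vs measured):  0.965
Converged:          True (245 iterations)
```

The generator planted N₀ = 25 spikes, ε = 0.003/deg, a field centre at
(36.0°, 23.3°) and σ_P = 0.6 mm with C_V = 0.15 multiplicative noise — all
recovered from the synthetic session alone. The same run yields the
mean–SD noise regression (slope 0.142, offset 0.30 spikes, r = 0.96),
near-linear phase trajectories (median deviation 0.16 spikes), a median
spike-density/velocity correlation of 0.97 for trials with ≥ 15 spikes,
and a one-tailed KS rejection of the shuffle null at p < 10⁻³⁴.

A CLI wraps the same chain:

```
sc-gaze simulate --seed 7 --n-trials 300 --out session.h5
sc-gaze analyze session.h5 --seed 7 --out report/
```

## Layout

| module | contents |
| --- | --- |
| `scgaze.sc_map` | complex-log afferent/efferent map |
| `scgaze.kinematics` | trace differentiation, gaze-shift detection, straight-line projection |
| `scgaze.spike_tools` | burst selection, fixed/adaptive kernel spike densities, ISI rates |
| `scgaze.movement_field` | gain-field model, Nelder–Mead fit, noise sampling & regression |
| `scgaze.dynamics` | phase trajectories, SD–velocity correlations, shuffle null, beta fit, peak/partial/head regressions |
| `scgaze.synthetic_data` | forward simulator: kinematics, population spikes, decoder, plant, sessions |
| `scgaze.session_io`, `scgaze.pipeline`, `scgaze.cli` | HDF5 storage, orchestration, CLI |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
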