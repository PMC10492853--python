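# Methods

This note documents the models implemented in `scgaze`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that shape the results.

## The motor map and its inverse

The afferent map writes the gaze vector as a complex number
z = ΔG·e^{iΦ} and applies u + i·(B_u/B_v)·v = B_u·log((z + A)/A), with
B_u = 1.4 mm, B_v = 1.8 mm/rad, A = 3.0 deg (classic microstimulation
calibration of the primate SC). The efferent (inverse) map is therefore
exact in closed form, z = A·exp(u/B_u + i·v/B_v) − A, and the round trip
is machine-precision; tests enforce 1e-9 over a dense grid. Directions are
handled in degrees at the API surface and radians internally. The
direction term uses the two-argument arctangent so quadrants survive
beyond ±90°, but the calibration was derived for the contralateral
hemifield; analyses here stay within |Φ| ≤ 80°, matching the range over
which movement fields are typically recorded.

## Kinematic processing

Velocities come from a two-point central difference followed by an 80-Hz
FIR low-pass of order 50 (the standard acquisition chain for 1-kHz coil
data). The filter is applied forward–backward (zero phase): a causal
application would delay the velocity trace by ~25 ms and corrupt the
20-ms lead between SC activity and the movement, which several analyses
depend on.

Gaze shifts are detected on the vectorial gaze speed with a two-threshold
rule — onset at 30 deg/s, extension while above 20 deg/s, minimum
duration 15 ms. These are conventional saccade-detection values; they are
configurable because no single setting suits all noise levels. Detection
is invariant to constant position offsets by construction.

The straight-line displacement Δg(t) projects the (possibly curved)
trajectory, re-referenced to the onset position, onto the overall
direction Φ = atan2(ΔG_V, ΔG_H); its endpoint equals the vectorial
amplitude exactly, and for curved paths it is bounded above by the
vectorial path length. The head contribution ΔH is the head displacement
over the gaze-shift interval projected on Φ (a vectorial option exists;
projected is the default because the quantity enters regressions against
movement-direction-aligned variables).

## Spike tools

Burst spikes are those in [onset − 20 ms, offset − 20 ms]: a window of
movement duration shifted by the efferent lead, discarding prelude and
post-saccadic activity. Spike densities are sums of unit-area Gaussian
kernels, fixed σ_K = 4 ms by default, or adaptive with σ_K(i) equal to
the local inter-spike interval clipped below at 1 ms (the final spike
reuses the preceding interval — the trailing interval does not exist and
the preceding one is the best local bandwidth estimate). Kernels are not
truncated at window edges; densities are evaluated on a grid extended by
six kernel widths so the cumulative density reaches exactly N_spk. This
preserves mass at the cost of attributing a little density outside the
window; the alternative (renormalizing truncated kernels) distorts the
density shape near the edges that the phase analysis uses. The grid step
is 1 ms, matching acquisition. No optimal-bandwidth selection is
attempted.

## Movement-field fitting

The five-parameter gain-field model is fitted by unweighted least squares
with Nelder–Mead. Initialization is data-driven: (u₀, v₀) from the
count-weighted centroid of the mapped gaze vectors, N₀ from the 95th
percentile count, σ_P = 0.5 mm, ε = 0. Counts are integers but the model
is continuous; residuals are taken against the raw counts without
variance weighting. Fits require ≥ 10 events and non-degenerate vector
spread; non-convergence is flagged on the results object rather than
raised. Goodness of fit is the Pearson correlation between predicted and
measured counts. σ_P is isotropic in (u, v).

The mean–SD noise regression orders trials by predicted count and slides
bins 2 predicted spikes wide in 1-spike steps; bins with fewer than 5
trials are dropped (SD estimates from < 5 counts are too unstable to
regress on), and ≥ 10 populated bins are required. The slope estimates
C_V, the intercept the additive floor. On conditioned synthetic sessions
the slope shows a small (~0.01–0.02) downward bias from integer rounding
and the binning itself; this sits well within the ±0.04 recovery
tolerance used in validation.

## Dynamic analyses

Phase trajectories pair Δg(t) with the smoothed cumulative spike density
shifted by ΔT = 20 ms, fitted by ordinary least squares; the deviation SD
quantifies straightness. Predicted slopes are α = N_STMF/ΔG. Trials need
≥ 10 spikes for phase fits and ≥ 15 for correlation histograms (fewer
spikes make the density estimate unreliable); both thresholds are
configurable.

The per-trial correlation is Pearson's r between SD(t−ΔT) and the
straight-line velocity over [onset, offset] at 1 kHz. ΔT is fixed at
20 ms for all cells and trials — it is not optimized per cell, and no
extra smoothing is applied to the density before correlating. The
shuffle null permutes the assignment of velocity profiles to spike
trials across the whole session (self-pairings allowed — excluding them
biases small sessions); each re-paired correlation is computed over the
interval set by the pairing, truncating both signals to the shorter
duration. A time-warping alternative (`mode="resample"`) is provided.
Distribution shift is tested with a one-tailed two-sample KS test at
α = 0.005 (A "higher" than B ⇔ CDF_A below CDF_B).

Correlation histograms use bin width BW = range/√N and are summarized by
P(r) = P₀·(r+0.5)^α·(1−r)^β, fitted by least squares to the binned
densities; a maximum-likelihood option uses
the equivalence r = −0.5 + 1.5·X with X ~ Beta(α+1, β+1). The analytic
mode (α − 0.5β)/(α + β) is verified against the numerical argmax.

Peak analyses regress peak spike density and spike count on peak gaze
velocity (bootstrap CIs, 1000 resamples) and report the mean timing
difference between density and velocity peaks. The eye-position
confound is dissociated with a no-intercept multiple regression on
z-scores. Cluster selection groups gaze-shift endpoints in 2×2-deg bins
within 10° of the field centre, keeping bins with ≥ 3 events.

## The synthetic-data generator

The generator emulates the study conditions: E₀ ∈ {−15, 0, +15} deg with
the head initially deviated oppositely (initial gaze straight ahead);
sessions of several hundred trials; a recorded cell with N₀ = 25 spikes,
ε = 0.003/deg, field centre (36.0°, 23.3°), σ_P = 0.6 mm; multiplicative
count noise C_V = 0.15 (0.20 in noise-recovery checks); burst gain
B = 70 s⁻¹ and lead ΔT = 20 ms, chosen inside the ranges over which the
downstream model is characterized (50–80 s⁻¹, 12–20 ms).

Velocity profiles are Beta densities on the normalized movement time
whose area equals ΔG exactly. Their shape and duration depend on E₀:
durations follow T = (45 + 1.8·ΔG + 1.5·max(0, ΔG−35)) ms scaled by
(1 + 0.014·E₀) and lognormal jitter (σ = 0.08); profile peaks sit at
normalized time 0.32 + 0.007·E₀ with concentration 4 − 0.04·E₀. These
constants were set so that 50-deg movements span roughly 470 (ipsi) to
950 deg/s (contra) with the peak-velocity decline above ~35 deg where the
head takes over — the qualitative phenomenology of head-unrestrained
primate gaze shifts. The head contribution is a phenomenological ramp,
ΔH = max(0, 0.6·(ΔG + E₀ − 20)), with onset delayed by 30 − 1.5·E₀ ms
(earlier for ipsilateral eye positions); there is no head plant, no
vestibulo-ocular gain modulation, and no oculomotor-range saturation
dynamics.

The recorded cell's spikes are generated in one of three modes.
`conditioned` (default): the count is drawn from the multiplicative-noise
model and spike times are placed by stratified sampling of the
normalized displacement profile — one spike per quantile stratum with
within-stratum jitter. This makes the session's count statistics exactly
the multiplicative model (an unconditioned Poisson process would add a
√mean term and the session would no longer embody SD ≈ C_V·mean) while
keeping burst profiles tightly locked to the kinematics, as the
synchronized-population assumption implies. `poisson`: an inhomogeneous
Poisson process on the scaled velocity envelope with a shared per-trial
multiplicative factor (used for the population/decoder pathway, where
super-Poisson count statistics across trials are the point).
`quantile`: deterministic placement at envelope quantiles — the
noiseless-envelope limit used to validate phase-trajectory linearity.

The decoder places a square grid of ~225 cells spanning ±2.5 population
widths (σ_pop = 0.5 mm) around the target's map image, draws independent
Poisson trains from the shared envelope, and sums each spike's efferent
gaze vector divided by a calibration constant η fixed once per
configuration (the expected vector-sum amplitude over target amplitude
for the centred target). Because the map is near-exponential away from
the fovea, the convexity correction of the vector sum is nearly
site-independent, so a single scalar η conserves endpoints within a few
percent across nearby targets. The downstream plant integrates
v̇ = B·(c − v(t−ΔT)) by explicit 1-ms Euler stepping (stable for
B·ΔT < π/2) with a 3-s settle horizon so the delay-loop ringing decays
before endpoints are read.

**What the generator does not emulate**, and hence what passing tests do
not show about real recordings: no curvature of gaze trajectories (the
simulated path is straight, so Δg(t) equals the vectorial displacement);
no prelude or post-saccadic spiking; no multi-peaked or irregular
velocity profiles beyond the E₀ family; no recording artifacts, sorting
errors, or non-stationarity across a session; head kinematics are a
ramp, not dynamics. Parameter-recovery results demonstrate internal
consistency of model + fitter, not that real cells follow the model.

## Validation problem sizes

Session-level checks use 500–750 trials per session (the scale of a good
single-cell recording); Monte-Carlo recoveries use 20 seeds; decoder
conservation uses 100 trials; beta-fit recovery uses 3000 draws. The
full suite and the acceptance script each run in well under five
minutes on one CPU.

## Known limitations

- The gain field cannot distinguish eye-position from head-position
  modulation: the paradigm varies both symmetrically.
- The beta-family fit can run into its parameter bounds on strongly
  concentrated correlation histograms (the least-squares surface is flat
  in α, β there); the histogram and bin edges are always reported so the
  fit can be judged.
- The detection offset criterion ends events where speed falls below
  20 deg/s, slightly before flat-tailed profiles actually stop; burst
  windows inherit this convention.
- `noise_regression` requires a fitted movement field; with < 10
  populated bins (small or narrow sessions) it raises rather than
  extrapolating.
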