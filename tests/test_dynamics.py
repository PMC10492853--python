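import numpy as np
import pytest
from scipy import stats

from scgaze import dynamics
from scgaze.dynamics import (BetaFit, CorrelationRecord, PhaseTrajectory,
                             cluster_gaze_shifts, fit_beta_distribution,
                             head_amplitude_effect, histogram_binwidth,
                             ks_one_tailed, peak_regressions,
                             phase_fit_and_deviation, predict_cumulative_count,
                             sample_beta_correlations, sd_velocity_correlation,
                             shuffle_null, zscore_partial_regression)
from scgaze.kinematics import GazeShiftEvent
from scgaze.movement_field import MovementFieldParams
from scgaze.sc_map import MapParams, afferent_map
from scgaze.spike_tools import DensityProfile


def _event(dG=50.0, phi_deg=0.0, E0=0.0, onset=0.0, dur=150.0, trial_id=0):
    ev = GazeShiftEvent(onset_ms=onset, offset_ms=onset + dur)
    ev.dG = dG
    ev.dG_h = dG * np.cos(np.deg2rad(phi_deg))
    ev.dG_v = dG * np.sin(np.deg2rad(phi_deg))
    ev.phi = float(np.deg2rad(phi_deg))
    ev.E0 = E0
    ev.trial_id = trial_id
    return ev


def _profile_from_sd(t, sd):
    csd = np.concatenate([[0.0], np.cumsum(0.5 * (sd[1:] + sd[:-1]))])
    return DensityProfile(t=t, sd=sd, csd=csd, method="fixed",
                          sigma_K=np.array([4.0]))


class TestPredictCumulativeCount:
    def test_linearity_and_endpoint(self):
        u0, v0 = afferent_map(50.0, 0.0)
        mf = MovementFieldParams(N0=20.0, eps=0.0, u0=u0, v0=v0, sigmaP=0.6)
        ev = _event(dG=50.0)
        dg = np.linspace(0, 50, 151)
        ncs = predict_cumulative_count(ev, mf, MapParams(), dg)
        assert ncs[-1] == pytest.approx(20.0)  # endpoint = N_STMF
        assert ncs[75] == pytest.approx(ncs[-1] * dg[75] / 50.0)
        # slope alpha = N_STMF / dG = 0.4 spikes/deg
        assert (ncs[1] - ncs[0]) / (dg[1] - dg[0]) == pytest.approx(0.4)

    def test_zero_amplitude_rejected(self):
        u0, v0 = afferent_map(50.0, 0.0)
        mf = MovementFieldParams(N0=20.0, eps=0.0, u0=u0, v0=v0, sigmaP=0.6)
        ev = _event(dG=50.0)
        ev.dG = 0.0
        with pytest.raises(ValueError):
            predict_cumulative_count(ev, mf, MapParams(), np.zeros(10))


class TestPhaseFit:
    def test_exact_line_recovered(self):
        dg = np.linspace(0, 50, 200)
        traj = PhaseTrajectory(dg=dg, ncs=0.4 * dg, n_spk=20)
        a, b, dev = phase_fit_and_deviation(traj)
        assert a == pytest.approx(0.4)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert dev == pytest.approx(0.0, abs=1e-12)

    def test_constant_displacement_rejected(self):
        traj = PhaseTrajectory(dg=np.full(50, 5.0), ncs=np.arange(50.0),
                               n_spk=20)
        with pytest.raises(ValueError):
            phase_fit_and_deviation(traj)


class TestSdVelocityCorrelation:
    def test_proportional_signals_give_unit_correlation(self):
        t_move = np.arange(0.0, 150.0)
        gdot = stats.beta.pdf(t_move / 150.0, 2, 3) * 400
        t_sd = t_move - 20.0
        prof = _profile_from_sd(t_sd, gdot * 0.01)
        rec = sd_velocity_correlation(prof, gdot, _event(dur=149.0))
        assert rec.r == pytest.approx(1.0, abs=1e-9)
        assert rec.peak_sd_time - rec.peak_velocity_time == pytest.approx(-20.0)

    def test_time_reversed_profile_decorrelates(self):
        t_move = np.arange(0.0, 150.0)
        gdot = stats.beta.pdf(t_move / 150.0, 2, 5) * 400  # skewed
        prof = _profile_from_sd(t_move - 20.0, gdot[::-1] * 0.01)
        rec = sd_velocity_correlation(prof, gdot, _event(dur=149.0))
        assert rec.r < 0.9

    def test_zero_variance_flagged(self):
        t_move = np.arange(0.0, 100.0)
        prof = _profile_from_sd(t_move - 20.0, np.zeros(100))
        rec = sd_velocity_correlation(prof, np.ones(100), _event(dur=99.0))
        assert not rec.valid


class TestShuffleNull:
    def _session(self, n, rng, vary=True):
        profs, gdots, events = [], [], []
        for i in range(n):
            dur = 100 + (rng.integers(0, 120) if vary else 0)
            t_move = np.arange(0.0, float(dur))
            shape_b = 2 + 3 * rng.random() if vary else 3.0
            gdot = stats.beta.pdf(t_move / dur, 2, shape_b) * 300
            profs.append(_profile_from_sd(t_move - 20.0, gdot * 0.01))
            gdots.append(gdot)
            events.append(_event(dur=float(dur) - 1, trial_id=i))
        return profs, gdots, events

    def test_shuffling_preserves_velocity_multiset(self):
        rng = np.random.default_rng(0)
        profs, gdots, events = self._session(12, rng)
        recs = shuffle_null(profs, gdots, events, rng)
        assert len(recs) == 12

    def test_identical_profiles_leave_distribution_unchanged(self):
        rng = np.random.default_rng(1)
        profs, gdots, events = self._session(10, rng, vary=False)
        orig = [sd_velocity_correlation(p, g, e).r
                for p, g, e in zip(profs, gdots, events)]
        null = [r.r for r in shuffle_null(profs, gdots, events, rng)]
        assert np.allclose(sorted(orig), sorted(null), atol=1e-9)

    def test_variable_kinematics_shift_null_left(self):
        rng = np.random.default_rng(2)
        profs, gdots, events = self._session(300, rng, vary=True)
        orig = [sd_velocity_correlation(p, g, e).r
                for p, g, e in zip(profs, gdots, events)]
        null = [r.r for r in shuffle_null(profs, gdots, events, rng)]
        ks, p, reject = ks_one_tailed(orig, null)
        assert reject

    def test_resample_mode_runs(self):
        rng = np.random.default_rng(3)
        profs, gdots, events = self._session(8, rng)
        recs = shuffle_null(profs, gdots, events, rng, mode="resample")
        assert all(np.isfinite(r.r) for r in recs if r.valid)


class TestBetaFit:
    def test_symmetric_exponents_mode_at_quarter(self):
        fit = BetaFit(P0=1.0, alpha=1.3, beta=1.3)
        assert fit.mode_r == pytest.approx(0.25)

    def test_printed_parameter_mode(self):
        """alpha = 1.71, beta = 0.70 put the mode at 1.36/2.41 ~ 0.564."""
        fit = BetaFit(P0=131.1, alpha=1.71, beta=0.70)
        assert fit.mode_r == pytest.approx(1.36 / 2.41, abs=1e-6)
        assert fit.mode_r == pytest.approx(0.564, abs=5e-4)

    def test_analytic_mode_matches_numeric_argmax(self):
        rng = np.random.default_rng(4)
        r = sample_beta_correlations(1.71, 0.70, 3000, rng)
        fit = fit_beta_distribution(r)
        grid = np.linspace(-0.499, 0.999, 3000)
        numeric = grid[np.argmax(fit.pdf_shape(grid))]
        assert fit.mode_r == pytest.approx(numeric, abs=1e-3)

    def test_generate_and_refit_recovers_exponents(self):
        rng = np.random.default_rng(5)
        r = sample_beta_correlations(1.71, 0.70, 3000, rng)
        fit = fit_beta_distribution(r)
        assert fit.alpha == pytest.approx(1.71, rel=0.10)
        assert fit.beta == pytest.approx(0.70, rel=0.10)

    def test_out_of_support_values_excluded(self):
        rng = np.random.default_rng(6)
        r = np.concatenate([sample_beta_correlations(2.0, 1.0, 200, rng),
                            [-0.7, 1.2]])
        with pytest.warns(UserWarning):
            fit_beta_distribution(r)

    def test_mle_option(self):
        rng = np.random.default_rng(7)
        r = sample_beta_correlations(1.71, 0.70, 3000, rng)
        fit = fit_beta_distribution(r, method="mle")
        assert fit.alpha == pytest.approx(1.71, rel=0.15)
        assert fit.beta == pytest.approx(0.70, rel=0.15)


class TestHistogramBinwidth:
    def test_formula(self):
        assert histogram_binwidth(1.5, 100) == pytest.approx(0.15)

    def test_single_point_gives_full_range(self):
        assert histogram_binwidth(2.0, 1) == pytest.approx(2.0)

    def test_degenerate_range(self):
        assert histogram_binwidth(0.0, 50) == 0.0


class TestKsOneTailed:
    def test_identical_samples_not_rejected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 500)
        _, p, reject = ks_one_tailed(a, a.copy())
        assert not reject

    def test_shifted_sample_rejected(self):
        rng = np.random.default_rng(9)
        b = rng.normal(0, 1, 500)
        _, p, reject = ks_one_tailed(b + 0.3, b)
        assert reject and p < 0.005

    def test_directionality(self):
        """Testing 'A higher' must not reject when A is shifted BELOW B."""
        rng = np.random.default_rng(10)
        b = rng.normal(0, 1, 500)
        _, _, reject = ks_one_tailed(b - 0.5, b)
        assert not reject

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_one_tailed([], [1.0])


class TestClusterGazeShifts:
    def test_identical_endpoints_form_one_cluster(self):
        events = [_event(dG=40.0, phi_deg=10.0, trial_id=i) for i in range(6)]
        clusters = cluster_gaze_shifts(events, 40.0, 10.0)
        assert len(clusters) == 1 and len(clusters[0]) == 6

    def test_spread_endpoints_form_no_cluster(self):
        events = [_event(dG=30.0 + 3 * i, phi_deg=0.0, trial_id=i)
                  for i in range(4)]
        assert cluster_gaze_shifts(events, 33.0, 0.0) == []

    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(11)
        cx = 36.0 * np.cos(np.deg2rad(20.0))
        cy = 36.0 * np.sin(np.deg2rad(20.0))
        # plant 7 clusters, each inside its own 2x2 deg bin around the centre
        bins = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-2, 0)]
        events = []
        for bx, by in bins:
            for _ in range(int(rng.integers(4, 6))):
                ev = _event(dG=36.0, phi_deg=20.0)
                ev.dG_h = cx + 2.0 * bx + rng.uniform(0.1, 1.9)
                ev.dG_v = cy + 2.0 * by + rng.uniform(0.1, 1.9)
                events.append(ev)
        clusters = cluster_gaze_shifts(events, 36.0, 20.0, radius_deg=10.0)
        assert len(clusters) == 7
        assert all(4 <= len(c) <= 5 for c in clusters)


def _records(n, rng, lead=20.0, sd_coupling=True):
    recs = []
    for i in range(n):
        vpk = rng.uniform(300, 900)
        fpk = (0.5 * vpk if sd_coupling else 400.0) + rng.normal(0, 20)
        recs.append(CorrelationRecord(
            trial_id=i, r=float(rng.uniform(0.6, 0.95)), n_spk=20,
            peak_sd=fpk, peak_sd_time=100.0 - lead,
            peak_velocity=vpk, peak_velocity_time=100.0,
            head_contribution=rng.uniform(0, 30), E0=0.0))
    return recs


class TestPeakRegressions:
    def test_coupled_sd_uncoupled_count(self):
        rng = np.random.default_rng(12)
        recs = _records(80, rng)
        out = peak_regressions(recs, n_boot=200, rng=rng)
        assert out["peak_sd_vs_velocity"]["slope"] == pytest.approx(0.5, abs=0.05)
        assert abs(out["n_spk_vs_velocity"]["slope"]) < 0.005

    def test_planted_uniform_lead(self):
        rng = np.random.default_rng(13)
        out = peak_regressions(_records(40, rng), n_boot=100, rng=rng)
        assert out["mean_timing_lead_ms"] == pytest.approx(-20.0)

    def test_too_few_records_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError):
            peak_regressions(_records(5, rng), n_boot=10, rng=rng)


class TestZscorePartialRegression:
    def test_exact_predictor(self):
        rng = np.random.default_rng(15)
        F = rng.normal(0, 1, 200)
        N = rng.normal(0, 1, 200)
        out = zscore_partial_regression(F, F, N, n_boot=200, rng=rng)
        assert out["p_SD"] == pytest.approx(1.0, abs=1e-9)
        assert out["p_NS"] == pytest.approx(0.0, abs=0.05)

    def test_planted_coefficients_recovered_within_ci(self):
        rng = np.random.default_rng(16)
        F = rng.normal(0, 1, 400)
        N = rng.normal(0, 1, 400)
        V = 0.8 * F - 0.4 * N + rng.normal(0, 0.2, 400)
        out = zscore_partial_regression(V, F, N, n_boot=300, rng=rng)
        sd_scale = np.std(V)
        assert out["ci_SD"][0] <= 0.8 / sd_scale <= out["ci_SD"][1]
        assert out["ci_NS"][0] <= -0.4 / sd_scale <= out["ci_NS"][1]

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(17)
        F = rng.normal(0, 1, 100)
        with pytest.raises(ValueError):
            zscore_partial_regression(F, F, F * 2.0 + 1.0)


class TestHeadAmplitudeEffect:
    def test_no_head_effect_gives_flat_slope(self):
        rng = np.random.default_rng(18)
        recs = _records(100, rng)
        out = head_amplitude_effect(recs)
        assert abs(out["slope"]) < 0.003

    def test_planted_degradation_recovered(self):
        rng = np.random.default_rng(19)
        recs = _records(100, rng)
        for rec in recs:
            rec.r = 0.9 - 0.01 * rec.head_contribution + rng.normal(0, 0.02)
        out = head_amplitude_effect(recs)
        assert out["slope"] == pytest.approx(-0.01, abs=0.002)
        assert out["r"] < -0.5
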