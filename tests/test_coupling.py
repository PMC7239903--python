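import numpy as np
import pytest

from ripplering.circular import circ_diff, circular_correlation
from ripplering.core import EpochSet, EventSeries, SpikeTrain
from ripplering.coupling import (
    Correlogram,
    assign_spike_phases,
    event_cross_correlogram,
    fit_antisymmetric_dynamics,
    jpca_fit,
    swr_energy,
    swr_phase,
    theta_modulation,
    theta_phases,
    z_normalize_ccg,
)
from ripplering.synth import SessionConfig, build_ground_truth, simulate_units, synthesize_lfp


class TestEventCcg:
    def test_silent_unit_all_zero(self):
        c = event_cross_correlogram(np.array([100.0]), np.arange(5.0, 50.0, 5.0))
        assert np.all(c.rate == 0.0)

    def test_poisson_mean_rate(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 2000.0, rng.poisson(20000)))
        events = np.sort(rng.uniform(10, 1990.0, 500))
        c = event_cross_correlogram(spikes, events)
        assert abs(c.rate.mean() - 10.0) < 0.5

    def test_spike_at_peak_in_zero_lag_bin(self):
        c = event_cross_correlogram(np.array([10.0001]), np.array([10.0]))
        zero_bin = np.argmin(np.abs(c.lag_centers_s - 0.0025))
        assert c.counts[zero_bin] == 1
        assert c.counts.sum() == 1


class TestZNormalize:
    def test_already_smooth_ccg_z_zero(self):
        lags = np.arange(-0.5, 0.5, 0.005) + 0.0025
        rate = np.full(lags.size, 7.0)
        c = Correlogram(lags, rate, n_ref=100, bin_s=0.005, counts=rate * 100 * 0.005)
        cz = z_normalize_ccg(c)
        np.testing.assert_allclose(cz.z, 0.0, atol=1e-9)

    def test_forced_arithmetic(self):
        # a bin holding 25 counts where 16 are expected must give z = 2.25
        z = (25 - 16) / np.sqrt(16)
        assert z == 2.25

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        events = np.sort(rng.uniform(50, 950, 500))
        zs = []
        for _ in range(30):
            spikes = np.sort(rng.uniform(0, 1000.0, rng.poisson(10000)))
            cz = z_normalize_ccg(event_cross_correlogram(spikes, events))
            zs.append(cz.z)
        Z = np.concatenate(zs)
        assert abs(Z.mean()) < 0.05
        assert 0.9 < Z.std() < 1.1

    def test_slow_comodulation_removed(self):
        # unit modulated only at the UP/DOWN timescale, comodulated with
        # events: raw CCG is sloped but z stays flat
        rng = np.random.default_rng(2)
        period = 1.2
        t = np.arange(0, 2000.0, 0.001)
        gate = (np.sin(2 * np.pi * t / period) > -0.2).astype(float)
        rate = 12.0 * gate
        spikes = t[rng.random(t.size) < rate * 0.001]
        # events occur only in the active phase, like SWRs in UP states
        cand = rng.uniform(100, 1900, 4000)
        phase_ok = np.sin(2 * np.pi * cand / period) > 0.2
        events = np.sort(cand[phase_ok])[:600]
        c = event_cross_correlogram(spikes, events)
        cz = z_normalize_ccg(c)
        assert c.rate.max() - c.rate.min() > 2.0  # visibly non-flat raw CCG
        assert abs(np.nanmean(cz.z)) < 0.1


class TestSwrEnergy:
    def test_zero(self):
        assert swr_energy(np.zeros(100)) == 0.0

    def test_single_bin(self):
        z = np.zeros(50)
        z[10] = 3.0
        assert swr_energy(z) == 3.0

    def test_variance_variant(self):
        z = np.array([1.0, -1.0, 1.0, -1.0])
        assert swr_energy(z, variant="variance") == pytest.approx(1.0)

    def test_coupled_units_have_higher_energy(self):
        meds = {}
        for amp in (0.0, 2.0):
            cfg = SessionConfig(
                n_hd=0, n_nonhd=8, wake_s=10.0, nrem_s=600.0, rem_s=0.0,
                swr_amplitude_range=(amp, amp), burst_range=(0, 0), slow_sigma=0.0,
                theta_depth_range=(0, 0), with_lfp=False,
            )
            truth = build_ground_truth(cfg, 11)
            units = simulate_units(truth)
            ens = [
                swr_energy(z_normalize_ccg(event_cross_correlogram(u, truth.swr_times)).z) for u in units
            ]
            meds[amp] = np.median(ens)
        assert meds[2.0] > meds[0.0]


@pytest.fixture(scope="module")
def theta_session():
    cfg = SessionConfig(
        n_hd=0, n_nonhd=6, wake_s=5.0, nrem_s=5.0, rem_s=150.0, theta_depth_range=(0.8, 0.8),
        burst_range=(0, 0), slow_sigma=0.0, swr_amplitude_range=(0, 0), with_lfp=False,
    )
    truth = build_ground_truth(cfg, 9)
    units = simulate_units(truth)
    lfp = synthesize_lfp(truth, seed=9, noise_sd=0.5)
    phases = theta_phases(lfp, truth.epochs["rem"])
    return truth, units, lfp, phases


class TestTheta:
    def test_pure_theta_phase_tracks_ground_truth(self, theta_session):
        truth, _, lfp, phases = theta_session
        from ripplering.synth import theta_phase_truth

        gt = theta_phase_truth(lfp.times, truth.epochs, truth.theta_freq_hz)
        s, e = truth.epochs["rem"].intervals[0]
        sel = (lfp.times > s + 0.5) & (lfp.times < e - 0.5)
        err = np.abs(circ_diff(phases.phase[sel], gt[sel]))
        assert np.percentile(err, 95) < 0.1

    def test_preferred_phase_recovery(self, theta_session):
        truth, units, _, phases = theta_session
        for u, spec in zip(units[:3], truth.unit_specs[:3]):
            tm = theta_modulation(assign_spike_phases(u, phases))
            assert abs(circ_diff(tm.preferred_phase, spec.theta_phase)) < 0.3
            assert tm.rayleigh_p < 1e-3

    def test_unmodulated_unit_calibration(self, theta_session):
        truth, _, _, phases = theta_session
        rng = np.random.default_rng(3)
        s, e = truth.epochs["rem"].intervals[0]
        rej = 0
        n_rep = 100
        for _ in range(n_rep):
            spikes = np.sort(rng.uniform(s, e, 400))
            tm = theta_modulation(assign_spike_phases(spikes, phases))
            rej += tm.rayleigh_p < 0.05
        assert rej / n_rep < 0.15

    def test_all_spikes_at_pi(self):
        tm = theta_modulation(np.full(100, np.pi))
        assert tm.preferred_phase == pytest.approx(np.pi)
        assert tm.depth == pytest.approx(1.0)

    def test_too_few_spikes_flagged(self):
        tm = theta_modulation(np.array([0.1, 0.2]))
        assert not tm.reliable

    def test_short_epoch_skipped_with_warning(self, theta_session):
        _, _, lfp, _ = theta_session
        with pytest.warns(RuntimeWarning, match="skipped"):
            theta_phases(lfp, EpochSet("rem", [[0.0, 0.1]]))


class TestJpca:
    def test_closed_form_rotation(self):
        w = 3.0
        t = np.linspace(0, 2 * np.pi, 500)
        X = np.column_stack([np.cos(w * t), np.sin(w * t)])
        Xdot = np.column_stack([-w * np.sin(w * t), w * np.cos(w * t)])
        M = fit_antisymmetric_dynamics(X, Xdot)
        np.testing.assert_allclose(M, [[0.0, -w], [w, 0.0]], atol=1e-6)
        ev = np.linalg.eigvals(M)
        np.testing.assert_allclose(np.sort(ev.imag), [-w, w], atol=1e-6)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 5))
        Xdot = rng.standard_normal((200, 5))
        M = fit_antisymmetric_dynamics(X, Xdot)
        np.testing.assert_array_equal(M + M.T, np.zeros((5, 5)))

    def test_phase_recovery_up_to_rotation(self):
        N, T = 40, 200
        phis = np.linspace(0, 2 * np.pi, N, endpoint=False)
        tt = np.arange(T)
        Z = np.cos(2 * np.pi * tt[None, :] / T - phis[:, None])
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            model = jpca_fit(Z, K=6)
        r, _ = circular_correlation(model.phases, phis)
        assert abs(r) > 0.95

    def test_swr_phase_trivia(self):
        rng = np.random.default_rng(5)
        Z = rng.standard_normal((30, 100))
        model = jpca_fit(Z, K=6)
        # consistency with the fitted per-unit phases
        assert swr_phase(Z[3], model) == pytest.approx(model.phases[3])
        # scale invariance
        assert swr_phase(2.0 * Z[3] - model.mean_ccg, model) == pytest.approx(
            swr_phase(Z[3] * 2.0 - model.mean_ccg, model)
        )

    def test_projection_phase_conventions(self):
        # y = (1, 0) -> 0 and y = (0, -1) -> -pi/2
        assert np.arctan2(0.0, 1.0) == 0.0
        assert np.arctan2(-1.0, 0.0) == pytest.approx(-np.pi / 2)

    def test_jpca_theta_phase_correlation(self):
        # population injected with the same per-unit phase for theta and SWR
        cfg = SessionConfig(
            n_hd=0, n_nonhd=30, wake_s=5.0, nrem_s=900.0, rem_s=120.0,
            swr_amplitude_range=(1.5, 1.5), theta_depth_range=(0.7, 0.7),
            burst_range=(0, 0), slow_sigma=0.0, couple_theta_swr_phase=True, with_lfp=False,
        )
        truth = build_ground_truth(cfg, 13)
        units = simulate_units(truth)
        Z = np.vstack(
            [np.nan_to_num(z_normalize_ccg(event_cross_correlogram(u, truth.swr_times)).z) for u in units]
        )
        model = jpca_fit(Z, K=6, dt=0.005, smooth_sd_bins=2.0)
        theta_pref = np.array([s.theta_phase for s in truth.unit_specs])
        r, _ = circular_correlation(model.phases, theta_pref)
        assert abs(r) > 0.5
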