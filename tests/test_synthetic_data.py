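"""Generator-level checks: task structure, agent, wheel, spikes, RF."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from bwmap import encoding
from bwmap import synthetic_data as sd


class TestBlockLengths:
    def test_within_bounds_and_deterministic(self):
        a = sd.sample_block_lengths(60, (20, 100), 500, seed=7)
        b = sd.sample_block_lengths(60, (20, 100), 500, seed=7)
        assert np.array_equal(a, b)
        assert a.min() >= 20 and a.max() <= 100
        assert np.issubdtype(a.dtype, np.integer)

    def test_degenerate_bounds(self):
        assert np.all(sd.sample_block_lengths(37.0, (20, 20), 50, seed=0) == 20)

    def test_mean_matches_truncated_exponential_expectation(self):
        # independent oracle: numerically integrate the truncated density
        scale, (a, b) = 60.0, (20, 100)
        dens = lambda x: np.exp(-x / scale)
        z, _ = integrate.quad(dens, a, b)
        mean_num, _ = integrate.quad(lambda x: x * dens(x) / z, a, b)
        assert mean_num == pytest.approx(
            sd.truncated_exponential_mean(scale, (a, b)), abs=1e-6)
        draws = sd.sample_block_lengths(scale, (a, b), 50_000, seed=11)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mean_num) < 4 * se + 0.5  # rounding bias

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            sd.sample_block_lengths(-1, (20, 100), 5)
        with pytest.raises(ValueError):
            sd.sample_block_lengths(60, (100, 20), 5)


class TestTrialSequence:
    def test_unbiased_phase_counts_exact(self):
        tr = sd.generate_trial_sequence(sd.TaskConfig(), seed=3)
        first = tr.iloc[:90]
        assert (first["p_right_block"] == 0.5).all()
        assert (first["contrast"] == 0).sum() == 10
        for level in (1.0, 0.25, 0.125, 0.0625):
            sub = first[first["contrast"] == level]
            assert (sub["stim_side"] == -1).sum() == 10
            assert (sub["stim_side"] == 1).sum() == 10

    def test_biased_block_side_fraction(self):
        tr = sd.generate_trial_sequence(
            sd.TaskConfig(session_length=30_000), seed=5)
        right = tr[tr["p_right_block"] == 0.8]
        frac = (right["stim_side"] == 1).mean()
        assert frac == pytest.approx(0.8, abs=0.02)
        left = tr[tr["p_right_block"] == 0.2]
        assert (left["stim_side"] == 1).mean() == pytest.approx(0.2, abs=0.02)

    def test_blocks_alternate_and_lengths_bounded(self):
        tr = sd.generate_trial_sequence(
            sd.TaskConfig(session_length=5000), seed=9)
        biased = tr[tr["block_idx"] > 0]
        per_block = biased.groupby("block_idx")["p_right_block"].agg(["first",
                                                                      "size"])
        # strict alternation of the prior and bounded lengths (the final
        # block may be truncated by the session end)
        priors = per_block["first"].to_numpy()
        assert np.all(priors[1:] != priors[:-1])
        assert per_block["size"].iloc[:-1].between(20, 100).all()

    def test_determinism(self):
        t1 = sd.generate_trial_sequence(sd.TaskConfig(), seed=42)
        t2 = sd.generate_trial_sequence(sd.TaskConfig(), seed=42)
        pd.testing.assert_frame_equal(t1, t2)


class TestPriorUpdate:
    def test_no_learning_and_full_update(self):
        assert sd.update_prior(0.3, 1, 0.0) == 0.3
        assert sd.update_prior(0.3, -1, 0.0) == 0.3
        assert sd.update_prior(0.3, 1, 1.0) == 1.0
        assert sd.update_prior(0.3, -1, 1.0) == 0.0

    def test_closed_form_recursion(self):
        # constant rightward actions: pi_t = 1 - (1-a)^t (1-pi0)
        alpha, pi0 = 0.2, 0.4
        pi = pi0
        for t in range(1, 12):
            pi = sd.update_prior(pi, 1, alpha)
            assert pi == pytest.approx(1 - (1 - alpha) ** t * (1 - pi0))

    def test_invalid_action(self):
        with pytest.raises(ValueError):
            sd.update_prior(0.5, 0, 0.1)


class TestAgent:
    def test_deterministic_policy_limit(self):
        cfg = sd.TaskConfig(session_length=200)
        tr = sd.generate_trial_sequence(cfg, seed=1)
        params = sd.AgentParams(policy_slope=50.0, policy_prior_weight=0.0,
                                lapse=0.0)
        out, _ = sd.simulate_agent(tr, params, seed=2)
        full = out[out["contrast"] == 1.0]
        assert (full["feedback"] == 1).all()

    def test_prior_following_beats_chance_on_zero_contrast(self):
        # the subjective prior tracks the block only through
        # stimulus-informed actions; with the prior fed into the policy,
        # zero-contrast accuracy in biased blocks exceeds chance, and
        # without it, it does not
        cfg = sd.TaskConfig(session_length=20_000)
        tr = sd.generate_trial_sequence(cfg, seed=3)
        accs = {}
        for w in (0.0, 0.7):
            params = sd.AgentParams(policy_prior_weight=w)
            out, _ = sd.simulate_agent(tr, params, seed=4)
            zero = out[(out["contrast"] == 0) & (out["block_idx"] > 0)]
            accs[w] = (zero["feedback"] == 1).mean()
        assert accs[0.7] > 0.55
        assert abs(accs[0.0] - 0.5) < 0.05
        assert accs[0.7] > accs[0.0]

    def test_pi_trace_bounded_for_any_alpha(self):
        cfg = sd.TaskConfig(session_length=300)
        tr = sd.generate_trial_sequence(cfg, seed=5)
        for alpha in (0.0, 0.01, 0.5, 0.99, 1.0):
            _, pi = sd.simulate_agent(tr, sd.AgentParams(alpha=alpha), seed=6)
            assert np.all((pi >= 0) & (pi <= 1))

    def test_event_times_and_latency_law(self, tuned_session):
        tr = tuned_session.trials
        lat = tr["first_move_s"] - tr["stim_on_s"]
        assert lat.between(0.08, 2.0).all()
        assert (tr["stim_on_s"].diff().dropna() > 0).all()
        assert (tr["feedback_s"] > tr["first_move_s"]).all()
        # feedback consistent with choice vs side
        assert (tr["feedback"] == np.where(tr["choice"] == tr["stim_side"],
                                           1, -1)).all()


class TestWheel:
    def test_turn_sign_and_speed(self, tuned_session):
        wheel = tuned_session.wheel
        tr = tuned_session.trials
        v = wheel["velocity_rad_s"].to_numpy()
        t = wheel["time_s"].to_numpy()
        dt = t[1] - t[0]
        left = tr[tr["choice"] == -1].iloc[0]
        sel = (t >= left["first_move_s"]) & (t <= left["first_move_s"] + 0.3)
        assert np.trapezoid(v[sel], dx=dt) < 0
        right = tr[tr["choice"] == 1].iloc[0]
        sel = (t >= right["first_move_s"]) & (t <= right["first_move_s"] + 0.3)
        assert np.trapezoid(v[sel], dx=dt) > 0
        # quiescence before stimulus onset is still
        q = tr.iloc[10]
        sel = (t >= q["stim_on_s"] - q["quiescence_s"]) & (t < q["stim_on_s"])
        assert np.all(v[sel] == 0)
        # position integrates velocity
        pos = wheel["position_rad"].to_numpy()
        assert np.allclose(pos, np.cumsum(v) * dt, atol=1e-9)


class TestSpikes:
    def test_homogeneous_rate(self):
        cfg = sd.TaskConfig(session_length=150)
        tr = sd.generate_trial_sequence(cfg, seed=1)
        tr, _ = sd.simulate_agent(tr, seed=2)
        tun = sd.GroundTruthTuning(baseline=np.array([15.0]))
        spk, _ = sd.simulate_spikes(tr, None, tun, seed=3)
        duration = tr["feedback_s"].max() + 2.0
        rate = len(spk) / duration
        se = np.sqrt(15.0 / duration)
        assert abs(rate - 15.0) < 3 * se

    def test_duration_scaling(self):
        cfg_a = sd.TaskConfig(session_length=120)
        cfg_b = sd.TaskConfig(session_length=240)
        counts = []
        for cfg, seed in ((cfg_a, 1), (cfg_b, 1)):
            tr = sd.generate_trial_sequence(cfg, seed=seed)
            tr, _ = sd.simulate_agent(tr, seed=2)
            tun = sd.GroundTruthTuning(baseline=np.array([20.0]))
            spk, _ = sd.simulate_spikes(tr, None, tun, seed=3,
                                        duration=float(cfg.session_length))
            counts.append(len(spk))
        expect = 20.0 * 120
        assert abs(counts[1] - 2 * counts[0]) < 4 * np.sqrt(2 * expect)

    def test_stim_tuned_peth_laterality(self):
        cfg = sd.TaskConfig(session_length=300)
        tr = sd.generate_trial_sequence(cfg, seed=4)
        tr, _ = sd.simulate_agent(tr, seed=5)
        tun = sd.GroundTruthTuning(baseline=np.array([10.0]),
                                   amplitudes={"stim_right": np.array([1.5])})
        spk, _ = sd.simulate_spikes(tr, None, tun, seed=6)
        t = spk["time_s"].to_numpy()
        rates = {}
        for side in (-1, 1):
            on = tr.loc[tr["stim_side"] == side, "stim_on_s"].to_numpy()
            c = np.searchsorted(t, on + 0.1) - np.searchsorted(t, on)
            rates[side] = c.mean()
        assert rates[1] > rates[-1]

    def test_drift_induces_lag1_autocorrelation(self, null_session):
        tr = null_session.trials
        t = null_session.spike_times(0)
        on = tr["stim_on_s"].to_numpy()
        counts = np.searchsorted(t, on + 0.5) - np.searchsorted(t, on - 0.5)
        c = counts - counts.mean()
        rho1 = np.sum(c[1:] * c[:-1]) / np.sum(c * c)
        assert rho1 > 0.1

    def test_generator_and_fitter_share_design_matrix(self, tuned_session):
        tr = tuned_session.trials
        dm1 = encoding.build_design_matrix(tr, tuned_session.wheel)
        dm2 = encoding.build_design_matrix(tr, tuned_session.wheel)
        assert np.array_equal(dm1.X, dm2.X)
        assert dm1.groups == dm2.groups

    def test_hierarchical_seeding_adding_neurons_is_stable(self):
        cfg = sd.TaskConfig(session_length=120)
        tr = sd.generate_trial_sequence(cfg, seed=1)
        tr, _ = sd.simulate_agent(tr, seed=2)
        t_a, _ = sd.simulate_spikes(
            tr, None, sd.GroundTruthTuning(baseline=np.array([10.0])), seed=9)
        t_b, _ = sd.simulate_spikes(
            tr, None, sd.GroundTruthTuning(baseline=np.array([10.0, 12.0])),
            seed=9)
        a = t_a.loc[t_a["neuron_id"] == 0, "time_s"].to_numpy()
        b = t_b.loc[t_b["neuron_id"] == 0, "time_s"].to_numpy()
        assert np.array_equal(a, b)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            sd.GroundTruthTuning(baseline=np.array([0.0]))


class TestRFStimulus:
    def test_switch_prob_one_changes_every_frame(self):
        stim = sd.generate_rf_stimulus(50, switch_prob=1.0, seed=1)
        assert np.all(np.diff(stim.states.astype(int), axis=0) != 0)

    def test_epoch_durations_geometric(self):
        stim = sd.generate_rf_stimulus(3000, switch_prob=1 / 6, seed=2)
        ep = sd.rf_state_epochs(stim)
        mean_ms = ep.mean() / stim.frame_rate * 1000
        assert mean_ms == pytest.approx(100.0, abs=10.0)

    def test_rf_neuron_prefers_its_center(self):
        stim = sd.generate_rf_stimulus(2000, seed=3)
        spikes = sd.simulate_rf_neuron(stim, true_center=(4, 10), seed=4)
        on, _ = sd.rf_transition_maps(stim)
        near = np.flatnonzero(on[:, 4, 10]) + 1
        far = np.flatnonzero(on[:, 12, 2]) + 1
        dt = 1.0 / stim.frame_rate

        def mean_rate(frames):
            t0 = frames * dt
            return np.mean(np.searchsorted(spikes, t0 + 0.1)
                           - np.searchsorted(spikes, t0))

        assert mean_rate(near) > mean_rate(far)


class TestEnsemble:
    def test_null_drift_scenario_has_no_tuning(self, null_session):
        amps = null_session.ground_truth["amplitudes"]
        assert all(np.all(v == 0) for v in amps.values()) or not amps

    def test_reproducible(self):
        e1 = sd.generate_ensemble(1, ["A"], (4, 4), "null-drift", seed=5,
                                  cfg=sd.TaskConfig(session_length=120))
        e2 = sd.generate_ensemble(1, ["A"], (4, 4), "null-drift", seed=5,
                                  cfg=sd.TaskConfig(session_length=120))
        pd.testing.assert_frame_equal(e1[0].trials, e2[0].trials)
        pd.testing.assert_frame_equal(e1[0].spikes, e2[0].spikes)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            sd.generate_ensemble(1, ["A"], (4, 4), "bogus", seed=1)
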