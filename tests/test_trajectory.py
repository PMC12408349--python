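"""Supersession trajectories: distance algebra, latency, pseudo-trial null."""

import numpy as np
import pandas as pd
import pytest

from bwmap import trajectory as tj
from bwmap import synthetic_data as sd
from bwmap.core_data import SessionBundle


def _regular_session(rate_hz=100.0, n_trials=30, n_cells=2,
                     region="R", sid="s"):
    """Deterministic session: every cell fires a regular spike train, so
    every overlapping bin holds exactly rate * bin_s spikes."""
    stim_on = 5.0 + 3.0 * np.arange(n_trials)
    trials = pd.DataFrame({
        "trial_idx": np.arange(n_trials),
        "stim_side": np.resize([-1, 1], n_trials),
        "contrast": 0.25,
        "p_right_block": 0.8,
        "choice": np.resize([1, -1], n_trials),
        "feedback": np.resize([-1, 1], n_trials),
        "stim_on_s": stim_on,
        "first_move_s": stim_on + 0.3,
        "feedback_s": stim_on + 0.6,
        "quiescence_s": 0.5,
        "block_idx": np.resize([1, 1, 2, 2], n_trials),
    })
    t_end = stim_on[-1] + 2.0
    step = 1.0 / rate_hz
    base = np.arange(step / 2, t_end, step)
    spikes = pd.DataFrame({
        "neuron_id": np.repeat(np.arange(n_cells), base.size),
        "time_s": np.tile(base, n_cells),
    })
    neurons = pd.DataFrame({"neuron_id": np.arange(n_cells),
                            "region": region, "well_isolated": True})
    return SessionBundle(sid, trials, spikes, neurons)


class TestSupersession:
    def test_constant_rate_cell_gives_constant_rows(self):
        b = _regular_session(rate_hz=80.0)
        ss = tj.build_supersession([b], "R", "stimulus", min_cells=1)
        assert np.allclose(ss.cond_neg, 80.0)
        assert np.allclose(ss.cond_pos, 80.0)

    def test_overlapping_bin_value_matches_direct_count(self):
        b = _regular_session(rate_hz=100.0)
        starts = tj.overlapping_bin_starts()
        rates = tj._trial_cell_rates(b, b.trials, "stim_on_s", starts,
                                     tj.BIN_LENGTH_S, "R")
        t = b.spike_times(0)
        align = b.trials["stim_on_s"].iloc[3]
        s = starts[7]
        direct = np.sum((t >= align + s) & (t < align + s + 0.0125)) / 0.0125
        assert rates[3, 0, 7] == pytest.approx(direct)

    def test_min_cells_enforced(self):
        b = _regular_session(n_cells=2)
        with pytest.raises(ValueError, match="fewer than"):
            tj.build_supersession([b], "R", "stimulus", min_cells=20)

    def test_bin_grid_drops_partial_final_bin(self):
        starts = tj.overlapping_bin_starts((0.0, 0.150))
        assert starts[-1] + tj.BIN_LENGTH_S <= 0.150 + 1e-12
        assert np.allclose(np.diff(starts), 0.002)


class TestDistance:
    def test_identical_conditions(self):
        m = np.random.default_rng(0).random((6, 10))
        assert np.allclose(tj.distance_curve(m, m), 0.0)

    def test_uniform_offset(self):
        rng = np.random.default_rng(1)
        m = rng.random((9, 12))
        d = tj.distance_curve(m, m + 0.7)
        assert np.allclose(d, 0.7)     # ||delta 1||/sqrt(N) = delta

    def test_single_cell_offset_scaling(self):
        n = 16
        m = np.zeros((n, 5))
        m2 = m.copy()
        m2[3] += 2.0
        assert np.allclose(tj.distance_curve(m, m2), 2.0 / np.sqrt(n))

    def test_invariances(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((8, 20)), rng.random((8, 20))
        d = tj.distance_curve(a, b)
        perm = rng.permutation(8)
        assert np.allclose(tj.distance_curve(a[perm], b[perm]), d)
        assert np.allclose(tj.distance_curve(3 * a, 3 * b), 3 * d)


class TestAmplitudeLatency:
    def test_constant_curve(self):
        a, lat = tj.amplitude_latency(np.linspace(0, 0.15, 76),
                                      np.full(76, 4.0))
        assert a == 0.0 and np.isnan(lat)

    def test_linear_ramp_closed_form(self):
        k = 3.0
        t = np.linspace(0, 0.150, 1501)     # includes 105 ms exactly
        a, lat = tj.amplitude_latency(t, k * t)
        assert a == pytest.approx(0.15 * k)
        assert lat == pytest.approx(0.105, abs=1e-9)

    def test_triangle_latency_on_rising_edge(self):
        t = np.linspace(0, 0.15, 1501)
        d = np.minimum(t, 0.15 - t)         # peak at 75 ms
        a, lat = tj.amplitude_latency(t, d)
        assert a == pytest.approx(0.075)
        assert lat == pytest.approx(0.7 * 0.075, abs=1e-9)
        assert lat < 0.075

    def test_amplitude_ignores_constant_offset_between_conditions(self):
        # a time-constant offset vector shifts d(t) but adds no
        # modulation; the amplitude of a constant curve stays zero
        m = np.tile(np.linspace(1, 2, 10), (4, 1))
        d0 = tj.distance_curve(m, m)
        d1 = tj.distance_curve(m, m + 1.5)
        assert tj.amplitude_latency(np.arange(10.0), d0)[0] == 0.0
        assert tj.amplitude_latency(np.arange(10.0), d1)[0] == \
            pytest.approx(0.0, abs=1e-12)


class TestPseudoTrialNull:
    def test_permute_within_strata_preserves_singletons(self, rng):
        labels = np.array([1, -1, 1, -1, 1])
        strata = np.array([0, 0, 1, 2, 3])   # strata 1..3 singletons
        out = tj._permute_within_strata(labels, strata, rng)
        assert np.array_equal(out[2:], labels[2:])
        assert sorted(out[:2]) == sorted(labels[:2])

    def test_formula_floor_when_observed_dominates(self, tuned_session):
        ens = [tuned_session]
        ss = tj.build_supersession(ens, "VIS", "stimulus", min_cells=5)
        p, a_obs, null_a = tj.pseudo_trial_null(ss, M=100, seed=0)
        if np.all(null_a < a_obs):
            assert p == pytest.approx(1 / 101)
        assert 0 < p <= 1

    def test_calibration_on_label_independent_sessions(self):
        """Pseudo-trial p-values are roughly uniform when rates ignore
        the condition label."""
        rng = np.random.default_rng(7)
        ps = []
        for rep in range(40):
            rates = rng.poisson(3.0, size=(40, 25, 30)).astype(float)
            labels = np.where(rng.random(40) < 0.5, 1, -1)
            strata = rng.integers(0, 3, size=(40, 1))
            cache = tj.SessionCache(rates=rates, labels=labels,
                                    strata=strata,
                                    stim_side=labels.copy())
            ss = tj.Supersession(
                cond_neg=rates[labels < 0].mean(axis=0),
                cond_pos=rates[labels > 0].mean(axis=0),
                times=np.arange(30) * 0.002, region="R",
                variable="stimulus", sessions=[cache])
            p, _, _ = tj.pseudo_trial_null(ss, M=60, seed=rep)
            ps.append(p)
        assert 0.35 < np.mean(ps) < 0.65

    def test_feedback_null_derives_pseudo_feedback(self):
        """For the feedback variable, pseudo-labels come from permuted
        choices compared with true stimulus sides, so null feedback
        rates reflect the session's accuracy structure."""
        rng = np.random.default_rng(8)
        n = 60
        side = np.where(rng.random(n) < 0.5, 1, -1)
        choice = np.where(rng.random(n) < 0.8, side, -side)
        feedback = np.where(choice == side, 1, -1)
        rates = rng.poisson(3.0, size=(n, 25, 10)).astype(float)
        cache = tj.SessionCache(rates=rates, labels=feedback,
                                strata=np.stack([side], axis=1),
                                stim_side=side)
        ss = tj.Supersession(
            cond_neg=rates[feedback < 0].mean(axis=0),
            cond_pos=rates[feedback > 0].mean(axis=0),
            times=np.arange(10) * 0.002, region="R",
            variable="feedback", sessions=[cache])
        p, _, null_a = tj.pseudo_trial_null(ss, M=30, seed=9)
        assert null_a.shape == (30,)
        assert 0 < p <= 1

    def test_region_pipeline_on_tuned_ensemble(self, tuned_session):
        res = tj.trajectory_region_test([tuned_session], "VIS", "stimulus",
                                        M=99, seed=3, min_cells=5)
        assert res.p_combined < 0.05
        assert res.effect_size > 0


class TestPCA:
    def test_rank_one_variance(self):
        t = np.linspace(0, 1, 30)
        load = np.random.default_rng(0).random(12)
        a = np.outer(load, t)
        b = np.outer(load, 1 - t)
        ss = tj.Supersession(cond_neg=a, cond_pos=b, times=t, region="R",
                             variable="stimulus", sessions=[])
        _, _, evr = tj.pca_project(ss)
        assert evr[0] > 0.99

    def test_projection_preserves_distance_up_to_truncation(self):
        rng = np.random.default_rng(1)
        # rank-3 data: projection onto 3 PCs is lossless
        basis = rng.random((10, 3))
        coef_a, coef_b = rng.random((3, 25)), rng.random((3, 25))
        a, b = basis @ coef_a, basis @ coef_b
        ss = tj.Supersession(cond_neg=a, cond_pos=b, times=np.arange(25.0),
                             region="R", variable="stimulus", sessions=[])
        pa, pb, _ = tj.pca_project(ss)
        d_true = np.linalg.norm(a - b, axis=0)
        d_proj = np.linalg.norm(pa - pb, axis=1)
        assert np.allclose(d_proj, d_true, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((8, 20)), rng.random((8, 20))
        ss = tj.Supersession(cond_neg=a, cond_pos=b, times=np.arange(20.0),
                             region="R", variable="stimulus", sessions=[])
        p1 = tj.pca_project(ss)
        p2 = tj.pca_project(ss)
        assert np.allclose(p1[0], p2[0])
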