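"""Raised-cosine bases, design matrix, ridge fits and group delta-R^2."""

import numpy as np
import pandas as pd
import pytest

from bwmap import encoding
from bwmap import synthetic_data as sd


class TestBasis:
    def test_peaks_and_support(self):
        bs = encoding.make_basis(5, 0.4)
        # interior bases reach ~1 at their sampled peak; values vanish
        # outside each basis's support
        assert bs.values.max(axis=0).min() > 0.6
        assert bs.values.max() <= 1.0 + 1e-12
        assert np.all(bs.values >= 0)

    def test_centre_spacing_increases_in_linear_time(self):
        bs = encoding.make_basis(5, 0.4)
        peaks = bs.lags[np.argmax(bs.values, axis=0)]
        gaps = np.diff(peaks)
        assert np.all(gaps[1:] >= gaps[:-1] - 1e-12)

    def test_even_coverage(self):
        for b, span in ((5, 0.4), (3, 0.2), (3, 0.3)):
            bs = encoding.make_basis(b, span)
            assert bs.values.sum(axis=1).min() > 0

    def test_anticausal_lags_negative(self):
        bs = encoding.make_basis(3, 0.2, causal=False)
        assert np.all(bs.lags < 0)
        # fast basis sits just before the event
        assert bs.values[-1, 0] == bs.values.max(axis=0)[0] or \
            bs.values[-1, 0] > 0.5

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            encoding.make_basis(0, 0.4)


class TestContrastHeight:
    def test_printed_values(self):
        assert encoding.contrast_height(1.0) == pytest.approx(1.0)
        assert encoding.contrast_height(0.0) == 0.0
        assert encoding.contrast_height(0.0625) == pytest.approx(0.3026,
                                                                 abs=2e-4)

    def test_monotone(self):
        c = np.linspace(0, 1, 50)
        assert np.all(np.diff(encoding.contrast_height(c)) > 0)


def _one_event_trials(event_offset=0.0, side=1, contrast=1.0):
    stim_on = 10.0
    return pd.DataFrame({
        "trial_idx": [0],
        "stim_side": [side],
        "contrast": [contrast],
        "p_right_block": [0.8],
        "choice": [side],
        "feedback": [1],
        "stim_on_s": [stim_on],
        "first_move_s": [stim_on + event_offset if event_offset else np.nan],
        "feedback_s": [stim_on + 0.6],
        "quiescence_s": [0.5],
        "block_idx": [1],
    })


class TestDesignMatrix:
    def test_single_event_copies_basis(self):
        tr = _one_event_trials()
        dm = encoding.build_design_matrix(tr)
        bs = encoding.make_basis(5, 0.4)
        sl = dm.groups["stim_right"]
        # stimulus onset at bin 20 (0.4 s pre-window / 20 ms)
        col = dm.X[:, sl]
        assert np.allclose(col[20:40], bs.values)
        assert np.allclose(col[:20], 0)
        assert np.allclose(col[40:], 0)

    def test_contrast_scales_stimulus_columns(self):
        dm1 = encoding.build_design_matrix(_one_event_trials(contrast=1.0))
        dm2 = encoding.build_design_matrix(_one_event_trials(contrast=0.0625))
        sl = dm1.groups["stim_right"]
        h = encoding.contrast_height(0.0625)
        assert np.allclose(dm2.X[:, sl], h * dm1.X[:, sl])

    def test_two_events_superpose(self):
        tr = pd.concat([_one_event_trials(), _one_event_trials()],
                       ignore_index=True)
        tr["trial_idx"] = [0, 1]
        tr.loc[1, ["stim_on_s", "feedback_s"]] = [40.0, 40.6]
        dm = encoding.build_design_matrix(tr)
        sl = dm.groups["feedback_correct"]
        one = dm.X[:dm.n_bins, sl]
        two = dm.X[dm.n_bins:, sl]
        assert np.allclose(one, two)

    def test_anticausal_zero_at_and_after_event(self):
        tr = _one_event_trials(event_offset=0.3)
        dm = encoding.build_design_matrix(tr)
        sl = dm.groups["move_right"]
        event_bin = int(round((0.4 + 0.3) / 0.02))
        col = dm.X[:, sl]
        assert np.allclose(col[event_bin:], 0)
        assert col[:event_bin].sum() > 0

    def test_block_probability_step(self):
        dm = encoding.build_design_matrix(_one_event_trials())
        assert np.allclose(dm.X[:, dm.groups["block_prob"]], 0.8)

    def test_deterministic(self, tuned_session):
        tr = tuned_session.trials.iloc[:50]
        a = encoding.build_design_matrix(tr, tuned_session.wheel)
        b = encoding.build_design_matrix(tr, tuned_session.wheel)
        assert np.array_equal(a.X, b.X)


@pytest.fixture(scope="module")
def fitted_linear():
    """Design matrix plus a linear synthetic neuron with known weights."""
    cfg = sd.TaskConfig(session_length=300)
    tr = sd.generate_trial_sequence(cfg, seed=1)
    tr, _ = sd.simulate_agent(tr, seed=2)
    wheel = sd.simulate_wheel(tr, seed=3)
    dm = encoding.build_design_matrix(tr, wheel)
    rng = np.random.default_rng(4)
    beta_true = rng.normal(0, 0.5, dm.X.shape[1])
    y = 1.5 + dm.X @ beta_true + 0.3 * rng.standard_normal(dm.X.shape[0])
    fit = encoding.fit_encoding(y, dm, seed=0)
    return dm, y, beta_true, fit


class TestFit:
    def test_recovers_known_weights(self, fitted_linear):
        dm, y, beta_true, fit = fitted_linear
        assert np.corrcoef(fit.beta, beta_true)[0, 1] > 0.95
        assert fit.r2 > 0.9

    def test_pure_noise_neuron(self, fitted_linear, rng):
        dm = fitted_linear[0]
        y = rng.standard_normal(dm.X.shape[0])
        fit = encoding.fit_encoding(y, dm, seed=1)
        assert fit.r2 <= 0.02

    def test_infinite_ridge_limit(self, fitted_linear):
        dm, y, _, _ = fitted_linear
        fit = encoding.fit_encoding(y, dm, alpha_grid=(1e12,), seed=2)
        assert np.abs(fit.beta).max() < 1e-3
        assert fit.beta0 == pytest.approx(y.mean(), rel=1e-3)


class TestDeltaR2:
    def test_zero_columns_give_zero_delta(self):
        # a session with no incorrect feedback: that group's columns are
        # all zero and removing them changes nothing
        tr = _one_event_trials()
        tr = pd.concat([tr] * 40, ignore_index=True)
        tr["trial_idx"] = np.arange(40)
        tr["stim_on_s"] = 10.0 + 3.0 * np.arange(40)
        tr["feedback_s"] = tr["stim_on_s"] + 0.6
        tr["first_move_s"] = tr["stim_on_s"] + 0.3
        dm = encoding.build_design_matrix(tr)
        assert np.allclose(dm.X[:, dm.groups["feedback_incorrect"]], 0)
        rng = np.random.default_rng(5)
        y = rng.poisson(2.0, dm.X.shape[0]).astype(float)
        fit = encoding.fit_encoding(y, dm, seed=3)
        assert encoding.delta_r2(y, dm, fit, "feedback_incorrect") == \
            pytest.approx(0.0, abs=1e-10)

    def test_stim_only_neuron_ranks_groups(self, fitted_linear):
        dm, _, _, _ = fitted_linear
        rng = np.random.default_rng(6)
        beta = np.zeros(dm.X.shape[1])
        beta[dm.groups["stim_right"]] = [1.0, 0.5, 0.25, 0.1, 0.05]
        y = 1.0 + dm.X @ beta + 0.3 * rng.standard_normal(dm.X.shape[0])
        fit = encoding.fit_encoding(y, dm, seed=4)
        d_stim = encoding.delta_r2(y, dm, fit, "stim_right")
        d_fb = encoding.delta_r2(y, dm, fit, "feedback_correct")
        assert d_stim > 0.01
        assert d_stim > d_fb

    def test_irrelevant_groups_concentrate_near_zero(self, fitted_linear):
        dm = fitted_linear[0]
        rng = np.random.default_rng(7)
        deltas = []
        for _ in range(15):
            y = rng.standard_normal(dm.X.shape[0])
            fit = encoding.fit_encoding(y, dm, seed=5)
            deltas.append(encoding.delta_r2(y, dm, fit, "stim_left"))
        assert abs(np.median(deltas)) < 0.002

    def test_pair_sensitivity_symmetric(self):
        a = encoding.pair_sensitivity(0.01, 0.003)
        b = encoding.pair_sensitivity(0.003, 0.01)
        assert a == b
        assert encoding.pair_sensitivity(0.01, 0.01) == -np.inf


class TestGeneratorRoundTrip:
    def test_sign_and_ordering_of_largest_kernels(self):
        """Spikes simulated from known kernel gains, fit back with the
        shared design matrix: the driven groups dominate delta-R^2."""
        cfg = sd.TaskConfig(session_length=400)
        tr = sd.generate_trial_sequence(cfg, seed=11)
        tr, _ = sd.simulate_agent(tr, seed=12)
        wheel = sd.simulate_wheel(tr, seed=13)
        dm = encoding.build_design_matrix(tr, wheel)
        tun = sd.GroundTruthTuning(
            baseline=np.array([40.0]),
            amplitudes={"stim_right": np.array([1.0]),
                        "feedback_correct": np.array([0.8])})
        spk, info = sd.simulate_spikes(tr, wheel, tun, seed=14, dm=dm)
        t = spk.loc[spk["neuron_id"] == 0, "time_s"].to_numpy()
        t0 = tr["stim_on_s"].to_numpy() + encoding.TRIAL_WINDOW[0]
        counts = np.empty(dm.n_trials * dm.n_bins)
        for l in range(dm.n_trials):
            edges = t0[l] + 0.02 * np.arange(dm.n_bins + 1)
            counts[l * dm.n_bins:(l + 1) * dm.n_bins] = np.diff(
                np.searchsorted(t, edges))
        fit = encoding.fit_encoding(counts, dm, seed=0)
        d = encoding.all_delta_r2(counts, dm, fit)
        driven = {"stim_right", "feedback_correct"}
        undriven_max = max(v for k, v in d.items() if k not in driven
                           and k not in ("move_init", "wheel_speed"))
        assert d["stim_right"] > 0
        assert d["feedback_correct"] > 0
        assert min(d["stim_right"], d["feedback_correct"]) > undriven_max
        # recovered stimulus weights point the right way
        assert fit.beta[dm.groups["stim_right"]].sum() > 0
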