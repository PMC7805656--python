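"""Protocol structure, amplitude windows, determinism, and the encoded
band-informativeness ordering of the synthetic generator."""

import numpy as np
import pytest

from fmgforce import (
    AXES,
    BandLayout,
    ConfigError,
    CouplingModel,
    DataError,
    ProtocolConfig,
    generate_focused_session,
    generate_free_session,
    generate_subject,
    synthesize_fmg,
)
from fmgforce.synthetic import DEFAULT_BAND_GAIN_SCALE


class TestFocusedSession:
    def test_row_count_and_amplitude_window(self, default_cfg, rng):
        y = generate_focused_session(default_cfg, "Fx", rng)
        assert y.shape == (400, 6)
        peak = np.abs(y[:, 0]).max()
        assert 0.9 * 20 * 0.9 <= peak <= 1.1 * 20  # +-10% jitter on 20 N

    def test_zero_leakage_zero_noise_gives_exact_zeros(self, rng):
        cfg = ProtocolConfig(leakage_range=(0.0, 0.0), focused_noise_frac=0.0)
        y = generate_focused_session(cfg, "Ty", rng)
        focused = AXES.index("Ty")
        others = [j for j in range(6) if j != focused]
        assert np.all(y[:, others] == 0.0)
        assert np.abs(y[:, focused]).max() > 0

    @pytest.mark.parametrize("axis", AXES)
    def test_focused_axis_dominates_over_seeds(self, axis):
        # leakage <= 0.30 and smooth noise <= 0.1 x amplitude imply the
        # focused column always has the largest peak and variance
        cfg = ProtocolConfig(session_duration_s=10.0)
        j = AXES.index(axis)
        for seed in range(20):
            y = generate_focused_session(cfg, axis, np.random.default_rng(seed))
            peaks = np.abs(y).max(axis=0)
            assert peaks[j] == peaks.max()
            assert y.var(axis=0).argmax() == j

    def test_unknown_axis_is_labeled_error(self, default_cfg, rng):
        with pytest.raises(DataError):
            generate_focused_session(default_cfg, "Fq", rng)


class TestFreeSession:
    def test_shape_and_amplitude(self, default_cfg, rng):
        y = generate_free_session(default_cfg, rng)
        assert y.shape == (400, 6)
        # peak scaled to 0.7 x the axis amplitude
        assert np.abs(y[:, 0]).max() == pytest.approx(0.7 * 20)
        assert np.abs(y[:, 3]).max() == pytest.approx(0.7 * 2)

    def test_zero_amplitude_scale_gives_zeros(self, rng):
        cfg = ProtocolConfig(free_amp_frac=0.0)
        assert np.all(generate_free_session(cfg, rng) == 0.0)

    def test_axes_exchangeable_in_normalized_variance(self):
        # after dividing by the axis amplitude, each axis should win the
        # largest-variance contest in ~1/6 of seeds
        cfg = ProtocolConfig(session_duration_s=10.0)
        amps = np.array([cfg.amplitude(a) for a in AXES])
        winners = np.zeros(6)
        n_seeds = 60
        for seed in range(n_seeds):
            y = generate_free_session(cfg, np.random.default_rng(seed))
            winners[(y / amps).var(axis=0).argmax()] += 1
        frac = winners[0] / n_seeds
        p = 1.0 / 6.0
        tol = 4 * np.sqrt(p * (1 - p) / n_seeds)
        assert abs(frac - p) < tol


class TestSynthesizeFmg:
    def test_zero_labels_constant_baseline(self, layout, default_cfg, rng):
        coup = CouplingModel.default(layout, seed=3)
        coup.noise_sd = 0.0
        coup.trial_gain_sd = 0.0
        coup.drift_rate = np.zeros(layout.n_channels)
        labels = np.zeros((50, 6))
        x = synthesize_fmg(labels, coup, layout, 0, rng)
        expected = coup.baseline + np.log(2.0)  # softplus(0)
        assert np.allclose(x, np.tile(expected, (50, 1)))

    def test_deterministic_under_seed(self, layout, default_cfg):
        coup = CouplingModel.default(layout, seed=3)
        labels = np.random.default_rng(1).normal(size=(40, 6))
        a = synthesize_fmg(labels, coup, layout, 0, np.random.default_rng(9))
        b = synthesize_fmg(labels, coup, layout, 0, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_output_nonnegative(self, layout, rng):
        coup = CouplingModel.default(layout, seed=3)
        labels = np.random.default_rng(2).normal(scale=30.0, size=(100, 6))
        assert np.all(synthesize_fmg(labels, coup, layout, 0, rng) >= 0)

    def test_dimension_mismatch_is_labeled(self, layout, rng):
        coup = CouplingModel.default(layout, seed=3)
        with pytest.raises(DataError):
            synthesize_fmg(np.zeros((10, 5)), coup, layout, 0, rng)

    def test_muscle_belly_band_more_torque_correlated_than_upper_arm(self, layout):
        # encoded structure: band 3 responds to torque, band 4 barely does
        cfg = ProtocolConfig(session_duration_s=20.0)
        bands = np.asarray(layout.channel_bands)
        wins = 0
        n_sessions = 10
        for seed in range(n_sessions):
            rng = np.random.default_rng(seed)
            coup = CouplingModel.default(layout, seed=seed + 100)
            y = generate_focused_session(cfg, "Tx", rng)
            x = synthesize_fmg(y, coup, layout, 0, rng)
            tx = y[:, AXES.index("Tx")]
            corr = np.array(
                [abs(np.corrcoef(x[:, j], tx)[0, 1]) for j in range(x.shape[1])]
            )
            if corr[bands == 3].mean() > corr[bands == 4].mean():
                wins += 1
        assert wins >= n_sessions - 1


class TestGenerateSubject:
    def test_default_protocol_sample_count(self, layout, coupling):
        ds = generate_subject(ProtocolConfig(), coupling, layout, seed=5)
        assert ds.n_samples == 5 * 7 * 400 == 14_000
        assert ds.n_channels == 60

    def test_four_trial_subject(self, layout, coupling):
        ds = generate_subject(ProtocolConfig(n_trials=4), coupling, layout, seed=5)
        assert ds.n_samples == 4 * 7 * 400 == 11_200
        assert len(np.unique(ds.trial_id)) == 4

    def test_samples_per_trial_session_block(self, small_subject, short_cfg):
        for t in small_subject.trials:
            for s in short_cfg.session_order:
                m = (small_subject.trial_id == t) & (small_subject.session_id == s)
                assert m.sum() == short_cfg.samples_per_session

    def test_byte_identical_under_same_seed(self, short_cfg, coupling, layout):
        a = generate_subject(short_cfg, coupling, layout, seed=11)
        b = generate_subject(short_cfg, coupling, layout, seed=11)
        assert np.array_equal(a.fmg, b.fmg)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.trial_id, b.trial_id)

    def test_single_trial_config_rejected(self):
        with pytest.raises(ConfigError):
            ProtocolConfig(n_trials=1)


class TestCouplingDefaults:
    def test_muscle_belly_row_dominates_elementwise(self):
        g = DEFAULT_BAND_GAIN_SCALE
        for row in (0, 1, 3):
            assert np.all(g[2] >= g[row])

    def test_upper_arm_torque_gain_near_zero(self):
        g = DEFAULT_BAND_GAIN_SCALE
        assert np.all(g[3, 3:] <= 0.05 * g[2, 3:])

    def test_all_gains_nonnegative(self):
        assert np.all(DEFAULT_BAND_GAIN_SCALE >= 0)

    def test_noiseless_preset(self, layout):
        c = CouplingModel.default(layout, seed=1, preset="noiseless")
        assert c.noise_sd == 0.0 and c.trial_gain_sd == 0.0
        assert np.all(c.drift_rate == 0.0)
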