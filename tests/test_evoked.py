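import numpy as np
import pytest

import gammappi as g
from gammappi.evoked import BASELINE_WINDOW, SCORE_WINDOW, TrialEpochs, morlet_cycles


class TestFrequencyGrid:
    def test_default_grid(self):
        f = g.morlet_frequency_grid()
        assert f.size == 180
        assert f[0] == 20.0 and f[-1] == 200.0
        assert np.allclose(np.diff(f), (200 - 20) / 179)

    def test_two_point_grid(self):
        f = g.morlet_frequency_grid(g.MorletConfig(n_freqs=2))
        assert f.tolist() == [20.0, 200.0]

    def test_cycles_increase_from_3_to_10(self):
        f = g.morlet_frequency_grid()
        for schedule in ("linear", "geometric"):
            c = morlet_cycles(f, g.MorletConfig(cycle_schedule=schedule))
            assert c[0] == pytest.approx(3.0) and c[-1] == pytest.approx(10.0)
            assert np.all(np.diff(c) > 0)


class TestExtractEpochs:
    def test_index_arithmetic(self):
        fs = 2000.0
        ch = np.arange(int(210 * fs), dtype=float)
        ep = g.extract_trial_epochs(ch, fs, [100.0])
        assert ep.samples.shape == (1, 2000)
        assert ep.samples[0, 0] == 199200.0  # (100 - 0.4) * 2000
        assert ep.samples[0, -1] == 201199.0

    def test_underflowing_trial_dropped(self, caplog):
        fs = 500.0
        ch = np.zeros(int(10 * fs))
        ep = g.extract_trial_epochs(ch, fs, [0.2, 5.0])
        assert ep.samples.shape[0] == 1

    def test_all_full_windows_kept(self):
        fs = 500.0
        onsets = np.arange(1.0, 25.0, 2.0)
        ep = g.extract_trial_epochs(np.zeros(int(30 * fs)), fs, onsets)
        assert ep.samples.shape[0] == onsets.size

    def test_no_usable_trials_rejected(self):
        with pytest.raises(ValueError, match="no usable trials"):
            g.extract_trial_epochs(np.zeros(100), 500.0, [0.05])


class TestMorletTFR:
    def test_zero_signal_zero_power(self):
        times, freqs, p, mask = g.morlet_tfr(np.zeros(1000), fs=1000.0)
        assert np.all(p == 0)

    def test_deterministic(self, rng):
        x = rng.standard_normal(1000)
        _, _, p1, _ = g.morlet_tfr(x, fs=1000.0)
        _, _, p2, _ = g.morlet_tfr(x.copy(), fs=1000.0)
        assert np.array_equal(p1, p2)

    def test_tone_ridge_on_nearest_grid_bin(self):
        fs = 1000.0
        t = np.arange(int(1 * fs)) / fs
        for f0 in (35.0, 60.0, 120.0):
            _, freqs, p, mask = g.morlet_tfr(np.sin(2 * np.pi * f0 * t), fs=fs)
            avg = np.array([p[i, mask[i]].mean() for i in range(freqs.size)])
            assert np.argmax(avg) == np.argmin(np.abs(freqs - f0))

    def test_frequencies_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            g.morlet_tfr(np.zeros(1000), fs=300.0)

    def test_mask_leaves_analysis_windows_valid(self):
        times, freqs, _, mask = g.morlet_tfr(np.zeros(1000), fs=1000.0)
        for lo, hi in (BASELINE_WINDOW, SCORE_WINDOW):
            sel = (times >= lo) & (times < hi)
            assert mask[:, sel].all()

    def test_time_shift_equivariance(self, rng):
        # shifting signal and window together leaves the map unchanged
        fs = 1000.0
        x = rng.standard_normal(1300)
        cfg = g.MorletConfig()
        shift = int(0.1 * fs)
        _, _, p1, m1 = g.morlet_tfr(x[:1000], fs=fs)
        _, _, p2, m2 = g.morlet_tfr(x[shift : 1000 + shift], fs=fs)
        step = int(cfg.time_step * fs)
        k = shift // step
        valid = m1[:, k:] & m2[:, :-k]
        a, b = p1[:, k:][valid], p2[:, :-k][valid]
        assert np.allclose(a, b, rtol=1e-9)


@pytest.fixture(scope="module")
def stationary_maps():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((60, 1000))
    ep = TrialEpochs(x, 1000.0)
    times, freqs, p, mask = g.morlet_tfr(ep)
    return times, freqs, p, mask


class TestERSP:
    def test_stationary_input_near_zero_db(self, stationary_maps):
        times, freqs, p, mask = stationary_maps
        m = g.ersp(p, times, freqs, mask)
        assert abs(np.nanmean(m.value)) < 0.5

    def test_global_gain_cancels_exactly(self, stationary_maps):
        times, freqs, p, mask = stationary_maps
        a = g.ersp(p, times, freqs, mask).value
        b = g.ersp(4.0 * p, times, freqs, mask).value  # signal x2 -> power x4
        assert np.nanmax(np.abs(a - b)) == 0.0

    def test_constructed_burst_scores_10db(self):
        # modulated white noise raising 0-100 ms band power 10-fold
        rng = np.random.default_rng(9)
        fs = 1000.0
        tt = -0.4 + np.arange(1000) / fs
        gain = np.where((tt >= 0.02) & (tt < 0.08), 4.0, 1.0)  # window mean power = 10x
        x = rng.standard_normal((60, 1000)) * gain[None, :]
        times, freqs, p, mask = g.morlet_tfr(TrialEpochs(x, fs))
        score = g.evoked_gamma_score(g.ersp(p, times, freqs, mask))
        assert score.value == pytest.approx(10.0, abs=0.5)

    def test_zero_baseline_rejected(self, stationary_maps):
        times, freqs, p, mask = stationary_maps
        with pytest.raises(ValueError, match="baseline"):
            g.ersp(np.zeros_like(p), times, freqs, mask)


class TestScore:
    @staticmethod
    def _flat_map(db_in_window, db_outside=0.0):
        times = np.arange(-0.4, 0.6, 0.002)
        freqs = g.morlet_frequency_grid()
        v = np.full((freqs.size, times.size), db_outside)
        v[:, (times >= 0) & (times < 0.1)] = db_in_window
        return g.ERSPMap(times, freqs, v, np.ones_like(v, dtype=bool))

    def test_zero_map_scores_zero(self):
        assert g.evoked_gamma_score(self._flat_map(0.0)).value == 0.0

    def test_uniform_10db_window_scores_10(self):
        m = self._flat_map(10.0)
        assert g.evoked_gamma_score(m).value == pytest.approx(10.0)
        assert g.evoked_gamma_score(m, db_average=True).value == pytest.approx(10.0)

    def test_baseline_window_scores_zero_by_construction(self, rng):
        x = rng.standard_normal((40, 1000))
        times, freqs, p, mask = g.morlet_tfr(TrialEpochs(x, 1000.0))
        m = g.ersp(p, times, freqs, mask)
        s = g.evoked_gamma_score(m, window=BASELINE_WINDOW)
        assert abs(s.value) < 0.15

    def test_no_valid_cells_rejected(self):
        m = self._flat_map(5.0)
        m.valid_mask[:] = False
        with pytest.raises(ValueError, match="no valid cells"):
            g.evoked_gamma_score(m)


class TestSessionEvoked:
    def test_evoked_gain_monotonicity(self, scaled_design):
        s1 = g.generate_session(scaled_design, g.EffectSpec(evoked_gain=1.0), seed=21)
        s0 = g.generate_session(scaled_design, g.EffectSpec(evoked_gain=0.0), seed=21)
        assert g.session_evoked_score(s1).value > g.session_evoked_score(s0).value

    def test_uses_only_post_injection_prepulse_trials(self, null_session):
        t_inj = null_session.injection_time("injection_nmdar")
        n_post = null_session.prepulse_onsets(after=t_inj).size
        assert g.session_evoked_score(null_session).n_trials == n_post
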