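"""Time-frequency, latency, coherence and Granger statistics."""

import numpy as np
import pytest

from priorclarity import neural, simulate

FS = 250.0


def _sinusoid_trials(freq, n_trials=8, n_samples=500, amp=1.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / FS
    phases = rng.uniform(0, 2 * np.pi, n_trials)[:, None]
    x = amp * np.sin(2 * np.pi * freq * t[None, :] + phases)
    if noise:
        x = x + noise * rng.standard_normal(x.shape)
    return x


class TestMorlet:
    def test_frequency_localisation_and_grid(self):
        tf = neural.morlet_tf(_sinusoid_trials(20.0))
        assert tf.freqs_hz.size == 39
        assert tf.freqs_hz[0] == 4.0 and tf.freqs_hz[-1] == 80.0
        valid_t = tf.valid.all(axis=1)
        peak_bin = tf.power[valid_t].mean(axis=0).argmax()
        assert tf.freqs_hz[peak_bin] == 20.0

    def test_power_scales_quadratically_with_amplitude(self):
        tf1 = neural.morlet_tf(_sinusoid_trials(20.0, amp=1.0))
        tf2 = neural.morlet_tf(_sinusoid_trials(20.0, amp=2.0))
        sel = tf1.valid
        ratio = tf2.power[sel] / tf1.power[sel]
        np.testing.assert_allclose(ratio, 4.0, rtol=1e-6)

    def test_supra_nyquist_rejected(self):
        with pytest.raises(ValueError):
            neural.morlet_tf(_sinusoid_trials(20.0), freqs=np.array([130.0]))

    def test_edge_samples_masked(self):
        tf = neural.morlet_tf(_sinusoid_trials(20.0))
        assert not tf.valid[0].any()  # no frequency has full support at t=0


class TestBaselineRescale:
    def _flat_map(self, value=2.0):
        times = np.arange(0, 1000, 4.0)
        freqs = neural.DEFAULT_FREQS
        return neural.TimeFrequencyMap(
            times, freqs, np.full((times.size, freqs.size), value)
        )

    def test_power_equal_to_baseline_gives_zero(self):
        out = neural.baseline_log_rescale(self._flat_map(), (0, 200))
        np.testing.assert_allclose(out.power, 0.0, atol=1e-12)

    def test_tenfold_power_gives_plus_ten_db(self):
        tf = self._flat_map(1.0)
        tf.power[tf.times_ms >= 500] = 10.0
        out = neural.baseline_log_rescale(tf, (0, 400))
        np.testing.assert_allclose(out.power[out.times_ms >= 500], 10.0)

    def test_double_rescale_rejected(self):
        out = neural.baseline_log_rescale(self._flat_map(), (0, 200))
        with pytest.raises(ValueError):
            neural.baseline_log_rescale(out, (0, 200))


class TestSubtractEvoked:
    def test_residual_condition_means_are_zero(self, rng):
        trials = rng.standard_normal((20, 100)) + np.sin(
            2 * np.pi * 10 * np.arange(100) / FS
        )
        cond = np.repeat([0, 1], 10)
        resid = neural.subtract_evoked(trials, cond)
        for c in (0, 1):
            np.testing.assert_allclose(
                resid[cond == c].mean(axis=0), 0.0, atol=1e-10
            )

    def test_identical_trials_give_zero_residuals(self):
        trials = np.tile(np.sin(np.linspace(0, 10, 50)), (4, 1))
        np.testing.assert_allclose(neural.subtract_evoked(trials), 0.0, atol=1e-12)

    def test_variance_never_increased(self, rng):
        evoked = np.sin(2 * np.pi * 5 * np.arange(200) / FS)
        trials = evoked[None, :] + rng.standard_normal((30, 200))
        resid = neural.subtract_evoked(trials)
        assert resid.var() <= trials.var()

    def test_single_trial_condition_rejected(self, rng):
        with pytest.raises(ValueError):
            neural.subtract_evoked(rng.standard_normal((1, 50)))


class TestBandContrastLatency:
    def _maps(self, contrast):
        times = np.arange(0, 1000.1, 4.0)
        freqs = neural.DEFAULT_FREQS
        band = (freqs >= 12) & (freqs <= 24)
        mm = np.zeros((times.size, freqs.size))
        mm[:, band] = contrast[:, None]
        zero = np.zeros_like(mm)
        kw = dict(times_ms=times, freqs_hz=freqs, rescaled=True)
        return (
            neural.TimeFrequencyMap(power=zero, **kw),
            neural.TimeFrequencyMap(power=mm, **kw),
        )

    def test_linear_ramp_analytic_case(self):
        # zero until 300 ms, linear to peak at 500 ms -> t80 = 300 + 0.8*200
        times = np.arange(0, 1000.1, 4.0)
        contrast = np.clip((times - 300.0) / 200.0, 0.0, 1.0)
        m, mm = self._maps(contrast)
        series = neural.band_contrast_latency(m, mm)
        assert series.t80_ms == pytest.approx(460.0)
        assert series.t80_ms <= series.peak_time_ms

    def test_step_contrast_latency_at_step(self):
        times = np.arange(0, 1000.1, 4.0)
        m, mm = self._maps((times >= 400.0).astype(float))
        assert neural.band_contrast_latency(m, mm).t80_ms == pytest.approx(400.0)

    def test_nonpositive_peak_flagged_undefined(self):
        times = np.arange(0, 1000.1, 4.0)
        m, mm = self._maps(np.full(times.size, -1.0))
        series = neural.band_contrast_latency(m, mm)
        assert not series.defined and series.t80_ms is None

    def test_mismatched_rescaling_rejected(self):
        times = np.arange(0, 1000.1, 4.0)
        m, mm = self._maps(np.ones(times.size))
        m.rescaled = False
        with pytest.raises(ValueError):
            neural.band_contrast_latency(m, mm)

    def test_latency_shift_tracks_onset_delay(self):
        base = 300.0
        lats = []
        for delta in (0.0, 100.0, 248.0):
            m, mm = simulate.simulate_tf_contrast(base + delta, seed=1)
            lats.append(neural.band_contrast_latency(m, mm).t80_ms)
        assert abs((lats[1] - lats[0]) - 100.0) <= 4.0
        assert abs((lats[2] - lats[0]) - 248.0) <= 4.0


class TestMultitaper:
    def test_taper_count_for_study_window(self):
        # T = 0.912 s, W = 4 Hz -> floor(2TW - 1) = 6
        assert neural.multitaper_n_tapers(228, FS, 4.0) == 6

    def test_white_noise_autospectrum_flat(self, rng):
        x = rng.standard_normal((1000, 228))
        y = rng.standard_normal((1000, 228))
        est = neural.multitaper_cross_spectra(x, y)
        sxx = est.cross_spectra[:, :, 0, 0].real.mean(axis=0)
        inner = sxx[(est.freqs_hz > 10) & (est.freqs_hz < 115)]
        assert inner.std() / inner.mean() < 0.1

    def test_hermitian_and_nonnegative(self, rng):
        x = rng.standard_normal((10, 228))
        y = rng.standard_normal((10, 228))
        est = neural.multitaper_cross_spectra(x, y)
        cs = est.cross_spectra
        assert np.all(cs[:, :, 0, 0].real >= 0)
        assert np.all(cs[:, :, 1, 1].real >= 0)
        np.testing.assert_allclose(
            cs[:, :, 0, 1], np.conj(cs[:, :, 1, 0]), atol=1e-12
        )

    def test_sinusoid_peak_within_bandwidth(self):
        x = _sinusoid_trials(18.0, n_trials=20, n_samples=228, noise=0.5)
        y = _sinusoid_trials(18.0, n_trials=20, n_samples=228, noise=0.5, seed=1)
        est = neural.multitaper_cross_spectra(x, y)
        peak = est.freqs_hz[est.cross_spectra[:, :, 0, 0].real.mean(axis=0).argmax()]
        assert abs(peak - 18.0) <= 4.0

    def test_short_window_rejected(self, rng):
        with pytest.raises(ValueError):
            neural.multitaper_cross_spectra(
                rng.standard_normal((5, 100)),
                rng.standard_normal((5, 100)),
                min_freq_hz=2.0,  # one 2 Hz cycle (0.5 s) exceeds the 0.4 s window
            )


class TestImaginaryCoherence:
    def test_zero_lag_identical_signals_near_zero(self, rng):
        common = _sinusoid_trials(18.0, n_trials=60, n_samples=228, seed=3)
        x = common + 0.5 * rng.standard_normal(common.shape)
        y = common + 0.5 * rng.standard_normal(common.shape)
        icoh = neural.imaginary_coherence(neural.multitaper_cross_spectra(x, y))
        assert icoh.max() < 0.15

    def test_invariant_to_added_zero_lag_common_signal(self, rng):
        spec = simulate.CouplingSpec(direction="none")
        src = simulate.simulate_coupled_sources(spec, 60, 7)
        icoh0 = neural.imaginary_coherence(
            neural.multitaper_cross_spectra(src.frontal, src.temporal)
        )
        common = 2.0 * _sinusoid_trials(10.0, 60, 228, seed=8)
        icoh1 = neural.imaginary_coherence(
            neural.multitaper_cross_spectra(src.frontal + common, src.temporal + common)
        )
        # volume-conduction-like mixing does not create spurious coherence
        assert icoh1.max() < 0.2
        assert abs(icoh1.mean() - icoh0.mean()) < 0.05

    def test_quarter_cycle_lag_detected_against_null(self, rng):
        n, fs = 228, FS
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, 60)[:, None]
        tau = 1.0 / (4 * 18.0)
        x = np.sin(2 * np.pi * 18 * t[None, :] + phases) + rng.standard_normal((60, n))
        y = np.sin(2 * np.pi * 18 * (t[None, :] - tau) + phases) + rng.standard_normal(
            (60, n)
        )

        def stat(a, b):
            return neural.imaginary_coherence(neural.multitaper_cross_spectra(a, b))

        obs = stat(x, y)
        _, q = neural.permutation_null(x, y, stat, n_permutations=300, seed=0)
        band = (np.fft.rfftfreq(n, 1 / fs) >= 14) & (np.fft.rfftfreq(n, 1 / fs) <= 22)
        assert (obs[band] > q[band]).all()

    def test_single_trial_rejected(self, rng):
        est = neural.multitaper_cross_spectra(
            rng.standard_normal((1, 228)), rng.standard_normal((1, 228))
        )
        with pytest.raises(ValueError):
            neural.imaginary_coherence(est)


class TestPermutationNull:
    def test_seeded_null_reproducible(self, rng):
        x = rng.standard_normal((20, 228))
        y = rng.standard_normal((20, 228))

        def stat(a, b):
            return neural.imaginary_coherence(neural.multitaper_cross_spectra(a, b))

        _, q1 = neural.permutation_null(x, y, stat, 150, seed=5)
        _, q2 = neural.permutation_null(x, y, stat, 150, seed=5)
        np.testing.assert_array_equal(q1, q2)

    def test_observed_not_in_ensemble(self, rng):
        x = rng.standard_normal((20, 228))
        y = rng.standard_normal((20, 228))

        def stat(a, b):
            return neural.imaginary_coherence(neural.multitaper_cross_spectra(a, b))

        obs = stat(x, y)
        ensemble, _ = neural.permutation_null(x, y, stat, 150, seed=5)
        assert not any(np.allclose(row, obs) for row in ensemble)

    def test_few_permutations_warn(self, rng):
        x = rng.standard_normal((6, 228))
        y = rng.standard_normal((6, 228))
        with pytest.warns(RuntimeWarning):
            neural.permutation_null(
                x, y, lambda a, b: np.zeros(3), n_permutations=50, seed=0
            )


class TestGranger:
    def test_values_nonnegative_everywhere(self, rng):
        src = simulate.simulate_coupled_sources(simulate.CouplingSpec(), 40, 1)
        gc = neural.spectral_granger(src.frontal, src.temporal)
        assert (gc.values["x_to_y"] >= 0).all()
        assert (gc.values["y_to_x"] >= 0).all()

    def test_independent_series_within_null(self):
        """Granger on uncoupled regions stays within its permutation null.

        Per-frequency exceedances are strongly correlated across the
        smooth spectrum, so containment is pooled over independent
        simulations (marginal type-I is ~5% per frequency)."""
        containment = []
        for seed in range(6):
            src = simulate.simulate_coupled_sources(
                simulate.CouplingSpec(direction="none"), 60, seed
            )
            gc = neural.spectral_granger(src.frontal, src.temporal, order=5)

            def stat(a, b):
                return neural.spectral_granger(a, b, order=5).values["x_to_y"]

            _, q = neural.permutation_null(
                src.frontal, src.temporal, stat, 200, seed=seed + 50
            )
            containment.append(np.mean(gc.values["x_to_y"] <= q))
        assert np.mean(containment) >= 0.90

    def test_unstable_var_rejected(self):
        # a random walk has a unit root; pooled VAR fit should flag it
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.standard_normal((5, 500)), axis=1)
        y = np.cumsum(rng.standard_normal((5, 500)), axis=1)
        with pytest.raises(ValueError, match="unstable"):
            neural.spectral_granger(x, y, order=1)


class TestRelativeInfluence:
    def test_flat_spectrum_maps_to_ones(self):
        relative = neural.relative_influence(np.full(30, 3.3))
        np.testing.assert_allclose(relative, 1.0)
        assert relative.shape == (30,)

    def test_mean_exactly_one_and_scale_invariant(self, rng):
        g = rng.random(40) + 0.1
        r1 = neural.relative_influence(g)
        r7 = neural.relative_influence(7.0 * g)
        assert abs(r1.mean() - 1.0) < 1e-9
        np.testing.assert_allclose(r1, r7, rtol=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            neural.relative_influence(np.zeros(10))


class TestDirectionalityContrast:
    def _profiles(self, rng, n_sub=12, n_freq=30, effect=None):
        a = 1.0 + 0.15 * rng.standard_normal((n_sub, n_freq))
        b = 1.0 + 0.15 * rng.standard_normal((n_sub, n_freq))
        if effect is not None:
            a = a + effect[None, :]
        return a, b

    def test_opposite_sign_clusters_recovered(self, rng):
        n_freq = 30
        effect = np.zeros(n_freq)
        effect[2:6] = -0.5  # low-frequency dominance of the other direction
        effect[10:16] = 0.5  # beta-band dominance of this direction
        a, b = self._profiles(rng, effect=effect)
        res = neural.directionality_contrast(a, b, n_permutations=500, seed=0)
        sig = [c for c in res["clusters"] if c["significant"]]
        signs = {np.sign(c["mass"]) for c in sig}
        assert {-1.0, 1.0} <= signs

    def test_symmetric_profiles_rarely_significant(self, rng):
        false_positives = 0
        runs = 40
        for i in range(runs):
            a, b = self._profiles(rng)
            res = neural.directionality_contrast(a, b, n_permutations=200, seed=i)
            if res["significant_mask"].any():
                false_positives += 1
        assert false_positives / runs <= 0.10

    def test_single_frequency_reduces_to_paired_test(self, rng):
        a = rng.standard_normal((15, 1)) + 1.0
        b = rng.standard_normal((15, 1))
        res = neural.directionality_contrast(a, b, n_permutations=500, seed=0)
        from scipy import stats as sps

        t_ref = sps.ttest_rel(a[:, 0], b[:, 0]).statistic
        assert res["t"][0] == pytest.approx(t_ref)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            neural.directionality_contrast(
                rng.standard_normal((2, 10)), rng.standard_normal((2, 10))
            )
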