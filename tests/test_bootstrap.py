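"""Bootstrapped CI bands, the significant-run rule, group comparisons."""

import numpy as np
import pytest

from photobeh.bootstrap import (BootstrapSettings, SignificanceMask,
                                WaveformSummary, bootstrap_ci,
                                compare_waveforms, significant_runs)

RATE = 30.0


def _summary(mean, ci_lo, ci_hi, rate=RATE):
    n = len(mean)
    t = np.arange(n) / rate
    return WaveformSummary(t, np.asarray(mean, float),
                           np.asarray(mean, float),
                           np.asarray(ci_lo, float),
                           np.asarray(ci_hi, float), n_subjects=8)


class TestBootstrapCI:
    def test_identical_waveforms_collapse_band(self):
        w = np.tile(np.sin(np.arange(50) / 5.0), (4, 1))
        s = bootstrap_ci(w, np.arange(50) / RATE, BootstrapSettings(seed=0))
        assert np.allclose(s.ci_lo, w[0], atol=1e-12)
        assert np.allclose(s.ci_hi, w[0], atol=1e-12)
        assert np.allclose(s.mean, w[0])

    def test_expansion_factor_five_fourths_at_n5(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal((5, 20))
        t = np.arange(20) / RATE
        on = bootstrap_ci(w, t, BootstrapSettings(seed=42, expand=True))
        off = bootstrap_ci(w, t, BootstrapSettings(seed=42, expand=False))
        np.testing.assert_allclose(on.boot_mean - on.ci_lo,
                                   1.25 * (off.boot_mean - off.ci_lo))
        np.testing.assert_allclose(on.ci_hi - on.boot_mean,
                                   1.25 * (off.ci_hi - off.boot_mean))

    def test_band_brackets_bootstrap_mean(self):
        rng = np.random.default_rng(8)
        w = rng.standard_normal((7, 60))
        s = bootstrap_ci(w, np.arange(60) / RATE, BootstrapSettings(seed=1))
        assert np.all(s.ci_lo <= s.boot_mean + 1e-12)
        assert np.all(s.ci_hi >= s.boot_mean - 1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        w = rng.standard_normal((6, 30))
        t = np.arange(30) / RATE
        a = bootstrap_ci(w, t, BootstrapSettings(seed=9))
        b = bootstrap_ci(w, t, BootstrapSettings(seed=9))
        assert np.array_equal(a.ci_lo, b.ci_lo)
        c = bootstrap_ci(w, t, BootstrapSettings(seed=10))
        assert not np.array_equal(a.ci_lo, c.ci_lo)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            bootstrap_ci(np.ones((1, 10)), np.arange(10) / RATE,
                         BootstrapSettings())

    def test_coverage_near_nominal_and_improved_by_expansion(self):
        """Monte-Carlo at one time point: 95% band covers the true mean at
        close to nominal rate for n=10; at n=5 the n/(n-1) expansion can
        only raise coverage."""
        n_mc, n_boot = 400, 500
        rng = np.random.default_rng(2024)

        def coverage(n_subj, expand):
            hits = 0
            for _ in range(n_mc):
                x = rng.standard_normal((n_subj, 1))
                s = bootstrap_ci(x, np.zeros(1), BootstrapSettings(
                    n_boot=n_boot, expand=expand, seed=int(
                        rng.integers(2 ** 31))))
                hits += (s.ci_lo[0] <= 0.0 <= s.ci_hi[0])
            return hits / n_mc

        cov10 = coverage(10, True)
        assert 0.90 <= cov10 <= 0.99  # loose gate; tight gate in acceptance
        assert coverage(5, True) >= coverage(5, False) - 0.02


class TestSignificantRuns:
    def test_half_second_excursion_is_one_run(self):
        n = 120
        mean = np.zeros(n)
        lo, hi = np.full(n, -0.1), np.full(n, 0.1)
        mean[30:45] = 0.8     # 15 samples = 0.5 s at 30 Hz
        lo[30:45] = 0.2
        mask = significant_runs(_summary(mean, lo, hi), BootstrapSettings())
        assert len(mask) == 1
        start, end, sign = mask.runs[0]
        assert sign == "+"
        assert end - start == pytest.approx(0.5)

    def test_fifth_of_second_is_no_run(self):
        n = 120
        mean, lo, hi = np.zeros(n), np.full(n, -0.1), np.full(n, 0.1)
        mean[30:36] = 0.8     # 6 samples = 0.2 s < 1/3 s
        lo[30:36] = 0.2
        assert len(significant_runs(_summary(mean, lo, hi),
                                    BootstrapSettings())) == 0

    def test_subthreshold_mean_is_no_run(self):
        n = 120
        mean, lo, hi = np.zeros(n), np.full(n, -0.1), np.full(n, 0.1)
        mean[30:60] = 0.4     # CI excludes 0 but mean below 0.5
        lo[30:60] = 0.2
        assert len(significant_runs(_summary(mean, lo, hi),
                                    BootstrapSettings())) == 0

    def test_negative_runs_detected_with_sign(self):
        n = 120
        mean, lo, hi = np.zeros(n), np.full(n, -0.1), np.full(n, 0.1)
        mean[50:70] = -0.9
        hi[50:70] = -0.2
        mask = significant_runs(_summary(mean, lo, hi), BootstrapSettings())
        assert len(mask) == 1 and mask.runs[0][2] == "-"

    def test_exact_third_of_second_counts(self):
        n = 120
        mean, lo, hi = np.zeros(n), np.full(n, -0.1), np.full(n, 0.1)
        mean[30:40] = 0.8     # exactly 10 samples = 1/3 s at 30 Hz
        lo[30:40] = 0.2
        assert len(significant_runs(_summary(mean, lo, hi),
                                    BootstrapSettings())) == 1

    def test_runs_nonoverlapping_and_long_enough(self):
        rng = np.random.default_rng(77)
        n = 600
        mean = rng.standard_normal(n)
        lo, hi = mean - 0.3, mean + 0.3
        mask = significant_runs(_summary(mean, lo, hi),
                                BootstrapSettings())
        prev_end = -np.inf
        for start, end, _ in mask.runs:
            assert end - start >= 1.0 / 3.0 - 1e-9
            assert start >= prev_end
            prev_end = end


class TestCompareWaveforms:
    def test_paired_identical_groups_empty_mask(self):
        rng = np.random.default_rng(6)
        w = rng.standard_normal((6, 90))
        t = np.arange(90) / RATE
        _, mask = compare_waveforms(w, w.copy(), t, BootstrapSettings(seed=1),
                                    paired=True)
        assert len(mask) == 0

    def test_constant_offset_detected_over_whole_window(self):
        rng = np.random.default_rng(14)
        base = rng.standard_normal((6, 90)) * 0.1
        t = np.arange(90) / RATE
        _, mask = compare_waveforms(base + 2.0, base, t,
                                    BootstrapSettings(seed=3), paired=True)
        assert len(mask) == 1
        start, end, sign = mask.runs[0]
        assert sign == "+" and start == 0.0
        assert end == pytest.approx(90 / RATE)

    def test_paired_mismatched_subjects_rejected(self):
        t = np.arange(10) / RATE
        with pytest.raises(ValueError, match="matched"):
            compare_waveforms(np.ones((4, 10)), np.ones((5, 10)), t,
                              BootstrapSettings(), paired=True)

    def test_unpaired_same_distribution_rarely_significant(self):
        """Type-I control: the mean fraction of time marked significant for
        two groups from one process stays at or below 2*alpha."""
        rng = np.random.default_rng(100)
        n_sim, n, T = 60, 8, 90
        t = np.arange(T) / RATE
        settings = BootstrapSettings(n_boot=300, seed=0)
        frac = []
        for k in range(n_sim):
            a = rng.standard_normal((n, T))
            b = rng.standard_normal((n, T))
            _, mask = compare_waveforms(
                a, b, t, settings, paired=False,
                rng=np.random.default_rng(k + 1))
            frac.append(mask.total_duration_s() / (T / RATE))
        assert np.mean(frac) <= 2 * settings.alpha

    def test_no_magnitude_threshold_on_differences(self):
        # a 0.3-z offset (below the 0.5 vs-zero threshold) must still be
        # detectable between conditions
        rng = np.random.default_rng(21)
        base = rng.standard_normal((8, 60)) * 0.05
        t = np.arange(60) / RATE
        _, mask = compare_waveforms(base + 0.3, base, t,
                                    BootstrapSettings(seed=5), paired=True)
        assert len(mask) == 1


class TestPowerMonotonicity:
    def test_detection_probability_grows_with_amplitude(self):
        rng = np.random.default_rng(55)
        T = 60
        t = np.arange(T) / RATE
        bump = np.zeros(T)
        bump[20:40] = 1.0
        settings = BootstrapSettings(n_boot=300, seed=0)

        def detect_rate(amp, n_subj=8, n_sim=40):
            hits = 0
            for k in range(n_sim):
                w = amp * bump + rng.standard_normal((n_subj, T)) * 0.4
                s = bootstrap_ci(w, t, settings,
                                 rng=np.random.default_rng(1000 + k))
                hits += len(significant_runs(s, settings)) > 0
            return hits / n_sim

        rates = [detect_rate(a) for a in (0.0, 0.6, 1.5)]
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9
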