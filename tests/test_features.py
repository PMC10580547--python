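import numpy as np
import pytest

from motorage.features import (
    ParamConfig,
    all_feature_names,
    amplitude_features,
    approximate_entropy,
    compute_parameters,
    extract_feature_matrix,
    fuzzy_entropy,
    spectral_features,
    statistical_features,
    zero_crossings,
)

FS = 50.0


# --- independent naive oracles (direct transcription of the definitions) ---


def apen_oracle(x, m=2, r_coeff=0.2):
    x = np.asarray(x, float)
    n = len(x)
    r = r_coeff * np.std(x)

    def phi(mm):
        size = n - mm + 1
        emb = [x[i : i + mm] for i in range(size)]
        total = 0.0
        for i in range(size):
            c = sum(1 for j in range(size) if np.max(np.abs(emb[i] - emb[j])) <= r)
            total += np.log(c / size)
        return total / size

    return phi(m) - phi(m + 1)


def fuzzyen_oracle(x, m=2, r_coeff=0.2, gradient=2):
    x = np.asarray(x, float)
    n = len(x)
    r = r_coeff * np.std(x)
    size = n - m

    def phi(mm):
        emb = [x[i : i + mm] - np.mean(x[i : i + mm]) for i in range(size)]
        total = 0.0
        for i in range(size):
            s = sum(
                np.exp(-((np.max(np.abs(emb[i] - emb[j])) / r) ** gradient))
                for j in range(size)
                if j != i
            )
            total += s / (size - 1)
        return total / size

    return np.log(phi(m)) - np.log(phi(m + 1))


# --------------------------------------------------------------------------


class TestAmplitude:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1, -1, 1, -1], dict(MAV=1, MAVFD=2, MAVSD=0, RMS=1, Peak=1)),
            ([0, 0, 0, 0], dict(MAV=0, MAVFD=0, MAVSD=0, RMS=0, Peak=0)),
            ([2, -2, 2, -2, 2], dict(MAV=2, MAVFD=4, MAVSD=0, RMS=2, Peak=2)),
        ],
    )
    def test_examples(self, x, expected):
        got = amplitude_features(np.array(x, float))
        for k, v in expected.items():
            assert got[k] == pytest.approx(v), k

    def test_all_negative_series_has_zero_peak(self):
        assert amplitude_features(np.array([-3.0, -1.0, -2.0]))["Peak"] == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            amplitude_features(np.array([1.0, 2.0]))


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1, -1, 1, -1], 3),
            ([1, 2, 3, 4], 0),
            ([1, 0, -1], 0),  # exact zeros block the strict rule
            ([-1, 1], 1),
        ],
    )
    def test_strict_rule(self, x, expected):
        assert zero_crossings(np.array(x, float)) == expected


class TestSpectral:
    CFG = ParamConfig(psd_method="periodogram")

    def test_pure_tone_peak_and_median(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        got = spectral_features(x, FS, self.CFG)
        assert got["FPeak"] == pytest.approx(5.0)
        assert got["F50"] == pytest.approx(5.0)

    def test_pure_tone_band_power_fraction(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        from motorage.features import power_spectrum

        f, P = power_spectrum(x, FS, self.CFG)
        got = spectral_features(x, FS, self.CFG)
        assert got["Power3.5_7.5"] / P.sum() > 0.99

    def test_white_noise_mean_frequency_is_half_nyquist(self, rng):
        x = rng.normal(size=5000)
        got = spectral_features(x, FS, self.CFG)
        assert got["FMean"] == pytest.approx(12.5, rel=0.05)

    def test_degenerate_zero_signal(self):
        got = spectral_features(np.zeros(128), FS, self.CFG)
        assert all(v == 0.0 for v in got.values())

    def test_welch_and_periodogram_agree_on_peak(self, rng):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 6.0 * t) + 0.1 * rng.normal(size=t.size)
        welch = spectral_features(x, FS, ParamConfig(psd_method="welch"))
        per = spectral_features(x, FS, self.CFG)
        assert welch["FPeak"] == pytest.approx(per["FPeak"], abs=0.3)


class TestStatistical:
    def test_symmetric_series(self):
        got = statistical_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert got["VAR"] == pytest.approx(5.0)  # raw sum of squared deviations
        assert got["RANGE"] == pytest.approx(3.0)
        assert got["SKEWNESS"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_kurtosis_population_convention(self):
        got = statistical_features(np.array([1.0, 1.0, 3.0, 3.0]))
        assert got["KURTOSIS"] == pytest.approx(1.0)

    def test_interquartile_linear_interpolation(self):
        got = statistical_features(np.arange(1.0, 9.0))
        assert got["INTQ"] == pytest.approx(6.25 - 2.75)

    def test_sample_variance_switch(self):
        got = statistical_features(
            np.array([1.0, 2.0, 3.0, 4.0]), ParamConfig(variance_mode="sample")
        )
        assert got["VAR"] == pytest.approx(5.0 / 3.0)

    def test_constant_series_moments_flagged_zero(self):
        got = statistical_features(np.full(10, 7.0))
        assert got["SKEWNESS"] == 0.0 and got["KURTOSIS"] == 0.0


class TestEntropies:
    def test_constant_series_is_perfectly_predictable(self):
        assert approximate_entropy(np.full(100, 3.14)) == 0.0
        assert fuzzy_entropy(np.full(100, 3.14)) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("n", [15, 20, 30])
    def test_match_naive_oracles(self, seed, n):
        x = np.random.default_rng(seed).normal(size=n)
        assert approximate_entropy(x) == pytest.approx(apen_oracle(x), abs=1e-10)
        assert fuzzy_entropy(x) == pytest.approx(fuzzyen_oracle(x), abs=1e-10)

    def test_alternation_more_regular_than_noise(self):
        alt = np.tile([1.0, 2.0], 30)
        noise = np.random.default_rng(3).normal(size=60)
        assert approximate_entropy(alt) < approximate_entropy(noise)

    def test_noise_less_regular_than_sine(self):
        t = np.arange(200) / FS
        sine = np.sin(2 * np.pi * 5.0 * t)
        noise = np.random.default_rng(4).normal(size=200)
        assert fuzzy_entropy(noise) > fuzzy_entropy(sine)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.arange(4.0))


class TestScaleBehaviour:
    """MAV/RMS/Peak/RANGE scale linearly; the rest are scale-invariant."""

    @pytest.mark.parametrize("a", [2.0, 17.5])
    def test_equivariance_and_invariance(self, a, rng):
        x = rng.normal(size=300) + 0.2
        base = compute_parameters(x, FS)
        scaled = compute_parameters(a * x, FS)
        for k in ("MAV", "MAVFD", "MAVSD", "RMS", "Peak", "RANGE"):
            assert scaled[k] == pytest.approx(a * base[k], rel=1e-9), k
        for k in ("ZC", "FPeak", "F50", "F80", "SKEWNESS", "KURTOSIS", "ApEn", "FuzzyEn"):
            assert scaled[k] == pytest.approx(base[k], rel=1e-6, abs=1e-9), k

    def test_fuzz_all_parameters_finite(self):
        rng = np.random.default_rng(99)
        for _ in range(150):
            x = rng.normal(scale=rng.uniform(0.01, 10), size=128) + rng.uniform(-1, 1)
            vals = compute_parameters(x, FS)
            assert all(np.isfinite(v) for v in vals.values())


class TestExtraction:
    def test_full_grid_shape_and_names(self, small_extraction):
        names = all_feature_names()
        assert len(names) == 324
        assert list(small_extraction.trial_features.columns) == names

    def test_identical_recording_gives_identical_vector(self, small_cohort):
        cfg = ParamConfig()
        part = small_cohort.participants[0]
        t = part.trial_signal(1, 1, "A1")
        from motorage.preprocess import preprocess_trial

        r = preprocess_trial(t)
        v1 = compute_parameters(r.values, r.fs, cfg)
        v2 = compute_parameters(r.values.copy(), r.fs, cfg)
        assert v1 == v2

    def test_zero_recording_amplitude_features_zero(self):
        vals = compute_parameters(np.zeros(300), FS)
        for k in ("MAV", "RMS", "Peak", "VAR", "RANGE", "ApEn", "FuzzyEn"):
            assert vals[k] == 0.0
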