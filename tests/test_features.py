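import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neohrv import (
    EntropyParams,
    RRSeries,
    approximate_entropy,
    coarse_grain,
    correlation_dimension,
    distribution_entropy,
    extract_features,
    feature_names,
    frequency_domain,
    geometric,
    multiscale,
    poincare,
    sample_entropy,
    time_domain,
)
from neohrv._bruteforce import (
    approximate_entropy_naive,
    distribution_entropy_naive,
    sample_entropy_naive,
)
from neohrv.features import TRI_BIN_MS


def rr_from_ms(rr_ms, start=0.0):
    return RRSeries(start + np.concatenate([[0.0], np.cumsum(rr_ms)]) / 1000.0)


class TestTimeDomain:
    def test_constant_rr(self):
        out = time_domain(rr_from_ms([500.0] * 4))
        assert out["SDNN"] == 0 and out["RMSSD"] == 0 and out["pNN50"] == 0
        assert out["HR"] == pytest.approx(120.0)

    def test_alternating_rr(self):
        out = time_domain(rr_from_ms([800.0, 900.0, 800.0, 900.0]))
        assert out["pNN50"] == 100.0
        assert out["RMSSD"] == pytest.approx(100.0)

    def test_sample_sd_denominator(self):
        out = time_domain(rr_from_ms([700.0, 800.0, 900.0]))
        assert out["SDNN"] == pytest.approx(100.0)   # n-1 denominator

    def test_short_input_missing(self):
        out = time_domain(rr_from_ms([700.0, 800.0]))
        assert all(np.isnan(v) for v in out.values())


class TestGeometric:
    def test_identical_rr_tri_is_one(self):
        out = geometric(rr_from_ms([500.0] * 25))
        assert out["TRI"] == 1.0
        assert out["TINN"] == pytest.approx(TRI_BIN_MS)

    def test_uniform_histogram_tri_equals_bin_count(self):
        # 5 bins x 8 counts, values centered in distinct bins
        vals = np.repeat(500.0 + TRI_BIN_MS * np.arange(5) + TRI_BIN_MS / 2, 8)
        out = geometric(rr_from_ms(vals))
        assert out["TRI"] == pytest.approx(5.0)

    def test_tinn_recovers_triangular_support(self):
        # symmetric triangular histogram over 9 bins
        counts = [1, 2, 3, 4, 5, 4, 3, 2, 1]
        vals = np.concatenate([
            np.full(c, 500.0 + TRI_BIN_MS * (i + 0.5))
            for i, c in enumerate(counts)
        ])
        out = geometric(rr_from_ms(vals))
        support = 9 * TRI_BIN_MS
        assert abs(out["TINN"] - support) <= 2 * TRI_BIN_MS

    def test_short_input_missing(self):
        out = geometric(rr_from_ms([500.0] * 10))
        assert np.isnan(out["TRI"]) and np.isnan(out["TINN"])


class TestPoincare:
    def test_constant_series(self):
        out = poincare(rr_from_ms([500.0] * 10))
        assert out["SD2"] == 0.0 and np.isnan(out["SD1SD2ratio"])

    def test_alternating_series_dominated_by_sd1(self):
        rr = np.tile([700.0, 900.0], 50)
        out = poincare(rr_from_ms(rr))
        # direct oracle: project successive pairs on/off the identity line
        pairs = np.column_stack([rr[:-1], rr[1:]])
        along = (pairs[:, 0] + pairs[:, 1]) / np.sqrt(2)
        across = (pairs[:, 1] - pairs[:, 0]) / np.sqrt(2)
        assert out["SD1SD2ratio"] > 5.0
        assert np.std(across, ddof=1) / np.std(along, ddof=1) > 5.0

    def test_white_noise_ratio_near_one(self, rng):
        rr = rng.normal(600.0, 30.0, size=500)
        out = poincare(rr_from_ms(rr))
        assert out["SD1SD2ratio"] == pytest.approx(1.0, abs=0.1)


class TestCorrelationDimension:
    def test_sinusoidal_rr_is_one_dimensional(self):
        rr = 600.0 + 50.0 * np.sin(2 * np.pi * 0.03 * np.arange(400))
        cd = correlation_dimension(rr_from_ms(rr))
        assert cd == pytest.approx(1.0, abs=0.2)

    def test_iid_uniform_fills_the_plane(self, rng):
        rr = rng.uniform(500.0, 700.0, size=400)
        cd = correlation_dimension(rr_from_ms(rr))
        assert cd == pytest.approx(2.0, abs=0.3)

    def test_constant_series_missing(self):
        assert np.isnan(correlation_dimension(rr_from_ms([500.0] * 200)))


class TestFrequencyDomain:
    def test_pure_lf_tone_concentrates_power(self):
        t = np.arange(0, 180, 0.45)
        rr_ms = 450.0 + 20.0 * np.sin(2 * np.pi * 0.1 * t)
        rr = RRSeries(np.concatenate([[0.0], np.cumsum(rr_ms)]) / 1000.0)
        out = frequency_domain(rr, 0.0, 180.0)
        assert out["pLF"] >= 95.0

    def test_band_partition_sums(self, rng):
        rr_ms = rng.normal(450.0, 25.0, size=400)
        rr = rr_from_ms(rr_ms)
        out = frequency_domain(rr, 0.0, float(rr.peak_times_s[-1]) + 0.5)
        assert out["VLF"] + out["LF"] + out["HF"] == pytest.approx(out["TotalPower"], rel=1e-12)
        assert out["pLF"] + out["pHF"] == pytest.approx(100.0, abs=1e-9)
        assert min(out["VLF"], out["LF"], out["HF"]) >= 0.0

    def test_constant_rr_zero_power(self):
        out = frequency_domain(rr_from_ms([500.0] * 200), 0.0, 100.0)
        assert out["TotalPower"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(out["LFHFratio"])


class TestEntropies:
    def test_constant_series(self):
        x = np.full(30, 5.0)
        assert sample_entropy(x, 2, 0.5) == 0.0
        assert approximate_entropy(x, 2, 0.5) == 0.0
        assert distribution_entropy(x, 2, 1, 512) == 0.0

    def test_alternating_series_matches_bruteforce(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        assert sample_entropy(x, 2, 0.5) == pytest.approx(
            sample_entropy_naive(x, 2, 0.5), abs=1e-12)

    def test_too_short_series_missing(self):
        assert np.isnan(sample_entropy(np.arange(3.0), 2, 0.5))
        assert np.isnan(approximate_entropy(np.arange(3.0), 2, 0.5))
        assert np.isnan(distribution_entropy(np.arange(2.0), 2))

    def test_distribution_entropy_uniform_bins(self):
        # pairwise distances {1,1,1,2,2,3} split 3/3 over two bins
        assert distribution_entropy(np.array([0.0, 1.0, 2.0, 3.0]), m=1, n_bins=2) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_series_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(12, 40)))
        r = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(x, 2, r) == pytest.approx(
            sample_entropy_naive(x, 2, r), abs=1e-12, nan_ok=True)
        assert approximate_entropy(x, 2, r) == pytest.approx(
            approximate_entropy_naive(x, 2, r), abs=1e-12)
        assert distribution_entropy(x, 2, 1, 64) == pytest.approx(
            distribution_entropy_naive(x, 2, 1, 64), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-50, 50), st.floats(0.1, 10))
    def test_translation_and_scale_behavior(self, seed, shift, scale):
        """Entropies ignore additive shifts; with r proportional to the SD,
        SampEn also ignores positive rescaling."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60)
        r = 0.2 * np.std(x, ddof=1)
        base = sample_entropy(x, 2, r)
        assert sample_entropy(x + shift, 2, r) == pytest.approx(base, abs=1e-9, nan_ok=True)
        assert sample_entropy(x * scale, 2, r * scale) == pytest.approx(base, abs=1e-9, nan_ok=True)
        assert distribution_entropy(x + shift, 2) == pytest.approx(
            distribution_entropy(x, 2), abs=1e-9)


class TestMultiscale:
    def test_coarse_grain(self):
        assert np.array_equal(coarse_grain([1, 3, 5, 7], 2), [2.0, 6.0])
        x = np.arange(7.0)
        assert np.array_equal(coarse_grain(x, 1), x)
        assert coarse_grain(x, 3).size == 2
        with pytest.raises(ValueError):
            coarse_grain(x, 0)

    def test_scale_one_identity(self, rng):
        x = rng.normal(size=150)
        params = EntropyParams(scales=(1,), min_points=100)
        r = 0.2 * np.std(x, ddof=1)
        assert multiscale(x, "SampEn", params)[1] == sample_entropy(x, 2, r)
        assert multiscale(x, "DistEn", params)[1] == distribution_entropy(x, 2, 1, 512)

    def test_mde_bounded(self, rng):
        x = rng.normal(size=450)
        out = multiscale(x, "DistEn", EntropyParams())
        for v in out.values():
            assert 0.0 <= v <= 1.0

    def test_short_scale_missing(self, rng):
        x = rng.normal(size=90)
        out = multiscale(x, "SampEn", EntropyParams(scales=(1,)))
        assert np.isnan(out[1])


class TestAssembly:
    def test_empty_rr_all_missing(self):
        out = extract_features(RRSeries(np.empty(0)), 180.0, 0.0, 180.0)
        assert len(out) == 26 and all(np.isnan(v) for v in out.values())

    @pytest.mark.parametrize("L,n", [(60.0, 20), (180.0, 26)])
    def test_field_counts(self, L, n, rng):
        assert len(feature_names(L)) == n
        rr = rr_from_ms(rng.normal(450, 20, size=int(L / 0.45)))
        out = extract_features(rr, L, 0.0, L)
        assert list(out) == feature_names(L)

    def test_realistic_epoch_mostly_defined(self, rng):
        rr = rr_from_ms(rng.normal(430.0, 20.0, size=418))
        out = extract_features(rr, 180.0, 0.0, 180.0)
        missing = [k for k, v in out.items() if not np.isfinite(v)]
        assert missing == []
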