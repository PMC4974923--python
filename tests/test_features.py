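"""The 114-feature descriptor: moments, correlation, spectrum, assembly."""
import numpy as np
import pytest

import emogait as eg
from emogait.errors import DegenerateFeatureError, LengthError
from emogait import features as ft

from .conftest import make_recording
from .oracles import (
    naive_correlation,
    naive_dft,
    naive_kurtosis,
    naive_psd_summary,
    naive_skewness,
    naive_std,
)


class TestMoments:
    def test_symmetric_sample_has_zero_skewness(self):
        assert ft.skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_binary_sample(self):
        # [0,0,0,1]: m2=3/16, m3=3/32, m4=...; frozen from the direct formula
        assert ft.skewness([0, 0, 0, 1]) == pytest.approx(naive_skewness([0, 0, 0, 1]))
        assert ft.skewness([0, 0, 0, 1]) == pytest.approx(1.1547005383792517)
        assert ft.kurtosis([0, 0, 0, 1]) == pytest.approx(naive_kurtosis([0, 0, 0, 1]))
        assert ft.kurtosis([0, 0, 0, 1]) == pytest.approx(2.3333333333333335)

    def test_two_point_symmetric_kurtosis_is_one(self):
        assert ft.kurtosis([-1.0, 1.0]) == pytest.approx(1.0)

    def test_population_std_of_two_points(self):
        assert ft.standard_deviation([0.0, 2.0]) == pytest.approx(1.0)
        assert ft.standard_deviation(np.full(10, 3.3)) == 0.0

    def test_translation_and_scale_invariance(self, rng):
        x = rng.normal(size=60)
        a, c = 2.7, -13.0
        assert ft.skewness(x + c) == pytest.approx(ft.skewness(x), abs=1e-9)
        assert ft.kurtosis(a * x) == pytest.approx(ft.kurtosis(x), rel=1e-9)
        assert ft.standard_deviation(a * x) == pytest.approx(a * ft.standard_deviation(x))

    def test_matches_direct_formula_oracles(self, rng):
        """Population moments, divisor n, no bias correction — 100 draws."""
        for _ in range(100):
            n = int(rng.integers(4, 200))
            x = rng.normal(loc=rng.normal(scale=5), scale=rng.uniform(0.1, 10), size=n)
            assert ft.skewness(x) == pytest.approx(naive_skewness(list(x)), abs=1e-9)
            assert ft.kurtosis(x) == pytest.approx(naive_kurtosis(list(x)), rel=1e-9)
            assert ft.standard_deviation(x) == pytest.approx(naive_std(list(x)), rel=1e-12)

    def test_zero_variance_raises_degenerate(self):
        for fn in (ft.skewness, ft.kurtosis):
            with pytest.raises(DegenerateFeatureError):
                fn(np.ones(16))


class TestCorrelation:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.normal(size=50)
        assert ft.axis_correlation(x, x) == pytest.approx(1.0)
        assert ft.axis_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_covariance_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 150))
            a = rng.normal(size=n)
            b = rng.normal(size=n) + 0.5 * a
            got = ft.axis_correlation(a, b)
            assert -1.0 <= got <= 1.0
            assert got == pytest.approx(naive_correlation(list(a), list(b)), abs=1e-9)

    def test_constant_axis_raises_degenerate(self, rng):
        with pytest.raises(DegenerateFeatureError):
            ft.axis_correlation(np.ones(10), rng.normal(size=10))


class TestSpectrum:
    def test_constant_signal_is_dc_only(self):
        amps = ft.fft_amplitudes(np.full(128, 2.5))
        assert amps[0] == pytest.approx(128 * 2.5)
        assert np.allclose(amps[1:], 0.0, atol=1e-9)

    def test_pure_cosine_concentrates_at_its_bin(self):
        t = np.arange(128)
        x = 3.0 * np.cos(2 * np.pi * 5 * t / 128)
        amps = ft.fft_amplitudes(x)
        assert amps[5] == pytest.approx(3.0 * 128 / 2, rel=1e-9)
        others = np.delete(amps, 5)
        assert np.all(others < 1e-8)

    def test_wrong_length_rejected(self):
        with pytest.raises(LengthError):
            ft.fft_amplitudes(np.zeros(100))

    def test_matches_naive_dft_oracle(self, rng):
        """First 32 moduli of the O(n^2) direct-summation DFT."""
        for _ in range(20):
            x = rng.normal(scale=rng.uniform(0.1, 5), size=128)
            want = np.abs(naive_dft(x)[:32])
            got = ft.fft_amplitudes(x)
            assert np.allclose(got, want, rtol=1e-6)

    def test_parseval_on_the_full_transform(self, rng):
        x = rng.normal(size=128)
        spectrum = naive_dft(x)
        assert np.sum(np.abs(spectrum) ** 2) == pytest.approx(
            128 * np.sum(x**2), rel=1e-6
        )
        # the 32 retained amplitudes are a prefix of that verified spectrum
        assert np.allclose(ft.fft_amplitudes(x), np.abs(spectrum[:32]), rtol=1e-6)


class TestPsd:
    def test_zero_signal(self):
        assert ft.psd_summary(np.zeros(128), 5.0) == (0.0, 0.0)

    def test_constant_signal_closed_form(self):
        # only the DC bin is nonzero: P0 = (n c)^2/(n fs); 65 one-sided bins
        c, n, fs = 1.7, 128, 5.0
        p0 = (n * c) ** 2 / (n * fs)
        mean, std = ft.psd_summary(np.full(n, c), fs)
        assert mean == pytest.approx(p0 / 65, rel=1e-12)
        assert std == pytest.approx(np.sqrt(p0**2 / 65 - (p0 / 65) ** 2), rel=1e-9)

    def test_matches_naive_periodogram_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=128)
            want_mean, want_std = naive_psd_summary(x, 5.0)
            got_mean, got_std = ft.psd_summary(x, 5.0)
            assert got_mean == pytest.approx(want_mean, rel=1e-6)
            assert got_std == pytest.approx(want_std, rel=1e-6)


class TestExtractFeatures:
    @pytest.fixture
    def seg(self, rng):
        rec = make_recording(rng.normal(scale=2.0, size=(300, 3)))
        return eg.segment(rec)[0]

    def test_vector_has_114_named_entries_in_fixed_order(self, seg):
        fv = eg.extract_features(seg)
        assert len(fv) == 114 == 38 * 3
        assert fv.names == eg.FEATURE_NAMES
        assert fv.names[0] == "x_skewness"
        assert fv.names[38] == "y_skewness"
        assert fv.names[-1] == "z_fft_31"
        assert np.all(np.isfinite(fv.values))

    def test_extraction_is_deterministic(self, seg):
        a = eg.extract_features(seg)
        b = eg.extract_features(seg)
        assert np.array_equal(a.values, b.values)

    def test_correlation_slot_mapping(self, rng):
        """x-slot = corr(x,y), y-slot = corr(y,z), z-slot = corr(x,z)."""
        data = rng.normal(size=(128, 3))
        data[:, 1] = data[:, 0]  # y == x
        rec = make_recording(data)
        fv = eg.extract_features(eg.segment(rec)[0])
        vals = dict(zip(fv.names, fv.values))
        assert vals["x_correlation"] == pytest.approx(1.0)
        assert vals["y_correlation"] == pytest.approx(
            naive_correlation(list(data[:, 1]), list(data[:, 2])), abs=1e-9
        )
        assert vals["z_correlation"] == pytest.approx(
            naive_correlation(list(data[:, 0]), list(data[:, 2])), abs=1e-9
        )

    def test_constant_axis_maps_degenerate_features_to_zero(self, rng, caplog):
        data = rng.normal(size=(128, 3))
        data[:, 0] = 4.0  # constant x channel
        rec = make_recording(data)
        with caplog.at_level("WARNING"):
            fv = eg.extract_features(eg.segment(rec)[0])
        vals = dict(zip(fv.names, fv.values))
        assert vals["x_skewness"] == 0.0
        assert vals["x_kurtosis"] == 0.0
        assert vals["x_correlation"] == 0.0  # corr(x, y) with constant x
        assert vals["x_std"] == 0.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_scale_behaviour_per_axis(self, rng):
        """x -> a*x: shape stats invariant, sigma and |X_k| scale by a, PSD by a^2."""
        data = rng.normal(size=(128, 3))
        a = 3.0
        fv1 = eg.extract_features(eg.segment(make_recording(data))[0])
        fv2 = eg.extract_features(eg.segment(make_recording(a * data))[0])
        v1 = dict(zip(fv1.names, fv1.values))
        v2 = dict(zip(fv2.names, fv2.values))
        for axis in "xyz":
            assert v2[f"{axis}_skewness"] == pytest.approx(v1[f"{axis}_skewness"], abs=1e-9)
            assert v2[f"{axis}_kurtosis"] == pytest.approx(v1[f"{axis}_kurtosis"], rel=1e-9)
            assert v2[f"{axis}_correlation"] == pytest.approx(
                v1[f"{axis}_correlation"], abs=1e-9
            )
            assert v2[f"{axis}_std"] == pytest.approx(a * v1[f"{axis}_std"], rel=1e-9)
            assert v2[f"{axis}_psd_mean"] == pytest.approx(
                a**2 * v1[f"{axis}_psd_mean"], rel=1e-9
            )
            for k in range(32):
                assert v2[f"{axis}_fft_{k:02d}"] == pytest.approx(
                    a * v1[f"{axis}_fft_{k:02d}"], rel=1e-9, abs=1e-9
                )
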