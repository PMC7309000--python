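"""Feature bank: hand-computed statistics, spectral oracles, entropy closed
forms, asymmetry ratios, wavelet energy conservation and matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegfsel import (
    BandSpec,
    DEFAULT_BANDS,
    Montage,
    SynthSpec,
    band_power,
    differential_entropy,
    extract_all,
    feature_count,
    generate_synthetic_trials,
    rasm_features,
    statistical_features,
    wavelet_features,
)


class TestStatistical:
    def test_hand_computed_example(self):
        f = statistical_features(np.array([1.0, 2.0, 3.0, 4.0]))
        sigma = np.sqrt(1.25)
        assert f.mean == pytest.approx(2.5)
        assert f.std == pytest.approx(sigma)          # population (1/N) convention
        assert f.mean_abs_diff1 == pytest.approx(1.0)
        assert f.norm_mean_abs_diff1 == pytest.approx(1.0 / sigma)
        assert f.mean_abs_diff2 == pytest.approx(2.0)
        assert f.norm_mean_abs_diff2 == pytest.approx(2.0 / sigma)

    def test_constant_signal_degenerates_to_zero(self):
        f = statistical_features(np.full(10, 3.0))
        assert f.mean == 3.0
        assert f.std == f.mean_abs_diff1 == f.mean_abs_diff2 == 0.0
        assert f.norm_mean_abs_diff1 == f.norm_mean_abs_diff2 == 0.0

    def test_shift_invariance_of_differences(self):
        x = np.random.default_rng(0).standard_normal(100)
        a, b = statistical_features(x), statistical_features(x + 10)
        assert b.mean == pytest.approx(a.mean + 10)
        for attr in ("std", "mean_abs_diff1", "norm_mean_abs_diff1",
                     "mean_abs_diff2", "norm_mean_abs_diff2"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            statistical_features(np.array([1.0, 2.0]))


class TestBandPower:
    def test_alpha_tone_lands_in_alpha(self):
        t = np.arange(128 * 8) / 128
        x = np.sin(2 * np.pi * 10 * t)
        p = band_power(x, 128, DEFAULT_BANDS)
        assert p[1] / p.sum() >= 0.90  # alpha share of the 4-50 Hz bank

    def test_white_noise_parseval_partition(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(128 * 16) * 2.0
        edges = np.linspace(0.5, 63.5, 8)
        bands = tuple(
            BandSpec(f"b{i}", edges[i], edges[i + 1]) for i in range(len(edges) - 1)
        )
        # pad partition to [0, fs/2) with explicit end bands via total variance
        p = band_power(x, 128, bands)
        total = np.var(x)
        # the partition covers [0.5, 63.5) of [0, 64): compare within 10%
        assert p.sum() == pytest.approx(total, rel=0.10)

    def test_zero_signal_zero_power(self):
        assert (band_power(np.zeros(1024), 128) == 0).all()

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(1024), 64, DEFAULT_BANDS)


class TestDifferentialEntropy:
    def test_unit_band_variance_matches_numerical_integral(self):
        """Closed form 0.5*ln(2*pi*e) vs numerical -integral(p ln p) for N(0,1)."""
        from scipy import integrate, stats

        rng = np.random.default_rng(2)
        x = rng.standard_normal(128 * 16)
        de = differential_entropy(x, 128)[1]  # alpha band of broadband noise
        # scale so alpha-band variance is 1: DE is shift-equivariant in ln sigma
        var = np.exp(2 * de) / (2 * np.pi * np.e)
        x_scaled = x / np.sqrt(var)
        de1 = differential_entropy(x_scaled, 128)[1]
        pdf = stats.norm(0, 1).pdf
        oracle, _ = integrate.quad(lambda v: -pdf(v) * np.log(pdf(v)), -12, 12)
        assert abs(de1 - oracle) < 1e-3

    def test_reference_variance_gives_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(128 * 8)
        de = differential_entropy(x, 128)
        var0 = np.exp(2 * de[0]) / (2 * np.pi * np.e)
        x_scaled = x * np.sqrt(1 / (2 * np.pi * np.e) / var0)
        assert differential_entropy(x_scaled, 128)[0] == pytest.approx(0.0, abs=1e-9)

    def test_amplitude_doubling_adds_ln2(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(128 * 8)
        d1 = differential_entropy(x, 128)
        d2 = differential_entropy(2 * x, 128)
        np.testing.assert_allclose(d2 - d1, np.log(2), atol=1e-9)

    def test_zero_signal_sentinel(self):
        de = differential_entropy(np.zeros(1024), 128)
        assert (de == -np.inf).all()


class TestRASM:
    @pytest.fixture()
    def montage(self):
        return Montage(["F3", "F4"], [("F3", "F4")])

    def test_identical_hemispheres_give_unity(self, montage):
        x = np.random.default_rng(5).standard_normal(128 * 4)
        trial = np.vstack([x, x])
        r = rasm_features(trial, 128, montage)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_default_montage_yields_28_values(self, montage_trials):
        m = Montage.for_labels(montage_trials.channel_labels)
        assert len(m.asymmetry_pairs) == 7
        r = rasm_features(montage_trials.trials[0], montage_trials.fs, m)
        assert r.shape == (28,)

    def test_swapping_sides_gives_reciprocal(self, montage):
        rng = np.random.default_rng(6)
        trial = rng.standard_normal((2, 128 * 4))
        fwd = rasm_features(trial, 128, montage)
        swapped = Montage(["F3", "F4"], [("F4", "F3")])
        rev = rasm_features(trial, 128, swapped)
        np.testing.assert_allclose(rev, 1.0 / fwd, rtol=1e-10)

    def test_missing_pair_channel_named(self):
        with pytest.raises(ValueError, match="F7-F8"):
            Montage(["F3", "F4"], [("F7", "F8")])


class TestWavelet:
    def test_zero_signal_zero_features(self):
        ent, eng = wavelet_features(np.zeros(256))
        assert (ent == 0).all() and (eng == 0).all()

    def test_unit_impulse_energy_conserved(self):
        import pywt

        x = np.zeros(256)
        x[100] = 1.0
        ent, eng = wavelet_features(x)
        coeffs = pywt.wavedec(x, "db4", level=5, mode="periodization")
        approx_energy = (coeffs[0] ** 2).sum()
        assert eng.sum() + approx_energy == pytest.approx(1.0, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_energy_conservation_random_signals(self, seed):
        import pywt

        x = np.random.default_rng(seed).standard_normal(512)
        _, eng = wavelet_features(x)
        approx = pywt.wavedec(x, "db4", level=5, mode="periodization")[0]
        total = eng.sum() + (approx**2).sum()
        assert abs(total - (x**2).sum()) / (x**2).sum() < 1e-6

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            wavelet_features(np.zeros(16), levels=5)


class TestExtractAll:
    def test_column_formula_at_14_channels(self):
        spec = SynthSpec(n_trials_per_class=2, n_channels=14, duration=2.0, seed=0)
        ts = generate_synthetic_trials(spec)
        m = Montage(ts.channel_labels, [(f"Ch{i:02d}", f"Ch{i + 7:02d}") for i in range(1, 8)])
        fm = extract_all(ts, montage=m)
        assert fm.n_features == feature_count(14, 7) == 364
        assert len(set(fm.column_names)) == 364

    def test_family_slices_partition_columns(self, montage_trials):
        fm = extract_all(montage_trials)
        stops = sorted(s.stop for s in fm.family_slices.values())
        assert stops[-1] == fm.n_features
        covered = sum(s.stop - s.start for s in fm.family_slices.values())
        assert covered == fm.n_features
        assert fm.values.shape[0] == montage_trials.n_trials

    def test_permuting_trials_permutes_rows(self, small_trials):
        from dataclasses import replace

        fm = extract_all(small_trials)
        perm = np.array([3, 1, 4, 0, 2, 9, 5, 8, 7, 6])
        shuffled = replace(
            small_trials,
            trials=small_trials.trials[perm],
            labels=small_trials.labels[perm],
            ratings=small_trials.ratings[perm],
        )
        fm2 = extract_all(shuffled)
        np.testing.assert_allclose(fm2.values, fm.values[perm], atol=1e-12)

    def test_scaling_shifts_de_and_keeps_rasm_signs(self, small_trials):
        from dataclasses import replace

        k = 3.0
        fm = extract_all(small_trials)
        fm2 = extract_all(replace(small_trials, trials=small_trials.trials * k))
        de = fm.family_slices["de"]
        np.testing.assert_allclose(
            fm2.values[:, de] - fm.values[:, de], np.log(k), atol=1e-9
        )
        rs = fm.family_slices["rasm"]
        assert np.array_equal(
            np.sign(fm2.values[:, rs]), np.sign(fm.values[:, rs])
        )

    def test_csv_round_trip(self, small_trials, tmp_path):
        from eegfsel import FeatureMatrix

        fm = extract_all(small_trials)
        fm.to_csv(tmp_path / "features.csv")
        back = FeatureMatrix.from_csv(tmp_path / "features.csv")
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
        assert back.column_names == fm.column_names
        assert back.family_slices == fm.family_slices
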