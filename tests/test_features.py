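"""HRV feature bank against independent brute-force oracles and identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neomat.features import (
    FEATURE_REGISTRY,
    dfa,
    extract_features,
    frequency_domain,
    poincare,
    sample_entropy,
    time_domain,
    visibility_adjacency,
    visibility_graph,
)

from .oracles import sampen_brute, time_domain_brute, visibility_brute

rr_series = st.lists(
    st.floats(min_value=200.0, max_value=900.0, allow_nan=False), min_size=12, max_size=60
)


class TestTimeDomain:
    def test_constant_series(self):
        td = time_domain(np.full(50, 400.0))
        assert td["sdnn"] == 0 and td["rmssd"] == 0 and td["pnn50"] == 0

    def test_alternating_rmssd(self):
        td = time_domain(np.array([400.0, 420.0] * 30))
        assert td["rmssd"] == pytest.approx(20.0)
        assert td["pnn20"] == 0.0  # differences are exactly 20, not > 20
        assert td["pnn50"] == 0.0

    def test_five_beat_hand_computation(self):
        rr = [400.0, 410.0, 405.0, 420.0, 400.0]
        expected = time_domain_brute(rr)
        got = time_domain(np.array(rr))
        for k, v in expected.items():
            assert got[k] == pytest.approx(v, abs=1e-12), k

    @settings(derandomize=True, max_examples=30)
    @given(rr_series)
    def test_matches_oracle(self, rr):
        got = time_domain(np.array(rr))
        expected = time_domain_brute(rr)
        for k in expected:
            assert got[k] == pytest.approx(expected[k], rel=1e-9, abs=1e-9)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            time_domain(np.array([400.0]))


class TestFrequencyDomain:
    def _times(self, n=4500, rr_s=0.4):
        return np.arange(1, n + 1) * rr_s

    def test_lf_modulation_concentrates_in_lf(self):
        t = self._times()
        rr = 400 + 10 * np.sin(2 * np.pi * 0.1 * t)
        fd = frequency_domain(t, rr)
        assert fd["lf_power"] / (fd["lf_power"] + fd["hf_power"]) >= 0.90
        # a 10-ms sinusoid carries A²/2 = 50 ms² of power
        assert fd["lf_power"] == pytest.approx(50.0, rel=0.1)

    def test_hf_modulation_dominates(self):
        t = self._times()
        rr = 400 + 10 * np.sin(2 * np.pi * 0.5 * t)
        fd = frequency_domain(t, rr)
        assert fd["hf_power"] > fd["lf_power"]

    def test_constant_series_near_zero_power(self):
        t = self._times(500)
        fd = frequency_domain(t, np.full(500, 400.0))
        assert fd["lf_power"] < 1e-6 and fd["hf_power"] < 1e-6
        assert math.isnan(fd["lf_hf_ratio"])  # missing, never infinity

    def test_periodogram_matches_scipy(self, rng):
        from scipy.signal import lombscargle

        from neomat.features import lomb_periodogram

        t = np.sort(rng.uniform(0, 100, 300))
        x = rng.normal(0, 1, 300)
        x -= x.mean()
        w = 2 * np.pi * np.linspace(0.01, 2.0, 500)
        np.testing.assert_allclose(
            lomb_periodogram(t, x, w), lombscargle(t, x, w), atol=1e-10
        )

    def test_overlapping_bands_rejected(self):
        t = self._times(100)
        with pytest.raises(ValueError, match="disjoint"):
            frequency_domain(t, np.full(100, 400.0), {"a": (0.0, 0.3), "b": (0.2, 1.0)})


class TestPoincare:
    def test_constant(self):
        p = poincare(np.full(20, 400.0))
        assert p["sd1"] == 0 and p["sd2"] == 0 and math.isnan(p["sd1_sd2_ratio"])

    @settings(derandomize=True, max_examples=30)
    @given(rr_series)
    def test_identities(self, rr):
        rr = np.array(rr)
        p = poincare(rr)
        td = time_domain(rr)
        assert p["sd1"] == pytest.approx(td["rmssd"] / math.sqrt(2), abs=1e-9)
        assert p["sd1"] ** 2 + p["sd2"] ** 2 == pytest.approx(
            2 * td["sdnn"] ** 2, rel=1e-6, abs=1e-9
        )

    def test_identity_on_long_random_series(self, rng):
        rr = rng.normal(400, 25, 1000)
        p = poincare(rr)
        td = time_domain(rr)
        assert p["sd1"] ** 2 + p["sd2"] ** 2 == pytest.approx(
            2 * td["sdnn"] ** 2, rel=1e-6
        )


class TestSampleEntropy:
    def test_constant_is_zero(self):
        assert sample_entropy(np.full(50, 400.0)) == 0.0

    def test_ramp_with_covering_tolerance_is_zero(self):
        x = np.arange(100, dtype=float)
        assert sample_entropy(x, r=50.0) == 0.0

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(5):
            x = rng.normal(400, 15, 60)
            assert sample_entropy(x) == pytest.approx(
                sampen_brute(x), abs=1e-12, nan_ok=True
            )

    def test_scale_invariance(self, rng):
        x = rng.normal(400, 15, 80)
        assert sample_entropy(x) == pytest.approx(sample_entropy(x / 1000.0), abs=1e-9)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]))


class TestDFA:
    def test_white_noise_alpha(self):
        x = np.random.default_rng(0).standard_normal(10000)
        a = dfa(x)
        assert 0.4 <= a["dfa_alpha1"] <= 0.6
        assert 0.4 <= a["dfa_alpha2"] <= 0.6

    def test_integrated_noise_alpha(self):
        x = np.cumsum(np.random.default_rng(0).standard_normal(10000))
        a = dfa(x)
        assert 1.3 <= a["dfa_alpha1"] <= 1.7
        assert 1.3 <= a["dfa_alpha2"] <= 1.7

    def test_doubling_leaves_alpha_unchanged(self):
        x = np.random.default_rng(3).standard_normal(5000)
        a1 = dfa(x)
        a2 = dfa(np.concatenate([x, x]))
        assert a2["dfa_alpha1"] == pytest.approx(a1["dfa_alpha1"], abs=0.05)
        assert a2["dfa_alpha2"] == pytest.approx(a1["dfa_alpha2"], abs=0.05)

    def test_scale_invariance(self):
        x = 400 + 10 * np.random.default_rng(4).standard_normal(2000)
        a1, a2 = dfa(x), dfa(x / 1000.0)
        assert a1["dfa_alpha1"] == pytest.approx(a2["dfa_alpha1"], abs=1e-9)

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            dfa(np.arange(50, dtype=float))


class TestVisibilityGraph:
    def test_convex_series_complete_graph(self):
        t = np.arange(30, dtype=float)
        vg = visibility_graph(t**2, t)
        assert vg["vg_mean_degree"] == pytest.approx(29.0)

    def test_constant_series_path_graph(self):
        n = 20
        vg = visibility_graph(np.full(n, 5.0), np.arange(n, dtype=float))
        assert vg["vg_mean_degree"] == pytest.approx(2 * (n - 1) / n)

    def test_adjacency_matches_brute_force(self, rng):
        for _ in range(5):
            y = rng.normal(0, 1, 50)
            t = np.sort(rng.uniform(0, 50, 50))
            np.testing.assert_array_equal(
                visibility_adjacency(y, t), visibility_brute(y, t)
            )

    def test_affine_rescaling_invariance(self, rng):
        y = rng.normal(400, 20, 60)
        t = np.cumsum(rng.uniform(0.3, 0.5, 60))
        a = visibility_adjacency(y, t)
        b = visibility_adjacency(y / 1000.0, t * 1000.0)
        np.testing.assert_array_equal(a, b)

    def test_short_series_missing(self):
        vg = visibility_graph(np.arange(5, dtype=float))
        assert math.isnan(vg["vg_mean_degree"])

    def test_cap_subsampling_deterministic(self, rng):
        y = rng.normal(400, 20, 2000)
        v1 = visibility_graph(y, cap=256)
        v2 = visibility_graph(y, cap=256)
        assert v1 == v2


class TestExtractFeatures:
    def test_requested_names_only(self, segment_factory, rng):
        seg = segment_factory(rng.normal(400, 15, 300))
        vec = extract_features(seg, ["sdnn", "sampen"])
        assert set(vec.values) == {"sdnn", "sampen"}

    def test_unknown_name_lists_registry(self, segment_factory, rng):
        seg = segment_factory(rng.normal(400, 15, 50))
        with pytest.raises(KeyError, match="foo"):
            extract_features(seg, ["sdnn", "foo"])

    def test_deterministic(self, segment_factory, rng):
        seg = segment_factory(rng.normal(400, 15, 300))
        v1 = extract_features(seg)
        v2 = extract_features(seg)
        assert v1.values == v2.values

    def test_all_features_finite_on_clean_segments(self, segment_factory, rng):
        # dozens of seeded draws of realistic clean segments: every feature
        # except the degenerate-by-construction ones must be finite
        for _ in range(25):
            rr = 400 + 12 * rng.standard_normal(400)
            vec = extract_features(segment_factory(rr))
            for name, value in vec.values.items():
                if name == "vg_assortativity":
                    continue  # may be undefined on degree-regular graphs
                assert np.isfinite(value), (name, vec.reasons.get(name))

    def test_missing_values_carry_reasons(self, segment_factory):
        seg = segment_factory(np.full(300, 400.0))  # constant: ratio undefined
        vec = extract_features(seg, ["lf_hf_ratio", "sd1_sd2_ratio"])
        assert math.isnan(vec.values["lf_hf_ratio"])
        assert vec.reasons["lf_hf_ratio"] == "hf_power_zero"
        assert vec.reasons["sd1_sd2_ratio"] == "sd2_zero"

    def test_registry_covers_named_families(self):
        for name in ("sdnn", "rmssd", "lf_power", "hf_power", "sampen",
                     "dfa_alpha1", "sd1", "sd2", "vg_mean_degree"):
            assert name in FEATURE_REGISTRY
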