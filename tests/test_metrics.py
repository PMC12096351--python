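"""The four similarity metrics: anchors, symmetries, invariances, oracle parity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aminospec.metrics import (
    MetricParams,
    entropy_similarity,
    evaluate_pair,
    rmse_padded,
    spectral_contrast_angle,
    weighted_cosine,
)
from aminospec.spectra import pad_pair
from conftest import make_spectrum, random_peak_dict
from oracles import rmse_oracle, sca_oracle, sen_oracle, wcs_oracle


def _pair(a: dict, b: dict):
    return pad_pair(make_spectrum(a), make_spectrum(b))


class TestAnchors:
    """Hand-checkable values computed independently of the implementation."""

    def test_rmse_single_peak_difference(self):
        # one 20-unit difference spread over 51 padded positions
        pair = _pair({50: 80.0}, {50: 100.0})
        assert rmse_padded(pair) == pytest.approx(math.sqrt(400 / 51), abs=1e-12)
        assert rmse_padded(pair) == pytest.approx(2.8006, abs=5e-5)

    def test_sca_one_vs_two_equal_peaks_is_45_degrees(self):
        pair = _pair({100: 100.0}, {100: 100.0, 200: 100.0})
        assert spectral_contrast_angle(pair) == pytest.approx(45.0, abs=1e-9)

    def test_wcs_shared_peak_fraction(self):
        # cos = 50*sqrt(100)*50*sqrt(100) / (|[500,1000]| * |[500]|) = 50/sqrt(50^2+100^2)
        pair = _pair({50: 100.0, 100: 100.0}, {50: 100.0})
        expected = 50.0 / math.sqrt(50.0**2 + 100.0**2)
        assert weighted_cosine(pair, MetricParams(1.0, 0.5)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4472, abs=5e-5)

    def test_sen_single_vs_split_peak(self):
        # p={50:1}, q={50:.5,60:.5}: m={50:.75,60:.25},
        # value = 1 - (2 H(m) - 0 - ln 2)/ln 4 = 0.688722 (oracle-computed)
        pair = _pair({50: 100.0}, {50: 50.0, 60: 50.0})
        expected = sen_oracle({50: 1.0}, {50: 0.5, 60: 0.5})
        assert entropy_similarity(pair) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.6887219, abs=1e-6)


class TestIdentityAndOrthogonality:
    def test_identical_spectra(self):
        s = make_spectrum({50: 10.0, 60: 100.0, 77: 45.0})
        res = evaluate_pair(s, s)
        assert res.rmse == 0.0
        assert res.sca_deg == 0.0
        assert res.wcs == pytest.approx(1.0, abs=1e-12)
        assert res.sen == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_spectra(self):
        res = evaluate_pair(make_spectrum({50: 100.0, 70: 40.0}),
                            make_spectrum({51: 100.0, 71: 40.0}))
        assert res.rmse > 0
        assert res.sca_deg == pytest.approx(90.0, abs=1e-9)
        assert res.wcs == pytest.approx(0.0, abs=1e-12)
        assert res.sen == pytest.approx(0.0, abs=1e-12)

    def test_single_peak_same_mz_identical_after_normalization(self):
        # different absolute intensities at the same m/z normalize away
        res = evaluate_pair(make_spectrum({88: 12.0}), make_spectrum({88: 430.0}))
        assert res.as_tuple() == pytest.approx((0.0, 0.0, 1.0, 1.0), abs=1e-12)

    def test_zero_norm_rejected(self):
        pair = _pair({50: 1.0}, {60: 1.0})
        pair.observed[:] = 0.0
        with pytest.raises(ValueError):
            spectral_contrast_angle(pair)
        with pytest.raises(ValueError):
            entropy_similarity(pair)


@st.composite
def normalized_pair(draw):
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    return random_peak_dict(rng), random_peak_dict(rng)


class TestProperties:
    @given(ab=normalized_pair())
    @settings(max_examples=60, deadline=None)
    def test_symmetry_under_argument_exchange(self, ab):
        a, b = ab
        fwd = evaluate_pair(make_spectrum(a), make_spectrum(b))
        rev = evaluate_pair(make_spectrum(b), make_spectrum(a))
        assert fwd.rmse == pytest.approx(rev.rmse, abs=1e-12)
        assert fwd.sca_deg == pytest.approx(rev.sca_deg, abs=1e-9)
        assert fwd.wcs == pytest.approx(rev.wcs, abs=1e-12)
        assert fwd.sen == pytest.approx(rev.sen, abs=1e-12)

    @given(ab=normalized_pair(), scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance_of_angular_and_entropy_metrics(self, ab, scale):
        # invariance of the raw metrics themselves, without any prior
        # normalization step (RMSE deliberately lacks this property)
        a, b = ab
        base = _pair(a, b)
        scaled = _pair({k: v * scale for k, v in a.items()}, b)
        assert spectral_contrast_angle(scaled) == pytest.approx(
            spectral_contrast_angle(base), abs=1e-8)
        assert weighted_cosine(scaled) == pytest.approx(weighted_cosine(base), abs=1e-9)
        assert entropy_similarity(scaled) == pytest.approx(entropy_similarity(base), abs=1e-9)

    def test_bounded_and_finite_on_random_pairs(self, rng):
        for _ in range(200):
            a = random_peak_dict(rng)
            b = random_peak_dict(rng)
            res = evaluate_pair(make_spectrum(a), make_spectrum(b))
            assert 0.0 <= res.sca_deg <= 90.0
            assert 0.0 <= res.wcs <= 1.0
            assert 0.0 <= res.sen <= 1.0
            assert res.rmse >= 0.0
            assert all(math.isfinite(v) for v in res.as_tuple())


class TestOracleParity:
    def test_all_four_metrics_match_dict_oracles(self, random_pairs):
        params = MetricParams()
        for a, b in random_pairs:
            pair = _pair(a, b)
            assert rmse_padded(pair) == pytest.approx(rmse_oracle(a, b), abs=1e-9)
            assert spectral_contrast_angle(pair) == pytest.approx(sca_oracle(a, b), abs=1e-9)
            assert weighted_cosine(pair, params) == pytest.approx(wcs_oracle(a, b), abs=1e-9)
            assert entropy_similarity(pair, params) == pytest.approx(sen_oracle(a, b), abs=1e-9)

    def test_wcs_alternative_exponents_match_oracle(self, random_pairs):
        # Stein-Scott-style weighting must flow through the parameter object
        params = MetricParams(wcs_mz_exponent=3.0, wcs_intensity_exponent=0.6)
        for a, b in random_pairs[:20]:
            pair = _pair(a, b)
            assert weighted_cosine(pair, params) == pytest.approx(
                wcs_oracle(a, b, 3.0, 0.6), abs=1e-9)


class TestSenLiWeighting:
    def test_weighting_changes_low_entropy_result(self):
        a = {50: 100.0, 60: 2.0}
        b = {50: 100.0, 61: 2.0}
        pair = _pair(a, b)
        plain = entropy_similarity(pair, MetricParams())
        weighted = entropy_similarity(pair, MetricParams(sen_apply_li_weighting=True))
        assert weighted != pytest.approx(plain, abs=1e-6)

    def test_weighting_keeps_identity_and_range(self, rng):
        params = MetricParams(sen_apply_li_weighting=True)
        s = make_spectrum(random_peak_dict(rng))
        assert evaluate_pair(s, s, params).sen == pytest.approx(1.0, abs=1e-12)
        for _ in range(50):
            a, b = random_peak_dict(rng), random_peak_dict(rng)
            val = evaluate_pair(make_spectrum(a), make_spectrum(b), params).sen
            assert 0.0 <= val <= 1.0


def test_compound_id_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        evaluate_pair(make_spectrum({50: 1.0}, "a"), make_spectrum({50: 1.0}, "b"))


def test_fractional_mz_binned_before_scoring():
    res = evaluate_pair(make_spectrum({59.9: 60.0, 60.2: 40.0}), make_spectrum({60: 100.0}))
    assert res.as_tuple() == pytest.approx((0.0, 0.0, 1.0, 1.0), abs=1e-12)
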