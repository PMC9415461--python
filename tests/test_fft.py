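"""DFT correctness against a direct-summation oracle; feature assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenofft import (build_feature_matrix, dft, dominant_feature,
                      load_reference_features, spectral_features)
from phenofft.datasets import export_reference_features, reference_fixture_text
from phenofft.fft_profiler import FEATURE_COLUMNS, Spectrum
from phenofft.params import PARAM_KEYS
from phenofft.timeseries import CenteredSeries


def dft_direct(x):
    """O(N²) direct summation of Σ x_n e^{−i2πkn/N} — the independent
    oracle for the transform."""
    n = len(x)
    k = np.arange(n)[:, None]
    m = np.arange(n)[None, :]
    return (x[None, :] * np.exp(-2j * np.pi * k * m / n)).sum(axis=1)


def centered(x, condition="c", parameter="area"):
    idx = pd.RangeIndex(1, len(x) + 1, name="cycle")
    values = pd.DataFrame({parameter: np.asarray(x, dtype=float)}, index=idx)
    return CenteredSeries(condition=condition, values=values,
                          location=pd.Series(0.0, index=[parameter]),
                          scale=pd.Series(1.0, index=[parameter]))


def spectrum_of(x):
    return dft(centered(x))["area"]


def test_dft_matches_direct_summation_oracle(rng):
    for _ in range(10):
        x = rng.standard_normal(400)
        x -= x.mean()
        np.testing.assert_allclose(spectrum_of(x).coefficients, dft_direct(x),
                                   rtol=1e-9, atol=1e-9)


def test_dft_single_tone():
    """cos(2π·3n/400) puts all energy in |X_3| = 200."""
    n = 400
    x = np.cos(2 * np.pi * 3 * np.arange(n) / n)
    mag = np.abs(spectrum_of(x).coefficients)
    assert mag[3] == pytest.approx(200.0, rel=1e-9)
    others = np.delete(mag[1:201], 2)
    assert others.max() < 1e-9 * n


def test_dft_zero_input():
    assert not np.abs(spectrum_of(np.zeros(16)).coefficients).any()


def test_dft_centered_dc_is_zero(rng):
    x = rng.standard_normal(400)
    x -= x.mean()
    assert abs(spectrum_of(x).coefficients[0]) < 1e-6 * 400


def test_dft_conjugate_symmetry(rng):
    c = spectrum_of(rng.standard_normal(128)).coefficients
    np.testing.assert_allclose(c[1:], np.conj(c[1:][::-1]), rtol=1e-9, atol=1e-9)


def test_dft_parseval(rng):
    x = rng.standard_normal(400)
    c = spectrum_of(x).coefficients
    assert np.sum(x ** 2) == pytest.approx(np.sum(np.abs(c) ** 2) / 400, rel=1e-9)


def test_dft_linearity(rng):
    x, y = rng.standard_normal((2, 256))
    lhs = spectrum_of(2.5 * x - 1.5 * y).coefficients
    rhs = 2.5 * spectrum_of(x).coefficients - 1.5 * spectrum_of(y).coefficients
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)


def test_dft_rejects_nonfinite():
    x = np.zeros(16)
    x[5] = np.nan
    with pytest.raises(ValueError, match="cycle"):
        dft(centered(x))


def test_dft_rejects_short_series():
    with pytest.raises(ValueError):
        dft(centered([1.0, -1.0]))


def test_dominant_feature_cosine_tone():
    """0.7·cos(2π·5n/400) → k* = 5, amplitude 0.7, phase 0."""
    n = 400
    f = dominant_feature(spectrum_of(0.7 * np.cos(2 * np.pi * 5 * np.arange(n) / n)))
    assert f.k_star == 5
    assert f.amplitude == pytest.approx(0.7, rel=1e-9)
    assert f.phase == pytest.approx(0.0, abs=1e-9)
    assert f.period == pytest.approx(80.0)


def test_dominant_feature_sine_tone():
    """0.7·sin(2π·5n/400) → k* = 5, phase −π/2."""
    n = 400
    f = dominant_feature(spectrum_of(0.7 * np.sin(2 * np.pi * 5 * np.arange(n) / n)))
    assert f.k_star == 5
    assert f.phase == pytest.approx(-np.pi / 2, rel=1e-9)


def test_dominant_feature_linear_ramp_is_low_frequency():
    """A centered linear trend is dominated by the k = 1 bin."""
    x = np.linspace(-1, 1, 400)
    spec = spectrum_of(x)
    f = dominant_feature(spec)
    band = np.abs(spec.coefficients[1:200])
    assert f.k_star == int(np.argmax(band)) + 1 == 1


@settings(deadline=None, max_examples=30, derandomize=True)
@given(k=st.integers(min_value=1, max_value=99),
       amp=st.floats(min_value=0.05, max_value=10.0),
       phi=st.floats(min_value=-3.1, max_value=3.1))
def test_single_tone_recovery_property(k, amp, phi):
    """a·cos(2πkn/N + φ) recovers (k, a, φ) under the stated conventions."""
    n = 200
    x = amp * np.cos(2 * np.pi * k * np.arange(n) / n + phi)
    f = dominant_feature(spectrum_of(x))
    assert f.k_star == k
    assert f.amplitude == pytest.approx(amp, rel=1e-9)
    assert np.angle(np.exp(1j * (f.phase - phi))) == pytest.approx(0.0, abs=1e-7)


def test_time_shift_covariance(rng):
    """Circular shift by s multiplies X_k by e^{−i2πks/N}: amplitudes are
    invariant, phases shift accordingly."""
    x = rng.standard_normal(128)
    s = 17
    c0 = spectrum_of(x).coefficients
    cs = spectrum_of(np.roll(x, s)).coefficients
    k = np.arange(128)
    np.testing.assert_allclose(cs, c0 * np.exp(-2j * np.pi * k * s / 128),
                               rtol=1e-9, atol=1e-9)


def test_dominant_feature_rejects_empty_band():
    with pytest.raises(ValueError, match="all-zero"):
        dominant_feature(Spectrum("c", "area", np.zeros(8, dtype=complex)))


def test_nyquist_excluded_from_search():
    """With energy only at the Nyquist bin the band is empty."""
    n = 8
    x = np.cos(np.pi * np.arange(n))  # pure Nyquist tone
    with pytest.raises(ValueError):
        dominant_feature(spectrum_of(x))


# ---------------------------------------------------------------------------
# feature matrix assembly


def features_for(conditions, rng):
    feats = []
    for c in conditions:
        series = centered_all(c, rng)
        feats.extend(spectral_features(series))
    return feats


def centered_all(condition, rng):
    idx = pd.RangeIndex(1, 65, name="cycle")
    vals = rng.standard_normal((64, 11))
    vals -= vals.mean(axis=0)
    values = pd.DataFrame(vals, index=idx, columns=list(PARAM_KEYS))
    return CenteredSeries(condition=condition, values=values,
                          location=pd.Series(0.0, index=values.columns),
                          scale=pd.Series(1.0, index=values.columns))


def test_feature_matrix_shape_and_order(rng):
    feats = features_for(["a", "b", "c", "d"], rng)
    m = build_feature_matrix(feats, normalize=True)
    assert m.data.shape == (4, 22)
    assert list(m.data.columns) == list(FEATURE_COLUMNS)
    assert abs(m.data.mean(axis=0)).max() < 1e-9


def test_feature_matrix_zscore_closed_form(rng):
    """A column holding 1,2,3,4 normalizes to ±1.1619, ±0.3873."""
    feats = features_for(["a", "b", "c", "d"], rng)
    m = build_feature_matrix(feats, normalize=False)
    m.data.loc[:, "amp_area"] = [1.0, 2.0, 3.0, 4.0]
    renorm = (m.data - m.data.mean(axis=0)) / m.data.std(axis=0, ddof=1)
    np.testing.assert_allclose(
        renorm["amp_area"], [-1.161895, -0.387298, 0.387298, 1.161895],
        atol=1e-6)


def test_feature_matrix_passthrough_without_normalize(rng):
    feats = features_for(["a", "b", "c"], rng)
    m = build_feature_matrix(feats, normalize=False)
    f0 = [f for f in feats if f.condition == "a" and f.parameter == "area"][0]
    assert m.data.loc["a", "amp_area"] == f0.amplitude
    assert m.data.loc["a", "phase_area"] == f0.phase


def test_feature_matrix_missing_pair_errors(rng):
    feats = features_for(["a", "b", "c"], rng)
    with pytest.raises(ValueError, match="missing"):
        build_feature_matrix(feats[:-1], normalize=False)


def test_feature_matrix_too_few_conditions_for_normalize(rng):
    feats = features_for(["a", "b"], rng)
    with pytest.raises(ValueError, match="3 conditions"):
        build_feature_matrix(feats, normalize=True)


def test_reference_fixture_round_trip_bit_exact():
    """Loading the packaged reference table and re-exporting reproduces
    the file byte for byte."""
    matrix = load_reference_features()
    assert matrix.data.shape == (4, 22)
    assert matrix.conditions == ["Control", "PTX", "CLC", "VBL"]
    assert export_reference_features(matrix) == reference_fixture_text()
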