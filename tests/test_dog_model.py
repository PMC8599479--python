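"""Closed-form DoG mathematics: balance, bias, spectra, 1D filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dogprf as d
from dogprf.dog_model import balanced_delta_1d, dog_kernel_1d
from dogprf.errors import InputError, ParameterError

sigmas = st.floats(0.2, 5.0)


def test_dog_value_at_centre_and_far_field():
    params = d.DoGParams(1.5, -2.0, 1.0, 2.0, 0.4)
    grid = d.VisualFieldGrid(17.4, 101)
    field = d.evaluate_dog(params, grid)
    iy = np.argmin(np.abs(grid.axis - params.y0))
    ix = np.argmin(np.abs(grid.axis - params.x0))
    # grid samples hit (x0, y0) only approximately; evaluate exactly via a
    # grid centred on the pRF
    centred = d.evaluate_dog(d.DoGParams(0, 0, 1.0, 2.0, 0.4), grid)
    mid = grid.resolution // 2
    assert centred[mid, mid] == pytest.approx(1 - 0.4, abs=1e-12)
    assert abs(field[iy, ix] - (1 - 0.4)) < 0.05
    far = field[0, 0]  # corner is ~20 deg from the centre, >> 6*sigma2
    assert abs(far) < 1e-12
    assert np.all(np.isfinite(field))


def test_dog_rejects_nonpositive_sigma():
    with pytest.raises(ParameterError):
        d.DoGParams(0, 0, -1.0, 2.0, 0.3)
    with pytest.raises(ParameterError):
        d.DoGParams(0, 0, 1.0, 0.0, 0.3)


def test_discrete_integral_matches_analytic():
    """Riemann sum of the sampled DoG approaches 2*pi*(s1^2 - d*s2^2)."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        s2 = rng.uniform(0.5, 3.0)
        s1 = s2 * rng.uniform(0.2, 0.9)
        delta = rng.uniform(0.1, 0.9)
        params = d.DoGParams(0.0, 0.0, s1, s2, delta)
        grid = d.VisualFieldGrid(extent=6.5 * s2, resolution=201)
        total = d.evaluate_dog(params, grid).sum() * grid.cell_area
        expected = 2 * math.pi * (s1**2 - delta * s2**2)
        assert total == pytest.approx(expected, abs=1e-3 * max(abs(expected), 1.0))


@pytest.mark.parametrize(
    "s1, s2, expected", [(1.0, 2.0, 0.25), (2.0, 2.0, 1.0), (1.0, 3.0, 1.0 / 9.0)]
)
def test_balanced_delta_examples(s1, s2, expected):
    assert d.balanced_delta(s1, s2) == pytest.approx(expected, rel=1e-12)


def test_equal_sigmas_fall_outside_restricted_space():
    delta = d.balanced_delta(2.0, 2.0)
    assert not d.DoGParams(0, 0, 2.0, 2.0, delta).in_restricted_space()


@pytest.mark.parametrize("s2, delta, expected", [(2.0, 0.25, 1.0), (2.0, 1.0, 2.0)])
def test_balanced_sigma1_examples(s2, delta, expected):
    assert d.balanced_sigma1(s2, delta) == pytest.approx(expected, rel=1e-12)


@settings(max_examples=200, deadline=None)
@given(sigma2=sigmas, delta=st.floats(0.05, 0.95))
def test_balance_round_trip(sigma2, delta):
    """balanced_delta(balanced_sigma1(s, d), s) recovers d exactly."""
    assert d.balanced_delta(d.balanced_sigma1(sigma2, delta), sigma2) == pytest.approx(
        delta, abs=1e-12
    )


@pytest.mark.parametrize(
    "s1, s2, delta, value, cls",
    [
        (1.0, 2.0, 0.25, 0.0, "balanced"),
        (1.0, 2.0, 0.5, -1.0, "negative"),
        (2.0, 3.0, 0.25, 1.75, "positive"),
    ],
)
def test_bias_examples(s1, s2, delta, value, cls):
    b = d.bias(d.DoGParams(0, 0, s1, s2, delta))
    assert b.value == pytest.approx(value, abs=1e-12)
    assert b.classification == cls


def test_balanced_counterparts():
    out = d.balanced_counterparts(d.DoGParams(0, 0, 1.0, 2.0, 0.5))
    assert out.delta_variant.delta == pytest.approx(0.25, abs=1e-12)
    assert out.sigma1_variant.sigma1 == pytest.approx(math.sqrt(2), abs=1e-12)
    assert out.sigma2_variant.sigma2 == pytest.approx(math.sqrt(2), abs=1e-12)
    for variant in out:
        assert abs(d.bias(variant).value) <= 1e-12
    balanced = d.DoGParams(0, 0, 1.0, 2.0, 0.25)
    for variant in d.balanced_counterparts(balanced):
        assert variant == balanced


def test_frequency_response_dc_equals_two_pi_bias():
    p = d.DoGParams(0, 0, 1.0, 2.0, 0.1)
    assert d.frequency_response(p, np.array([0.0]))[0] == pytest.approx(
        2 * math.pi * 0.6, rel=1e-12
    )
    balanced = d.DoGParams(0, 0, 1.0, 2.0, 0.25)
    assert d.frequency_response(balanced, np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-12)


def test_frequency_response_matches_fft_of_sampled_kernel():
    """Analytic spectrum vs the DFT of the sampled 2D kernel (oracle)."""
    params = d.DoGParams(0.0, 0.0, 0.8, 1.9, d.balanced_delta(0.8, 1.9))
    grid = d.VisualFieldGrid(extent=12.0, resolution=241)
    field = d.evaluate_dog(params, grid)
    spec2d = np.abs(np.fft.rfft2(field)) * grid.cell_area
    freqs = np.fft.rfftfreq(grid.resolution, d=grid.cell_size)
    numeric = spec2d[0, :]  # radial slice along the x-frequency axis
    analytic = np.abs(d.frequency_response(params, freqs))
    keep = analytic > 0.05 * analytic.max()
    assert np.allclose(numeric[keep], analytic[keep], rtol=0.02)
    peak = np.argmax(analytic)
    assert 0 < peak < freqs.size - 1  # bandpass: interior spectral peak


def test_classify_filter():
    assert d.classify_filter(d.DoGParams(0, 0, 1, 2, 0.25)) == "bandpass"
    assert d.classify_filter(d.DoGParams(0, 0, 2, 3, 0.25)) == "lowpass"
    assert d.classify_filter(d.DoGParams(0, 0, 1, 2, 0.5)) == "negative"
    # tolerance boundary is inclusive: |bias| == tol still counts balanced
    slightly = d.DoGParams(0, 0, 1.0, 2.0, 0.2499)
    b = abs(d.bias(slightly).value)
    assert d.classify_filter(slightly, tol=b) == "bandpass"
    assert d.classify_filter(slightly, tol=b * 0.999) == "lowpass"
    with pytest.raises(ParameterError):
        d.classify_filter(d.DoGParams(0, 0, 2, 2, 0.5))


def test_filter_constant_with_1d_balanced_kernel_gives_zeros():
    params = d.DoGParams(0, 0, 1.0, 2.0, balanced_delta_1d(1.0, 2.0))
    out = d.filter_signal(np.full(500, 9.2), params, sampling=10.0)
    assert np.max(np.abs(out)) < 1e-8 * 9.2


def test_filter_offset_sinusoid():
    """A 1D-balanced kernel removes the sinusoid's 9.2 DC offset,
    a positively biased kernel amplifies it by its (>1) kernel sum."""
    sampling, n = 10.0, 1000
    x = np.arange(n) / sampling
    signal = np.sin(2 * np.pi * 0.1 * x) + 9.2
    balanced = d.DoGParams(0, 0, 1.0, 2.0, balanced_delta_1d(1.0, 2.0))
    out = d.filter_signal(signal, balanced, sampling)
    assert abs(out.mean()) < 1e-8
    # output retains the input frequency on the DFT lattice
    in_peak = np.argmax(np.abs(np.fft.rfft(signal - signal.mean())))
    out_peak = np.argmax(np.abs(np.fft.rfft(out - out.mean())))
    assert in_peak == out_peak

    biased = d.DoGParams(0, 0, 1.0, 2.0, 0.2)
    kernel_sum = dog_kernel_1d(biased, sampling).sum()
    out_b = d.filter_signal(signal, biased, sampling)
    assert out_b.mean() == pytest.approx(signal.mean() * kernel_sum, rel=1e-8)
    assert kernel_sum > 1 and out_b.mean() > signal.mean()


def test_filter_signal_input_errors():
    p = d.DoGParams(0, 0, 1.0, 2.0, 0.25)
    with pytest.raises(InputError):
        d.filter_signal(np.array([]), p, 10.0)
    with pytest.raises(InputError):
        d.filter_signal(np.ones(10), p, 10.0)  # kernel support exceeds signal
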