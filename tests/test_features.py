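"""Feature computations against independent brute-force loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from epiloop.features import (FeatureVector, amplitude, compute_features,
                              line_length, power, slope,
                              slope_subwindow_samples)
from epiloop.signal_io import Epoch


# --- independent oracles (plain loops, no numpy vector tricks) -------------

def ll_oracle(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def amp_oracle(x):
    return sum(abs(v) for v in x) / len(x)


def power_oracle(x):
    return sum(v * v for v in x) / len(x)


def slope_oracle(x, w):
    vals = []
    for s in range(0, len(x), w):
        sub = list(x[s:s + w])
        i_max = sub.index(max(sub))
        i_min = sub.index(min(sub))
        gap = abs(i_max - i_min)
        vals.append((max(sub) - min(sub)) / gap if gap else 0.0)
    return sum(vals) / len(vals)


float_epochs = hnp.arrays(
    float, st.integers(8, 64).map(lambda k: 8 * k),
    elements=st.floats(-1000, 1000, allow_nan=False, width=32))


class TestExamples:
    def test_line_length_explicit(self):
        assert line_length(np.array([1, 3, 2, 2])) == 3
        assert line_length(np.full(16, 7.0)) == 0

    def test_line_length_needs_two_samples(self):
        with pytest.raises(ValueError):
            line_length(np.array([1.0]))

    def test_amplitude_float(self):
        assert amplitude(np.array([-2.0, 2.0])) == 2.0
        assert amplitude(np.zeros(8)) == 0.0

    def test_amplitude_hardware_shift(self):
        x = np.full(256, 3, dtype=np.int64)  # sum 768 -> 768 >> 8 == 3
        assert amplitude(x, "hardware") == 3

    def test_hardware_requires_256_samples(self):
        with pytest.raises(ValueError):
            amplitude(np.ones(128, dtype=np.int64), "hardware")
        with pytest.raises(ValueError):
            power(np.ones(128, dtype=np.int64), "hardware")

    def test_hardware_rejects_non_integer(self):
        with pytest.raises(ValueError):
            amplitude(np.full(256, 1.5), "hardware")

    def test_power_float(self):
        assert power(np.array([3.0, 4.0])) == 12.5

    def test_slope_linear_ramp(self):
        # x(i) = 2i over one 8-sample subwindow: (14 - 0) / 7 == 2
        assert slope(2.0 * np.arange(8), w=8) == 2.0

    def test_slope_constant_is_zero(self):
        assert slope(np.full(32, 5.0), w=8) == 0.0

    def test_slope_mean_over_subwindows(self):
        x = np.tile(2.0 * np.arange(8), 32)  # 32 subwindows, slope 2 each
        assert slope(x, w=8) == 2.0

    def test_slope_bad_subwindow(self):
        with pytest.raises(ValueError):
            slope(np.arange(8.0), w=1)
        with pytest.raises(ValueError):
            slope(np.arange(10.0), w=8)  # does not tile

    def test_subwindow_samples_from_rate(self):
        assert slope_subwindow_samples(4000.0, 2.0) == 8

    def test_zero_epoch_gives_zero_vector(self):
        fv = compute_features(Epoch(np.zeros(256), 0, 256), fs=4000.0)
        assert (fv.amp, fv.slp, fv.ll, fv.power) == (0, 0, 0, 0)


class TestOracleEquivalence:
    @given(x=float_epochs)
    @settings(max_examples=250, deadline=None)
    def test_float_features_match_bruteforce(self, x):
        xs = list(x)
        assert line_length(x) == pytest.approx(ll_oracle(xs), rel=1e-9, abs=1e-9)
        assert amplitude(x) == pytest.approx(amp_oracle(xs), rel=1e-9, abs=1e-9)
        assert power(x) == pytest.approx(power_oracle(xs), rel=1e-6, abs=1e-9)
        assert slope(x, w=8) == pytest.approx(slope_oracle(xs, 8), rel=1e-9,
                                              abs=1e-9)

    def test_bulk_random_epochs_match_bruteforce(self, rng):
        """>=1000 random epochs, both arithmetic modes."""
        for _ in range(500):
            x = rng.integers(-8192, 8192, size=256)
            xs = [int(v) for v in x]
            assert line_length(x) == ll_oracle(xs)
            assert amplitude(x) == pytest.approx(amp_oracle(xs))
            assert power(x) == pytest.approx(power_oracle(xs))
            # hardware mode: floor-shift of the exact integer sums
            assert amplitude(x, "hardware") == sum(map(abs, xs)) >> 8
            assert power(x, "hardware") == sum(v * v for v in xs) >> 8


class TestProperties:
    @given(x=float_epochs)
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_and_even_in_sign(self, x):
        fv = compute_features(Epoch(x, 0, len(x)), fs=4000.0)
        assert min(fv.amp, fv.slp, fv.ll, fv.power) >= 0
        neg = compute_features(Epoch(-x, 0, len(x)), fs=4000.0)
        assert neg.amp == pytest.approx(fv.amp)
        assert neg.ll == pytest.approx(fv.ll)
        assert neg.power == pytest.approx(fv.power)

    @given(x=float_epochs, a=st.floats(0.1, 50))
    @settings(max_examples=100, deadline=None)
    def test_homogeneity_degrees(self, x, a):
        assert line_length(a * x) == pytest.approx(a * line_length(x), rel=1e-6)
        assert amplitude(a * x) == pytest.approx(a * amplitude(x), rel=1e-6)
        assert power(a * x) == pytest.approx(a * a * power(x), rel=1e-6)
        assert slope(a * x, w=8) == pytest.approx(a * slope(x, w=8), rel=1e-6)

    @given(x=float_epochs)
    @settings(max_examples=100, deadline=None)
    def test_line_length_reversal_invariant(self, x):
        assert line_length(x) == pytest.approx(line_length(x[::-1]))

    def test_hardware_floor_never_exceeds_float(self, rng):
        """Integer shift-by-8 sits within [float - 1, float]."""
        for _ in range(300):
            x = rng.integers(-8192, 8192, size=256)
            for f_hw, f_fl in ((amplitude(x, "hardware"), amplitude(x)),
                               (power(x, "hardware"), power(x))):
                assert f_fl - 1 < f_hw <= f_fl

    def test_extremum_ties_take_first_occurrence(self):
        # max 5 at indices 1 and 3; min 0 at 0 and 2 -> gap |1-0| = 1
        x = np.array([0.0, 5.0, 0.0, 5.0, 1.0, 1.0, 1.0, 1.0])
        assert slope(x, w=8) == 5.0
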