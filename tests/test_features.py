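import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edanx.decompose import ScrEvent
from edanx.features import (
    FEATURE_NAMES,
    BaselineStats,
    PsdEstimate,
    event_features,
    extract_all,
    fmd,
    fmn,
    hr_band_decompose,
    hr_freq_features,
    hr_time_features,
    mar,
    mav,
    psd,
    ssc,
    std,
    wamp,
    wl,
)
from edanx.segment import LabeledWindow

# ---------------------------------------------------------------- oracles
# Independent brute-force definitions, written as plain loops.


def naive_mav(x):
    return sum(abs(v) for v in x) / len(x)


def naive_std(x):
    m = sum(x) / len(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def naive_wl(x):
    return sum((x[k] - x[k - 1]) ** 2 for k in range(1, len(x)))


def naive_ssc(x, eps=0.001):
    count = 0
    for k in range(1, len(x) - 1):
        d1 = x[k] - x[k - 1]
        d2 = x[k + 1] - x[k]
        if d1 * d2 < 0 and abs(d1) >= eps and abs(d2) >= eps:
            count += 1
    return count


def naive_wamp(x, eps_w=0.5):
    return sum(1 for k in range(1, len(x)) if abs(x[k] - x[k - 1]) >= eps_w)


NAIVE = {
    mav: naive_mav,
    std: naive_std,
    wl: naive_wl,
    ssc: naive_ssc,
    wamp: naive_wamp,
}


class TestTimeDomainExamples:
    @pytest.mark.parametrize(
        "fn, x, expected",
        [
            (mav, [1, -1, 1, -1], 1.0),
            (mav, [2, 4, 6], 4.0),
            (mav, [0.5, 1.5, 1.0], 1.0),
            (std, [3, 3, 3], 0.0),
            (std, [0, 10], 7.0710678),
            (wl, [5, 5, 5], 0.0),
            (wl, [0, 1, 0, 1], 3.0),
            (wl, [0, 2, 4], 8.0),
            (ssc, [0, 1, 2, 3], 0),
            (ssc, [0, 1, 0, 1], 2),
            (ssc, [0, 1, 1.0005, 1], 0),
            (wamp, [2, 2, 2], 0),
            (wamp, [0, 1, 0, 1], 3),
            (wamp, [0, 0.4, 0.8], 0),
        ],
    )
    def test_hand_examples(self, fn, x, expected):
        assert fn(np.array(x, dtype=float)) == pytest.approx(expected)

    def test_mar(self):
        assert mar([2, -4, 6], 2.0) == pytest.approx(2.0)
        assert mar([1, 1], 1.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            mar([1, 2], 0.0)

    @pytest.mark.parametrize("fn", [mav, std, wl, ssc, wamp])
    def test_oracle_equivalence_random_vectors(self, fn, rng):
        """Vectorized ops agree with brute-force loops on 1000 random vectors."""
        naive = NAIVE[fn]
        for _ in range(1000):
            x = rng.normal(0, 2, rng.integers(3, 40))
            assert fn(x) == pytest.approx(naive(list(x)), abs=1e-9)

    @given(
        x=st.lists(st.floats(-10, 10), min_size=3, max_size=30),
        a=st.floats(0.1, 5.0),
        c=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scaling_and_shift_laws(self, x, a, c):
        """mav/std/wl scale as a, a, a^2; ssc and wamp are shift-invariant."""
        x = np.array(x)
        assert mav(a * x) == pytest.approx(a * mav(x), rel=1e-9, abs=1e-9)
        assert std(a * x) == pytest.approx(a * std(x), rel=1e-9, abs=1e-9)
        assert wl(a * x) == pytest.approx(a * a * wl(x), rel=1e-9, abs=1e-9)
        assert std(x + c) == pytest.approx(std(x), rel=1e-9, abs=1e-9)
        assert ssc(x + c) == ssc(x)
        assert wamp(x + c) == wamp(x)

    def test_empty_and_short_inputs(self):
        with pytest.raises(ValueError):
            mav([])
        with pytest.raises(ValueError):
            std([1.0])
        with pytest.raises(ValueError):
            ssc([1.0, 2.0])


class TestEventFeatures:
    def test_no_events(self):
        assert event_features([]) == (0, 0.0, 0.0)

    def test_two_events(self):
        nr, avra, maxra = event_features([ScrEvent(1.0, 0.2), ScrEvent(2.0, 0.6)])
        assert (nr, avra, maxra) == (2, pytest.approx(0.4), pytest.approx(0.6))

    def test_single_event(self):
        assert event_features([ScrEvent(0.5, 0.1)]) == (1, 0.1, 0.1)


class TestPsd:
    def test_canonical_grid(self, fs):
        p = psd(np.random.default_rng(0).normal(size=256), fs)
        assert p.frequencies.size == 513
        assert p.frequencies[0] == 0.0
        assert p.frequencies[-1] == pytest.approx(25.6)
        assert np.allclose(np.diff(p.frequencies), 0.05)

    def test_tone_peak_location(self, fs):
        t = np.arange(256) / fs
        p = psd(np.sin(2 * np.pi * 5.0 * t), fs)
        assert p.frequencies[np.argmax(p.power)] == pytest.approx(5.0, abs=0.051)

    def test_parseval_white_noise(self, fs, rng):
        x = rng.normal(0, 1.3, 256)
        p = psd(x, fs)
        assert p.total_power == pytest.approx(np.mean(x**2), rel=0.01)

    def test_zero_signal(self, fs):
        p = psd(np.zeros(256), fs)
        assert np.all(p.power == 0)

    def test_other_rate_warns(self):
        with pytest.warns(UserWarning):
            p = psd(np.ones(128), 32.0)
        assert p.frequencies[-1] == pytest.approx(16.0)


class TestSpectralStatistics:
    def test_flat_spectrum_midpoint(self):
        freqs = np.arange(513) * 0.05
        p = PsdEstimate(frequencies=freqs, power=np.ones(513))
        assert fmd(p) == pytest.approx(12.8)
        assert fmn(p) == pytest.approx(12.8)

    def test_single_bin(self):
        freqs = np.arange(513) * 0.05
        power = np.zeros(513)
        power[60] = 2.0  # 3.0 Hz
        p = PsdEstimate(frequencies=freqs, power=power)
        assert fmd(p) == pytest.approx(3.0)
        assert fmn(p) == pytest.approx(3.0)

    def test_three_bin_enumeration(self):
        p = PsdEstimate(
            frequencies=np.array([0.0, 0.05, 0.1]), power=np.array([1.0, 1.0, 2.0])
        )
        assert fmd(p) == pytest.approx(0.1)

    def test_weighted_mean(self):
        p = PsdEstimate(frequencies=np.array([0.0, 1.0]), power=np.array([1.0, 3.0]))
        assert fmn(p) == pytest.approx(0.75)

    def test_zero_power_rejected(self):
        p = PsdEstimate(frequencies=np.zeros(3), power=np.zeros(3))
        with pytest.raises(ValueError):
            fmd(p)
        with pytest.raises(ValueError):
            fmn(p)

    def test_bounds_and_concentration(self, fs, rng):
        """fmd/fmn stay on the grid; mass below f0 keeps fmn below f0."""
        for _ in range(20):
            x = rng.normal(size=256)
            p = psd(x, fs)
            assert 0 <= fmd(p) <= 25.6
            assert 0 <= fmn(p) <= 25.6
        t = np.arange(256) / fs
        low = np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        assert fmn(psd(low, fs)) <= 3.0


class TestHeartRate:
    def test_time_features_hand_values(self):
        assert hr_time_features([70, 70, 70]) == (70.0, 0.0)
        hr_mav, hr_std = hr_time_features([60.0, 80.0])
        assert hr_mav == pytest.approx(70.0)
        assert hr_std == pytest.approx(14.1421356)

    def test_band_separation(self, fs):
        t = np.arange(int(120 * fs)) / fs
        low_tone = np.sin(2 * np.pi * 0.1 * t)
        h_low, h_high = hr_band_decompose(low_tone, fs)
        tail = slice(int(60 * fs), None)
        amp_low = np.abs(h_low[tail]).max()
        amp_high = np.abs(h_high[tail]).max()
        assert amp_low >= 5 * amp_high

        high_tone = np.sin(2 * np.pi * 0.3 * t)
        h_low2, h_high2 = hr_band_decompose(high_tone, fs)
        assert np.abs(h_high2[tail]).max() >= 5 * np.abs(h_low2[tail]).max()

    def test_dc_rejected(self, fs):
        h_low, h_high = hr_band_decompose(np.full(int(120 * fs), 72.0), fs)
        tail = slice(int(60 * fs), None)
        assert np.abs(h_low[tail]).max() < 0.5
        assert np.abs(h_high[tail]).max() < 0.5

    def test_unresolvable_rate_rejected(self):
        with pytest.raises(ValueError):
            hr_band_decompose(np.zeros(100), 0.5)

    def test_intensity_ratio(self):
        x = np.sin(np.linspace(0, 20 * np.pi, 500))
        lfi, hfi, hlr = hr_freq_features(2 * x, x)
        assert hlr == pytest.approx(0.25)
        lfi, hfi, hlr = hr_freq_features(x, x)
        assert hlr == pytest.approx(1.0)
        with pytest.raises(ValueError):
            hr_freq_features(np.zeros(10), x[:10])


def _window(gsr, scl, scr, hr, events=(), fs=51.2):
    return LabeledWindow(
        subject_id="S1",
        window_index=1,
        gsr=np.asarray(gsr, dtype=float),
        scl=np.asarray(scl, dtype=float),
        scr=np.asarray(scr, dtype=float),
        hr=np.asarray(hr, dtype=float),
        events_in_window=list(events),
        anx=3,
        fs=fs,
    )


class TestExtractAll:
    def test_vector_shape_and_order(self, fs, rng):
        n = 256
        w = _window(
            5 + rng.normal(0, 0.1, n),
            5 + rng.normal(0, 0.01, n),
            np.abs(rng.normal(0, 0.1, n)),
            70 + rng.normal(0, 1, n),
            events=[ScrEvent(1.0, 0.2)],
        )
        baseline = BaselineStats(5.0, 5.0, 0.05)
        vec = extract_all(w, baseline)
        assert list(vec.index) == list(FEATURE_NAMES)
        assert len(vec) == 32
        assert np.all(np.isfinite(vec.to_numpy()))
        assert vec["GSR_nr"] == 1.0

    def test_constant_window(self, fs):
        n = 256
        w = _window(np.full(n, 4.0), np.full(n, 4.0), np.zeros(n), np.full(n, 70.0))
        vec = extract_all(w, BaselineStats(4.0, 4.0, 1.0))
        for stream in ("GSR", "SCL", "SCR"):
            for stat in ("std", "wl", "ssc", "wamp"):
                assert vec[f"{stream}_{stat}"] == 0.0
        assert vec["GSR_nr"] == 0.0
        assert vec["HR_std"] == 0.0

    def test_window_matching_baseline_gives_unit_mar(self, fs, rng):
        n = 256
        gsr = 6 + rng.normal(0, 0.05, n)
        scl = 5.5 + rng.normal(0, 0.01, n)
        scr = np.abs(rng.normal(0, 0.1, n))
        w = _window(gsr, scl, scr, np.full(n, 70.0))
        baseline = BaselineStats(mav(gsr), mav(scl), mav(scr))
        vec = extract_all(w, baseline)
        for stream in ("GSR", "SCL", "SCR"):
            assert vec[f"{stream}_mar"] == pytest.approx(1.0)
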