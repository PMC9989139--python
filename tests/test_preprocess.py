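"""Filtering, window bookkeeping, condition contrast and ITPC."""

import numpy as np
import pandas as pd
import pytest

from threatnet.preprocess import (
    EpochedSourceSeries,
    WindowScheme,
    antialias_lowpass,
    bandpass_filter,
    condition_contrast,
    itpc,
    slice_windows,
)

FS = 250.0


def make_series(data: np.ndarray, t0_index: int = 62) -> EpochedSourceSeries:
    return EpochedSourceSeries(
        subject="sub-00",
        condition="CS+",
        data=data,
        fs=FS,
        t0_index=t0_index,
        roi_names=[f"ROI{i:03d}" for i in range(data.shape[1])],
    )


class TestBandpass:
    def test_passband_tone_preserved(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 20 * t)
        y = bandpass_filter(x, 3, 45, FS)
        core = slice(500, 1500)
        assert np.abs(y[core]).max() > 0.95 * np.abs(x[core]).max()

    def test_stopband_tone_rejected(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass_filter(x, 3, 45, FS)
        core = slice(1000, 3000)
        assert np.abs(y[core]).max() < 0.1 * np.abs(x[core]).max()

    def test_idempotent_in_passband(self):
        rng = np.random.default_rng(0)
        x = bandpass_filter(rng.normal(size=4000), 10, 20, FS)
        once = bandpass_filter(x, 3, 45, FS)
        twice = bandpass_filter(once, 3, 45, FS)
        core = slice(500, 3500)
        rel = np.sqrt(np.mean((twice[core] - once[core]) ** 2)) / np.sqrt(
            np.mean(once[core] ** 2)
        )
        assert rel < 0.01

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 1000))
        lhs = bandpass_filter(2.0 * x + 3.0 * y, 3, 45, FS)
        rhs = 2.0 * bandpass_filter(x, 3, 45, FS) + 3.0 * bandpass_filter(y, 3, 45, FS)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros(100), 3, 125, FS)

    def test_antialias_lowpass_at_nyquist_is_noop_with_warning(self):
        x = np.random.default_rng(2).normal(size=500)
        with pytest.warns(RuntimeWarning, match="no-op"):
            y = antialias_lowpass(x, 125.0, FS)
        assert np.array_equal(x, y)


class TestWindows:
    def test_baseline_slice_is_62_samples(self):
        scheme = WindowScheme()
        sl = scheme.sample_slice("baseline", FS, 62, 438)
        assert (sl.start, sl.stop) == (0, 62)

    def test_post_stimulus_windows_tile_375_samples(self):
        scheme = WindowScheme()
        slices = [scheme.sample_slice(f"T{k}", FS, 62, 438) for k in range(1, 7)]
        covered = set()
        for sl in slices:
            samples = set(range(sl.start, sl.stop))
            assert not covered & samples  # pairwise disjoint
            covered |= samples
        assert len(covered) == 375
        assert covered == set(range(62, 437))

    def test_subwindows_partition_each_window(self):
        scheme = WindowScheme()
        for name in scheme.names:
            outer = scheme.sample_slice(name, FS, 62, 438)
            subs = scheme.subwindow_slices(name, FS, 62, 438)
            assert len(subs) == 5
            assert subs[0].start == outer.start and subs[-1].stop == outer.stop
            for a, b in zip(subs, subs[1:]):
                assert a.stop == b.start

    def test_window_beyond_epoch_is_named_in_error(self):
        scheme = WindowScheme(windows=[("huge", 0.0, 5000.0)])
        series = make_series(np.zeros((1, 2, 438)))
        with pytest.raises(ValueError, match="huge"):
            slice_windows(series, scheme)

    def test_empty_scheme_empty_mapping(self):
        series = make_series(np.zeros((1, 2, 438)))
        assert slice_windows(series, WindowScheme(windows=[])) == {}


class TestConditionContrast:
    @staticmethod
    def tables(rng):
        keys = pd.DataFrame(
            {"subject": np.repeat(["s1", "s2"], 3), "window": ["T1", "T2", "T3"] * 2}
        )
        a = keys.assign(value=rng.normal(size=6))
        b = keys.assign(value=rng.normal(size=6))
        return a, b

    def test_identical_tables_zero_contrast(self, rng):
        a, _ = self.tables(rng)
        out = condition_contrast(a, a.copy(), ["subject", "window"])
        assert np.allclose(out["value"], 0)

    def test_constant_offset(self, rng):
        a, _ = self.tables(rng)
        b = a.assign(value=a["value"] - 1.0)
        out = condition_contrast(a, b, ["subject", "window"])
        assert np.allclose(out["value"], 1.0)

    def test_equals_elementwise_subtraction(self, rng):
        a, b = self.tables(rng)
        out = condition_contrast(a, b, ["subject", "window"])
        merged = a.merge(b, on=["subject", "window"], suffixes=("_a", "_b"))
        assert np.allclose(
            out.sort_values(["subject", "window"])["value"].to_numpy(),
            (merged["value_a"] - merged["value_b"]).to_numpy(),
        )

    def test_key_mismatch_lists_missing(self, rng):
        a, b = self.tables(rng)
        b = b[b["window"] != "T3"]
        with pytest.raises(ValueError, match="T3"):
            condition_contrast(a, b, ["subject", "window"])


class TestItpc:
    def test_identical_trials_give_unit_coherence(self):
        t = np.arange(438) / FS
        trial = np.sin(2 * np.pi * 6 * t)
        data = np.tile(trial, (5, 1, 1))
        series = make_series(data)
        course = itpc(series, 0, (4, 8))
        assert np.allclose(course, 1.0, atol=1e-6)

    def test_uniform_phases_match_resultant_expectation(self):
        # expected resultant length of n independent uniform unit phasors is
        # ~0.886/sqrt(n); independent noise trials average down to it
        rng = np.random.default_rng(5)
        data = rng.normal(size=(100, 1, 1000))
        series = make_series(data, t0_index=62)
        course = itpc(series, 0, (4, 8))
        expected = 0.886 / np.sqrt(100)
        assert abs(course[100:-100].mean() - expected) < 0.2 * expected

    def test_bounded_in_unit_interval(self, rng):
        series = make_series(rng.normal(size=(8, 2, 438)))
        course = itpc(series, 1, (4, 8))
        assert (course >= 0).all() and (course <= 1).all()

    def test_single_trial_rejected(self):
        series = make_series(np.zeros((1, 2, 438)))
        with pytest.raises(ValueError, match="2 trials"):
            itpc(series, 0, (4, 8))
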