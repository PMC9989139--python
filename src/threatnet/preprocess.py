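"""Epoch bookkeeping, filtering, condition contrast and ITPC quality check.

Epoched source time series are stored trial x ROI x sample at a fixed
sampling rate (250 Hz by default), spanning -0.25 s to 1.5 s around stimulus
onset.  Sample indexing follows a fixed convention: sample k sits at
t_k = t_start + k/fs, and window boundaries in milliseconds map to sample
offsets by round-half-to-even of t*fs, half-open [start, end).  Under this
convention the canonical epoch holds 438 samples, the 250 ms baseline
occupies samples [0, 62) and the six post-stimulus windows T1..T6 tile
[62, 437) with no gaps or overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt


def _rint(x: float) -> int:
    return int(np.rint(x))


@dataclass
class EpochedSourceSeries:
    """Per-subject, per-condition epoched source-level time series."""

    subject: str
    condition: str
    data: np.ndarray  # trial x ROI x sample
    fs: float
    t0_index: int  # sample index of stimulus onset
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trial x ROI x sample")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError(
                f"ROI count {self.data.shape[1]} does not match "
                f"{len(self.roi_names)} roi_names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in epoched data")
        if not 0 <= self.t0_index < self.data.shape[2]:
            raise ValueError("t0_index outside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return (np.arange(self.n_samples) - self.t0_index) / self.fs


def default_windows() -> list[tuple[str, float, float]]:
    """Baseline plus six 250 ms windows covering 0-1500 ms post stimulus."""
    wins = [("baseline", -250.0, 0.0)]
    for k in range(6):
        wins.append((f"T{k + 1}", 250.0 * k, 250.0 * (k + 1)))
    return wins


@dataclass
class WindowScheme:
    """Ordered, contiguous analysis windows with 50 ms sub-windows.

    ``windows`` is a list of (name, start_ms, end_ms) relative to stimulus
    onset.  Each analysis window splits into ``subwindows_per_window`` equal
    sub-windows; with the 250 ms defaults these are the five 50 ms layers
    used for dynamic community detection.
    """

    windows: list[tuple[str, float, float]] = field(default_factory=default_windows)
    subwindows_per_window: int = 5

    def __post_init__(self) -> None:
        for (na, _, ea), (nb, sb, _) in zip(self.windows, self.windows[1:]):
            if not np.isclose(ea, sb):
                raise ValueError(f"windows {na} and {nb} are not contiguous")

    @property
    def names(self) -> list[str]:
        return [w[0] for w in self.windows]

    def sample_slice(
        self, name: str, fs: float, t0_index: int, n_samples: int
    ) -> slice:
        """Half-open sample slice of a named window within the epoch."""
        for wname, start_ms, end_ms in self.windows:
            if wname == name:
                lo = t0_index + _rint(start_ms / 1000.0 * fs)
                hi = t0_index + _rint(end_ms / 1000.0 * fs)
                if lo < 0 or hi > n_samples:
                    raise ValueError(
                        f"window {name!r} [{start_ms}, {end_ms}] ms exceeds the epoch"
                    )
                return slice(lo, hi)
        raise KeyError(f"unknown window {name!r}")

    def subwindow_slices(
        self, name: str, fs: float, t0_index: int, n_samples: int
    ) -> list[slice]:
        """Equal sub-window slices partitioning a named window exactly."""
        for wname, start_ms, end_ms in self.windows:
            if wname == name:
                k = self.subwindows_per_window
                edges = [
                    t0_index
                    + _rint((start_ms + (end_ms - start_ms) * j / k) / 1000.0 * fs)
                    for j in range(k + 1)
                ]
                if edges[0] < 0 or edges[-1] > n_samples:
                    raise ValueError(
                        f"window {name!r} [{start_ms}, {end_ms}] ms exceeds the epoch"
                    )
                return [slice(a, b) for a, b in zip(edges, edges[1:])]
        raise KeyError(f"unknown window {name!r}")


def bandpass_filter(
    data: np.ndarray, low_hz: float, high_hz: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis.

    Defaults elsewhere in the pipeline are 3-45 Hz at order 4.  The effective
    magnitude response is the squared Butterworth response because of the
    two-pass application.
    """
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(
            f"high cutoff {high_hz} Hz is at or above the Nyquist frequency {fs / 2} Hz"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def antialias_lowpass(
    data: np.ndarray, cutoff_hz: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; identity when the cutoff is >= Nyquist.

    A low-pass at or above Nyquist is mathematically vacuous for sampled
    data, so it is skipped with a warning rather than raising.
    """
    if cutoff_hz >= fs / 2:
        warnings.warn(
            f"low-pass cutoff {cutoff_hz} Hz >= Nyquist ({fs / 2} Hz); "
            "filter is a no-op",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.asarray(data, dtype=float)
    sos = butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def filter_series(
    series: EpochedSourceSeries,
    low_hz: float = 3.0,
    high_hz: float = 45.0,
    order: int = 4,
) -> EpochedSourceSeries:
    """Band-pass an epoched series per trial and ROI (zero phase)."""
    filtered = bandpass_filter(series.data, low_hz, high_hz, series.fs, order)
    return EpochedSourceSeries(
        subject=series.subject,
        condition=series.condition,
        data=filtered,
        fs=series.fs,
        t0_index=series.t0_index,
        roi_names=series.roi_names,
    )


def slice_windows(
    series: EpochedSourceSeries, scheme: WindowScheme
) -> dict[str, np.ndarray]:
    """Map window name -> trial x ROI x sample block (views, half-open)."""
    out: dict[str, np.ndarray] = {}
    for name in scheme.names:
        sl = scheme.sample_slice(name, series.fs, series.t0_index, series.n_samples)
        out[name] = series.data[:, :, sl]
    return out


def condition_contrast(
    table_csplus: pd.DataFrame,
    table_csminus: pd.DataFrame,
    keys: list[str],
    value: str = "value",
) -> pd.DataFrame:
    """Per-key CS+ minus CS- contrast of two aligned metric tables.

    Sign convention: threat minus safe, so threat-related increases are
    positive.  Both input tables are retained by callers that need the
    condition factor for the ANOVA stage.
    """
    a = table_csplus.set_index(keys)[value]
    b = table_csminus.set_index(keys)[value]
    missing = a.index.symmetric_difference(b.index)
    if len(missing):
        raise ValueError(f"condition tables misaligned; unmatched keys: {list(missing)}")
    out = (a - b).rename(value).reset_index()
    return out


def itpc(
    series: EpochedSourceSeries,
    roi: int | str,
    band: tuple[float, float],
    order: int = 4,
) -> np.ndarray:
    """Inter-trial phase coherence time course for one ROI in one band.

    Phases come from the analytic signal of the band-filtered data; ITPC at
    each sample is the modulus of the mean unit phasor across trials, hence
    always in [0, 1].  With n independent uniform phases the expectation is
    ~0.886/sqrt(n), so low values flag unreliable phase locking.
    """
    if series.n_trials < 2:
        raise ValueError("ITPC requires at least 2 trials")
    if isinstance(roi, str):
        roi = series.roi_names.index(roi)
    x = bandpass_filter(series.data[:, roi, :], band[0], band[1], series.fs, order)
    phases = np.angle(hilbert(x, axis=-1))
    return np.abs(np.exp(1j * phases).mean(axis=0))
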