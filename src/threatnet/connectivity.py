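"""Band power-envelope correlation networks and density thresholding.

The connectivity measure is the zero-lag Pearson correlation of band-limited
power envelopes: each ROI's series is band-pass filtered (theta 4-8 Hz or
alpha 8-12 Hz), the squared modulus of its analytic signal gives the power
envelope, and envelopes are correlated over the samples of an analysis
window.  Trial handling is either pooling (concatenate windowed samples
across trials before correlating - the default for 50 ms sub-windows whose
12-13 samples are too few on their own) or Fisher-z averaging of per-trial
correlations.  Correlations are rectified (absolute value) so proportional
density thresholding is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocess import bandpass_filter

BANDS: dict[str, tuple[float, float]] = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0)}


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted ROI x ROI matrix for one band/window/condition."""

    W: np.ndarray
    band: str = ""
    window: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        np.fill_diagonal(W, 0.0)
        self.W = W


@dataclass
class DensityGrid:
    """Evenly spaced proportional densities (20 values over [0.1, 0.6])."""

    min: float = 0.1
    max: float = 0.6
    n: int = 20
    densities: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.min < self.max <= 1:
            raise ValueError("need 0 < min < max <= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.densities = np.linspace(self.min, self.max, self.n)

    def __iter__(self):
        return iter(self.densities)

    def __len__(self) -> int:
        return self.n


def band_envelope(
    data: np.ndarray, band: str | tuple[float, float], fs: float, order: int = 4
) -> np.ndarray:
    """Power envelope (squared analytic-signal amplitude) of band-filtered data.

    Works on any array whose last axis is time (e.g. trial x ROI x sample).
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band ({lo}, {hi}) Hz outside the valid range (0, {fs / 2})")
    filtered = bandpass_filter(data, lo, hi, fs, order)
    return np.abs(hilbert(filtered, axis=-1)) ** 2


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    """Correlation matrix over the last axis; zero-variance rows give 0 edges."""
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"zero-variance envelope for node(s) {np.where(dead)[0].tolist()}; "
            "their edges are set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        sd = np.where(dead, 1.0, sd)
    c = (x @ x.T) / x.shape[-1]
    r = c / np.outer(sd, sd)
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    return np.clip(r, -1.0, 1.0)


def envelope_correlation_matrix(
    envelopes: np.ndarray,
    window: slice | None = None,
    pool_trials: bool = True,
    band: str = "",
    window_name: str = "",
    condition: str = "",
) -> ConnectivityMatrix:
    """Envelope-correlation matrix over one window's samples.

    ``envelopes`` is trial x ROI x sample.  With ``pool_trials`` the windowed
    samples of all trials are concatenated before a single Pearson
    correlation; otherwise per-trial correlations are averaged on the Fisher
    z-scale and back-transformed.  The result is rectified (absolute value)
    with a zero diagonal.
    """
    env = np.asarray(envelopes, dtype=float)
    if env.ndim == 2:
        env = env[None]
    if window is not None:
        env = env[:, :, window]
    n_trials, n_rois, n_samp = env.shape
    if n_samp < 3:
        raise ValueError(f"window has {n_samp} samples; need >= 3")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if pool_trials:
        # concatenate windowed samples across trials; trial-level envelope
        # co-fluctuations are part of the coupling signal and are kept
        pooled = np.moveaxis(env, 1, 0).reshape(n_rois, n_trials * n_samp)
        r = _pearson_matrix(pooled)
    else:
        zs = []
        for t in range(n_trials):
            rt = _pearson_matrix(env[t])
            zs.append(np.arctanh(np.clip(rt, -1 + 1e-12, 1 - 1e-12)))
        r = np.tanh(np.mean(zs, axis=0))
    W = np.abs(r)
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(W=W, band=band, window=window_name, condition=condition)


def proportional_threshold(W: np.ndarray | ConnectivityMatrix, density: float) -> np.ndarray:
    """Binarize by keeping the ceil(density * N(N-1)/2) strongest edges.

    Ties at the cut boundary are broken by (i, j) lexicographic order, so the
    kept edge sets are exactly nested across increasing densities.
    """
    if isinstance(W, ConnectivityMatrix):
        W = W.W
    W = np.asarray(W, dtype=float)
    if not 0 < density <= 1:
        raise ValueError(f"density {density} outside (0, 1]")
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    k = int(np.ceil(density * iu.size))
    order = np.lexsort((ju, iu, -W[iu, ju]))  # weight desc, then (i, j) asc
    keep = order[:k]
    A = np.zeros((n, n), dtype=int)
    A[iu[keep], ju[keep]] = 1
    A[ju[keep], iu[keep]] = 1
    return A
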