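"""Time-resolved effective connectivity via dual-Kalman MVAR and PDC.

A time-varying multivariate autoregressive (MVAR) model

    x_t = sum_r A_r(t) x_{t-r} + w_t

is estimated by a dual Kalman scheme: a signal filter tracks the (possibly
noise-contaminated) observations, and a weight filter tracks the vectorised
AR coefficients under random-walk dynamics with process-noise scale q.  The
two recursions are coupled: the weight filter regresses on the signal
filter's output, and the signal filter predicts through the current weight
estimates.  Partial directed coherence (PDC) is then evaluated per time
point from the time-varying coefficients,

    Abar(f, t) = I - sum_r A_r(t) exp(-i 2 pi f r / fs)
    pi_{i<-j}(f, t) = |Abar_ij| / sqrt(sum_k |Abar_kj|^2),

so for every source channel j the squared outflows over all targets sum to
one at each (f, t).  Directed influences are declared significant against a
null of time-reversed (and circularly shifted) trials, which destroys
directed temporal structure while preserving the power spectrum.

Convention: coefficient matrices follow A_r[i, j] = influence of channel j's
past on channel i; ``TPDCResult.values[source, target, f, t]`` stores the
source -> target flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import BANDS
from .preprocess import WindowScheme


@dataclass
class TVMVARModel:
    """Time-varying MVAR coefficients from the dual Kalman filter."""

    A: np.ndarray  # T x p x N x N
    sigma: np.ndarray  # N x N innovation covariance (diagonal estimate)
    order: int
    q: float
    fs: float
    burn_in: int
    innovations: np.ndarray | None = None  # T x N


@dataclass
class TPDCResult:
    """PDC values with surrogate thresholds and directionality calls."""

    values: np.ndarray  # source x target x freq x time
    freqs: np.ndarray
    observed: np.ndarray | None = None  # source x target summary
    threshold: np.ndarray | None = None
    significant: np.ndarray | None = None
    direction_class: dict = field(default_factory=dict)


def _as_batch(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("data must be (channels, samples) or (batch, channels, samples)")
    return data


def _dekf_batch(
    data: np.ndarray,
    order: int,
    q: float,
    init_scale: float,
    observation_noise: float,
    sigma_forget: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched dual Kalman recursion.

    data: (B, N, T).  Returns (A (B, T, p, N, N), sigma (B, N)).

    The weight covariance is shared across target channels (they regress on
    the same lagged predictors and the gain uses the channel-mean innovation
    variance), which keeps the recursion exactly decoupled per channel and
    cheap enough to batch across surrogates.
    """
    B, N, T = data.shape
    p = order
    k = N * p
    y = data
    # signal filter state (scalar covariance per batch)
    x_filt = np.zeros((B, N, T))
    p_x = np.full(B, init_scale)
    # weight filter
    w = np.zeros((B, N, k))
    P = np.tile(np.eye(k) * init_scale, (B, 1, 1))
    sigma = np.ones((B, N))
    A_out = np.zeros((B, T, p, N, N))

    for t in range(T):
        if t < p:
            x_filt[:, :, t] = y[:, :, t]
            continue
        phi = np.concatenate(
            [x_filt[:, :, t - r] for r in range(1, p + 1)], axis=1
        )  # (B, k)
        x_pred = np.einsum("bnk,bk->bn", w, phi)
        # signal filter: random-walk covariance, measurement noise R
        if observation_noise > 0:
            p_pred = p_x + q
            gain = p_pred / (p_pred + observation_noise)
            x_filt[:, :, t] = x_pred + gain[:, None] * (y[:, :, t] - x_pred)
            p_x = (1 - gain) * p_pred
        else:
            x_filt[:, :, t] = y[:, :, t]
        # weight filter: scalar observation per channel with shared gain
        Pphi = np.einsum("bij,bj->bi", P, phi)
        s = np.einsum("bi,bi->b", phi, Pphi) + sigma.mean(axis=1)
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise ValueError(
                "numerically singular innovation covariance in the weight "
                "filter; increase q or the regularization (init_scale)"
            )
        K = Pphi / s[:, None]  # (B, k)
        innov = x_filt[:, :, t] - x_pred  # (B, N)
        w = w + K[:, None, :] * innov[:, :, None]
        P = P - K[:, :, None] * Pphi[:, None, :]
        P[:, np.arange(k), np.arange(k)] += q
        sigma = (1 - sigma_forget) * sigma + sigma_forget * innov**2
        A_out[:, t] = w.reshape(B, N, p, N).transpose(0, 2, 1, 3)
    # backfill the first p samples with the first estimated coefficients
    A_out[:, :p] = A_out[:, p : p + 1]
    return A_out, sigma


def fit_dekf_mvar(
    series: np.ndarray,
    order: int = 5,
    q: float = 1e-3,
    init_scale: float = 1.0,
    fs: float = 250.0,
    observation_noise: float = 0.0,
    sigma_forget: float = 0.02,
) -> TVMVARModel:
    """Dual-Kalman time-varying MVAR fit of one (channels x samples) series.

    ``q`` is the random-walk process-noise scale of the coefficient state:
    larger values track faster changes at the price of noisier estimates.
    Estimates before the burn-in of ``5 * order`` samples are unreliable and
    are excluded from the summaries downstream.
    """
    data = _as_batch(series)
    if data.shape[0] != 1:
        raise ValueError("fit_dekf_mvar expects a single series; see surrogate test")
    N, T = data.shape[1], data.shape[2]
    if order < 1:
        raise ValueError("order must be >= 1")
    if T <= 10 * order:
        raise ValueError(
            f"series of {T} samples too short for order {order} (need > {10 * order})"
        )
    A, sig = _dekf_batch(data, order, q, init_scale, observation_noise, sigma_forget)
    return TVMVARModel(
        A=A[0],
        sigma=np.diag(sig[0]),
        order=order,
        q=q,
        fs=fs,
        burn_in=5 * order,
    )


def fit_ols_mvar(series: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Stationary least-squares MVAR fit: (A (p x N x N), residual cov)."""
    x = np.asarray(series, dtype=float)
    N, T = x.shape
    p = order
    Y = x[:, p:].T  # (T-p, N)
    X = np.concatenate([x[:, p - r : T - r].T for r in range(1, p + 1)], axis=1)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    A = coef.T.reshape(N, p, N).transpose(1, 0, 2)  # p x N x N
    resid = Y - X @ coef
    cov = resid.T @ resid / max(len(Y) - X.shape[1], 1)
    return A, cov


def select_order(
    series: np.ndarray, max_order: int = 10, criterion: str = "aic"
) -> int:
    """MVAR order by information criterion on a stationary OLS fit."""
    x = np.asarray(series, dtype=float)
    N, T = x.shape
    best, best_p = np.inf, 1
    for p in range(1, max_order + 1):
        _, cov = fit_ols_mvar(x, p)
        n_eff = T - p
        _, logdet = np.linalg.slogdet(cov + 1e-12 * np.eye(N))
        k = p * N * N
        score = logdet + (2 * k / n_eff if criterion == "aic"
                          else k * np.log(n_eff) / n_eff)
        if score < best:
            best, best_p = score, p
    return best_p


def pdc_from_coefficients(
    A: np.ndarray, freqs: np.ndarray, fs: float
) -> np.ndarray:
    """PDC (source x target x freq x time) from coefficients A (T x p x N x N).

    Accepts a stationary p x N x N array as a single time point.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 3:
        A = A[None]
    T, p, N, _ = A.shape
    freqs = np.asarray(freqs, dtype=float)
    phases = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / fs)  # (F, p)
    Abar = np.eye(N)[None, None] - np.einsum("tpij,fp->ftij", A, phases)  # (F,T,N,N)
    mag = np.abs(Abar)
    colnorm = np.sqrt((mag**2).sum(axis=2))  # (F, T, N) over targets k
    pi = mag / colnorm[:, :, None, :]  # (F, T, target, source)
    return pi.transpose(3, 2, 0, 1)  # source x target x F x T


def tpdc_spectrum(model: TVMVARModel, freqs: np.ndarray) -> TPDCResult:
    """Time-frequency PDC of a fitted time-varying MVAR model."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= model.fs / 2):
        raise ValueError("freqs must lie strictly inside (0, fs/2)")
    values = pdc_from_coefficients(model.A, freqs, model.fs)
    return TPDCResult(values=values, freqs=freqs)


def default_freq_grid(fmin: float = 2.0, fmax: float = 45.0, step: float = 0.5) -> np.ndarray:
    return np.round(np.arange(fmin, fmax + 1e-9, step), 10)


def band_freq_indices(freqs: np.ndarray, band: str | tuple[float, float]) -> np.ndarray:
    lo, hi = BANDS[band] if isinstance(band, str) else band
    idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if idx.size == 0:
        raise ValueError(f"no frequencies of the grid fall inside band ({lo}, {hi}) Hz")
    return idx


def band_window_summary(
    values: np.ndarray,
    freqs: np.ndarray,
    band: str | tuple[float, float],
    scheme: WindowScheme,
    fs: float,
    t0_index: int,
) -> pd.DataFrame:
    """Mean PDC per directed pair over a band's frequencies and each window.

    ``values`` is source x target x freq x time, with the time axis aligned
    to the epoch's samples.
    """
    f_idx = band_freq_indices(np.asarray(freqs), band)
    n = values.shape[0]
    n_samples = values.shape[3]
    band_name = band if isinstance(band, str) else f"{band[0]}-{band[1]}Hz"
    rows = []
    for wname in scheme.names:
        sl = scheme.sample_slice(wname, fs, t0_index, n_samples)
        if sl.stop <= sl.start:
            raise ValueError(f"window {wname!r} selects no samples")
        block = values[:, :, f_idx, sl]  # (N, N, F_b, T_w)
        mean = block.mean(axis=(2, 3))
        for s in range(n):
            for t in range(n):
                if s == t:
                    continue
                rows.append(
                    {"source": s, "target": t, "band": band_name,
                     "window": wname, "value": float(mean[s, t])}
                )
    return pd.DataFrame(rows)


def time_reverse(data: np.ndarray) -> np.ndarray:
    """Reverse the time axis (an involution: reversing twice is identity)."""
    return np.asarray(data)[..., ::-1].copy()


def _summary_stat(
    data: np.ndarray,
    order: int,
    q: float,
    init_scale: float,
    fs: float,
    freqs: np.ndarray,
    f_idx: np.ndarray,
    average_trials: bool = True,
) -> np.ndarray:
    """Band-mean PDC summaries (source x target) after burn-in.

    ``data`` is (B, trials, N, T); returns (B, N, N) when averaging across
    trials, (B, trials, N, N) otherwise.
    """
    B, n_trials, N, T = data.shape
    flat = data.reshape(B * n_trials, N, T)
    A, _ = _dekf_batch(flat, order, q, init_scale, 0.0, 0.02)
    burn = 5 * order
    vals = pdc_from_coefficients_batch(A[:, burn:], freqs, fs, f_idx)
    vals = vals.reshape(B, n_trials, N, N)
    return vals.mean(axis=1) if average_trials else vals


def pdc_from_coefficients_batch(
    A: np.ndarray, freqs: np.ndarray, fs: float, f_idx: np.ndarray
) -> np.ndarray:
    """Mean band PDC (batch x source x target) from batched coefficients."""
    Bt, T, p, N, _ = A.shape
    phases = np.exp(
        -2j * np.pi * np.outer(freqs[f_idx], np.arange(1, p + 1)) / fs
    )
    Abar = np.eye(N)[None, None] - np.einsum("btpij,fp->bftij", A, phases)
    mag = np.abs(Abar)
    colnorm = np.sqrt((mag**2).sum(axis=3, keepdims=True))
    pi = mag / colnorm  # (B, F, T, target, source)
    return pi.mean(axis=(1, 2)).transpose(0, 2, 1)  # (B, source, target)


def time_reversal_surrogate_test(
    series: np.ndarray,
    n_surrogates: int = 1000,
    alpha: float = 0.001,
    order: int = 2,
    q: float = 1e-3,
    init_scale: float = 1.0,
    fs: float = 250.0,
    band: str | tuple[float, float] | None = None,
    freqs: np.ndarray | None = None,
    seed: int = 0,
) -> TPDCResult:
    """Directed-pair significance against a time-reversal null.

    The observed statistic is the trial-averaged band-mean PDC per directed
    pair (after burn-in).  Each surrogate recomputes it after time-reversing
    a random subset of trials: reversal preserves every trial's spectrum but
    destroys (flips) its directed temporal structure, and because stationary
    trials are time-reversible under the no-coupling null the observed
    statistic is exchangeable with the surrogates, giving a calibrated
    randomization test.  A pair is significant when its observed value
    exceeds the (1 - alpha) quantile of its own null.  At least 2 trials are
    required so the randomization has support.
    """
    if n_surrogates < 19:
        raise ValueError("n_surrogates must be >= 19")
    if alpha < 1.0 / (n_surrogates + 1):
        raise ValueError(
            f"alpha={alpha} finer than the resolution of {n_surrogates} "
            f"surrogates (min {1.0 / (n_surrogates + 1):.4g})"
        )
    data = np.asarray(series, dtype=float)
    if data.ndim == 2:
        data = data[None]  # trials x N x T
    n_trials, N, T = data.shape
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    f_idx = (
        band_freq_indices(freqs, band) if band is not None
        else np.arange(freqs.size)
    )
    rng = np.random.default_rng(seed)

    if n_trials < 2:
        raise ValueError("the time-reversal randomization needs >= 2 trials")
    # the statistic is a trial average, so each surrogate is an average of
    # per-trial forward/reversed statistics: fit each trial twice, not once
    # per surrogate
    fwd = _summary_stat(data[None], order, q, init_scale, fs, freqs, f_idx,
                        average_trials=False)[0]
    rev = _summary_stat(time_reverse(data)[None], order, q, init_scale, fs,
                        freqs, f_idx, average_trials=False)[0]
    observed = fwd.mean(axis=0)
    flips = rng.random((n_surrogates, n_trials)) < 0.5
    picks = np.where(flips[:, :, None, None], rev[None], fwd[None])
    null = picks.mean(axis=1)

    threshold = np.quantile(null, 1 - alpha, axis=0)
    significant = observed > threshold
    np.fill_diagonal(significant, False)
    classes = direction_classes(significant)
    return TPDCResult(
        values=np.empty((0,)),
        freqs=freqs,
        observed=observed,
        threshold=threshold,
        significant=significant,
        direction_class=classes,
    )


def classify_directionality(sig_ij: bool, sig_ji: bool) -> str:
    """Directionality call for one pair from its two significance flags."""
    if sig_ij and sig_ji:
        return "bi"
    if sig_ij:
        return "uni(i->j)"
    if sig_ji:
        return "uni(j->i)"
    return "none"


def direction_classes(significant: np.ndarray) -> dict[tuple[int, int], str]:
    """Per undirected pair: none / uni (with orientation) / bi."""
    n = significant.shape[0]
    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            out[(i, j)] = classify_directionality(
                bool(significant[i, j]), bool(significant[j, i])
            )
    return out
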