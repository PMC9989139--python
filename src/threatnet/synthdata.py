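"""Synthetic cohorts with planted oscillatory, community and coupling structure.

The generator emulates the statistical structure the downstream analysis
assumes: per-ROI band-limited oscillations (damped AR(2) processes whose
complex-conjugate pole pair sets centre frequency and bandwidth), community
structure planted by coupling every ROI to a hidden per-community driver
oscillator, directed ROI-to-ROI coupling injected as lagged cross-terms,
condition-dependent community switching across 50 ms sub-window layers, an
optional exogenous perturbation (a TMS stand-in: a transient multiplicative
gain on the configured coupling coefficients), and behavioural covariates
(threat ratings, heart rate) tied to the planted switching rate through a
latent factor.

Everything is seeded through ``numpy.random.SeedSequence`` so a fixed seed
yields bit-identical output, and every distinct coefficient regime is checked
for covariance stationarity (companion spectral radius < 1) at generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochedSourceSeries, WindowScheme, _rint
from .atlas import roi_labels

CONDITIONS = ("CS+", "CS-")
_COND_FILE = {"CS+": "CSplus", "CS-": "CSminus"}


@dataclass
class Coupling:
    """Directed lagged coupling between two ROI channels.

    ``coef`` applies between ``start_ms`` and ``end_ms`` (relative to
    stimulus onset; ``None`` means from the epoch start / to the epoch end).
    """

    source: int
    target: int
    coef: float
    lag: int = 1
    band: str = "theta"
    start_ms: float | None = None
    end_ms: float | None = None


@dataclass
class Perturbation:
    """Transient multiplicative change of the coupling coefficients.

    Models exogenous stimulation delivered at ``onset_ms`` after the
    stimulus: for ``duration_ms`` every configured ROI-to-ROI coupling
    coefficient is multiplied by ``gain``, only for ``condition``.
    """

    onset_ms: float = 1000.0
    duration_ms: float = 250.0
    gain: float = 2.0
    condition: str = "CS+"


@dataclass
class BehaviourEffects:
    """Linear structure tying behaviour to condition and planted switching.

    Ratings and heart rate share a latent affect factor so that their
    correlation is plantable (~0.5 by default); the standardized per-subject
    switching-rate deviation enters the rating with weight
    ``flexibility_corr`` so the population behaviour-flexibility correlation
    equals that value.
    """

    rating_effect: float = 2.0  # CS+ minus CS- rating mean
    rating_sd: float = 1.0
    rating_base: float = 3.0
    heart_effect: float = 8.0  # bpm
    heart_sd: float = 4.0
    heart_base: float = 70.0
    rating_heart_corr: float = 0.5
    flexibility_corr: float = 0.6
    rate_sd: float = 0.1  # per-subject SD of the planted switching rate


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort."""

    n_subjects: int = 20
    n_rois: int = 90
    fs: float = 250.0
    epoch_span: tuple[float, float] = (-0.25, 1.5)
    n_trials_per_condition: dict[str, int] = field(
        default_factory=lambda: {"CS+": 36, "CS-": 24}
    )
    # (centre frequency Hz, pole radius) per band; ROIs cycle through bands
    band_oscillators: list[tuple[float, float]] = field(
        default_factory=lambda: [(6.0, 0.95), (10.0, 0.95)]
    )
    coupling_spec: list[Coupling] = field(default_factory=list)
    base_partition: np.ndarray | None = None  # ROI -> community label; None = no drivers
    switch_rates: dict[str, float] = field(
        default_factory=lambda: {"CS+": 0.4, "CS-": 0.2}
    )
    baseline_switch_rate: float = 0.05
    community_coupling: float = 0.9  # driver -> ROI lag-1 coefficient
    perturbation: Perturbation | None = None
    behaviour_effects: BehaviourEffects = field(default_factory=BehaviourEffects)
    noise_sd: float = 1.0
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for cond, r in self.switch_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"switch rate for {cond} outside [0, 1]: {r}")
        if not 0 <= self.baseline_switch_rate <= 1:
            raise ValueError("baseline_switch_rate outside [0, 1]")
        for c in self.coupling_spec:
            if not (0 <= c.source < self.n_rois and 0 <= c.target < self.n_rois):
                raise ValueError(
                    f"coupling {c.source}->{c.target} references an invalid ROI"
                )
        if self.base_partition is not None:
            self.base_partition = np.asarray(self.base_partition, dtype=int)
            if self.base_partition.shape != (self.n_rois,):
                raise ValueError("base_partition must have one label per ROI")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_span
        return _rint((t1 - t0) * self.fs)

    @property
    def t0_index(self) -> int:
        return _rint(-self.epoch_span[0] * self.fs)

    def roi_names(self) -> list[str]:
        return roi_labels(self.n_rois)


@dataclass
class GroundTruth:
    """Planted quantities for recovery tests (round-trips through JSON)."""

    planted_Q: dict[str, np.ndarray]  # condition -> subject x ROI x layer labels
    layer_names: list[str]
    planted_coupling: list[dict]
    planted_flexibility: dict[str, np.ndarray]  # condition -> subject x ROI
    planted_rates: dict[str, np.ndarray]  # condition -> per-subject switch rate
    behaviour_table: pd.DataFrame

    def to_json(self, path: Path) -> None:
        payload = {
            "planted_Q": {k: v.tolist() for k, v in self.planted_Q.items()},
            "layer_names": self.layer_names,
            "planted_coupling": self.planted_coupling,
            "planted_flexibility": {
                k: v.tolist() for k, v in self.planted_flexibility.items()
            },
            "planted_rates": {k: v.tolist() for k, v in self.planted_rates.items()},
            "behaviour_table": self.behaviour_table.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_Q={k: np.asarray(v, dtype=int) for k, v in d["planted_Q"].items()},
            layer_names=d["layer_names"],
            planted_coupling=d["planted_coupling"],
            planted_flexibility={
                k: np.asarray(v, dtype=float)
                for k, v in d["planted_flexibility"].items()
            },
            planted_rates={
                k: np.asarray(v, dtype=float) for k, v in d["planted_rates"].items()
            },
            behaviour_table=pd.DataFrame(d["behaviour_table"]),
        )


def ar2_coefficients(centre_hz: float, radius: float, fs: float) -> tuple[float, float]:
    """AR(2) coefficients for a damped oscillator with the given pole pair."""
    if not 0 < radius < 1:
        raise ValueError("pole radius must lie in (0, 1) for stationarity")
    theta = 2 * np.pi * centre_hz / fs
    return 2 * radius * np.cos(theta), -(radius**2)


def generate_community_timeline(
    base_partition: np.ndarray,
    switch_rates: float | np.ndarray,
    n_layers: int,
    seed: int | np.random.Generator,
    force_change: bool = True,
) -> np.ndarray:
    """Planted ROI x layer community labels from a Markov switching process.

    Layer 1 equals ``base_partition``; at each subsequent layer every node
    independently resamples its community with the transition's switch
    probability.  With ``force_change`` the resampled label always differs,
    so the expected nodal flexibility equals the switch rate exactly.

    ``switch_rates`` is a scalar or one probability per transition
    (length ``n_layers - 1``).
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    base = np.asarray(base_partition, dtype=int)
    labels = np.unique(base)
    rates = np.broadcast_to(np.asarray(switch_rates, dtype=float), (n_layers - 1,))
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError(f"switch rate outside [0, 1]: {np.asarray(switch_rates)}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = base.size
    Q = np.empty((n, n_layers), dtype=int)
    Q[:, 0] = base
    for q in range(1, n_layers):
        prev = Q[:, q - 1]
        switch = rng.random(n) < rates[q - 1]
        new = prev.copy()
        if labels.size > 1:
            # draw uniformly among the other labels when a change is forced
            draws = rng.integers(0, labels.size - (1 if force_change else 0), size=n)
            for i in np.where(switch)[0]:
                if force_change:
                    others = labels[labels != prev[i]]
                    new[i] = others[draws[i] % others.size]
                else:
                    new[i] = labels[draws[i]]
        Q[:, q] = new
    return Q


def _layer_slices(config: SyntheticConfig, scheme: WindowScheme) -> tuple[list[str], list[slice]]:
    """Names and sample slices of all sub-window layers, in temporal order."""
    names, slices = [], []
    for wname in scheme.names:
        subs = scheme.subwindow_slices(
            wname, config.fs, config.t0_index, config.n_samples
        )
        for j, sl in enumerate(subs):
            names.append(f"{wname}.s{j + 1}")
            slices.append(sl)
    return names, slices


def cohort_timeline_rates(config: SyntheticConfig, condition: str, n_layers: int,
                          subwins: int, rate_offset: float = 0.0) -> np.ndarray:
    """Per-transition switch probabilities: baseline rate inside the baseline
    window, the condition's rate for every later transition."""
    post = float(np.clip(config.switch_rates[condition] + rate_offset, 0.0, 1.0))
    rates = np.full(n_layers - 1, post)
    # transitions whose destination layer is still in the baseline window
    rates[: subwins - 1] = config.baseline_switch_rate
    return rates


def _companion_radius(a_lags: list[np.ndarray]) -> float:
    p = len(a_lags)
    n = a_lags[0].shape[0]
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(a_lags, axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _roi_block_coeffs(
    config: SyntheticConfig, gains: dict[int, float]
) -> list[np.ndarray]:
    """Lag matrices of the ROI sub-block for a given coupling-gain state."""
    n = config.n_rois
    max_lag = max([2] + [c.lag for c in config.coupling_spec])
    a_lags = [np.zeros((n, n)) for _ in range(max_lag)]
    for i in range(n):
        f, r = config.band_oscillators[i % len(config.band_oscillators)]
        a1, a2 = ar2_coefficients(f, r, config.fs)
        a_lags[0][i, i] = a1
        a_lags[1][i, i] = a2
    for k, c in enumerate(config.coupling_spec):
        a_lags[c.lag - 1][c.target, c.source] += c.coef * gains.get(k, 1.0)
    return a_lags


def _coupling_gain_segments(
    config: SyntheticConfig, condition: str
) -> list[tuple[int, int, dict[int, float]]]:
    """Partition the epoch into segments of constant coupling gains.

    Returns (start_sample, end_sample, {coupling index -> gain}) triples.
    Gains combine each coupling's own activity window and the perturbation.
    """
    fs, t0, n = config.fs, config.t0_index, config.n_samples
    edges = {0, n}
    for c in config.coupling_spec:
        if c.start_ms is not None:
            edges.add(int(np.clip(t0 + _rint(c.start_ms / 1000 * fs), 0, n)))
        if c.end_ms is not None:
            edges.add(int(np.clip(t0 + _rint(c.end_ms / 1000 * fs), 0, n)))
    pert = config.perturbation
    if pert is not None and condition == pert.condition:
        p0 = int(np.clip(t0 + _rint(pert.onset_ms / 1000 * fs), 0, n))
        p1 = int(np.clip(t0 + _rint((pert.onset_ms + pert.duration_ms) / 1000 * fs), 0, n))
        edges.update((p0, p1))
    cuts = sorted(edges)
    out = []
    for a, b in zip(cuts, cuts[1:]):
        gains: dict[int, float] = {}
        for k, c in enumerate(config.coupling_spec):
            lo = 0 if c.start_ms is None else t0 + _rint(c.start_ms / 1000 * fs)
            hi = n if c.end_ms is None else t0 + _rint(c.end_ms / 1000 * fs)
            g = 1.0 if (a >= lo and b <= hi) else 0.0
            if (
                pert is not None
                and condition == pert.condition
                and a >= t0 + _rint(pert.onset_ms / 1000 * fs)
                and b <= t0 + _rint((pert.onset_ms + pert.duration_ms) / 1000 * fs)
            ):
                g *= pert.gain
            gains[k] = g
        out.append((a, b, gains))
    return out


def generate_mvar_series(
    config: SyntheticConfig,
    condition: str,
    subject_seed: int,
    timeline: np.ndarray | None = None,
    scheme: WindowScheme | None = None,
    subject: str = "sub-00",
) -> EpochedSourceSeries:
    """Simulate one subject/condition as a piecewise-stationary MVAR process.

    Each ROI is a damped AR(2) oscillator at its configured band centre;
    community structure is injected by a lag-1 coefficient from the hidden
    driver oscillator of the ROI's current community (per sub-window layer of
    ``timeline``); directed ROI-to-ROI couplings follow ``coupling_spec``
    with the perturbation's multiplicative gain where configured.  The
    process is warmed up for 200 samples before the epoch starts and every
    distinct coefficient regime is verified stationary.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    scheme = scheme or WindowScheme()
    rng = np.random.default_rng(np.random.SeedSequence(subject_seed))
    n, fs, n_samp = config.n_rois, config.fs, config.n_samples

    drivers = config.base_partition is not None
    if drivers:
        comm_labels = np.unique(config.base_partition)
        n_comm = comm_labels.size
        if timeline is None:
            names, slices = _layer_slices(config, scheme)
            rates = cohort_timeline_rates(
                config, condition, len(slices), scheme.subwindows_per_window
            )
            timeline = generate_community_timeline(
                config.base_partition, rates, len(slices), rng
            )
        _, slices = _layer_slices(config, scheme)
        if timeline.shape != (n, len(slices)):
            raise ValueError("timeline must be ROI x layer for the window scheme")
        # per-sample layer index (trailing samples stay in the last layer)
        layer_of = np.full(n_samp, len(slices) - 1, dtype=int)
        for li, sl in enumerate(slices):
            layer_of[sl] = li
    else:
        n_comm = 0
        layer_of = np.zeros(n_samp, dtype=int)

    n_ch = n + n_comm
    gain_segments = _coupling_gain_segments(config, condition)

    # stability: drivers never receive input, so the companion spectrum is
    # the union of the (diagonal, stable-by-construction) driver block and
    # the ROI block, which only changes with the coupling-gain state
    for a, b, gains in gain_segments:
        roi_lags = _roi_block_coeffs(config, gains)
        rho = _companion_radius(roi_lags)
        if rho >= 1:
            hot = max(
                range(len(config.coupling_spec)),
                key=lambda k: abs(config.coupling_spec[k].coef * gains.get(k, 1.0)),
                default=-1,
            )
            culprit = (
                f" (largest active coefficient: coupling "
                f"{config.coupling_spec[hot].source}->{config.coupling_spec[hot].target})"
                if hot >= 0
                else ""
            )
            raise ValueError(
                f"unstable AR configuration in samples [{a}, {b}): spectral "
                f"radius {rho:.3f} >= 1{culprit}"
            )

    # assemble per-(segment, layer) lag matrices for the full channel set
    max_lag = max([2] + [c.lag for c in config.coupling_spec])

    def full_coeffs(gains: dict[int, float], layer: int) -> list[np.ndarray]:
        a_lags = [np.zeros((n_ch, n_ch)) for _ in range(max_lag)]
        roi = _roi_block_coeffs(config, gains)
        for r in range(max_lag):
            a_lags[r][:n, :n] = roi[r]
        if drivers:
            for j, lab in enumerate(comm_labels):
                f, r_ = config.band_oscillators[0]
                a1, a2 = ar2_coefficients(f, r_, fs)
                a_lags[0][n + j, n + j] = a1
                a_lags[1][n + j, n + j] = a2
            members = timeline[:, layer]
            for i in range(n):
                j = int(np.searchsorted(comm_labels, members[i]))
                a_lags[0][i, n + j] += config.community_coupling
        return a_lags

    n_trials = config.n_trials_per_condition[condition]
    burn = 200
    total = burn + n_samp
    noise = rng.normal(scale=config.noise_sd, size=(n_trials, n_ch, total))
    X = np.zeros((n_trials, n_ch, total))

    # per-sample (segment, layer) state; burn-in runs under the first state
    seg_of = np.zeros(n_samp, dtype=int)
    for si, (a, b, _) in enumerate(gain_segments):
        seg_of[a:b] = si
    state_of = seg_of * (layer_of.max() + 1) + layer_of
    cache: dict[int, list[np.ndarray]] = {}

    def coeffs_for(t_epoch: int) -> list[np.ndarray]:
        s = int(state_of[t_epoch])
        if s not in cache:
            si, li = divmod(s, layer_of.max() + 1)
            cache[s] = full_coeffs(gain_segments[si][2], li)
        return cache[s]

    for t in range(total):
        a_lags = coeffs_for(max(t - burn, 0))
        acc = noise[:, :, t].copy()
        for r, A in enumerate(a_lags, start=1):
            if t - r >= 0:
                acc += X[:, :, t - r] @ A.T
        X[:, :, t] = acc

    data = X[:, :n, burn:]
    if config.standardize:
        mu = data.mean(axis=-1, keepdims=True)
        sd = data.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        data = (data - mu) / sd
    return EpochedSourceSeries(
        subject=subject,
        condition=condition,
        data=data,
        fs=fs,
        t0_index=config.t0_index,
        roi_names=config.roi_names(),
    )


def _behaviour_draws(
    cfg: BehaviourEffects, z_flex: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Subject x condition ratings and heart rates with planted structure."""
    n = z_flex.size
    fc = cfg.flexibility_corr
    a = np.sqrt(cfg.rating_heart_corr)
    if fc**2 + a**2 > 1:
        raise ValueError("flexibility_corr and rating_heart_corr jointly infeasible")
    b = np.sqrt(1 - fc**2 - a**2)
    c = np.sqrt(1 - a**2)
    u = rng.normal(size=n)
    rows = []
    for cond in CONDITIONS:
        e1 = rng.normal(size=n)
        e2 = rng.normal(size=n)
        rating_z = fc * z_flex + a * u + b * e1
        heart_z = a * u + c * e2
        shift = cfg.rating_effect if cond == "CS+" else 0.0
        hshift = cfg.heart_effect if cond == "CS+" else 0.0
        for s in range(n):
            rows.append(
                {
                    "subject": f"sub-{s:02d}",
                    "condition": cond,
                    "rating": cfg.rating_base + shift + cfg.rating_sd * rating_z[s],
                    "heart_rate": cfg.heart_base + hshift + cfg.heart_sd * heart_z[s],
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[dict[tuple[str, str], EpochedSourceSeries], GroundTruth]:
    """Simulate a full cohort in memory.

    Returns a {(subject, condition): series} mapping and the ground truth.
    Per-subject switching rates deviate from the condition's rate by the
    behaviour model's latent factor, which also drives the planted
    behaviour-flexibility correlation.
    """
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    scheme = WindowScheme()
    base = (
        config.base_partition
        if config.base_partition is not None
        else default_base_partition(config.n_rois)
    )
    cfg = SyntheticConfig(**{**config.__dict__, "base_partition": base})
    names, slices = _layer_slices(cfg, scheme)
    ss = np.random.SeedSequence(cfg.seed)
    beh_rng = np.random.default_rng(ss.spawn(1)[0])
    z_flex = beh_rng.normal(size=cfg.n_subjects)
    behaviour = _behaviour_draws(cfg.behaviour_effects, z_flex, beh_rng)

    planted_Q = {c: np.empty((cfg.n_subjects, cfg.n_rois, len(names)), dtype=int)
                 for c in CONDITIONS}
    planted_rates = {c: np.empty(cfg.n_subjects) for c in CONDITIONS}
    planted_flex = {c: np.empty((cfg.n_subjects, cfg.n_rois)) for c in CONDITIONS}
    subw = scheme.subwindows_per_window
    series_map: dict[tuple[str, str], EpochedSourceSeries] = {}

    for s in range(cfg.n_subjects):
        for ci, cond in enumerate(CONDITIONS):
            child = ss.spawn(1)[0]
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(np.random.SeedSequence(sub_seed))
            offset = cfg.behaviour_effects.rate_sd * z_flex[s]
            rates = cohort_timeline_rates(cfg, cond, len(names), subw, offset)
            planted_rates[cond][s] = float(
                np.clip(cfg.switch_rates[cond] + offset, 0, 1)
            )
            Q = generate_community_timeline(base, rates, len(names), rng)
            planted_Q[cond][s] = Q
            post = Q[:, subw:]  # post-stimulus layers only
            changes = (post[:, 1:] != post[:, :-1]).mean(axis=1)
            planted_flex[cond][s] = changes
            series_map[(f"sub-{s:02d}", cond)] = generate_mvar_series(
                cfg, cond, sub_seed, timeline=Q, scheme=scheme,
                subject=f"sub-{s:02d}",
            )

    truth = GroundTruth(
        planted_Q=planted_Q,
        layer_names=names,
        planted_coupling=[
            {
                "source": c.source,
                "target": c.target,
                "lag": c.lag,
                "coef": c.coef,
                "band": c.band,
                "start_ms": c.start_ms,
                "end_ms": c.end_ms,
            }
            for c in cfg.coupling_spec
        ],
        planted_flexibility=planted_flex,
        planted_rates=planted_rates,
        behaviour_table=behaviour,
    )
    return series_map, truth


def generate_cohort(
    config: SyntheticConfig, outdir: str | Path, overwrite: bool = False
) -> tuple[Path, GroundTruth]:
    """Write a full synthetic cohort to disk and return its ground truth.

    Layout: ``series/sub-XX_<cond>.csv`` (long CSV, one row per trial x ROI,
    sample columns ``s000...``), ``metadata.json``, ``behaviour.csv`` and
    ``ground_truth.json``.
    """
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1; nothing written")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass overwrite=True"
        )
    series_map, truth = simulate_cohort(config)
    (outdir / "series").mkdir(parents=True, exist_ok=True)
    for (subject, cond), series in series_map.items():
        path = outdir / "series" / f"{subject}_{_COND_FILE[cond]}.csv"
        _write_series_csv(series, path)

    cfg = config
    meta = {
        "fs": cfg.fs,
        "epoch_span": list(cfg.epoch_span),
        "t0_index": cfg.t0_index,
        "n_samples": cfg.n_samples,
        "roi_names": cfg.roi_names(),
        "conditions": list(CONDITIONS),
        "n_trials_per_condition": cfg.n_trials_per_condition,
        "n_subjects": cfg.n_subjects,
        "seed": cfg.seed,
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=1))
    truth.behaviour_table.to_csv(outdir / "behaviour.csv", index=False)
    truth.to_json(outdir / "ground_truth.json")
    return outdir, truth


def coupled_oscillator_pair(
    n_trials: int,
    n_samples: int,
    coef: float,
    seed: int,
    fs: float = 250.0,
    centre_hz: float = 6.0,
    damping: float = 0.95,
    step_at: int | None = None,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Two damped oscillators with a lag-1 x -> y coupling (trials x 2 x T).

    A compact generator for effective-connectivity benchmarks; with
    ``step_at`` the coupling switches from 0 to ``coef`` at that sample,
    giving a known coefficient step for tracking tests.
    """
    a1, a2 = ar2_coefficients(centre_hz, damping, fs)
    rng = np.random.default_rng(seed)
    burn = 200
    total = n_samples + burn
    x = np.zeros((n_trials, 2, total))
    w = rng.normal(scale=noise_sd, size=(n_trials, 2, total))
    for t in range(2, total):
        c = coef if step_at is None or (t - burn) >= step_at else 0.0
        x[:, 0, t] = a1 * x[:, 0, t - 1] + a2 * x[:, 0, t - 2] + w[:, 0, t]
        x[:, 1, t] = (
            a1 * x[:, 1, t - 1] + a2 * x[:, 1, t - 2]
            + c * x[:, 0, t - 1] + w[:, 1, t]
        )
    return x[:, :, burn:]


def default_base_partition(n_rois: int, n_communities: int = 6) -> np.ndarray:
    """Contiguous, near-equal community blocks over the ROI axis."""
    n_communities = min(n_communities, n_rois)
    blocks = np.array_split(np.arange(n_rois), n_communities)
    return np.concatenate([np.full(len(b), k) for k, b in enumerate(blocks)])


def _write_series_csv(series: EpochedSourceSeries, path: Path) -> None:
    n_tr, n_roi, n_s = series.data.shape
    cols = [f"s{k:03d}" for k in range(n_s)]
    df = pd.DataFrame(series.data.reshape(n_tr * n_roi, n_s), columns=cols)
    df.insert(0, "roi", np.tile(series.roi_names, n_tr))
    df.insert(0, "trial", np.repeat(np.arange(n_tr), n_roi))
    df.to_csv(path, index=False, float_format="%.17g")
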