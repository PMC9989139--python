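"""Orchestration: the staged analysis from simulation to statistics.

``run_pipeline`` executes simulate -> preprocess -> connectivity ->
communities -> metrics -> tpdc -> stats against one run configuration,
writing tidy CSV outputs and a manifest (config hash per stage) that makes
re-runs idempotent: a stage whose outputs exist under an unchanged
configuration is skipped, and any stage that does run forces its
descendants to recompute.

The module also exposes the per-subject computation helpers
(``compute_window_matrices``, ``compute_layer_matrices``,
``window_flexibility_table``) that the analysis drivers and recovery tests
reuse directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import communities as comm
from . import graphmetrics as gm
from . import stats as st
from . import tpdc as tp
from .config import RunConfig
from .connectivity import DensityGrid, band_envelope, envelope_correlation_matrix
from .io import Manifest, config_hash, read_metadata, read_series, write_table
from .preprocess import EpochedSourceSeries, WindowScheme, filter_series
from .synthdata import (
    CONDITIONS,
    BehaviourEffects,
    Perturbation,
    SyntheticConfig,
    default_base_partition,
    generate_cohort,
)

STAGES = ["simulate", "preprocess", "connectivity", "communities",
          "metrics", "tpdc", "stats"]


@dataclass
class RunResult:
    out_dir: Path
    executed: list[str]

    def __fspath__(self) -> str:
        return str(self.out_dir)


def _synthetic_config(cfg: RunConfig) -> SyntheticConfig:
    s = cfg.synth
    pert = (
        Perturbation(gain=s.perturbation_gain)
        if s.perturbation_gain is not None
        else None
    )
    return SyntheticConfig(
        n_subjects=s.n_subjects,
        n_rois=s.n_rois,
        n_trials_per_condition={"CS+": s.n_trials_csplus, "CS-": s.n_trials_csminus},
        base_partition=default_base_partition(s.n_rois, s.n_communities),
        switch_rates={"CS+": s.switch_rate_csplus, "CS-": s.switch_rate_csminus},
        baseline_switch_rate=s.baseline_switch_rate,
        community_coupling=s.community_coupling,
        noise_sd=s.noise_sd,
        perturbation=pert,
        behaviour_effects=BehaviourEffects(
            rating_effect=s.rating_effect,
            heart_effect=s.heart_effect,
            flexibility_corr=s.flexibility_corr,
            rate_sd=s.rate_sd,
        ),
        seed=cfg.seed,
    )


def _cohort_series(cohort: Path) -> list[Path]:
    return sorted((cohort / "series").glob("*.csv"))


def compute_window_matrices(
    series: EpochedSourceSeries, band: str | tuple[float, float],
    scheme: WindowScheme,
) -> dict[str, np.ndarray]:
    """Full-window envelope-correlation matrix per analysis window."""
    env = band_envelope(series.data, band, series.fs)
    out = {}
    for name in scheme.names:
        sl = scheme.sample_slice(name, series.fs, series.t0_index, series.n_samples)
        out[name] = envelope_correlation_matrix(env, sl).W
    return out


def compute_layer_matrices(
    series: EpochedSourceSeries, band: str | tuple[float, float],
    scheme: WindowScheme,
) -> dict[str, list[np.ndarray]]:
    """Per 50 ms sub-window matrices (the community-detection layers)."""
    env = band_envelope(series.data, band, series.fs)
    out = {}
    for name in scheme.names:
        slices = scheme.subwindow_slices(
            name, series.fs, series.t0_index, series.n_samples
        )
        out[name] = [envelope_correlation_matrix(env, sl).W for sl in slices]
    return out


def window_flexibility_table(
    series: EpochedSourceSeries,
    band: str | tuple[float, float],
    scheme: WindowScheme,
    gamma: float = 1.0,
    omega: float = 1.0,
    n_iter: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window mean flexibility of one subject/condition series.

    For each analysis window, communities are detected across its five
    sub-window layers (multilayer consensus) and the flexibility of the
    resulting label matrix summarised; rows carry per-window F plus the
    detection stability.
    """
    layers = compute_layer_matrices(series, band, scheme)
    ss = np.random.SeedSequence(seed)
    rows = []
    for name, children in zip(scheme.names, ss.spawn(len(scheme.names))):
        dyn = comm.dynamic_assignment(
            layers[name], gamma=gamma, omega=omega, n_iter=n_iter,
            seed=int(children.generate_state(1)[0] % (2**31)),
            layer_names=[f"{name}.s{j + 1}" for j in range(len(layers[name]))],
        )
        f, F = gm.node_flexibility(dyn.Q)
        rows.append(
            {"subject": series.subject, "condition": series.condition,
             "band": band if isinstance(band, str) else str(band),
             "window": name, "value": F,
             "stability": float(dyn.stability.mean())}
        )
    return pd.DataFrame(rows)


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    if not cfg.simulate:
        return [Path(cfg.data_dir) / "metadata.json"]
    cohort = out / "cohort"
    generate_cohort(_synthetic_config(cfg), cohort, overwrite=True)
    return [cohort / "metadata.json", cohort / "behaviour.csv",
            cohort / "ground_truth.json"]


def _cohort_dir(cfg: RunConfig, out: Path) -> Path:
    return out / "cohort" if cfg.simulate else Path(cfg.data_dir)


def _stage_preprocess(cfg: RunConfig, out: Path) -> list[Path]:
    cohort = _cohort_dir(cfg, out)
    meta = read_metadata(cohort / "metadata.json")
    rows = []
    band0 = next(iter(cfg.bands.values()))
    for path in _cohort_series(cohort):
        series = read_series(path, metadata=meta)
        filtered = filter_series(series, cfg.filter_low_hz, cfg.filter_high_hz)
        from .preprocess import itpc

        course = itpc(filtered, 0, band0)
        rows.append(
            {"subject": series.subject, "condition": series.condition,
             "roi": series.roi_names[0], "itpc_mean": float(course.mean()),
             "itpc_max": float(course.max())}
        )
    out_path = write_table(pd.DataFrame(rows), out / "preprocess" / "itpc.csv")
    return [out_path]


def _each_series(cfg: RunConfig, out: Path):
    cohort = _cohort_dir(cfg, out)
    meta = read_metadata(cohort / "metadata.json")
    for path in _cohort_series(cohort):
        series = read_series(path, metadata=meta)
        yield filter_series(series, cfg.filter_low_hz, cfg.filter_high_hz)


def _stage_connectivity(cfg: RunConfig, out: Path) -> list[Path]:
    scheme = WindowScheme()
    win_rows, layer_rows = [], []
    for series in _each_series(cfg, out):
        for band_name, edges in cfg.bands.items():
            wmats = compute_window_matrices(series, edges, scheme)
            lmats = compute_layer_matrices(series, edges, scheme)
            iu, ju = np.triu_indices(series.n_rois, k=1)
            for wname, W in wmats.items():
                win_rows.append(
                    pd.DataFrame(
                        {"subject": series.subject, "condition": series.condition,
                         "band": band_name, "window": wname,
                         "i": iu, "j": ju, "weight": W[iu, ju]}
                    )
                )
            for wname, Ws in lmats.items():
                for li, W in enumerate(Ws):
                    layer_rows.append(
                        pd.DataFrame(
                            {"subject": series.subject,
                             "condition": series.condition,
                             "band": band_name, "window": wname,
                             "layer": li + 1, "i": iu, "j": ju,
                             "weight": W[iu, ju]}
                        )
                    )
    p1 = write_table(pd.concat(win_rows, ignore_index=True),
                     out / "connectivity" / "window_edges.csv")
    p2 = write_table(pd.concat(layer_rows, ignore_index=True),
                     out / "connectivity" / "layer_edges.csv")
    return [p1, p2]


def _edges_to_matrix(df: pd.DataFrame, n: int) -> np.ndarray:
    W = np.zeros((n, n))
    W[df["i"], df["j"]] = df["weight"]
    return W + W.T


def _stage_communities(cfg: RunConfig, out: Path) -> list[Path]:
    layer_edges = pd.read_csv(out / "connectivity" / "layer_edges.csv")
    n = int(layer_edges[["i", "j"]].max().max()) + 1
    scheme = WindowScheme()
    ss = np.random.SeedSequence(cfg.seed + 1)
    q_rows, flex_rows = [], []
    groups = layer_edges.groupby(["subject", "condition", "band"], sort=True)
    for (subject, condition, band_name), g in groups:
        for wname, child in zip(scheme.names, ss.spawn(len(scheme.names))):
            gw = g[g["window"] == wname]
            layers = [
                _edges_to_matrix(gw[gw["layer"] == li], n)
                for li in sorted(gw["layer"].unique())
            ]
            dyn = comm.dynamic_assignment(
                layers, gamma=cfg.gamma, omega=cfg.omega,
                n_iter=cfg.n_iterations,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            f, F = gm.node_flexibility(dyn.Q)
            flex_rows.append(
                {"subject": subject, "condition": condition, "band": band_name,
                 "window": wname, "metric": "flexibility", "value": F,
                 "stability": float(dyn.stability.mean())}
            )
            for roi in range(n):
                for li in range(dyn.Q.shape[1]):
                    q_rows.append(
                        {"subject": subject, "condition": condition,
                         "band": band_name, "window": wname, "roi": roi,
                         "layer": li + 1, "label": int(dyn.Q[roi, li])}
                    )
    p1 = write_table(pd.DataFrame(q_rows), out / "communities" / "q_labels.csv")
    p2 = write_table(pd.DataFrame(flex_rows), out / "communities" / "flexibility.csv")
    return [p1, p2]


def _stage_metrics(cfg: RunConfig, out: Path) -> list[Path]:
    window_edges = pd.read_csv(out / "connectivity" / "window_edges.csv")
    n = int(window_edges[["i", "j"]].max().max()) + 1
    grid = DensityGrid(cfg.densities.min, cfg.densities.max, cfg.densities.n)
    tables = []
    for (subject, condition, band_name, wname), g in window_edges.groupby(
        ["subject", "condition", "band", "window"], sort=True
    ):
        W = _edges_to_matrix(g, n)
        tables.append(
            gm.metrics_over_densities(
                W, grid, subject=subject, condition=condition,
                band=band_name, window=wname,
            )
        )
    table = pd.concat(tables, ignore_index=True)
    p1 = write_table(table, out / "metrics" / "metrics.csv")
    summary = gm.summarize_metrics(
        table, by=["subject", "condition", "band", "window"]
    )
    p2 = write_table(summary, out / "metrics" / "summary.csv")
    return [p1, p2]


def _stage_tpdc(cfg: RunConfig, out: Path) -> list[Path]:
    scheme = WindowScheme()
    t = cfg.tpdc
    freqs = tp.default_freq_grid(t.freq_min, t.freq_max, t.freq_step)
    ec_rows, sig_rows = [], []
    ss = np.random.SeedSequence(cfg.seed + 2)
    for series in _each_series(cfg, out):
        sub = series.data[:, t.node_subset, :]
        for band_name, edges in cfg.bands.items():
            # trial-averaged band/window EC summaries
            summaries = []
            for trial in range(sub.shape[0]):
                model = tp.fit_dekf_mvar(
                    sub[trial], order=t.order, q=t.q,
                    init_scale=t.init_scale, fs=series.fs,
                )
                spec = tp.tpdc_spectrum(model, freqs)
                summaries.append(
                    tp.band_window_summary(
                        spec.values, freqs, edges, scheme, series.fs,
                        series.t0_index,
                    )
                )
            mean = (
                pd.concat(summaries)
                .groupby(["source", "target", "band", "window"], as_index=False)[
                    "value"
                ]
                .mean()
            )
            mean.insert(0, "condition", series.condition)
            mean.insert(0, "subject", series.subject)
            mean["band"] = band_name
            ec_rows.append(mean)
            if t.n_surrogates > 0:
                child = ss.spawn(1)[0]
                res = tp.time_reversal_surrogate_test(
                    sub, n_surrogates=t.n_surrogates, alpha=t.alpha,
                    order=t.order, q=t.q, init_scale=t.init_scale,
                    fs=series.fs, band=edges, freqs=freqs,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                for (i, j), cls in res.direction_class.items():
                    sig_rows.append(
                        {"subject": series.subject,
                         "condition": series.condition, "band": band_name,
                         "source": t.node_subset[i], "target": t.node_subset[j],
                         "observed_ij": float(res.observed[i, j]),
                         "observed_ji": float(res.observed[j, i]),
                         "threshold_ij": float(res.threshold[i, j]),
                         "threshold_ji": float(res.threshold[j, i]),
                         "direction": cls}
                    )
    p1 = write_table(pd.concat(ec_rows, ignore_index=True), out / "tpdc" / "ec.csv")
    outputs = [p1]
    if sig_rows:
        outputs.append(
            write_table(pd.DataFrame(sig_rows), out / "tpdc" / "significance.csv")
        )
    return outputs


def _stage_stats(cfg: RunConfig, out: Path) -> list[Path]:
    cohort = _cohort_dir(cfg, out)
    behaviour = pd.read_csv(cohort / "behaviour.csv")
    flex = pd.read_csv(out / "communities" / "flexibility.csv")
    metrics = pd.read_csv(out / "metrics" / "metrics.csv")

    wide = behaviour.pivot_table(index="subject", columns="condition")
    beh_rows = []
    for var in ("rating", "heart_rate"):
        res = st.paired_ttest(
            wide[(var, "CS+")].to_numpy(), wide[(var, "CS-")].to_numpy(),
            cfg.alpha_behaviour,
        )
        beh_rows.append(
            {"variable": var, "t": res.t, "p": res.p,
             "significant": res.significant, "n": res.n}
        )
    beh = pd.DataFrame(beh_rows)

    anova_rows = []
    for band_name in cfg.bands:
        fb = flex[flex["band"] == band_name]
        res = st.rm_anova_2way(fb, dv="value", subject="subject",
                               within=("condition", "window"))
        for _, row in res.table.iterrows():
            anova_rows.append(
                {"band": band_name, "metric": "flexibility", **row.to_dict(),
                 "sphericity_p": res.sphericity_p, "gg_epsilon": res.gg_epsilon}
            )
        for metric in ("clustering", "global_efficiency", "local_efficiency"):
            mt = metrics[(metrics["band"] == band_name)
                         & (metrics["metric"] == metric)]
            res = st.rm_anova_2way(mt, dv="value", subject="subject",
                                   within=("condition", "window"))
            for _, row in res.table.iterrows():
                anova_rows.append(
                    {"band": band_name, "metric": metric, **row.to_dict(),
                     "sphericity_p": res.sphericity_p,
                     "gg_epsilon": res.gg_epsilon}
                )
    anova = pd.DataFrame(anova_rows)

    # behaviour-network correlations (CS+ flexibility vs rating / heart rate)
    flex_cs = (
        flex[(flex["condition"] == "CS+") & (flex["window"] != "baseline")]
        .groupby("subject")["value"].mean()
    )
    beh_cs = behaviour[behaviour["condition"] == "CS+"].set_index("subject")
    common = flex_cs.index.intersection(beh_cs.index)
    corr = st.correlate_bonferroni(
        [
            ("flexibility~rating", flex_cs[common].to_numpy(),
             beh_cs.loc[common, "rating"].to_numpy()),
            ("flexibility~heart_rate", flex_cs[common].to_numpy(),
             beh_cs.loc[common, "heart_rate"].to_numpy()),
            ("rating~heart_rate", beh_cs.loc[common, "rating"].to_numpy(),
             beh_cs.loc[common, "heart_rate"].to_numpy()),
        ],
        alpha=cfg.alpha_network,
    )

    p1 = write_table(beh, out / "stats" / "behaviour_tests.csv")
    p2 = write_table(anova, out / "stats" / "anova.csv")
    p3 = write_table(corr, out / "stats" / "correlations.csv")
    return [p1, p2, p3]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "connectivity": _stage_connectivity,
    "communities": _stage_communities,
    "metrics": _stage_metrics,
    "tpdc": _stage_tpdc,
    "stats": _stage_stats,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> RunResult:
    """Execute the staged analysis; skip stages already completed.

    ``stages`` restricts execution (in pipeline order); dependencies must
    already have run.  Raises with the failing stage's name on error,
    preserving partial outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out / "manifest.json")
    payload = cfg.dump()
    (out / "config.json").write_text(json.dumps(payload, indent=1))
    chash = config_hash(payload)
    todo = stages or STAGES
    executed: list[str] = []
    dirty = False
    for stage in STAGES:
        if stage not in todo:
            continue
        if not cfg.force and not dirty and manifest.is_done(stage, chash):
            continue
        try:
            outputs = _STAGE_FUNCS[stage](cfg, out)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        manifest.mark(stage, chash, outputs, extra={"seed": cfg.seed})
        executed.append(stage)
        dirty = True
    return RunResult(out_dir=out, executed=executed)
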