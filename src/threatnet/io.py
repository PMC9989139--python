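"""Readers and writers for the cohort CSV/JSON layout and run manifests."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ALL_LABELS
from .preprocess import EpochedSourceSeries

REQUIRED_METADATA = ("fs", "t0_index", "roi_names")


def read_metadata(path: str | Path) -> dict:
    meta = json.loads(Path(path).read_text())
    for key in REQUIRED_METADATA:
        if key not in meta:
            raise ValueError(f"metadata file {path} is missing required key {key!r}")
    return meta


def write_series(series: EpochedSourceSeries, path: str | Path) -> None:
    """Long-CSV writer (trial, roi, s000...) with round-trip-exact floats."""
    from .synthdata import _write_series_csv

    _write_series_csv(series, Path(path))


def read_series(
    path: str | Path,
    metadata: dict | str | Path | None = None,
    subject: str | None = None,
    condition: str | None = None,
) -> EpochedSourceSeries:
    """Read one subject/condition series CSV plus its metadata sidecar.

    ``metadata`` may be a dict or a path; by default the ``metadata.json``
    next to the series directory is used.  ROI labels not present in the
    atlas fixture trigger a warning (not an error) so renamed or generic
    label sets remain usable.
    """
    path = Path(path)
    if metadata is None:
        metadata = path.parent.parent / "metadata.json"
    if not isinstance(metadata, dict):
        metadata = read_metadata(metadata)
    for key in REQUIRED_METADATA:
        if key not in metadata:
            raise ValueError(f"series metadata is missing required key {key!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("trial", "roi"):
        if col not in df.columns:
            raise ValueError(f"series CSV {path} is missing column {col!r}")
    roi_names = list(metadata["roi_names"])
    unknown = sorted(set(roi_names) - set(ALL_LABELS) - {f"ROI{i:03d}" for i in range(1000)})
    if unknown:
        warnings.warn(
            f"ROI labels not in the atlas fixture: {unknown[:8]}"
            + ("..." if len(unknown) > 8 else ""),
            RuntimeWarning,
            stacklevel=2,
        )
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    n_trials = df["trial"].nunique()
    data = (
        df[sample_cols]
        .to_numpy(dtype=float)
        .reshape(n_trials, len(roi_names), len(sample_cols))
    )
    if subject is None or condition is None:
        stem = path.stem  # sub-XX_CSplus
        parts = stem.rsplit("_", 1)
        subject = subject or parts[0]
        condition = condition or {"CSplus": "CS+", "CSminus": "CS-"}.get(
            parts[-1], parts[-1]
        )
    return EpochedSourceSeries(
        subject=subject,
        condition=condition,
        data=data,
        fs=float(metadata["fs"]),
        t0_index=int(metadata["t0_index"]),
        roi_names=roi_names,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class Manifest:
    """Per-run stage ledger enabling idempotent re-runs."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.records: dict[str, dict] = {}
        if self.path.exists():
            self.records = json.loads(self.path.read_text()).get("stages", {})

    def is_done(self, stage: str, chash: str) -> bool:
        rec = self.records.get(stage)
        if rec is None or rec.get("config_hash") != chash:
            return False
        return all(Path(p).exists() for p in rec.get("outputs", []))

    def mark(self, stage: str, chash: str, outputs: list[str | Path], extra: dict | None = None) -> None:
        self.records[stage] = {
            "config_hash": chash,
            "outputs": [str(p) for p in outputs],
            **(extra or {}),
        }
        self.save()

    def invalidate_from(self, stage: str, order: list[str]) -> None:
        if stage not in order:
            return
        for s in order[order.index(stage):]:
            self.records.pop(s, None)
        self.save()

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps({"stages": self.records}, indent=1))
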