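"""Schema-validated run configuration (unknown keys rejected)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_subjects: int = 4
    n_rois: int = 12
    n_trials_csplus: int = 36
    n_trials_csminus: int = 24
    n_communities: int = 3
    switch_rate_csplus: float = 0.4
    switch_rate_csminus: float = 0.2
    baseline_switch_rate: float = 0.05
    community_coupling: float = 0.9
    noise_sd: float = 1.0
    rating_effect: float = 2.0
    heart_effect: float = 8.0
    flexibility_corr: float = 0.6
    rate_sd: float = 0.08
    perturbation_gain: float | None = None  # None = no perturbation


class DensityConfig(_Strict):
    min: float = 0.1
    max: float = 0.6
    n: int = 20


class TpdcConfig(_Strict):
    order: int = 2
    q: float = 1e-3
    init_scale: float = 1.0
    freq_min: float = 2.0
    freq_max: float = 45.0
    freq_step: float = 0.5
    n_surrogates: int = 200
    alpha: float = 0.01
    node_subset: list[int] = Field(default_factory=lambda: [0, 1, 2, 3])


class RunConfig(_Strict):
    """Top-level pipeline configuration.

    Serialized into every output manifest for provenance; unknown keys are
    rejected at load time.
    """

    out_dir: str = "results/run"
    data_dir: str | None = None  # existing cohort; None + simulate -> generate
    simulate: bool = True
    synth: SimulateConfig = Field(default_factory=SimulateConfig)
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"theta": (4.0, 8.0)}
    )
    filter_low_hz: float = 3.0
    filter_high_hz: float = 45.0
    densities: DensityConfig = Field(default_factory=DensityConfig)
    gamma: float = 1.0
    omega: float = 1.0
    n_iterations: int = 50
    tpdc: TpdcConfig = Field(default_factory=TpdcConfig)
    alpha_behaviour: float = 0.01
    alpha_network: float = 0.05
    contrast_scheme: str = "consecutive"
    seed: int = 0
    force: bool = False

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.simulate and self.data_dir is None:
            raise ValueError("either simulate=True or data_dir must be set")
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r} has invalid edges ({lo}, {hi})")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        return cls.model_validate(data or {})

    def dump(self) -> dict:
        return json.loads(self.model_dump_json())
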