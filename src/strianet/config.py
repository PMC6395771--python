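"""Pipeline configuration: nested per-stage parameter blocks with strict
key validation, loadable from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


def _from_dict(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateParams:
    n_genes: int = 2000
    n_case: int = 20
    n_control: int = 20
    module_sizes: list = field(default_factory=lambda: [100, 150, 200])
    module_loadings: float = 0.8
    disrupted_module: int | None = 1
    disruption_mode: str = "break_correlation"
    n_deg: int = 50
    deg_log2fc: float = 2.0
    dispersion: float = 0.05
    batch_levels: int = 2
    batch_effect_sd: float = 0.0


@dataclass
class PreprocessParams:
    min_cpm: float = 0.3
    min_frac: float = 0.5
    pseudocount: float = 0.5
    n_sv: int | str = "auto"


@dataclass
class DiffexpParams:
    design: list = field(default_factory=lambda: ["group"])
    adj_alpha: float = 0.05
    raw_alpha: float = 0.01


@dataclass
class NetworkParams:
    beta: int | str = 6
    r2_min: float = 0.8
    min_module_size: int = 30
    max_na_frac: float = 0.5


@dataclass
class PreserveParams:
    n_perm: int = 100


@dataclass
class HubParams:
    threshold: float = 0.9


@dataclass
class EnrichParams:
    method: str = "ora"
    n_iter: int = 10000
    n_sets: int = 10
    set_size: int = 100
    enriched_fraction: float = 0.5


@dataclass
class PipelineConfig:
    """Full pipeline configuration; ``regions`` lists independent analysis
    units (e.g. CN, NAC, PT), each simulated and analyzed separately with
    region-specific child seeds derived from the global seed."""

    regions: list = field(default_factory=lambda: ["CN", "NAC", "PT"])
    seed: int = 0
    make_plots: bool = False
    simulate: SimulateParams = field(default_factory=SimulateParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    diffexp: DiffexpParams = field(default_factory=DiffexpParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    preserve: PreserveParams = field(default_factory=PreserveParams)
    hubs: HubParams = field(default_factory=HubParams)
    enrich: EnrichParams = field(default_factory=EnrichParams)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        stage_classes = {
            "simulate": SimulateParams,
            "preprocess": PreprocessParams,
            "diffexp": DiffexpParams,
            "network": NetworkParams,
            "preserve": PreserveParams,
            "hubs": HubParams,
            "enrich": EnrichParams,
        }
        top_allowed = {f.name for f in fields(cls)}
        unknown = set(data) - top_allowed
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            if key in stage_classes:
                kwargs[key] = _from_dict(stage_classes[key], value or {}, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data or {})
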