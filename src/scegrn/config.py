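"""Pipeline configuration: one YAML file, nested keys, strict validation.

Every tunable of every stage lives here with its documented default; unknown
keys are rejected so typos fail loudly. All randomness in a run flows from
the single root ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class IntegrationConfig:
    upstream_bp: int = 100_000
    n_dims: int = 30
    n_features: int = 2000
    k_candidates: int = 10
    pairs_file: str | None = None  # pre-computed pairing (skips matching)


@dataclass
class TrajectoryConfig:
    groups: list[str] = field(default_factory=list)  # ordered, root -> terminal
    n_bins: int = 100
    window: int = 5


@dataclass
class ActivityConfig:
    n_iterations: int = 50
    n_neighbors: int = 50
    seed: int = 1


@dataclass
class LinkingConfig:
    tf_cor_cutoff: float = 0.4
    tf_cor_mode: str = "positive"
    link_cor_cutoff: float = 0.5
    max_distance: int = 250_000
    top_fraction: float = 0.1


@dataclass
class GRNConfig:
    weight_cutoff: float = 0.4
    weight_mode: str = "positive"
    min_tss_distance: int = 2000
    damping: float = 0.85


@dataclass
class IOConfig:
    data_dir: str = "data"
    out_dir: str = "results"


@dataclass
class SimulateConfig:
    enabled: bool = False
    unpaired: bool = False
    n_cells: int = 2000
    n_tfs: int = 10
    n_decoy_tfs: int = 10
    n_target_genes: int = 200
    n_decoy_genes: int = 200
    enhancers_per_gene: int = 2
    n_decoy_peaks: int = 200
    noise_sd: float = 0.2
    edge_density: float = 0.15
    depth_rna: float = 5000.0
    depth_atac: float = 5000.0


@dataclass
class PipelineConfig:
    seed: int = 1
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    activity: ActivityConfig = field(default_factory=ActivityConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    grn: GRNConfig = field(default_factory=GRNConfig)
    io: IOConfig = field(default_factory=IOConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _build(cls, data, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def sim_config(self):  # -> SimConfig; local import avoids a cycle
        from scegrn.synthetic import SimConfig

        s = self.simulate
        return SimConfig(
            n_cells=s.n_cells,
            n_tfs=s.n_tfs,
            n_decoy_tfs=s.n_decoy_tfs,
            n_target_genes=s.n_target_genes,
            n_decoy_genes=s.n_decoy_genes,
            enhancers_per_gene=s.enhancers_per_gene,
            n_decoy_peaks=s.n_decoy_peaks,
            noise_sd=s.noise_sd,
            edge_density=s.edge_density,
            depth_rna=s.depth_rna,
            depth_atac=s.depth_atac,
            seed=self.seed,
        )


def _build(cls: type, data: dict[str, Any], path: str) -> Any:
    """Construct a (possibly nested) config dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = path or "top level"
        raise ConfigError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)
        ):
            sub_cls = f.default_factory  # nested sections use default_factory=cls
            if not isinstance(value, dict):
                raise ConfigError(f"config section {path}{name} must be a mapping")
            kwargs[name] = _build(sub_cls, value, path=f"{path}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)
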