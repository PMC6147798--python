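"""Pipeline configuration: YAML in, validated nested dataclasses out.

Unknown keys are rejected up front. Defaults reproduce the standard analysis
parameters: 16 bp fixed end trims, MAPQ > 10, 100 kb bins, >100 basecalls in
>97.5% of cells, 150 principal components, and a 50-million-read-pair
reference depth for library-complexity extrapolation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml


class ConfigError(ValueError):
    """Raised for unknown keys or invalid parameter values."""


def _from_dict(cls, data: dict, path: str = ""):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = path or cls.__name__
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = _SECTION_TYPES.get((cls, name))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(sub, value, path=f"{path}.{name}" if path else name)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class SimulateConfig:
    n_cells_per_type: int = 10
    n_pairs_per_cell: int = 500
    conversion_rate: float = 0.995
    read_length: int = 100
    insert_mean: float = 250.0
    insert_sd: float = 60.0
    dimer_fraction: float = 0.06
    tail_mean: float = 8.0
    tail_max: int = 50
    contaminated: bool = False
    duplicate_rate: float = 0.05
    seq_error_rate: float = 0.001
    lambda_spike_fraction: float = 0.01


@dataclass
class TrimConfig:
    fixed_5p_r1: int = 16
    fixed_3p_r1: int = 16
    fixed_5p_r2: int = 16
    fixed_3p_r2: int = 16
    r2_extra_5p: int = 0
    min_insert: int = 30
    tail_detect: bool = True
    tail_max: int = 50


@dataclass
class AlignConfig:
    k: int = 16
    seed_step: int = 5
    max_mismatch_frac: float = 0.1
    mapq_min: int = 10


@dataclass
class QCConfig:
    reference_depth_pairs: float = 50_000_000
    max_extrapolation: float = 5e9
    extrapolation_step: float = 1e7


@dataclass
class ClusterConfig:
    bin_size: int = 100_000
    min_basecalls: int = 100
    min_cell_fraction: float = 0.975
    n_pcs: int = 150
    linkage: str = "ward"
    k: int | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    trim: TrimConfig = field(default_factory=TrimConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config YAML must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def param_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed fan-out from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


_SECTION_TYPES = {
    (PipelineConfig, "simulate"): SimulateConfig,
    (PipelineConfig, "trim"): TrimConfig,
    (PipelineConfig, "align"): AlignConfig,
    (PipelineConfig, "qc"): QCConfig,
    (PipelineConfig, "cluster"): ClusterConfig,
}
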