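"""Pipeline configuration and manifest serialization (YAML).

Configuration is strict: unknown keys are rejected and numeric
parameters are validated against their documented bounds at load time,
so a typo fails fast instead of silently running with defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .private_variants import ChromSets, SampleManifest

__all__ = [
    "ConfigError",
    "PathsConfig",
    "FilterConfig",
    "EnrichmentConfig",
    "SimulatorConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
    "manifest_to_yaml",
    "manifest_from_yaml",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the field path."""


def _from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class PathsConfig:
    vcf: str | None = None
    manifest: str | None = None
    genome: str | None = None
    depth_dir: str | None = None
    tracks: list[str] = field(default_factory=list)
    pwms: str | None = None
    background_pool: str | None = None
    private_tsv: str | None = None


@dataclass
class FilterConfig:
    qual_min: float = 10.0
    dp_lo: int = 10
    dp_hi: int = 200
    min_obs: int = 3
    min_nonmissing: int = 2
    introgression_window_kb: float = 100.0
    introgression_min_count: int = 20
    callable_lo: int = 10
    callable_hi: int = 200
    depth_thresholds: dict = field(default_factory=lambda: {"chr2": 9.0, "chr3": 5.0})

    def __post_init__(self) -> None:
        if self.qual_min < 0:
            raise ConfigError("filters.qual_min: must be >= 0")
        if not (0 < self.dp_lo <= self.dp_hi):
            raise ConfigError("filters.dp_lo/dp_hi: need 0 < dp_lo <= dp_hi")
        if self.min_obs < 0 or self.min_nonmissing < 0:
            raise ConfigError("filters.min_obs/min_nonmissing: must be >= 0")
        if self.introgression_window_kb <= 0 or self.introgression_min_count < 1:
            raise ConfigError("filters.introgression_*: invalid")


@dataclass
class EnrichmentConfig:
    window: int = 100
    n_sample: int = 10_000
    n_reps: int = 500
    fasta_width: int = 200

    def __post_init__(self) -> None:
        if self.window < 0 or self.n_sample < 1 or self.n_reps < 1:
            raise ConfigError("enrichment: window/n_sample/n_reps out of bounds")
        if self.fasta_width < 2:
            raise ConfigError("enrichment.fasta_width: must be >= 2")


@dataclass
class SimulatorConfig:
    chrom_lengths: dict = field(default_factory=lambda: {"chr3": 2_000_000})
    gc: float = 0.42
    n_motif_sites: int = 100
    n_peaks: int = 20
    base_rate: float = 8.4e-9
    target_rate_multiplier: float = 50.0
    target_window: int = 100
    deamination_fraction: float = 0.85
    generations: int = 10
    het_fraction: float = 0.883
    mean_depth: float = 19.2
    depth_dispersion: float = 0.2
    error_rate: float = 0.002
    missing_below: int = 5
    artifact_fraction: float = 0.1
    n_lines: int = 20
    replicate_count: int = 2
    n_background_individuals: int = 6
    n_mutagenized_individuals: int = 0
    n_background_stocks: int = 2
    fixed_diff_rate: float = 1e-4
    het_pocket_count: int = 5
    het_pocket_len: int = 50_000
    pocket_variant_rate: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 <= self.gc <= 1):
            raise ConfigError("simulator.gc: must be in [0, 1]")
        if self.base_rate <= 0 or self.target_rate_multiplier < 1:
            raise ConfigError("simulator.base_rate/target_rate_multiplier: invalid")
        if not (0 <= self.deamination_fraction <= 1):
            raise ConfigError("simulator.deamination_fraction: must be in [0, 1]")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigError("simulator.error_rate: must be in [0, 0.5)")


@dataclass
class PipelineConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    seed: int | None = None
    chrom: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root: expected a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"config root: unknown keys {sorted(unknown)}")
        return cls(
            paths=_from_dict(PathsConfig, data.get("paths", {}), "paths"),
            filters=_from_dict(FilterConfig, data.get("filters", {}), "filters"),
            enrichment=_from_dict(EnrichmentConfig, data.get("enrichment", {}), "enrichment"),
            simulator=_from_dict(SimulatorConfig, data.get("simulator", {}), "simulator"),
            seed=data.get("seed"),
            chrom=data.get("chrom"),
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def manifest_to_yaml(manifest: SampleManifest, path: str | Path) -> None:
    data = {
        "chromosomes": {
            c: {"full": cs.full, "mutagenized": cs.mutagenized, "background": cs.background}
            for c, cs in manifest.chromosomes.items()
        },
        "replicate_groups": manifest.replicate_groups,
        "mean_depth": manifest.mean_depth,
        "generations": manifest.generations,
        "tags": manifest.tags,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def manifest_from_yaml(path: str | Path) -> SampleManifest:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        chromosomes = {
            c: ChromSets(v["full"], v["mutagenized"], v["background"])
            for c, v in data["chromosomes"].items()
        }
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"manifest {path}: missing chromosome set definitions") from exc
    return SampleManifest(
        chromosomes=chromosomes,
        replicate_groups=data.get("replicate_groups", {}),
        mean_depth=data.get("mean_depth", {}),
        generations=data.get("generations", {}),
        tags=data.get("tags", {}),
    )
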