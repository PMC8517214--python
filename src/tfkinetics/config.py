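"""Pipeline configuration: a single YAML document with strict validation.

Unknown keys are rejected so typos cannot silently disable a threshold.
All randomness flows from the top-level seed via per-stage derived seeds
(stage seed = sha256(stage name) truncated to 32 bits, XOR the seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: Mapping[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class Thresholds:
    alpha: float = 0.05
    lfc_min: float = 1.0
    motif_p_cutoff: float = 1e-5
    scan_half_width: int = 1500
    merge_gap: int = 60
    peak_min_log2fc: float = 1.0
    peak_q_max: float = 1e-5
    sigma: float = 150.0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.lfc_min < 0:
            raise ConfigError("lfc_min must be >= 0")
        if not 0 < self.motif_p_cutoff < 1:
            raise ConfigError("motif_p_cutoff must lie in (0, 1)")
        if self.scan_half_width <= 0:
            raise ConfigError("scan_half_width must be positive")
        if self.merge_gap < 0:
            raise ConfigError("merge_gap must be >= 0")
        if self.peak_min_log2fc < 0:
            raise ConfigError("peak_min_log2fc must be >= 0")
        if not 0 < self.peak_q_max < 1:
            raise ConfigError("peak_q_max must lie in (0, 1)")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")


@dataclass
class Modes:
    ranking_metric: str = "pvalue"  # raw p drives the ranking
    pvalue_mode: str = "z"  # "z" or "permutation"
    stranded_counting: bool = False
    n_perm: int = 200
    min_overlap: int = 1

    def validate(self) -> None:
        if self.ranking_metric not in ("pvalue", "padj"):
            raise ConfigError("ranking_metric must be 'pvalue' or 'padj'")
        if self.pvalue_mode not in ("z", "permutation"):
            raise ConfigError("pvalue_mode must be 'z' or 'permutation'")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")


@dataclass
class Detection:
    bin_size: int = 15
    max_pair_distance: int = 600
    flank: int = 750
    min_strength: float = 0.0

    def validate(self) -> None:
        if self.bin_size < 1 or self.max_pair_distance < 1 or self.flank < 1:
            raise ConfigError("detection scales must be positive")
        if self.min_strength < 0:
            raise ConfigError("min_strength must be >= 0")


@dataclass
class InputPaths:
    genome: str | None = None
    motifs: str | None = None
    reads: dict = field(default_factory=dict)  # sample_id -> BED6 path
    read_conditions: dict = field(default_factory=dict)  # sample_id -> condition
    gene_counts: str | None = None
    gene_samples: str | None = None
    atac: dict = field(default_factory=dict)  # time point -> bedGraph path
    atac_bin_size: int = 50


@dataclass
class PipelineConfig:
    seed: int = 0
    paths: InputPaths = field(default_factory=InputPaths)
    thresholds: Thresholds = field(default_factory=Thresholds)
    modes: Modes = field(default_factory=Modes)
    detection: Detection = field(default_factory=Detection)
    simulate: dict | None = None  # SimulationConfig overrides; enables stage 0

    def validate(self) -> None:
        self.thresholds.validate()
        self.modes.validate()
        self.detection.validate()
        if self.simulate is None:
            missing = [
                name
                for name in ("genome", "motifs")
                if getattr(self.paths, name) is None
            ]
            if missing or not self.paths.reads:
                raise ConfigError(
                    "without a simulate section, paths.genome, paths.motifs and "
                    "paths.reads are required"
                )

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        for name, sub in (
            ("paths", InputPaths),
            ("thresholds", Thresholds),
            ("modes", Modes),
            ("detection", Detection),
        ):
            if name in data:
                kwargs[name] = _from_mapping(sub, data[name] or {})
        if "simulate" in data:
            kwargs["simulate"] = data["simulate"]
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(stage.encode()).digest()
    return (int.from_bytes(digest[:4], "big") ^ seed) & 0x7FFFFFFF
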