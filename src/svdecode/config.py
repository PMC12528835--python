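"""Pipeline configuration: one YAML file, explicit seeds per stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "apply_overrides"]


@dataclass
class CohortConfig:
    n_per_group: int = 5
    group_labels: tuple[str, str] = ("control", "oud")
    missing_rate: float = 0.02


@dataclass
class SignalConfig:
    amplitude: float = 1.0
    #: per-group, per-network amplitude overrides, e.g.
    #: {"oud": {"limbic": 0.0}} silences the limbic network in group B
    amplitude_overrides: dict = field(default_factory=dict)
    shared_across_contexts: float = 1.0
    noise_sd: float = 1.0
    rois_per_network: int = 2
    voxels_per_roi: tuple[int, int] = (12, 20)


@dataclass
class DecodeStageConfig:
    n_boot: int = 20
    C: float = 1.0
    split_kind: str = "overall"
    exclude_catch: bool = False


@dataclass
class InferenceConfig:
    n_perm: int = 200
    thresholds: tuple[float, ...] = (0.05, 0.01, 0.001)

    def __post_init__(self):
        if tuple(self.thresholds) != tuple(sorted(self.thresholds, reverse=True)):
            raise ValueError("thresholds must be sorted descending")


@dataclass
class PipelineConfig:
    seeds: dict = field(default_factory=lambda: {
        "cohort": 11, "decode": 12, "inference": 13})
    cohort: CohortConfig = field(default_factory=CohortConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    decode: DecodeStageConfig = field(default_factory=DecodeStageConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    out_dir: str = "svdecode_out"

    def __post_init__(self):
        for stage in ("cohort", "decode", "inference"):
            if stage not in self.seeds:
                raise ValueError(f"missing seed for stage {stage!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = {}
    sections = {"cohort": CohortConfig, "signal": SignalConfig,
                "decode": DecodeStageConfig, "inference": InferenceConfig}
    for key, val in raw.items():
        if key in sections:
            try:
                kwargs[key] = sections[key](**val)
            except TypeError as e:
                raise ValueError(f"config section {key!r}: {e}") from None
        elif key in ("seeds", "out_dir"):
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config field {key!r}")
    return PipelineConfig(**kwargs)


def apply_overrides(cfg: PipelineConfig, overrides: list[str]) -> PipelineConfig:
    """Apply CLI ``section.key=value`` overrides (YAML-parsed values)."""
    raw = cfg.to_dict()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not key=value")
        key, val = item.split("=", 1)
        val = yaml.safe_load(val)
        parts = key.split(".")
        node = raw
        for p in parts[:-1]:
            if p not in node:
                raise ValueError(f"unknown config field {key!r}")
            node = node[p]
        if parts[-1] not in node:
            raise ValueError(f"unknown config field {key!r}")
        node[parts[-1]] = val
    return _config_from_dict(raw)
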