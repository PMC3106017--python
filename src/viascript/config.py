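"""Run configuration: one schema for every command.

A :class:`RunConfig` collects the tunables of the whole pipeline —
extractor tolerances, smoothing widths, generation settings, arm geometry
and the answer policy — so a run is reproducible from its config plus its
seed.  Configs load from YAML (or JSON) mappings; unknown keys are
rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from typing import Any, Mapping

import yaml

from .errors import InvalidConfigError
from .motor import GenerationConfig, TwoJointArm, WorkspacePlacement
from .representation import SmoothingConfig

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    schema_version: int = CONFIG_SCHEMA_VERSION
    # extractor
    extractor_min_sep: float = 3.0
    # smoothing
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    # trajectory generation
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    # effector
    arm: TwoJointArm = field(default_factory=TwoJointArm)
    placement: WorkspacePlacement = field(default_factory=WorkspacePlacement)
    # inference
    answer_policy: str = "sample"

    def __post_init__(self):
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise InvalidConfigError(
                f"unsupported config schema version {self.schema_version}")
        if self.answer_policy not in ("sample", "argmax"):
            raise InvalidConfigError(
                f"answer_policy must be 'sample' or 'argmax', got {self.answer_policy!r}")
        if self.extractor_min_sep <= 0:
            raise InvalidConfigError("extractor_min_sep must be positive")

    @staticmethod
    def from_mapping(data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data or {})
        nested = {"smoothing": SmoothingConfig, "generation": GenerationConfig,
                  "arm": TwoJointArm, "placement": WorkspacePlacement}
        known = {f.name for f in fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in nested:
                sub = nested[key]
                sub_known = {f.name for f in fields(sub)}
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise InvalidConfigError(
                        f"unknown keys under {key!r}: {sorted(sub_unknown)}")
                kwargs[key] = sub(**value)
            else:
                kwargs[key] = value
        return RunConfig(**kwargs)

    @staticmethod
    def load(path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return RunConfig.from_mapping(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
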