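"""YAML run configuration with the full reference default set.

A :class:`RunConfig` bundles the extractor, fine-tuning, classifier and
evaluation settings. Every unset field falls back to the reference
hyperparameters (fine-tuning: lr 5e-4, momentum 0.95, batch 64, 3 epochs;
volume classifier: lr 1e-3, momentum 0.9, batch 64, 150 epochs). One global
seed fans out deterministically to named sub-seeds (splits, augmentation,
initialization) so components can be re-seeded independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifiers import VolumeClassifierConfig
from .extractor import ExtractorConfig, FineTuneConfig

__all__ = ["RunConfig", "load_config", "subseed"]

log = logging.getLogger("octfmap")


@dataclass(frozen=True)
class EvalProtocolConfig:
    k: int = 5
    train_fraction: float = 0.4
    repeats: int = 5

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    finetune: FineTuneConfig = field(default_factory=FineTuneConfig)
    classifier: VolumeClassifierConfig = field(default_factory=VolumeClassifierConfig)
    evaluation: EvalProtocolConfig = field(default_factory=EvalProtocolConfig)
    seed: int = 0
    log_level: str = "INFO"

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["finetune"]["frozen_blocks"] = sorted(out["finetune"]["frozen_blocks"])
        return out

    def echo(self, out_dir: str | Path | None = None) -> dict:
        """Log the fully resolved configuration; write it beside outputs."""
        resolved = self.resolved()
        log.info("resolved configuration: %s", json.dumps(resolved, default=str))
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / "resolved_config.json").write_text(
                json.dumps(resolved, indent=2, default=str))
        return resolved


def subseed(seed: int, name: str) -> int:
    """Derive a named sub-seed from the global seed, below 2**31."""
    import zlib
    return int(np.random.SeedSequence(
        [seed, zlib.crc32(name.encode())]).generate_state(1)[0] % (2 ** 31))


_SECTION_TYPES = {
    "extractor": ExtractorConfig,
    "finetune": FineTuneConfig,
    "classifier": VolumeClassifierConfig,
    "evaluation": EvalProtocolConfig,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> RunConfig:
    """Load a YAML config; absent file or sections mean pure defaults.

    Unknown keys raise with the offending key path; dataclass validators
    surface invalid values (negative learning rates, 2**n >= rows, ...).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                raw.setdefault(key, {}).update(val)
            else:
                raw[key] = val

    kwargs: dict = {}
    for section, value in raw.items():
        if section in ("seed", "log_level"):
            kwargs[section] = value
            continue
        cls = _SECTION_TYPES.get(section)
        if cls is None:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(value, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        for key in value:
            if key not in valid:
                raise ValueError(f"unknown config key {section}.{key}")
        coerced = dict(value)
        for tup_key in ("crop_scale_range", "aspect_ratio_range"):
            if tup_key in coerced:
                coerced[tup_key] = tuple(coerced[tup_key])
        if "frozen_blocks" in coerced:
            coerced["frozen_blocks"] = frozenset(coerced["frozen_blocks"])
        try:
            kwargs[section] = cls(**coerced)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid config section {section!r}: {exc}") from exc
    return RunConfig(**kwargs)
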