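"""Flat YAML configuration for the pipeline.

The config collects every overridable constant: the normative-model
coefficients, the VAL rotation magnitude and sense, and the landmark
pairs defining the structure lines.  ``config_hash`` fingerprints a
canonical JSON rendering so reports can state exactly which settings
produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import DEFAULT_STRUCTURE_PAIRS, VAL_ANGLE_DEG
from .normative import NormativeModel


@dataclass
class PipelineConfig:
    normative: NormativeModel = field(default_factory=NormativeModel)
    val_angle_deg: float = VAL_ANGLE_DEG
    val_rotation_sense: str = "posterior"
    structure_pairs: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_PAIRS)
    )

    def to_dict(self) -> dict:
        return {
            "normative": self.normative.to_dict(),
            "val_angle_deg": self.val_angle_deg,
            "val_rotation_sense": self.val_rotation_sense,
            "structure_pairs": {k: list(v) for k, v in self.structure_pairs.items()},
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        pairs = {
            k: tuple(v) for k, v in cfg.get("structure_pairs", {}).items()
        } or dict(DEFAULT_STRUCTURE_PAIRS)
        return cls(
            normative=NormativeModel.from_dict(cfg.get("normative", {})),
            val_angle_deg=float(cfg.get("val_angle_deg", VAL_ANGLE_DEG)),
            val_rotation_sense=cfg.get("val_rotation_sense", "posterior"),
            structure_pairs=pairs,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = str(source)
        if "\n" not in text:
            text = Path(source).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
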