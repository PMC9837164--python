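"""Run configuration: YAML-backed settings for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import DEFAULT_AUS, GazeConfig
from .openface import QCConfig

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, validated before any compute.

    ``pairs`` lists the latent-structure pairs exported for paired loading
    plots; the default mirrors the usual presentation of the first four
    structures as (1, 2) and (3, 4).
    """

    input_dir: Path
    annotation_file: Path
    output_dir: Path
    qc: QCConfig = field(default_factory=QCConfig)
    gaze: GazeConfig = field(default_factory=GazeConfig)
    aus: tuple[str, ...] = DEFAULT_AUS
    preprocessing: str = "center_scale"
    alpha: float = 0.05
    n_permutations: int = 0
    pairs: tuple[tuple[int, int], ...] = ((1, 2), (3, 4))
    seed: int = 0

    def validate(self) -> None:
        if not self.input_dir.is_dir():
            raise ConfigError(f"input_dir does not exist: {self.input_dir}")
        if not self.annotation_file.is_file():
            raise ConfigError(f"annotation_file does not exist: {self.annotation_file}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.preprocessing not in ("center", "center_scale"):
            raise ConfigError(f"unknown preprocessing mode {self.preprocessing!r}")
        if self.n_permutations < 0:
            raise ConfigError("n_permutations must be >= 0")
        if not self.aus:
            raise ConfigError("AU set must not be empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        try:
            base = path.parent
            qc = QCConfig(**raw.get("qc", {}))
            gaze_raw = dict(raw.get("gaze", {}))
            if "threshold_deg" in gaze_raw:
                gaze_raw["threshold_rad"] = math.radians(gaze_raw.pop("threshold_deg"))
            gaze = GazeConfig(**gaze_raw)
            return cls(
                input_dir=(base / raw["input_dir"]).resolve(),
                annotation_file=(base / raw["annotation_file"]).resolve(),
                output_dir=(base / raw["output_dir"]).resolve(),
                qc=qc,
                gaze=gaze,
                aus=tuple(raw.get("aus", DEFAULT_AUS)),
                preprocessing=raw.get("preprocessing", "center_scale"),
                alpha=float(raw.get("alpha", 0.05)),
                n_permutations=int(raw.get("n_permutations", 0)),
                pairs=tuple(tuple(p) for p in raw.get("pairs", ((1, 2), (3, 4)))),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing required key {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "input_dir": str(self.input_dir),
            "annotation_file": str(self.annotation_file),
            "output_dir": str(self.output_dir),
            "qc": {
                "min_confidence": self.qc.min_confidence,
                "min_retained": self.qc.min_retained,
                "min_frames": self.qc.min_frames,
            },
            "gaze": {"threshold_rad": self.gaze.threshold_rad},
            "aus": list(self.aus),
            "preprocessing": self.preprocessing,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "pairs": [list(p) for p in self.pairs],
            "seed": self.seed,
        }

    def settings_dict(self) -> dict:
        """The settings without filesystem paths (stable across run locations)."""
        d = self.to_dict()
        for k in ("input_dir", "annotation_file", "output_dir"):
            d.pop(k)
        return d

    def config_hash(self) -> str:
        """Stable digest of the settings (paths excluded) for the run report."""
        return hashlib.sha256(
            json.dumps(self.settings_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
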