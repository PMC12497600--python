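"""Run configuration: every rule threshold in one serialisable schema.

Defaults are the study's values: 15 ms arousal drop over 5-45 s in the
150-500 ms validity band, 17-beat PTT2 window, 50 ms spike threshold,
3 h minimum artefact-free PTT (4 h for the sensitivity re-analysis), 4 h
minimum oximetry, ODI gates 7 and 4, 80% nadir threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 200
    mix: dict[str, float] | None = None      # category -> proportion
    artefact_level: float = 0.0              # cohort-mean artefact fraction
    study_hours_mean: float = 6.8
    study_hours_sd: float = 1.2
    generator: str = "features"              # "features" | "signals"
    analyze: bool = True
    min_ptt_hours: float = 3.0
    min_oximetry_hours: float = 4.0
    odi3_gate: float = 7.0
    odi4_gate: float = 4.0
    nadir_threshold: float = 80.0
    arousal_drop_ms: float = 15.0
    spike_threshold_ms: float = 50.0
    alpha: float = 0.05
    tree_split: float = 0.3
    out_dir: str = "results"
    verbosity: int = 1

    def validate(self) -> None:
        for name in ("min_ptt_hours", "min_oximetry_hours", "odi3_gate",
                     "odi4_gate", "nadir_threshold", "arousal_drop_ms",
                     "spike_threshold_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.generator not in ("features", "signals"):
            raise ValueError("generator must be 'features' or 'signals'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
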