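"""Pipeline configuration: serializable, hashable, strict about keys."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs; round-trips through JSON
    unchanged and rejects unknown keys on load."""

    input_dir: str = ""
    output_dir: str = ""
    fw_threshold: float = 0.8
    fw_comparator: str = "ge"  # shared by the CSF mask and fit eligibility
    b_max: float = 200.0
    min_voxels: int = 10
    subject_fraction: float = 0.5
    zone_edges_mm: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0)
    dilation_voxels: int = 3
    dilation_connectivity: int = 1
    outcomes: tuple[str, ...] = ("mmse", "moca", "stm", "ltm", "tmta")
    covariates: tuple[str, ...] = ("age", "sex", "education")
    cov_reps: int = 100
    cov_subsample: float = 0.95
    bootstrap_reps: int = 10
    bootstrap_subsample: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fw_comparator not in ("ge", "gt"):
            raise ValueError("fw_comparator must be 'ge' or 'gt'")
        object.__setattr__(self, "zone_edges_mm", tuple(float(e) for e in self.zone_edges_mm))
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "covariates", tuple(self.covariates))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "PipelineConfig":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**payload)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
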