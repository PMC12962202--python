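"""Run configuration: YAML round-trip, presets, and reproducibility hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .sequence_design import AcquisitionParams, get_preset


@dataclass
class RunConfig:
    """Everything needed to reproduce a design/simulate/fit/analyze run."""

    protocol: str | dict = "3T"  # preset name or inline AcquisitionParams fields
    phantom: dict = field(default_factory=lambda: {"kind": "vials"})
    noise_sd: float = 0.0
    snr: float | None = None
    seed: int = 0
    n_reps: int = 1
    fit_method: str = "magnitude"  # magnitude | complex | hybrid
    hybrid_weight: float = 0.5
    lambda_smooth: float = 0.05
    flip: dict = field(default_factory=lambda: {"mode": "fam"})  # or {"mode": "constant", "alpha_deg": 3}
    phantom_temperature_correction: bool = True
    out_dir: str = "famfat_out"
    log_level: str = "INFO"

    def acquisition_params(self) -> AcquisitionParams:
        if isinstance(self.protocol, str):
            return get_preset(self.protocol)
        fields = dict(self.protocol)
        for key in ("matrix", "fov_cm"):
            if key in fields:
                fields[key] = tuple(fields[key])
        preset = fields.pop("preset", None)
        return get_preset(preset, **fields) if preset else AcquisitionParams(**fields)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
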