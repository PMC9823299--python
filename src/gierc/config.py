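"""Run configuration with the computational settings used throughout.

Defaults: attenuation cutoffs rcs = 5.0 Å / rc = 6.0 Å, consensus
clustering widths 0.1 Å / 20° / 20° for bonds / angles / dihedrals, latent
dimension 128 and 5% latent noise.  Serialises to JSON; parse → serialise is
a fixed point.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    rcs: float = 5.0
    rc: float = 6.0
    eps_bond: float = 0.1
    eps_angle: float = 20.0
    eps_dihedral: float = 20.0
    latent_dim: int = 128
    noise_percent: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.rcs < self.rc:
            raise ValueError("require 0 < rcs < rc")
        if min(self.eps_bond, self.eps_angle, self.eps_dihedral) <= 0:
            raise ValueError("clustering widths must be positive")

    @property
    def eps(self):
        return (self.eps_bond, self.eps_angle, self.eps_dihedral)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path):
        Path(path).write_text(self.to_json() + "\n")
        return Path(path)
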