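"""Study configuration: one object that pins every pipeline choice.

The defaults ARE the simulated study conditions: the acquisition schedules,
the ASL constants, a 20-subject cohort (5 healthy volunteers, 5 heart
failure, 10 transplant) whose tissue parameters are drawn from the
reference-cohort group distributions, moderate image noise, and two
simulated observers with 0.5 mm contour jitter.  The configuration
round-trips losslessly through JSON; unknown keys are rejected so a typo in
a config file fails loudly instead of being ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .qmap import ASLConstants, DEFAULT_B_VALUES, DEFAULT_TI_MS

__all__ = ["StudyConfig"]


def _default_groups() -> dict[str, int]:
    return {"HV": 5, "HF": 5, "Tx": 10}


@dataclass
class StudyConfig:
    # phantom grid
    shape: tuple[int, int, int] = (26, 46, 46)
    spacing: tuple[float, float, float] = (4.0, 2.5, 2.5)  # (dz, dy, dx) mm
    # acquisition schedules
    ti_ms: tuple[float, ...] = DEFAULT_TI_MS
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    asl: ASLConstants = field(default_factory=ASLConstants)
    # image noise (signal units on M0 ~= 1000)
    noise_sd_molli: float = 10.0
    noise_sd_dwi: float = 10.0
    noise_sd_asl: float = 5.0
    # cohort
    groups: dict[str, int] = field(default_factory=_default_groups)
    dwi_groups: tuple[str, ...] = ("HV", "Tx")  # DWI not acquired in HF
    # observers
    observer_jitter_mm: float = 0.5
    observer_bias_mm: float = 0.0
    # ROI options
    repcx_radius_mm: float = 4.0
    sd_ddof: int = 0            # within-ROI SD divisor: 0 -> n, 1 -> n-1
    cov_pooling: str = "mean"   # or "rms"
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.ti_ms = tuple(float(t) for t in self.ti_ms)
        self.b_values = tuple(float(b) for b in self.b_values)
        self.dwi_groups = tuple(self.dwi_groups)
        if isinstance(self.asl, dict):
            self.asl = ASLConstants(**self.asl)
        if self.sd_ddof not in (0, 1):
            raise ValueError("sd_ddof must be 0 or 1")
        if self.cov_pooling not in ("mean", "rms"):
            raise ValueError("cov_pooling must be 'mean' or 'rms'")
        if self.observer_jitter_mm < 0:
            raise ValueError("observer jitter must be non-negative")
        if any(n < 0 for n in self.groups.values()):
            raise ValueError("group sizes must be non-negative")

    @property
    def n_subjects(self) -> int:
        return sum(self.groups.values())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["asl"] = dataclasses.asdict(self.asl)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
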