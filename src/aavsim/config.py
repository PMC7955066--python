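"""Run configuration: YAML round-trip for all model parameter blocks.

A :class:`RunConfig` bundles the assembly model, instrument model, scoring
parameters and noise model of one analysis so a screen or simulation can
be reproduced from a single human-editable file.  CLI flags override file
values; ``config_hash`` fingerprints the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .scoring import ScoringConfig
from .simulate import ChargingModel, InstrumentModel
from .stoichiometry import AssemblyModel
from .synthetic import _AAVLIKE_MASSES, NoiseModel

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Complete, serializable parameter set of one aavsim run."""

    assembly: AssemblyModel = field(
        default_factory=lambda: AssemblyModel(_AAVLIKE_MASSES)
    )
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    output_dir: str = "."
    verbosity: str = "info"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["assembly"]["vp_masses"] = list(d["assembly"]["vp_masses"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        assembly = d.get("assembly", {})
        if assembly:
            assembly = dict(assembly)
            assembly["vp_masses"] = tuple(assembly["vp_masses"])
        instrument = dict(d.get("instrument", {}))
        charging = instrument.pop("charging", None)
        kwargs = {}
        if assembly:
            kwargs["assembly"] = AssemblyModel(**assembly)
        if instrument or charging:
            if charging is not None:
                instrument["charging"] = ChargingModel(**charging)
            kwargs["instrument"] = InstrumentModel(**instrument)
        if d.get("scoring"):
            kwargs["scoring"] = ScoringConfig(**d["scoring"])
        if d.get("noise"):
            kwargs["noise"] = NoiseModel(**d["noise"])
        for key in ("output_dir", "verbosity"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Stable sha256 fingerprint of the resolved configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
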