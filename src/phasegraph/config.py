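"""Pipeline configuration: a JSON-round-trippable description of a run.

A PipelineConfig names, for each of two groups, either input recording
paths or simulation configs, together with the analysis parameters
(epoch structure, slope fit range, alpha level, averaging convention).
Unknown keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .simulate import Coupling, SimulationConfig


@dataclass
class GroupSpec:
    """One group's inputs: recording paths XOR simulation configs."""

    paths: list[str] = field(default_factory=list)
    simulations: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if bool(self.paths) == bool(self.simulations):
            raise ValueError(
                "each group needs either 'paths' or 'simulations', not both"
            )


@dataclass
class PipelineConfig:
    group_a: GroupSpec
    group_b: GroupSpec
    epoch_length_s: float = 2.0
    overlap: float = 0.0
    fit_range: tuple[float, float] = (2.0, 43.0)
    alpha_level: float = 0.05
    average_mode: str = "cross_spectra"
    outdir: str = "results"
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        for key in ("group_a", "group_b"):
            if key not in raw:
                raise ValueError(f"config missing required {key!r}")
            grp = dict(raw[key])
            extra = set(grp) - {"paths", "simulations"}
            if extra:
                raise ValueError(f"unknown {key} keys: {sorted(extra)}")
            raw[key] = GroupSpec(**grp)
        if "fit_range" in raw:
            raw["fit_range"] = tuple(raw["fit_range"])
        return cls(**raw)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def simulation_configs(self, group: str) -> list[SimulationConfig]:
        """Materialise a group's simulation configs (seeded substreams)."""
        spec = getattr(self, group)
        configs = []
        for k, raw in enumerate(spec.simulations):
            raw = dict(raw)
            couplings = [_coupling_from_dict(c)
                         for c in raw.pop("couplings", [])]
            # substream seeds: distinct per group and per recording, all
            # derived from the single top-level seed
            raw.setdefault("seed", (self.seed * 10007 + k
                           + (0 if group == "group_a" else 5003)) % (2**31))
            configs.append(SimulationConfig(couplings=couplings, **raw))
        return configs


def _coupling_from_dict(c: dict) -> Coupling:
    if "band_name" in c:
        return Coupling.in_band(c["i"], c["j"], c["band_name"],
                                c["phase_lag"], c["amplitude"])
    return Coupling(c["i"], c["j"], tuple(c["band"]), c["phase_lag"],
                    c["amplitude"])
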