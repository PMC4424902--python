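"""Experiment configuration: defaults, loading, validation.

The defaults reproduce the reference simulation conditions: a cohort of
861 individuals with 166 observed SNVs, 10% of variants causal, the
score-causal relative-risk grid {1.1, 2, 4}, carrier phenotype
N(0.5, 0.2^2), median-split labels, 400 replicates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import CohortParams


@dataclass
class SimulationConfig:
    """Full configuration of the simulation-evaluation experiment."""

    cohort: CohortParams = field(default_factory=CohortParams)
    causal_fraction: float = 0.10
    mu: float = 0.5
    sd_carrier: float = 0.2
    rr_grid: list[float] = field(default_factory=lambda: [1.1, 2.0, 4.0])
    replicates: int = 400
    fix_cohort: bool = True
    penalty: str = "firth"
    penalty_strength: float = 1.0
    tau2: float | str = 1.0
    diag_v: bool = False
    master_seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        self.cohort.validate()
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.rr_grid:
            raise ValueError("rr_grid must be non-empty")
        if any(rr < 1 for rr in self.rr_grid):
            raise ValueError("rr_grid entries must be >= 1")
        if not 0 < self.causal_fraction < 1:
            raise ValueError("causal_fraction must be in (0, 1)")
        if self.sd_carrier <= 0:
            raise ValueError("sd_carrier must be positive")
        if self.penalty not in ("firth", "ridge", "none"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if self.tau2 != "moment" and float(self.tau2) < 0:
            raise ValueError("tau2 must be 'moment' or a non-negative number")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def echo(self, out_dir) -> Path:
        """Write the resolved configuration as JSON next to the outputs."""
        path = Path(out_dir) / "config.json"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def load_config(path) -> SimulationConfig:
    """Load a YAML (or JSON) configuration, rejecting unknown keys.

    An empty file yields all defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    cohort_raw = raw.pop("cohort", {}) or {}
    if not isinstance(cohort_raw, dict):
        raise ValueError("'cohort' must be a mapping")
    cohort_fields = {f.name for f in dataclasses.fields(CohortParams)}
    unknown = set(cohort_raw) - cohort_fields
    if unknown:
        raise ValueError(f"unknown cohort config key(s): {sorted(unknown)}")
    top_fields = {f.name for f in dataclasses.fields(SimulationConfig)} - {"cohort"}
    unknown = set(raw) - top_fields
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    config = SimulationConfig(cohort=CohortParams(**cohort_raw), **raw)
    config.validate()
    return config
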