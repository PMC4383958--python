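"""Run configuration: every pipeline tunable with its default.

The effective configuration is serialized into each output directory so a
run is reproducible from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # alignment / distances
    grid_start: float = 10.0
    grid_stop: float = 300.0
    grid_step: float = 10.0
    gap_open: int = 12
    gap_extend: int = 2
    min_score: float = 130.0
    min_aln_fraction: float = 0.6
    # pairs
    k_tolerance: float = 1.96
    witness_tol: float = 0.0
    witness_use_stderr: bool = True
    witness_se_multiplier: float = 1.96
    # groups / HOGs
    min_edges: int = 1
    fingerprint_k: int = 7
    # GO propagation
    clades: list[str] = field(default_factory=list)  # empty = all named nodes
    go_with_part_of: bool = False
    # homeology
    sd_multiplier: float = 2.5
    population_sd: bool = True
    # synteny
    window: int = 3
    # misc
    seed: int = 0

    def grid(self) -> tuple[float, ...]:
        out = []
        d = self.grid_start
        while d <= self.grid_stop + 1e-9:
            out.append(round(d, 6))
            d += self.grid_step
        return tuple(out)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
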