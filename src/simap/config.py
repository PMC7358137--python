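"""Single structured run configuration shared by all CLI stages.

Every threshold the pipeline uses (significance level, SDL ratio cutoff,
log-phase window, replicate counts, split/fold settings) lives here with an
explicit default, and the configuration is echoed verbatim into every output
directory so a run can be reproduced exactly from its artifacts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthetic import SimulationConfig


@dataclass
class RunConfig:
    seed: int = 0
    alpha: float = 0.05
    sdl_ratio_cutoff: float = 0.8
    lof_tolerance_px: float = 1.0          # degenerate-sentinel guard, pixels
    liquid_rate_tolerance: float = 1e-6    # degenerate |k_vec - k_wt| guard
    window_h: tuple[float, float] = (0.0, 6.0)
    interval_min: float = 4.0
    wells_per_variant: int = 8
    fitness_anchors: tuple[float, float] = (1.0, 0.0)  # external metric: wt-like, null
    split: float = 0.7
    folds: int = 5
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.window_h = tuple(self.window_h)  # type: ignore[assignment]
        self.fitness_anchors = tuple(self.fitness_anchors)  # type: ignore[assignment]

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, simulation=dataclasses.replace(self.simulation, seed=seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_h"] = list(self.window_h)
        d["fitness_anchors"] = list(self.fitness_anchors)
        d["simulation"]["calib_coeffs"] = list(self.simulation.calib_coeffs)
        return d

    def echo(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            if "calib_coeffs" in sim:
                sim["calib_coeffs"] = tuple(sim["calib_coeffs"])
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)
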