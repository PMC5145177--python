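"""Validated run configuration (YAML) and provenance echoing.

A run config bundles everything needed to reproduce a simulation: input
paths (habitat table plus either a gridded flow file or an analytic-flow
block), the physical/numerical run parameters, the release schedule, the
analysis toggles and the master seed.  Unknown keys are rejected so typos
fail loudly, and the fully resolved config is written next to the outputs
for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .flow_fields import FlowField, flow_from_config, read_gridded_flow
from .tracker import DEFAULT_END, DEFAULT_START, ReleaseSchedule, RunParams

_TOP_KEYS = {"habitat", "flow", "output_dir", "run", "schedule", "analysis", "seed"}
_RUN_KEYS = {
    "pld_days",
    "settle_radius_km",
    "eddy_diffusivity",
    "dt_seconds",
    "particles_per_pixel_per_day",
    "integrator",
    "replicates",
}
_SCHEDULE_KEYS = {"start", "end", "months"}
_ANALYSIS_KEYS = {"directions", "mantel_permutations", "mantel_include_diagonal", "settlement_denominator"}
_FLOW_KEYS = {"path", "analytic"}


@dataclass
class AnalysisOptions:
    directions: list = field(default_factory=lambda: ["rearward", "forward"])
    mantel_permutations: int = 999
    mantel_include_diagonal: bool = False
    settlement_denominator: str = "archipelago"

    def __post_init__(self):
        bad = set(self.directions) - {"rearward", "forward"}
        if bad:
            raise ValueError(f"unknown matrix directions: {sorted(bad)}")
        if self.mantel_permutations < 99:
            raise ValueError("mantel_permutations must be at least 99")
        if self.settlement_denominator not in ("archipelago", "island"):
            raise ValueError("settlement_denominator must be 'archipelago' or 'island'")


@dataclass
class RunConfig:
    """Fully validated configuration for one dispersal experiment."""

    habitat: str
    flow: dict
    output_dir: str = "out"
    params: RunParams = field(default_factory=RunParams)
    schedule_start: str = DEFAULT_START
    schedule_end: str = DEFAULT_END
    months: list | None = None
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0

    def build_schedule(self) -> ReleaseSchedule:
        return ReleaseSchedule.daily(self.schedule_start, self.schedule_end, self.months)

    def build_flow(self) -> FlowField:
        if "path" in self.flow:
            return read_gridded_flow(self.flow["path"])
        return flow_from_config(self.flow["analytic"])

    def to_dict(self) -> dict:
        return {
            "habitat": self.habitat,
            "flow": self.flow,
            "output_dir": self.output_dir,
            "run": asdict(self.params),
            "schedule": {"start": self.schedule_start, "end": self.schedule_end, "months": self.months},
            "analysis": asdict(self.analysis),
            "seed": self.seed,
        }

    def dump(self, path) -> None:
        """Write the resolved config (the provenance copy) as YAML."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    if "habitat" not in raw:
        raise ValueError("config missing required key 'habitat'")
    if "flow" not in raw:
        raise ValueError("config missing required key 'flow'")
    flow = raw["flow"]
    if not isinstance(flow, dict):
        raise ValueError("'flow' must be a mapping with 'path' or 'analytic'")
    _reject_unknown(flow, _FLOW_KEYS, "flow")
    if ("path" in flow) == ("analytic" in flow):
        raise ValueError("flow needs exactly one of 'path' or 'analytic'")

    run_block = raw.get("run", {}) or {}
    _reject_unknown(run_block, _RUN_KEYS, "run")
    seed = int(raw.get("seed", 0))
    params = RunParams(seed=seed, **run_block)  # RunParams validates values

    sched = raw.get("schedule", {}) or {}
    _reject_unknown(sched, _SCHEDULE_KEYS, "schedule")
    months = sched.get("months")
    if months is not None:
        months = [int(m) for m in months]

    ana = raw.get("analysis", {}) or {}
    _reject_unknown(ana, _ANALYSIS_KEYS, "analysis")

    return RunConfig(
        habitat=str(raw["habitat"]),
        flow=flow,
        output_dir=str(raw.get("output_dir", "out")),
        params=params,
        schedule_start=sched.get("start", DEFAULT_START),
        schedule_end=sched.get("end", DEFAULT_END),
        months=months,
        analysis=AnalysisOptions(**ana),
        seed=seed,
    )


def parse_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are hard errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})
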