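"""Scenario configuration and structured output.

A run is fully determined by a YAML/JSON config (scenario geometry, agent
population, niche dynamics, schedule, seed).  Validation collects *all*
schema violations before failing, and unknown keys are rejected so typos
surface instead of silently using defaults.

Outputs: a per-step CSV table, a JSONL event log, a JSON summary, and the
final trace field serialized as one delimited matrix per action (row-major
grid) with a JSON sidecar holding labels, shape and dynamics parameters.
All writers are deterministic for a fixed record (floats printed with 12
significant digits) so same-seed runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .generative_model import DirichletCounts
from .niche import NicheModel

FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class ScenarioConfig:
    kind: str = "desire_path"
    width: int = 10
    height: int = 10
    start: tuple[int, int] = (0, 0)
    goals: tuple[tuple[int, int], ...] = ((9, 9),)
    trace_quantization: tuple[float, float] = (15.0, 40.0)
    obs_noise: float = 0.05


@dataclass(frozen=True)
class AgentConfig:
    n: int = 20
    archetype_mix: dict = field(default_factory=lambda: {"cafe_goer": 0.8, "wanderer": 0.2})
    precision: float = 4.0
    deontic_weight: float = 2.0
    horizon: int = 1
    learning_rate: float = 1.0


@dataclass(frozen=True)
class NicheConfig:
    deposit: float = 0.1
    consolidation: float = 10.0
    decay: float = 0.01
    type_learn_rate: float = 1.0
    initial_trace: float = 1.0


@dataclass(frozen=True)
class ScheduleConfig:
    steps: int = 200
    generations: int = 5
    persist_niche: bool = True


@dataclass(frozen=True)
class RunConfig:
    scenario: ScenarioConfig
    agents: AgentConfig
    niche: NicheConfig
    schedule: ScheduleConfig
    seed: int
    output: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["start"] = list(d["scenario"]["start"])
        d["scenario"]["goals"] = [list(g) for g in d["scenario"]["goals"]]
        d["scenario"]["trace_quantization"] = list(d["scenario"]["trace_quantization"])
        return d


def default_config(seed: int = 1) -> RunConfig:
    """The canned desire-path demo configuration."""
    return RunConfig(
        scenario=ScenarioConfig(),
        agents=AgentConfig(),
        niche=NicheConfig(),
        schedule=ScheduleConfig(),
        seed=seed,
    )


_SECTION_FIELDS = {
    "scenario": ScenarioConfig,
    "agents": AgentConfig,
    "niche": NicheConfig,
    "schedule": ScheduleConfig,
}


def parse_config(data: dict, source: str = "<config>") -> RunConfig:
    """Validate a raw mapping into a RunConfig, reporting every violation."""
    problems: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError([f"{source}: top level must be a mapping"])
    known_top = set(_SECTION_FIELDS) | {"seed", "output"}
    for key in data:
        if key not in known_top:
            problems.append(f"unknown top-level key {key!r}")

    sections = {}
    for name, cls in _SECTION_FIELDS.items():
        raw = data.get(name, {})
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            problems.append(f"section {name!r} must be a mapping")
            raw = {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in allowed:
                problems.append(f"{name}: unknown key {key!r} (allowed: {sorted(allowed)})")
        kwargs = {}
        for key, value in raw.items():
            if key in allowed:
                if key in ("start",):
                    value = tuple(value)
                elif key in ("goals",):
                    value = tuple(tuple(g) for g in value)
                elif key in ("trace_quantization",):
                    value = tuple(float(v) for v in value)
                kwargs[key] = value
        try:
            sections[name] = cls(**kwargs)
        except (TypeError, ValueError) as exc:
            problems.append(f"{name}: {exc}")
            sections[name] = cls()

    if "seed" not in data or data["seed"] is None:
        problems.append("missing required field 'seed'")
        seed = 0
    else:
        try:
            seed = int(data["seed"])
        except (TypeError, ValueError):
            problems.append(f"seed must be an integer, got {data['seed']!r}")
            seed = 0

    # range checks
    sc, ag, ni, sch = (sections[k] for k in ("scenario", "agents", "niche", "schedule"))
    if sc.kind not in ("desire_path", "burrow"):
        problems.append(f"scenario.kind must be 'desire_path' or 'burrow', got {sc.kind!r}")
    if sc.width < 1 or sc.height < 1 or sc.width * sc.height < 2:
        problems.append(f"scenario grid {sc.width}x{sc.height} has fewer than 2 cells")
    if not (0.0 <= sc.obs_noise < 1.0):
        problems.append(f"scenario.obs_noise must be in [0, 1), got {sc.obs_noise!r}")
    if ag.n < 1:
        problems.append(f"agents.n must be >= 1, got {ag.n!r}")
    if not ag.precision > 0:
        problems.append(f"agents.precision must be positive, got {ag.precision!r}")
    if ag.deontic_weight < 0:
        problems.append(f"agents.deontic_weight must be non-negative, got {ag.deontic_weight!r}")
    if ag.horizon < 1:
        problems.append(f"agents.horizon must be >= 1, got {ag.horizon!r}")
    if not (0.0 <= ni.decay < 1.0):
        problems.append(f"niche.decay must be in [0, 1), got {ni.decay!r}")
    if ni.deposit < 0:
        problems.append(f"niche.deposit must be non-negative, got {ni.deposit!r}")
    if ni.consolidation < 0:
        problems.append(f"niche.consolidation must be non-negative, got {ni.consolidation!r}")
    if not ni.initial_trace > 0:
        problems.append(f"niche.initial_trace must be positive, got {ni.initial_trace!r}")
    if sch.steps < 1:
        problems.append(f"schedule.steps must be >= 1, got {sch.steps!r}")
    if sch.generations < 1:
        problems.append(f"schedule.generations must be >= 1, got {sch.generations!r}")

    if problems:
        raise ConfigError([f"{source}: {p}" for p in problems])
    return RunConfig(
        scenario=sc, agents=ag, niche=ni, schedule=sch, seed=seed, output=data.get("output")
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError([f"config file not found: {p}"])
    with open(p) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data, source=str(p))


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# record and field writers


def write_record(record, outdir, config: RunConfig | None = None, niche: NicheModel | None = None) -> dict[str, Path]:
    """Write an episode/record to ``outdir``.

    Emits steps.csv (per-step table), events.jsonl, summary.json and, when
    the final niche is supplied, the trace/affordance field files.  Returns
    the mapping of artifact name to path.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    df = record.to_dataframe()
    paths["steps"] = out / "steps.csv"
    df.to_csv(paths["steps"], index=False, float_format=FLOAT_FMT)

    paths["events"] = out / "events.jsonl"
    with open(paths["events"], "w") as fh:
        for row in record.steps:
            fh.write(json.dumps(dataclasses.asdict(row), sort_keys=True) + "\n")

    summary = record.summary()
    summary["time_to_goal"] = {str(k): v for k, v in sorted(record.time_to_goal.items())}
    summary["reached"] = {str(k): bool(v) for k, v in sorted(record.reached.items())}
    summary["seed"] = record.seed
    if config is not None:
        summary["config"] = config.to_dict()
    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if niche is not None:
        paths.update(write_trace_field(niche, out))
    return paths


def write_trace_field(niche: NicheModel, outdir) -> dict[str, Path]:
    """Serialize the trace field: one delimited matrix per action (row-major
    over locations) plus a JSON sidecar with labels, shape and parameters."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for k, a in enumerate(niche.actions):
        p = out / f"trace_{a}.tsv"
        np.savetxt(p, niche.trace.concentration[:, k], fmt=FLOAT_FMT, delimiter="\t")
        paths[f"trace_{a}"] = p
    sidecar = {
        "locations": list(niche.locations),
        "actions": list(niche.actions),
        "agent_types": list(niche.agent_types),
        "shape": list(niche.trace.shape),
        "floor": niche.trace.floor,
        "decay_rate": niche.decay_rate,
        "type_counts": [float(v) for v in niche.type_counts.concentration],
        "action_likelihood": [[float(v) for v in row] for row in niche.action_likelihood],
    }
    paths["field_meta"] = out / "field.json"
    with open(paths["field_meta"], "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def load_trace_field(outdir) -> NicheModel:
    """Round-trip loader for :func:`write_trace_field`."""
    out = Path(outdir)
    with open(out / "field.json") as fh:
        meta = json.load(fh)
    cols = []
    for a in meta["actions"]:
        cols.append(np.loadtxt(out / f"trace_{a}.tsv", delimiter="\t"))
    trace = np.column_stack(cols)
    return NicheModel(
        agent_types=tuple(meta["agent_types"]),
        type_counts=DirichletCounts(np.asarray(meta["type_counts"]), floor=meta["floor"]),
        action_likelihood=np.asarray(meta["action_likelihood"]),
        locations=tuple(meta["locations"]),
        actions=tuple(meta["actions"]),
        trace=DirichletCounts(trace, floor=meta["floor"]),
        decay_rate=meta["decay_rate"],
    )
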