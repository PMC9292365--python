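"""Run organisms and niche together and close the circle of causality.

Each global step interleaves, synchronously: every active agent perceives,
selects an action (reading deontic cues off the affordance field at its
location, scaled by its deontic weight), and moves; the niche observes each
(location, action) event, updates its type beliefs, deposits a shallow
trace, and then decays once.  When an agent reaches a goal its realized
path — loop-erased to the final exit action per visited cell — receives a
consolidation deposit: trails only deepen when they demonstrably led
somewhere, which is what lets worn paths come to encode routes rather than
meanders.

Free energy is extensive: the joint free energy of the coupled system at a
step is simply the sum of the organism-side and niche-side totals for the
shared (sensation, action) pair, and this identity is logged and enforced
at every recorded step.

Across generations, agents are reset to naive (fresh beliefs and Dirichlet
counts, back at the start cell; phenotypic preferences persist) while the
niche — trace field and type posterior — persists.  Whatever navigational
competence later generations show beyond the first has therefore been
uploaded into the niche, and an ablation flag that resets the niche between
generations removes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .agent import AgentState, agent_step, deontic_vector, enumerate_policies
from .errors import EAIError
from .generative_model import entropy
from .inference import FreeEnergyReport
from .niche import (
    NicheModel,
    affordance_field,
    decay_traces,
    deposit_trace,
    location_label,
    niche_step,
    trace_entropy,
)
from .scenarios import GRID_OBSERVATIONS, GridWorld


def joint_free_energy(organism: FreeEnergyReport, niche_r: FreeEnergyReport) -> float:
    """Extensivity of free energy: the coupled system's free energy is the
    sum of the organism's and the niche's, conditioned on the shared
    sensation/action pair of the same timestep."""
    return organism.total + niche_r.total


@dataclass(frozen=True)
class StepRow:
    """One logged perception-action-niche event."""

    t: int
    agent_id: int
    position: str
    observation: str
    action: str
    org_divergence: float
    org_surprisal: float
    org_total: float
    niche_divergence: float
    niche_surprisal: float
    niche_total: float
    joint: float
    policy_entropy: float
    affordance_at_loc: tuple[float, ...]


@dataclass
class SimulationRecord:
    """Complete per-step log of an episode plus per-agent outcomes."""

    steps: list[StepRow]
    actions: tuple[str, ...]
    time_to_goal: dict[int, int]
    reached: dict[int, bool]
    consolidated_paths: dict[int, dict[str, str]]
    max_steps: int
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "t", "agent_id", "position", "observation", "action",
            "org_divergence", "org_surprisal", "org_total",
            "niche_divergence", "niche_surprisal", "niche_total",
            "joint", "policy_entropy",
        ]
        data = {c: [getattr(r, c) for r in self.steps] for c in cols}
        for k, a in enumerate(self.actions):
            data[f"affordance_{a}"] = [r.affordance_at_loc[k] for r in self.steps]
        return pd.DataFrame(data)

    def summary(self) -> dict:
        times = [self.time_to_goal[i] for i in sorted(self.time_to_goal)]
        out = {
            "n_steps": len(self.steps),
            "n_agents": len(self.time_to_goal),
            "fraction_reached": (
                float(np.mean([self.reached[i] for i in sorted(self.reached)])) if self.reached else 0.0
            ),
            "median_time_to_goal": float(np.median(times)) if times else float("nan"),
            "mean_time_to_goal": float(np.mean(times)) if times else float("nan"),
        }
        if self.steps:
            out.update(
                mean_org_free_energy=float(np.mean([r.org_total for r in self.steps])),
                mean_niche_free_energy=float(np.mean([r.niche_total for r in self.steps])),
                mean_joint_free_energy=float(np.mean([r.joint for r in self.steps])),
                mean_policy_entropy=float(np.mean([r.policy_entropy for r in self.steps])),
            )
        return out


@dataclass
class EpisodeResult:
    record: SimulationRecord
    niche: NicheModel
    agents: list[AgentState]


def run_episode(
    world: GridWorld,
    agents: Sequence[AgentState],
    niche: NicheModel,
    max_steps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    step_deposit: float = 0.1,
    consolidation: float = 10.0,
    type_learn_rate: float = 1.0,
    deterministic: bool = False,
) -> EpisodeResult:
    """Run one synchronous episode until every agent reached a goal or
    ``max_steps`` elapsed.

    Agents arriving at a goal are absorbed (their arrival step recorded as
    time-to-goal; non-finishers are censored at ``max_steps``).  The result
    is bit-reproducible given identical inputs and seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    agents = list(agents)
    n = len(agents)
    done = [False] * n
    time_to_goal: dict[int, int] = {}
    trajectories: list[dict[str, str]] = [dict() for _ in range(n)]
    rows: list[StepRow] = []
    goal_cells = {world.cell_index(g) for g in world.goals}
    n_obs = len(GRID_OBSERVATIONS)

    try:
        for t in range(max_steps):
            A = world.observation_matrix(niche)
            aff = affordance_field(niche)
            # deontic cues only speak where the trace is at least 'visible':
            # shallow traces encode alternative mappings of near-equal prior
            # probability and carry no invitation yet
            cell_totals = niche.trace.concentration.sum(axis=1)
            salient = cell_totals >= world.trace_thresholds[0]
            for i in range(n):
                if done[i]:
                    continue
                agent = replace(agents[i], model=agents[i].model.with_likelihood(A))
                j = world.cell_index(agent.position)
                obs_col = A[:, j]
                if deterministic:
                    obs = GRID_OBSERVATIONS[int(np.argmax(obs_col))]
                else:
                    obs = GRID_OBSERVATIONS[int(rng.choice(n_obs, p=obs_col))]

                policies = enumerate_policies(agent.model.actions, agent.horizon)
                kappa = agent.deontic_weight if salient[j] else 0.0
                deontic = deontic_vector(
                    policies, aff.values[j], agent.model.actions, kappa
                )
                res = agent_step(agent, obs, deontic, rng, deterministic=deterministic)

                old_pos = agent.position
                new_pos = world.move(old_pos, res.action)
                trajectories[i][location_label(old_pos)] = res.action
                niche, _, nreport = niche_step(
                    niche, old_pos, res.action, deposit=step_deposit, type_learn_rate=type_learn_rate
                )
                rows.append(
                    StepRow(
                        t=t,
                        agent_id=i,
                        position=location_label(old_pos),
                        observation=obs,
                        action=res.action,
                        org_divergence=res.free_energy.divergence,
                        org_surprisal=res.free_energy.surprisal,
                        org_total=res.free_energy.total,
                        niche_divergence=nreport.divergence,
                        niche_surprisal=nreport.surprisal,
                        niche_total=nreport.total,
                        joint=joint_free_energy(res.free_energy, nreport),
                        policy_entropy=entropy(res.policy_posterior),
                        affordance_at_loc=tuple(float(v) for v in aff.values[j]),
                    )
                )
                agents[i] = replace(res.state, position=new_pos)
                if world.cell_index(new_pos) in goal_cells:
                    done[i] = True
                    time_to_goal[i] = t + 1
                    if consolidation > 0:
                        for cell, act in trajectories[i].items():
                            niche = deposit_trace(niche, cell, act, consolidation)
            niche = decay_traces(niche)
            if all(done):
                break
    except EAIError as exc:
        record = _finish_record(rows, niche, time_to_goal, done, trajectories, max_steps, seed)
        exc.partial_record = record
        raise

    record = _finish_record(rows, niche, time_to_goal, done, trajectories, max_steps, seed)
    return EpisodeResult(record=record, niche=niche, agents=agents)


def _finish_record(rows, niche, time_to_goal, done, trajectories, max_steps, seed) -> SimulationRecord:
    n = len(done)
    return SimulationRecord(
        steps=rows,
        actions=tuple(niche.actions),
        time_to_goal={i: time_to_goal.get(i, max_steps) for i in range(n)},
        reached={i: done[i] for i in range(n)},
        consolidated_paths={i: dict(trajectories[i]) for i in range(n) if done[i]},
        max_steps=max_steps,
        seed=seed,
    )


@dataclass(frozen=True)
class GenerationSummary:
    generation: int
    median_time_to_goal: float
    mean_time_to_goal: float
    fraction_reached: float
    mean_org_free_energy: float
    mean_niche_free_energy: float
    mean_joint_free_energy: float
    mean_policy_entropy: float
    n_steps: int


@dataclass
class GenerationResult:
    summary: GenerationSummary
    record: SimulationRecord


@dataclass
class RunResult:
    generations: list[GenerationResult]
    final_niche: NicheModel

    @property
    def summaries(self) -> list[GenerationSummary]:
        return [g.summary for g in self.generations]


def run_generations(
    world: GridWorld,
    niche: NicheModel,
    n_generations: int,
    agents_per_generation: int,
    steps_per_generation: int,
    seed: int,
    archetype_mix=None,
    persist_niche: bool = True,
    step_deposit: float = 0.1,
    consolidation: float = 10.0,
    type_learn_rate: float = 1.0,
    deontic_weight: float = 2.0,
    precision: float = 4.0,
    horizon: int = 1,
) -> RunResult:
    """Repeat episodes across agent generations.

    Between generations agent beliefs, counts and positions reset to naive
    while preferences (the phenotype) persist; the niche persists unless
    ``persist_niche=False``, the uploading ablation, in which case each
    generation faces the pristine initial niche.
    """
    from .scenarios import make_agent_population

    if n_generations < 1:
        raise ValueError(f"n_generations must be >= 1, got {n_generations!r}")
    if archetype_mix is None:
        archetype_mix = {"cafe_goer": 1.0}
    initial_niche = niche
    children = np.random.SeedSequence(seed).spawn(n_generations)
    results: list[GenerationResult] = []
    for g in range(n_generations):
        if not persist_niche:
            niche = initial_niche
        rng = np.random.default_rng(children[g])
        agents = make_agent_population(
            world,
            niche,
            agents_per_generation,
            archetype_mix,
            rng,
            precision=precision,
            deontic_weight=deontic_weight,
            horizon=horizon,
        )
        ep = run_episode(
            world,
            agents,
            niche,
            max_steps=steps_per_generation,
            rng=rng,
            seed=seed,
            step_deposit=step_deposit,
            consolidation=consolidation,
            type_learn_rate=type_learn_rate,
        )
        niche = ep.niche
        s = ep.record.summary()
        results.append(
            GenerationResult(
                summary=GenerationSummary(
                    generation=g,
                    median_time_to_goal=s["median_time_to_goal"],
                    mean_time_to_goal=s["mean_time_to_goal"],
                    fraction_reached=s["fraction_reached"],
                    mean_org_free_energy=s.get("mean_org_free_energy", float("nan")),
                    mean_niche_free_energy=s.get("mean_niche_free_energy", float("nan")),
                    mean_joint_free_energy=s.get("mean_joint_free_energy", float("nan")),
                    mean_policy_entropy=s.get("mean_policy_entropy", float("nan")),
                    n_steps=s["n_steps"],
                ),
                record=ep.record,
            )
        )
    return RunResult(generations=results, final_niche=niche)


def mutual_predictability(record: SimulationRecord, window: int = 50) -> list[float]:
    """Windowed divergence between what the niche expects and what agents do.

    For each block of ``window`` time steps: the niche's predicted action
    distribution is the visit-weighted mixture of affordance-field rows at
    the locations agents actually occupied, and the agents' behaviour is
    their empirical action frequency; the series is KL[empirical ||
    predicted] in nats (finite because the field is strictly positive).
    Mutually predictable coupling drives the series toward zero.
    """
    if window < 10:
        raise ValueError(f"window must be >= 10 steps, got {window!r}")
    if not record.steps:
        raise ValueError("empty record")
    idx = {a: k for k, a in enumerate(record.actions)}
    n_a = len(record.actions)
    series: list[float] = []
    t_max = max(r.t for r in record.steps)
    for w0 in range(0, t_max + 1, window):
        rows = [r for r in record.steps if w0 <= r.t < w0 + window]
        if not rows:
            continue
        emp = np.zeros(n_a)
        pred = np.zeros(n_a)
        for r in rows:
            emp[idx[r.action]] += 1.0
            pred += np.exp(np.asarray(r.affordance_at_loc))
        emp /= emp.sum()
        pred /= pred.sum()
        series.append(float(rel_entr(emp, pred).sum()))
    return series


def complexity_metric(record: SimulationRecord) -> float:
    """Mean policy-posterior entropy per decision (nats).

    Operationalizes counterfactual load: an agent whose niche tells it what
    to do needs to entertain fewer live alternatives per decision, so this
    mean drops as cues consolidate.
    """
    if not record.steps:
        raise ValueError("record contains no logged decisions")
    return float(np.mean([r.policy_entropy for r in record.steps]))


def realized_path_cells(record: SimulationRecord) -> list[str]:
    """Union of cells on the consolidated (loop-erased, goal-reaching)
    paths of the record's successful agents."""
    cells: dict[str, None] = {}
    for path in record.consolidated_paths.values():
        for cell in path:
            cells.setdefault(cell)
    return list(cells)


def path_trace_entropy(niche: NicheModel, cells: Sequence[str]) -> float:
    """Mean per-location entropy of the expected trace action distribution
    over the given cells (nats)."""
    if not cells:
        raise ValueError("no cells supplied")
    return float(np.mean(trace_entropy(niche, cells)))
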