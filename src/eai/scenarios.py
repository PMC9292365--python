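"""Synthetic-world generators.

Two worlds are provided:

* a desire-path park — a bounded grid with a start ("park gate") and one or
  more goal cells ("the café"), over which a niche trace field records the
  actions of passing agents; pedestrians wear paths into the grass that
  later pedestrians read as invitations to act;
* a two-state burrow world — hidden states in/out of a burrow, wet/dry
  sensations — the minimal worked example used throughout the docs and
  tests.

Plus a population factory drawing agents from named preference archetypes
(café-goer: strong goal preference; wanderer: flat preferences).

Conventions: coordinates are 0-based (column, row); moves that would leave
the grid resolve to staying put (clamping); trace intensities seen by the
agents are quantized to three levels (faint / visible / deep), the minimal
non-binary reading of "shallow" versus consolidated traces, plus an at-goal
flag that overrides them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .agent import DEFAULT_PRECISION, AgentState, floored_preferences
from .errors import ConfigError, UnknownLabelError
from .generative_model import Categorical, DirichletCounts, GenerativeModel, make_categorical
from .inference import Belief, Provenance
from .niche import NicheModel, location_label

GRID_ACTIONS = ("up", "down", "left", "right", "stay")
GRID_OBSERVATIONS = ("faint", "visible", "deep", "at_goal")
_MOVES = {"up": (0, -1), "down": (0, 1), "left": (-1, 0), "right": (1, 0), "stay": (0, 0)}

#: named preference archetypes: observation preferences and the niche's
#: hypothesis about each type's overall action profile p(a | type).  The
#: café-goer profile leans toward the café quadrant (right/down for the
#: default gate-at-(0,0), café-at-(9,9) layout); the wanderer is uniform.
ARCHETYPES: dict[str, dict] = {
    "cafe_goer": {
        "preferences": {"faint": 0.01, "visible": 0.01, "deep": 0.01, "at_goal": 0.97},
        "action_profile": {"up": 0.1, "down": 0.35, "left": 0.1, "right": 0.35, "stay": 0.1},
    },
    "wanderer": {
        "preferences": {"faint": 0.25, "visible": 0.25, "deep": 0.25, "at_goal": 0.25},
        "action_profile": {"up": 0.2, "down": 0.2, "left": 0.2, "right": 0.2, "stay": 0.2},
    },
}


@dataclass(frozen=True)
class GridWorld:
    """A bounded grid with goal cells and a trace-reading observation map.

    ``trace_thresholds = (t1, t2)`` quantize a cell's total trace
    concentration into faint (< t1), visible (< t2) and deep (>= t2);
    ``obs_noise`` spreads observation probability geometrically to adjacent
    levels (0 gives a deterministic observation function).
    """

    width: int
    height: int
    start: tuple[int, int]
    goals: frozenset
    trace_thresholds: tuple[float, float] = (15.0, 40.0)
    obs_noise: float = 0.05

    def __post_init__(self):
        if self.width < 1 or self.height < 1 or self.width * self.height < 2:
            raise ConfigError([f"grid {self.width}x{self.height} has fewer than 2 cells"])
        goals = frozenset((int(x), int(y)) for x, y in self.goals)
        if not goals:
            raise ConfigError(["at least one goal cell is required"])
        problems = []
        for name, (x, y) in [("start", self.start), *[("goal", g) for g in goals]]:
            if not (0 <= x < self.width and 0 <= y < self.height):
                problems.append(f"{name} ({x},{y}) outside {self.width}x{self.height} grid")
        if tuple(self.start) in goals:
            problems.append("start coincides with a goal")
        t1, t2 = self.trace_thresholds
        if not (0 < t1 < t2):
            problems.append(f"trace thresholds must satisfy 0 < t1 < t2, got {self.trace_thresholds}")
        if not (0.0 <= self.obs_noise < 1.0):
            problems.append(f"obs_noise must be in [0, 1), got {self.obs_noise!r}")
        if problems:
            raise ConfigError(problems)
        object.__setattr__(self, "start", (int(self.start[0]), int(self.start[1])))
        object.__setattr__(self, "goals", goals)

    # -- geometry ------------------------------------------------------------
    @property
    def cells(self) -> tuple[tuple[int, int], ...]:
        return tuple((x, y) for y in range(self.height) for x in range(self.width))

    @property
    def cell_labels(self) -> tuple[str, ...]:
        return tuple(location_label(c) for c in self.cells)

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def cell_index(self, cell) -> int:
        if isinstance(cell, str):
            x, y = (int(v) for v in cell.split(","))
        else:
            x, y = cell
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise UnknownLabelError(f"cell ({x},{y}) outside {self.width}x{self.height} grid")
        return y * self.width + x

    def move(self, position: tuple[int, int], action: str) -> tuple[int, int]:
        """Apply an action; off-grid moves clamp to staying put."""
        if action not in _MOVES:
            raise UnknownLabelError(f"unknown action {action!r}; known: {GRID_ACTIONS}")
        dx, dy = _MOVES[action]
        x, y = position[0] + dx, position[1] + dy
        if 0 <= x < self.width and 0 <= y < self.height:
            return (x, y)
        return (position[0], position[1])

    def transition_matrices(self) -> dict[str, np.ndarray]:
        n = self.n_cells
        mats = {}
        for a in GRID_ACTIONS:
            B = np.zeros((n, n))
            for j, cell in enumerate(self.cells):
                B[self.cell_index(self.move(cell, a)), j] = 1.0
            mats[a] = B
        return mats

    # -- observation model ----------------------------------------------------
    def trace_level(self, total_concentration: float) -> int:
        t1, t2 = self.trace_thresholds
        return 0 if total_concentration < t1 else (1 if total_concentration < t2 else 2)

    def observation_matrix(self, niche: NicheModel) -> np.ndarray:
        """(n_obs, n_cells) likelihood p(s | cell) given the current field.

        Goal cells emit 'at_goal' with certainty; elsewhere the quantized
        trace level is read with geometric confusion noise between levels.
        """
        totals = niche.trace.concentration.sum(axis=1)
        n = self.n_cells
        A = np.zeros((len(GRID_OBSERVATIONS), n))
        kernels = _level_kernels(self.obs_noise)
        goal_idx = {self.cell_index(g) for g in self.goals}
        for j in range(n):
            if j in goal_idx:
                A[3, j] = 1.0
            else:
                A[:3, j] = kernels[self.trace_level(float(totals[j]))]
        return A

    def observe(self, position, niche: NicheModel, rng: np.random.Generator | None = None) -> str:
        """Sample (or, with rng=None, take the modal) observation at a cell."""
        j = self.cell_index(position)
        col = self.observation_matrix_column(j, niche)
        if rng is None:
            return GRID_OBSERVATIONS[int(np.argmax(col))]
        return GRID_OBSERVATIONS[int(rng.choice(len(col), p=col))]

    def observation_matrix_column(self, cell_index: int, niche: NicheModel) -> np.ndarray:
        if cell_index in {self.cell_index(g) for g in self.goals}:
            col = np.zeros(len(GRID_OBSERVATIONS))
            col[3] = 1.0
            return col
        total = float(niche.trace.concentration[cell_index].sum())
        col = np.zeros(len(GRID_OBSERVATIONS))
        col[:3] = _level_kernels(self.obs_noise)[self.trace_level(total)]
        return col

    def agent_model(self, niche: NicheModel, preferences: Categorical) -> GenerativeModel:
        """The organism's generative model of this world: hidden states are
        cells, observations are trace levels plus the at-goal flag."""
        prior = np.zeros(self.n_cells)
        prior[self.cell_index(self.start)] = 1.0
        return GenerativeModel(
            states=self.cell_labels,
            observations=GRID_OBSERVATIONS,
            actions=GRID_ACTIONS,
            likelihood=self.observation_matrix(niche),
            prior=prior,
            transitions=self.transition_matrices(),
            preferences=preferences.probs,
        )


def _level_kernels(noise: float) -> np.ndarray:
    """Row k: p(observed level | true level k), geometric in level distance."""
    levels = np.arange(3)
    if noise == 0.0:
        return np.eye(3)
    K = noise ** np.abs(levels[:, None] - levels[None, :])
    return K / K.sum(axis=1, keepdims=True)


def make_desire_path_world(
    width: int = 10,
    height: int = 10,
    start: tuple[int, int] = (0, 0),
    goals: Iterable[tuple[int, int]] = ((9, 9),),
    trace_quantization_levels: tuple[float, float] = (15.0, 40.0),
    seed: int = 0,
    initial_trace: float = 1.0,
    decay_rate: float = 0.01,
    obs_noise: float = 0.05,
    agent_types: Sequence[str] = ("cafe_goer", "wanderer"),
) -> tuple[GridWorld, NicheModel]:
    """A park grid plus its naive niche: uniform trace concentrations (all
    alternative action-outcome mappings start at equal prior probability)
    and a uniform prior over agent-type hypotheses.

    Construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other factories and echoed nowhere.
    """
    world = GridWorld(
        width=width,
        height=height,
        start=tuple(start),
        goals=frozenset(tuple(g) for g in goals),
        trace_thresholds=tuple(trace_quantization_levels),
        obs_noise=obs_noise,
    )
    for t in agent_types:
        if t not in ARCHETYPES:
            raise UnknownLabelError(f"unknown archetype {t!r}; known: {sorted(ARCHETYPES)}")
    profile = np.column_stack(
        [[ARCHETYPES[t]["action_profile"][a] for a in GRID_ACTIONS] for t in agent_types]
    )
    niche = NicheModel(
        agent_types=tuple(agent_types),
        type_counts=DirichletCounts.uniform((len(agent_types),)),
        action_likelihood=profile,
        locations=world.cell_labels,
        actions=GRID_ACTIONS,
        trace=DirichletCounts.uniform((world.n_cells, len(GRID_ACTIONS)), value=initial_trace),
        decay_rate=decay_rate,
    )
    return world, niche


@dataclass(frozen=True)
class BurrowWorld:
    """Two hidden states (in/out of a burrow), wet/dry sensations, and
    enter/exit/stay actions — the minimal niche-as-informant toy."""

    states: tuple[str, str] = ("in_burrow", "outside")
    observations: tuple[str, str] = ("wet", "dry")
    actions: tuple[str, str, str] = ("enter", "exit", "stay")


def make_burrow_world(
    p_wet_in: float = 0.9,
    p_wet_out: float = 0.2,
    preference_wet: float = 0.9,
) -> tuple[BurrowWorld, GenerativeModel]:
    """Two-state model: p(wet | in_burrow) = p_wet_in, p(wet | outside) =
    p_wet_out, uniform prior, preferences putting ``preference_wet`` on wet
    sensations.  'enter' leads into the burrow from anywhere, 'exit' leads
    out, 'stay' keeps the state."""
    problems = [
        f"{name} must lie strictly inside (0, 1), got {v!r}"
        for name, v in [
            ("p_wet_in", p_wet_in),
            ("p_wet_out", p_wet_out),
            ("preference_wet", preference_wet),
        ]
        if not (0.0 < v < 1.0)
    ]
    if problems:
        raise ConfigError(problems)
    world = BurrowWorld()
    model = GenerativeModel(
        states=world.states,
        observations=world.observations,
        actions=world.actions,
        likelihood=np.array([[p_wet_in, p_wet_out], [1 - p_wet_in, 1 - p_wet_out]]),
        prior=np.array([0.5, 0.5]),
        transitions={
            "enter": np.array([[1.0, 1.0], [0.0, 0.0]]),
            "exit": np.array([[0.0, 0.0], [1.0, 1.0]]),
            "stay": np.eye(2),
        },
        preferences=np.array([preference_wet, 1 - preference_wet]),
    )
    return world, model


def make_agent_population(
    world: GridWorld,
    niche: NicheModel,
    n: int,
    archetype_mix: Categorical | Mapping[str, float],
    seed: int | np.random.Generator,
    precision: float = DEFAULT_PRECISION,
    deontic_weight: float = 2.0,
    horizon: int = 1,
    learning_rate: float = 1.0,
) -> list[AgentState]:
    """Draw ``n`` agents from named archetypes at the world's start cell.

    Beliefs start as a point mass on the gate; Dirichlet counts start
    uniform.  The world model (likelihood built from the current field) is
    shared across the population.
    """
    if n < 1:
        raise ConfigError([f"population size must be >= 1, got {n!r}"])
    if not isinstance(archetype_mix, Categorical):
        archetype_mix = make_categorical(
            list(archetype_mix.values()), labels=tuple(archetype_mix.keys())
        )
    for t in archetype_mix.labels:
        if t not in ARCHETYPES:
            raise UnknownLabelError(f"unknown archetype {t!r}; known: {sorted(ARCHETYPES)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(len(archetype_mix.labels), size=n, p=archetype_mix.probs)

    base_models = {
        t: world.agent_model(niche, floored_preferences(ARCHETYPES[t]["preferences"], GRID_OBSERVATIONS))
        for t in archetype_mix.labels
    }
    start_probs = np.zeros(world.n_cells)
    start_probs[world.cell_index(world.start)] = 1.0
    agents = []
    for k in draws:
        t = archetype_mix.labels[int(k)]
        model = base_models[t]
        agents.append(
            AgentState(
                model=model,
                belief=Belief(Categorical(world.cell_labels, start_probs), Provenance.PRIOR),
                position=world.start,
                likelihood_counts=DirichletCounts.uniform(model.likelihood.shape),
                prior_counts=DirichletCounts.uniform((world.n_cells,)),
                precision=precision,
                deontic_weight=deontic_weight,
                horizon=horizon,
                learning_rate=learning_rate,
                archetype=t,
            )
        )
    return agents
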