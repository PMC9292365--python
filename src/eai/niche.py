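"""The niche as a variational learner of its organisms.

Through the symmetry imposed by the Markov blanket separating an organism
from its surroundings, the environment can be treated as holding a
generative model of its denizens: the organisms' *actions* are the niche's
sensations, the organisms' internal profiles are its hidden causes.  The
niche-side free energy

    F(a, q) = KL[ q(mu) || p(mu | a) ] - ln p(a)

has exactly the organism-side form with sensory and active states swapped,
and everything here is implemented by delegating to the organism-side
machinery on a mirrored :class:`~eai.generative_model.GenerativeModel`
(states = agent types, observations = actions).  The surprisal term
-ln p(a) is the *negative affordance* of an action: affordance is the log
evidence an action provides for the niche's model of the creatures it is
learning about.

Alongside this global type inference, the niche keeps a spatial Dirichlet
trace field over (location, action): deposits record behavioural
regularities (stigmergy), decay forgets them, and the log of the expected
per-location action distribution is the affordance landscape — a state
space of invitations to act, whose peaks mark the locally most probable
(and thereby most adaptive) actions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidDistributionError, UnknownLabelError
from .generative_model import (
    Categorical,
    DirichletCounts,
    GenerativeModel,
    _check_columns_stochastic,
    entropy,
)
from .inference import FreeEnergyReport, exact_posterior, free_energy


@dataclass(frozen=True)
class NicheBelief:
    """q_eta(mu): the niche's variational density over agent types."""

    distribution: Categorical

    @property
    def probs(self) -> np.ndarray:
        return self.distribution.probs


@dataclass(frozen=True)
class NicheModel:
    """The niche's mirror-image generative model plus its trace field.

    Parameters
    ----------
    agent_types : labels of hypothesized organism profiles (preference
        archetypes) — the niche's hidden states mu
    type_counts : Dirichlet counts whose mean is the prior over types
    action_likelihood : (n_actions, n_types) array; column k is p(a | mu_k)
    locations : ordered location labels ("x,y" for grids)
    actions : ordered action labels
    trace : Dirichlet counts of shape (n_locations, n_actions)
    decay_rate : per-step multiplicative trace decay in [0, 1)
    """

    agent_types: tuple[str, ...]
    type_counts: DirichletCounts
    action_likelihood: np.ndarray
    locations: tuple[str, ...]
    actions: tuple[str, ...]
    trace: DirichletCounts
    decay_rate: float = 0.01
    type_log_evidence: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "agent_types", tuple(self.agent_types))
        object.__setattr__(self, "locations", tuple(self.locations))
        object.__setattr__(self, "actions", tuple(self.actions))
        L = np.asarray(self.action_likelihood, dtype=float)
        if L.shape != (len(self.actions), len(self.agent_types)):
            raise InvalidDistributionError(
                f"action_likelihood shape {L.shape} != (n_actions={len(self.actions)}, "
                f"n_types={len(self.agent_types)})"
            )
        _check_columns_stochastic(L, "action_likelihood")
        L = L.copy()
        L.flags.writeable = False
        object.__setattr__(self, "action_likelihood", L)
        if self.type_counts.shape != (len(self.agent_types),):
            raise InvalidDistributionError("type_counts shape does not match agent_types")
        if self.trace.shape != (len(self.locations), len(self.actions)):
            raise InvalidDistributionError(
                f"trace shape {self.trace.shape} != (n_locations, n_actions)"
            )
        if not (0.0 <= self.decay_rate < 1.0):
            raise InvalidDistributionError(f"decay_rate must be in [0, 1), got {self.decay_rate!r}")
        ev = (
            np.zeros(len(self.agent_types))
            if self.type_log_evidence is None
            else np.asarray(self.type_log_evidence, dtype=float).copy()
        )
        if ev.shape != (len(self.agent_types),):
            raise InvalidDistributionError("type_log_evidence shape does not match agent_types")
        ev.flags.writeable = False
        object.__setattr__(self, "type_log_evidence", ev)

    @property
    def type_prior(self) -> Categorical:
        return Categorical(self.agent_types, self.type_counts.expected())

    @property
    def type_posterior(self) -> Categorical:
        """The niche's running belief about the organisms it hosts:
        softmax of the (slow) type prior's log plus the cumulative
        log-likelihood of every action observed so far.  Matches sequential
        Bayes on the full action stream."""
        logits = np.log(np.maximum(self.type_counts.expected(), 1e-300)) + self.type_log_evidence
        logits = logits - logits.max()
        w = np.exp(logits)
        return Categorical(self.agent_types, w / w.sum())

    def type_prior_belief(self) -> NicheBelief:
        return NicheBelief(self.type_prior)

    def _clone_with(self, **fields) -> "NicheModel":
        # fast structural copy; caller-validated fields, rest untouched
        new = object.__new__(NicheModel)
        new.__dict__.update(self.__dict__)
        for name, value in fields.items():
            object.__setattr__(new, name, value)
        return new

    def location_index(self, location) -> int:
        lab = location_label(location)
        try:
            return self.locations.index(lab)
        except ValueError:
            raise UnknownLabelError(f"unknown location {lab!r}") from None

    def action_index(self, a: str) -> int:
        try:
            return self.actions.index(a)
        except ValueError:
            raise UnknownLabelError(f"unknown action label {a!r}; known: {self.actions}") from None


def location_label(location) -> str:
    if isinstance(location, str):
        return location
    x, y = location
    return f"{int(x)},{int(y)}"


def as_generative_model(niche: NicheModel) -> GenerativeModel:
    """The niche's model in organism-side form: states = agent types,
    observations = actions.  This adapter is what makes the niche-side free
    energy literally the organism-side functional with (s, mu) <-> (a, eta)
    swapped."""
    n_types = len(niche.agent_types)
    n_actions = len(niche.actions)
    return GenerativeModel(
        states=niche.agent_types,
        observations=niche.actions,
        actions=("observe",),
        likelihood=niche.action_likelihood,
        prior=niche.type_counts.expected(),
        transitions={"observe": np.eye(n_types)},
        preferences=np.full(n_actions, 1.0 / n_actions),
    )


def niche_exact_posterior(niche: NicheModel, a: str) -> NicheBelief:
    """p(mu | a) by Bayes rule over the agent-type hypothesis space."""
    post = exact_posterior(as_generative_model(niche), a)
    return NicheBelief(post.distribution)


def niche_free_energy(q: NicheBelief, niche: NicheModel, a: str) -> FreeEnergyReport:
    """Niche-side variational free energy for observed action ``a``.

    total = KL[q || p(mu|a)] + (-ln p(a)); the surprisal term is the
    negative affordance of the action.  Same bound/equality contracts as
    the organism-side functional.
    """
    return free_energy(q.distribution, as_generative_model(niche), a)


def deposit_trace(niche: NicheModel, location, a: str, amount: float) -> NicheModel:
    """Record a behavioural trace: concentration[location, a] += amount."""
    if not amount > 0:
        raise ValueError(f"deposit amount must be positive, got {amount!r}")
    i = niche.location_index(location)
    j = niche.action_index(a)
    return niche._clone_with(trace=niche.trace.added((i, j), amount))


def decay_traces(niche: NicheModel, rate: float | None = None) -> NicheModel:
    """Multiply every trace concentration by (1 - rate), flooring below.

    As concentrations approach the floor the expected per-location action
    distributions drift toward uniform: shallow traces are transient until
    consolidated by repeated deposits.
    """
    r = niche.decay_rate if rate is None else rate
    return niche._clone_with(trace=niche.trace.decayed(r))


@dataclass(frozen=True)
class AffordanceField:
    """ln p(a) per location: the affordance landscape.

    ``values[i, j]`` is the log expected probability of action j at
    location i (always <= 0); ``exp(values)`` rows are valid distributions.
    ``action_surprisal`` is the negated field, the quantity the niche's
    free energy bounds.
    """

    locations: tuple[str, ...]
    actions: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.locations), len(self.actions)):
            raise InvalidDistributionError("affordance values shape mismatch")
        if np.any(v > 1e-12):
            raise InvalidDistributionError("affordance values must be log-probabilities (<= 0)")
        sums = np.exp(v).sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            i = int(np.argmax(np.abs(sums - 1.0)))
            raise InvalidDistributionError(
                f"exp(affordance) at location {self.locations[i]!r} sums to {sums[i]!r}"
            )
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def action_surprisal(self) -> np.ndarray:
        return -self.values

    def row(self, location) -> np.ndarray:
        lab = location_label(location)
        return self.values[self.locations.index(lab)]

    def categorical(self, location) -> Categorical:
        return Categorical(self.actions, np.exp(self.row(location)))


def affordance_field(niche: NicheModel) -> AffordanceField:
    """Log of the trace field's expected action distribution per location."""
    expected = niche.trace.expected(axis=1)
    return AffordanceField(niche.locations, niche.actions, np.log(expected))


def niche_step(
    niche: NicheModel,
    location,
    a: str,
    deposit: float = 1.0,
    type_learn_rate: float = 1.0,
) -> tuple[NicheModel, NicheBelief, FreeEnergyReport]:
    """One niche update for an observed (location, action) event.

    Scores the event's free energy against the current type prior, infers
    the acting organism's type by exact Bayes, nudges the slow type prior
    toward that posterior by a Dirichlet increment (the niche "learning
    about organismal beliefs"), accumulates the action's log-likelihood
    into the running evidence, and deposits a trace at the location.  A
    deposit of 0 skips the trace update but still produces the report.
    Returns the updated niche, its running type posterior (sequential
    Bayes over the full action stream), and the free-energy report.
    """
    mirror = as_generative_model(niche)
    report = free_energy(niche.type_prior, mirror, a)
    posterior = NicheBelief(exact_posterior(mirror, a).distribution)
    evidence = niche.type_log_evidence + np.log(
        np.maximum(niche.action_likelihood[niche.action_index(a)], 1e-300)
    )
    evidence = evidence - evidence.max()  # shift-invariant; keeps logits bounded
    ev = evidence.copy()
    ev.flags.writeable = False
    new = niche._clone_with(
        type_counts=niche.type_counts.added(slice(None), type_learn_rate * posterior.probs),
        type_log_evidence=ev,
    )
    if deposit > 0:
        new = deposit_trace(new, location, a, deposit)
    else:
        # still validate the location so malformed events fail loudly
        new.location_index(location)
    return new, NicheBelief(new.type_posterior), report


def trace_entropy(niche: NicheModel, locations: Sequence | None = None) -> np.ndarray:
    """Entropy (nats) of the expected action distribution per location."""
    expected = niche.trace.expected(axis=1)
    if locations is not None:
        idx = [niche.location_index(loc) for loc in locations]
        expected = expected[idx]
    return np.array([entropy(row) for row in expected])
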