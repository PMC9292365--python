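"""The organism's perception-action loop.

Action selection follows the expected-free-energy recipe for discrete
active inference: each candidate policy (action sequence) is scored by

    G(pi) = sum_t  risk_t + ambiguity_t

where risk is the KL divergence from the predicted outcome distribution to
the preference distribution C (minimizing expected complexity), and
ambiguity is the expected entropy of the likelihood mapping under the
predicted state distribution (so maximizing expected accuracy is the same
as minimizing ambiguity; the epistemic value of a policy is the complement
of its ambiguity and is carried in the report rather than optimized
separately).  Policies are then passed through a softmax with inverse
temperature gamma (precision), plus an additive log-prior "deontic" bonus
contributed by niche cues — states of the world that tell the agent what
action to select.  With the deontic weight kappa = 0 the agent is deaf to
the niche and behaves as a plain active-inference agent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import rel_entr, xlogy

from .errors import UnknownLabelError
from .generative_model import Categorical, DirichletCounts, GenerativeModel, make_categorical
from .inference import Belief, FreeEnergyReport, Provenance, free_energy, learn_likelihood, learn_prior, update_beliefs

#: minimum preference probability; keeps risk (a KL divergence) finite
PREFERENCE_FLOOR = 1e-3

#: default softmax inverse temperature
DEFAULT_PRECISION = 4.0


def floored_preferences(weights: dict[str, float] | Sequence[float], labels: Sequence[str] | None = None) -> Categorical:
    """Build a strictly positive preference distribution (floor 1e-3)."""
    if isinstance(weights, dict):
        if labels is None:
            labels = tuple(weights)
        w = np.array([float(weights[lab]) for lab in labels])
    else:
        w = np.asarray(weights, dtype=float)
    w = np.maximum(w, PREFERENCE_FLOOR)
    return make_categorical(w, labels)


@dataclass(frozen=True)
class Policy:
    """An ordered action sequence; length is the planning horizon."""

    actions: tuple[str, ...]

    def __post_init__(self):
        if len(self.actions) < 1:
            raise ValueError("a policy must contain at least one action")
        object.__setattr__(self, "actions", tuple(self.actions))

    @property
    def first_action(self) -> str:
        return self.actions[0]

    @property
    def label(self) -> str:
        return ">".join(self.actions)


def enumerate_policies(actions: Sequence[str], horizon: int = 1) -> list[Policy]:
    """Exhaustive policy set: all action sequences of length ``horizon``."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon!r}")
    return [Policy(seq) for seq in itertools.product(actions, repeat=horizon)]


@dataclass(frozen=True)
class EFEReport:
    """Expected free energy of one policy: total = risk + ambiguity.

    ``deontic_bonus`` is the additive log-prior contribution from niche
    cues (0 when the niche is absent or ignored); it enters the policy
    softmax, not the total.
    """

    risk: float
    ambiguity: float
    total: float
    deontic_bonus: float = 0.0

    def __post_init__(self):
        if self.risk < -1e-12 or self.ambiguity < -1e-12:
            raise ValueError("risk and ambiguity must be non-negative")
        if abs(self.total - (self.risk + self.ambiguity)) > 1e-9:
            raise ValueError("total != risk + ambiguity")


def predict_outcomes(model: GenerativeModel, q: Belief | Categorical, policy: Policy) -> Categorical:
    """Predicted outcome distribution at the policy's final step.

    Propagates the belief through the action-conditioned transition
    matrices along the policy, then through the likelihood.
    """
    probs = (q.distribution if isinstance(q, Belief) else q).probs
    for a in policy.actions:
        if a not in model.transitions:
            raise UnknownLabelError(f"unknown action label {a!r}; known: {model.actions}")
        probs = model.transitions[a] @ probs
    return Categorical(model.observations, model.likelihood @ probs)


def expected_free_energy(model: GenerativeModel, q: Belief | Categorical, policy: Policy) -> EFEReport:
    """Risk + ambiguity, accumulated over the policy's steps.

    Per step t along the policy: the state prediction is rolled forward
    through the chosen transition, risk_t = KL[predicted outcomes || C] and
    ambiguity_t = E_{predicted states}[ H(likelihood column) ].  Requires a
    strictly positive preference vector (see :func:`floored_preferences`).
    """
    probs = (q.distribution if isinstance(q, Belief) else q).probs
    C = model.preferences
    col_entropies = -xlogy(model.likelihood, model.likelihood).sum(axis=0)
    risk = 0.0
    ambiguity = 0.0
    for a in policy.actions:
        if a not in model.transitions:
            raise UnknownLabelError(f"unknown action label {a!r}; known: {model.actions}")
        probs = model.transitions[a] @ probs
        predicted = model.likelihood @ probs
        if C.min() <= 0.0 and np.any((predicted > 0) & (C == 0)):
            from .errors import SupportMismatchError

            j = int(np.flatnonzero((predicted > 0) & (C == 0))[0])
            raise SupportMismatchError(
                f"zero preference on predicted outcome {model.observations[j]!r}", index=j
            )
        risk += float(rel_entr(predicted, C).sum())
        ambiguity += float(col_entropies @ probs)
    ambiguity = max(ambiguity, 0.0)
    return EFEReport(risk=risk, ambiguity=ambiguity, total=risk + ambiguity)


def policy_posterior(
    reports: Sequence[EFEReport],
    deontic: Sequence[float] | None = None,
    precision: float = DEFAULT_PRECISION,
    policies: Sequence[Policy] | None = None,
) -> Categorical:
    """Softmax over policies of (deontic - precision * G)."""
    if len(reports) == 0:
        raise ValueError("empty policy set")
    if not precision > 0:
        raise ValueError(f"precision must be positive, got {precision!r}")
    G = np.array([r.total for r in reports])
    d = np.zeros_like(G) if deontic is None else np.asarray(deontic, dtype=float)
    if d.shape != G.shape:
        raise ValueError(f"deontic length {d.size} != number of policies {G.size}")
    logits = d - precision * G
    logits -= logits.max()
    w = np.exp(logits)
    labels = (
        tuple(p.label for p in policies)
        if policies is not None
        else tuple(f"pi{i}" for i in range(G.size))
    )
    return Categorical(labels, w / w.sum())


def sample_policy_index(pi: Categorical, rng: np.random.Generator, deterministic: bool = False) -> int:
    """Sample a policy index from the posterior (or argmax in deterministic
    mode, ties broken by lowest index)."""
    if deterministic:
        return int(np.argmax(pi.probs))
    return int(rng.choice(pi.probs.size, p=pi.probs))


def sample_action(
    pi: Categorical,
    policies: Sequence[Policy],
    rng: np.random.Generator,
    deterministic: bool = False,
) -> str:
    """First action of the sampled policy."""
    return policies[sample_policy_index(pi, rng, deterministic)].first_action


@dataclass(frozen=True)
class AgentState:
    """Everything the organism carries: model, belief, position, learned
    counts, and its action-selection temperament."""

    model: GenerativeModel
    belief: Belief
    position: tuple[int, int] | str | None = None
    likelihood_counts: DirichletCounts | None = None
    prior_counts: DirichletCounts | None = None
    precision: float = DEFAULT_PRECISION
    deontic_weight: float = 0.0
    horizon: int = 1
    learning_rate: float = 1.0
    archetype: str = ""

    def __post_init__(self):
        if self.belief.distribution.labels != self.model.states:
            raise ValueError("belief is not defined over the model's state set")
        if not self.precision > 0:
            raise ValueError("precision must be positive")
        if self.deontic_weight < 0:
            raise ValueError("deontic weight must be non-negative")


@dataclass(frozen=True)
class AgentStepResult:
    action: str
    state: AgentState
    free_energy: FreeEnergyReport
    policy_posterior: Categorical
    policies: tuple[Policy, ...]
    efe_reports: tuple[EFEReport, ...]


def deontic_vector(policies: Sequence[Policy], affordance_row: np.ndarray, actions: Sequence[str], kappa: float) -> np.ndarray:
    """Map a per-action affordance row (log-probabilities) to a per-policy
    log-prior bonus: kappa * affordance of each policy's first action."""
    idx = {a: i for i, a in enumerate(actions)}
    return kappa * np.array([affordance_row[idx[p.first_action]] for p in policies])


def agent_step(
    agent: AgentState,
    observation: str,
    deontic: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
    learn: bool = True,
) -> AgentStepResult:
    """One perception-action cycle.

    Perceive (variational belief update against the current belief used as
    prior), evaluate the enumerated policy set by expected free energy, form
    the policy posterior softmax(deontic - gamma G), sample an action, apply
    Dirichlet learning, and roll the belief forward through the chosen
    action's transition.  Returns the perception-step free-energy report
    (divergence of the converged belief plus the surprisal of the sensation
    under the pre-update belief) along with the policy posterior for
    logging.
    """
    if rng is None and not deterministic:
        raise ValueError("a seeded rng is required unless deterministic=True")
    model = agent.model.with_prior(agent.belief.distribution.probs)
    q = update_beliefs(model, observation)
    report = free_energy(q, model, observation)

    policies = enumerate_policies(model.actions, agent.horizon)
    reports = [expected_free_energy(model, q, p) for p in policies]
    if deontic is not None:
        reports = [replace(r, deontic_bonus=float(b)) for r, b in zip(reports, deontic)]
    pi = policy_posterior(reports, deontic, agent.precision, policies)
    action = sample_action(pi, policies, rng, deterministic)

    lik_counts, prior_counts = agent.likelihood_counts, agent.prior_counts
    if learn and lik_counts is not None:
        lik_counts = learn_likelihood(lik_counts, model, observation, q, agent.learning_rate)
    if learn and prior_counts is not None:
        prior_counts = learn_prior(prior_counts, q, agent.learning_rate)

    next_probs = model.transitions[action] @ q.probs
    next_belief = Belief(Categorical(model.states, next_probs), Provenance.PRIOR)
    new_state = replace(
        agent,
        belief=next_belief,
        likelihood_counts=lik_counts,
        prior_counts=prior_counts,
    )
    return AgentStepResult(
        action=action,
        state=new_state,
        free_energy=report,
        policy_posterior=pi,
        policies=tuple(policies),
        efe_reports=tuple(reports),
    )
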