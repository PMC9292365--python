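"""Shared fixtures: the burrow worked example, random model factories, and
the bound-contract helper reused on both sides of the blanket."""

from __future__ import annotations

import numpy as np
import pytest

from eai.generative_model import Categorical, GenerativeModel
from eai.inference import Belief, exact_posterior, free_energy
from eai.scenarios import make_burrow_world


@pytest.fixture
def burrow_model() -> GenerativeModel:
    """p(wet|in) = 0.9, p(wet|out) = 0.2, uniform prior, preference 0.9 wet."""
    _, model = make_burrow_world(0.9, 0.2, 0.9)
    return model


def random_model(
    rng: np.random.Generator,
    n_states: int,
    n_obs: int | None = None,
    n_actions: int = 2,
    concentration: float = 1.0,
) -> GenerativeModel:
    """A dense random generative model (strictly positive columns)."""
    n_obs = n_obs or n_states
    A = rng.dirichlet(np.full(n_obs, concentration), size=n_states).T
    D = rng.dirichlet(np.full(n_states, concentration))
    actions = tuple(f"a{k}" for k in range(n_actions))
    trans = {a: rng.dirichlet(np.full(n_states, concentration), size=n_states).T for a in actions}
    C = rng.dirichlet(np.full(n_obs, concentration))
    return GenerativeModel(
        states=tuple(f"s{i}" for i in range(n_states)),
        observations=tuple(f"o{i}" for i in range(n_obs)),
        actions=actions,
        likelihood=A,
        prior=D,
        transitions=trans,
        preferences=np.maximum(C, 1e-3) / np.maximum(C, 1e-3).sum(),
    )


def random_belief(rng: np.random.Generator, model: GenerativeModel) -> Belief:
    return Belief(Categorical(model.states, rng.dirichlet(np.ones(len(model.states)))))


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def assert_bound_contracts(model: GenerativeModel, s: str, q: Belief) -> None:
    """The two consequences of minimizing F: it upper-bounds surprisal, with
    equality exactly when the belief is the true posterior."""
    report = free_energy(q, model, s)
    assert report.total >= report.surprisal - 1e-9
    assert report.divergence >= -1e-12
    post = exact_posterior(model, s)
    tv = total_variation(q.probs, post.probs)
    if report.total - report.surprisal <= 1e-9:
        assert tv <= 1e-6
    if tv <= 1e-12:
        assert report.total - report.surprisal <= 1e-9
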