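"""Organism-side variational machinery.

Perception is cast as minimization of variational free energy

    F(s, q) = KL[ q(eta) || p(eta | s) ] - ln p(s)
            = E_q[ -ln p(s, eta) ] - H[q]          (energy minus entropy)

over beliefs q about hidden causes.  Because the state space is finite and
the variational family is the full categorical simplex, the exact posterior
is computable by direct Bayes rule and serves as a sharp oracle for the
iterative scheme: at the optimum F equals the surprisal -ln p(s), and the
divergence term vanishes.

Learning is conjugate Dirichlet counting: observed (posterior-weighted)
co-occurrences increment concentration parameters on the likelihood and
prior, so the expected distributions track experience.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .errors import ConvergenceError, ImpossibleObservationError, SupportMismatchError
from .generative_model import (
    LOG_FLOOR,
    Categorical,
    DirichletCounts,
    GenerativeModel,
    surprisal,
)


class Provenance(str, enum.Enum):
    EXACT = "exact"
    VARIATIONAL = "variational"
    PRIOR = "prior"


@dataclass(frozen=True)
class Belief:
    """A variational density q(eta) over hidden states, with provenance."""

    distribution: Categorical
    provenance: Provenance = Provenance.PRIOR

    @property
    def probs(self) -> np.ndarray:
        return self.distribution.probs


@dataclass(frozen=True)
class FreeEnergyReport:
    """Decomposed variational free energy: total = divergence + surprisal.

    ``divergence`` is KL[q || true posterior] >= 0, ``surprisal`` is
    -ln p(s); their sum bounds the surprisal from above, with equality
    exactly when the belief is the true posterior.
    """

    divergence: float
    surprisal: float
    total: float

    def __post_init__(self):
        if self.divergence < -1e-12:
            raise ValueError(f"negative divergence: {self.divergence!r}")
        if abs(self.total - (self.divergence + self.surprisal)) > 1e-9:
            raise ValueError("total != divergence + surprisal")


def prior_belief(model: GenerativeModel) -> Belief:
    return Belief(model.prior_categorical(), Provenance.PRIOR)


def exact_posterior(model: GenerativeModel, s: str) -> Belief:
    """p(eta | s) by direct Bayes rule over the finite state set.

    The brute-force oracle for all variational code.  Raises
    :class:`ImpossibleObservationError` when p(s) = 0.
    """
    i = model.obs_index(s)
    joint = model.likelihood[i] * model.prior
    marginal = float(joint.sum())
    if marginal <= 0.0:
        raise ImpossibleObservationError(
            f"observation {s!r} is impossible under the model (zero marginal)"
        )
    return Belief(Categorical(model.states, joint / marginal), Provenance.EXACT)


def free_energy(q: Belief | Categorical, model: GenerativeModel, s: str) -> FreeEnergyReport:
    """Variational free energy of belief q given observation s.

    Computed via the energy-minus-entropy route,
    E_q[-ln p(s|eta) p(eta)] - H[q]; the divergence term is recovered as
    total minus surprisal, which the KL-against-exact-posterior route must
    match to 1e-9 (asserted in the test suite, not here).
    """
    dist = q.distribution if isinstance(q, Belief) else q
    i = model.obs_index(s)
    joint = model.likelihood[i] * model.prior
    qp = dist.probs
    if np.any((qp > 0) & (joint <= 0.0)):
        j = int(np.flatnonzero((qp > 0) & (joint <= 0.0))[0])
        raise SupportMismatchError(
            f"belief places mass on state {model.states[j]!r} which is impossible given {s!r}",
            index=j,
        )
    energy = float(-(xlogy(qp, np.maximum(joint, LOG_FLOOR))).sum())
    neg_entropy = float(xlogy(qp, qp).sum())
    total = energy + neg_entropy
    surp = surprisal(model, s)
    divergence = max(total - surp, 0.0)
    return FreeEnergyReport(divergence=divergence, surprisal=surp, total=divergence + surp)


def update_beliefs(
    model: GenerativeModel,
    s: str,
    init: Belief | None = None,
    tol: float = 1e-8,
    max_iter: int = 64,
    step_size: float = 1.0,
    callback=None,
) -> Belief:
    """Fixed-point minimization of F(s, q) in the softmax-of-log-evidence
    parameterization.

    Iterates ln q <- (1 - step_size) ln q + step_size (ln p(eta) + ln p(s|eta)),
    renormalizing each step.  Free energy is non-increasing along the
    iterate sequence, and the scheme converges to the exact posterior (the
    unique minimizer of F over the full simplex).  Convergence is declared
    when the divergence gap F(q) - (-ln p(s)) drops below ``tol`` nats; the
    optimum value -ln p(s) is known analytically, so no oracle call is made.

    ``callback(iteration, q, report)`` — if given — observes every iterate
    (including the initial one), e.g. to verify monotone descent.

    Raises :class:`ConvergenceError` (carrying the last iterate and its F)
    if ``max_iter`` is exhausted.
    """
    if not tol > 0:
        raise ValueError(f"tol must be positive, got {tol!r}")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter!r}")
    if not (0.0 < step_size <= 1.0):
        raise ValueError(f"step_size must lie in (0, 1], got {step_size!r}")

    i = model.obs_index(s)
    joint = model.likelihood[i] * model.prior
    if joint.sum() <= 0.0:
        raise ImpossibleObservationError(f"observation {s!r} is impossible under the model")
    target_logits = np.log(np.maximum(joint, LOG_FLOOR))
    surp = float(-np.log(joint.sum()))

    q = (init.distribution.probs if init is not None else model.prior).astype(float)
    report = free_energy(Categorical(model.states, q), model, s)
    if callback is not None:
        callback(0, Categorical(model.states, q), report)
    if report.divergence <= tol:
        return Belief(Categorical(model.states, q), Provenance.VARIATIONAL)

    logits = np.log(np.maximum(q, LOG_FLOOR))
    for it in range(1, max_iter + 1):
        logits = (1.0 - step_size) * logits + step_size * target_logits
        logits -= logits.max()
        q = np.exp(logits)
        q /= q.sum()
        report = free_energy(Categorical(model.states, q), model, s)
        if callback is not None:
            callback(it, Categorical(model.states, q), report)
        if report.divergence <= tol:
            return Belief(Categorical(model.states, q), Provenance.VARIATIONAL)

    last = Belief(Categorical(model.states, q), Provenance.VARIATIONAL)
    raise ConvergenceError(
        f"belief update did not reach tol={tol!r} within {max_iter} iterations "
        f"(F = {report.total!r}, bound gap = {report.divergence!r})",
        last_belief=last,
        free_energy=report.total,
    )


def learn_likelihood(
    counts: DirichletCounts, model: GenerativeModel, s: str, q: Belief, rate: float
) -> DirichletCounts:
    """Dirichlet update of likelihood counts: concentration[s, :] += rate * q.

    Experience-dependent plasticity as conjugate counting; the expected
    likelihood (counts normalized per column) renormalizes automatically.
    """
    if not rate > 0:
        raise ValueError(f"rate must be positive, got {rate!r}")
    if counts.shape != model.likelihood.shape:
        raise ValueError(
            f"counts shape {counts.shape} does not match likelihood {model.likelihood.shape}"
        )
    return counts.added(model.obs_index(s), rate * q.probs)


def learn_prior(counts: DirichletCounts, q: Belief, rate: float) -> DirichletCounts:
    """Dirichlet update of prior counts: concentration += rate * q."""
    if not rate > 0:
        raise ValueError(f"rate must be positive, got {rate!r}")
    if counts.shape != q.probs.shape:
        raise ValueError(f"counts shape {counts.shape} does not match belief {q.probs.shape}")
    return counts.added(slice(None), rate * q.probs)
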