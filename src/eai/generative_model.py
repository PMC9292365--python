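"""Categorical probabilistic objects and elementary information functionals.

Everything in the package is built from one currency: a normalized
probability vector over a finite, ordered label set (`Categorical`).  An
organism's world model (`GenerativeModel`) bundles a likelihood mapping
hidden causes to sensations, a prior over causes, action-conditioned
transition kernels, and a preference distribution over outcomes.  The same
structures, with sensory and active states swapped, serve the niche side
(see :mod:`eai.niche`).

All information quantities are in nats (natural log).  ``0 ln 0`` is taken
as 0 by continuity; probabilities are clamped below at 1e-300 only inside
logarithms, never in stored state.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.special import rel_entr, xlogy

from .errors import (
    ImpossibleObservationError,
    InvalidDistributionError,
    UnknownLabelError,
)

#: absolute tolerance for "sums to one" checks
NORM_ATOL = 1e-12

#: clamp applied inside logs only
LOG_FLOOR = 1e-300

#: default Dirichlet pseudocount floor; keeps expected distributions proper
#: even after heavy decay
DIRICHLET_FLOOR = 1e-6


def _as_prob_array(values, name: str = "probs") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise InvalidDistributionError(f"{name} must be a non-empty 1-d vector, got shape {arr.shape}")
    if arr.min(initial=0.0) < 0:
        i = int(np.argmin(arr))
        raise InvalidDistributionError(f"{name} has negative entry at index {i}: {arr[i]!r}")
    return arr


@dataclass(frozen=True)
class Categorical:
    """A normalized distribution over an ordered finite label set.

    Invariants (checked at construction): entries non-negative, sum within
    1e-12 of 1, and ``len(probs) == len(labels) >= 1``.
    """

    labels: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self):
        arr = _as_prob_array(self.probs)
        if len(self.labels) != arr.size:
            raise InvalidDistributionError(
                f"{arr.size} probabilities for {len(self.labels)} labels"
            )
        total = float(arr.sum())
        if abs(total - 1.0) > NORM_ATOL:
            raise InvalidDistributionError(f"probabilities sum to {total!r}, not 1")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "probs", arr)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return self.probs.size

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise UnknownLabelError(f"unknown label {label!r}; known: {self.labels}") from None

    def prob(self, label: str) -> float:
        return float(self.probs[self.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {lab: float(p) for lab, p in zip(self.labels, self.probs)}


def default_labels(n: int, prefix: str = "c") -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(n))


def make_categorical(weights: Sequence[float], labels: Sequence[str] | None = None) -> Categorical:
    """Normalize non-negative weights into a :class:`Categorical`.

    Raises :class:`InvalidDistributionError` naming the offending index on
    negative input, and on all-zero input (nothing to normalize).  The input
    is never modified.
    """
    arr = _as_prob_array(weights, "weights")
    total = float(arr.sum())
    if total <= 0.0:
        raise InvalidDistributionError("weights are all zero; no distribution to normalize")
    labs = tuple(labels) if labels is not None else default_labels(arr.size)
    return Categorical(labs, arr / total)


def entropy(p: Categorical | np.ndarray) -> float:
    """Shannon entropy in nats, S = E[-ln p]; 0 ln 0 := 0."""
    arr = p.probs if isinstance(p, Categorical) else np.asarray(p, dtype=float)
    return float(-xlogy(arr, arr).sum())


def kl_divergence(q: Categorical, p: Categorical) -> float:
    """KL[q || p] in nats.  Always >= 0; 0 iff q == p elementwise.

    Raises :class:`SupportMismatchError` (carrying the offending index) when
    q places mass on an outcome p rules out — the divergence is infinite and
    is reported as such rather than as an overflow.
    """
    from .errors import SupportMismatchError

    qa, pa = q.probs, p.probs
    if qa.size != pa.size:
        raise InvalidDistributionError(f"length mismatch: {qa.size} vs {pa.size}")
    bad = np.flatnonzero((qa > 0) & (pa == 0))
    if bad.size:
        i = int(bad[0])
        raise SupportMismatchError(
            f"KL[q||p] infinite: q[{i}]={qa[i]!r} > 0 but p[{i}] = 0", index=i
        )
    return float(rel_entr(qa, pa).sum())


@dataclass(frozen=True)
class GenerativeModel:
    """A discrete generative model p(s, eta) = p(s|eta) p(eta) plus dynamics.

    Parameters
    ----------
    states : labels of hidden causes eta
    observations : labels of sensations s
    actions : labels of actions a
    likelihood : (n_obs, n_states) array; column j is p(s | eta_j)
    prior : (n_states,) distribution over eta (the D vector)
    transitions : per action, (n_states, n_states) stochastic matrix whose
        column j is p(eta' | eta_j, a)
    preferences : (n_obs,) distribution over preferred outcomes (the C vector)
    """

    states: tuple[str, ...]
    observations: tuple[str, ...]
    actions: tuple[str, ...]
    likelihood: np.ndarray
    prior: np.ndarray
    transitions: Mapping[str, np.ndarray]
    preferences: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "observations", tuple(self.observations))
        object.__setattr__(self, "actions", tuple(self.actions))
        A = np.asarray(self.likelihood, dtype=float)
        n_s, n_o = len(self.states), len(self.observations)
        if A.shape != (n_o, n_s):
            raise InvalidDistributionError(
                f"likelihood shape {A.shape} != (n_obs={n_o}, n_states={n_s})"
            )
        _check_columns_stochastic(A, "likelihood")
        D = _as_prob_array(self.prior, "prior")
        if D.size != n_s or abs(D.sum() - 1.0) > NORM_ATOL:
            raise InvalidDistributionError("prior is not a distribution over the state set")
        trans = {}
        for a in self.actions:
            if a not in self.transitions:
                raise InvalidDistributionError(f"missing transition matrix for action {a!r}")
            B = np.asarray(self.transitions[a], dtype=float)
            if B.shape != (n_s, n_s):
                raise InvalidDistributionError(
                    f"transition for {a!r} has shape {B.shape}, expected ({n_s}, {n_s})"
                )
            _check_columns_stochastic(B, f"transition[{a!r}]")
            B = B.copy()
            B.flags.writeable = False
            trans[a] = B
        C = _as_prob_array(self.preferences, "preferences")
        if C.size != n_o or abs(C.sum() - 1.0) > NORM_ATOL:
            raise InvalidDistributionError("preferences is not a distribution over observations")
        for name, arr in (("likelihood", A), ("prior", D), ("preferences", C)):
            arr = arr.copy()
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "transitions", trans)

    # -- label lookup ------------------------------------------------------
    def state_index(self, label: str) -> int:
        return _index_of(label, self.states, "state")

    def obs_index(self, label: str) -> int:
        return _index_of(label, self.observations, "observation")

    def action_index(self, label: str) -> int:
        return _index_of(label, self.actions, "action")

    # -- views -------------------------------------------------------------
    def likelihood_column(self, state: str) -> Categorical:
        return Categorical(self.observations, self.likelihood[:, self.state_index(state)])

    def prior_categorical(self) -> Categorical:
        return Categorical(self.states, self.prior)

    def preferences_categorical(self) -> Categorical:
        return Categorical(self.observations, self.preferences)

    def _clone_with(self, **fields) -> "GenerativeModel":
        # fast structural copy: fields passed here are validated by the
        # caller, everything else was validated at original construction
        new = object.__new__(GenerativeModel)
        new.__dict__.update(self.__dict__)
        for name, value in fields.items():
            object.__setattr__(new, name, value)
        return new

    def with_prior(self, prior: np.ndarray | Categorical) -> "GenerativeModel":
        probs = prior.probs if isinstance(prior, Categorical) else np.asarray(prior, float)
        D = _as_prob_array(probs, "prior")
        if D.size != len(self.states) or abs(D.sum() - 1.0) > NORM_ATOL:
            raise InvalidDistributionError("prior is not a distribution over the state set")
        D = D.copy()
        D.flags.writeable = False
        return self._clone_with(prior=D)

    def with_likelihood(self, likelihood: np.ndarray) -> "GenerativeModel":
        A = np.asarray(likelihood, dtype=float)
        if A.shape != self.likelihood.shape:
            raise InvalidDistributionError(
                f"likelihood shape {A.shape} != {self.likelihood.shape}"
            )
        _check_columns_stochastic(A, "likelihood")
        A = A.copy()
        A.flags.writeable = False
        return self._clone_with(likelihood=A)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "observations": list(self.observations),
            "actions": list(self.actions),
            "likelihood": [[float(x) for x in row] for row in self.likelihood],
            "prior": [float(x) for x in self.prior],
            "transitions": {
                a: [[float(x) for x in row] for row in B] for a, B in self.transitions.items()
            },
            "preferences": [float(x) for x in self.preferences],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerativeModel":
        return cls(
            states=tuple(d["states"]),
            observations=tuple(d["observations"]),
            actions=tuple(d["actions"]),
            likelihood=np.asarray(d["likelihood"], dtype=float),
            prior=np.asarray(d["prior"], dtype=float),
            transitions={a: np.asarray(B, dtype=float) for a, B in d["transitions"].items()},
            preferences=np.asarray(d["preferences"], dtype=float),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GenerativeModel":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, TypeError):
                data = yaml.safe_load(io.StringIO(str(source)))
        return cls.from_dict(data)


def _index_of(label: str, labels: tuple[str, ...], kind: str) -> int:
    try:
        return labels.index(label)
    except ValueError:
        raise UnknownLabelError(f"unknown {kind} label {label!r}; known: {labels}") from None


def _check_columns_stochastic(M: np.ndarray, name: str) -> None:
    if M.min(initial=0.0) < 0:
        i, j = np.argwhere(M < 0)[0]
        raise InvalidDistributionError(f"{name}[{i},{j}] is negative: {M[i, j]!r}")
    sums = M.sum(axis=0)
    if np.abs(sums - 1.0).max() > NORM_ATOL:
        j = int(np.argmax(np.abs(sums - 1.0)))
        raise InvalidDistributionError(f"{name} column {j} sums to {sums[j]!r}, not 1")


def surprisal(model: GenerativeModel, s: str) -> float:
    """-ln p(s) under the model: negative log marginal likelihood in nats."""
    i = model.obs_index(s)
    marginal = float(model.likelihood[i] @ model.prior)
    if marginal <= 0.0:
        raise ImpossibleObservationError(
            f"observation {s!r} has zero marginal probability under the model"
        )
    return float(-np.log(marginal))


@dataclass(frozen=True)
class DirichletCounts:
    """Non-negative concentration parameters of any shape, with a floor.

    Normalizing any slice yields a proper expected distribution; the floor
    (default 1e-6) guarantees this survives arbitrary decay.  All update
    operations return new objects; counts are never mutated in place.
    """

    concentration: np.ndarray
    floor: float = DIRICHLET_FLOOR

    def __post_init__(self):
        if not (self.floor > 0):
            raise InvalidDistributionError(f"floor must be positive, got {self.floor!r}")
        arr = np.asarray(self.concentration, dtype=float)
        if np.any(arr < self.floor):
            idx = tuple(int(i) for i in np.argwhere(arr < self.floor)[0])
            raise InvalidDistributionError(
                f"concentration{list(idx)} = {arr[idx]!r} below floor {self.floor!r}"
            )
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "concentration", arr)

    @classmethod
    def uniform(cls, shape, value: float = 1.0, floor: float = DIRICHLET_FLOOR) -> "DirichletCounts":
        return cls(np.full(shape, float(value)), floor=floor)

    @property
    def shape(self):
        return self.concentration.shape

    def expected(self, axis: int | None = None) -> np.ndarray:
        """Normalized concentrations: the expected distribution(s).

        ``axis`` selects the axis along which each slice normalizes (e.g.
        axis=0 for likelihood columns, axis=1 for per-location trace rows);
        ``None`` normalizes the whole array.
        """
        c = self.concentration
        denom = c.sum(axis=axis, keepdims=axis is not None)
        return c / denom

    def added(self, index, amount) -> "DirichletCounts":
        """Return a copy with ``amount`` (scalar or broadcastable array)
        added at ``index``; every other entry unchanged."""
        c = self.concentration.copy()
        c[index] = c[index] + amount
        return DirichletCounts(c, floor=self.floor)

    def decayed(self, rate: float) -> "DirichletCounts":
        """Multiply every concentration by (1 - rate), then apply the floor."""
        if not (0.0 <= rate < 1.0):
            raise InvalidDistributionError(f"decay rate must be in [0, 1), got {rate!r}")
        return DirichletCounts(
            np.maximum(self.concentration * (1.0 - rate), self.floor), floor=self.floor
        )
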