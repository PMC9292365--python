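"""Exception hierarchy for the eai package."""

from __future__ import annotations


class EAIError(Exception):
    """Base class for all package-specific errors."""


class InvalidDistributionError(EAIError, ValueError):
    """A vector meant to be (normalizable to) a probability distribution is not."""


class UnknownLabelError(EAIError, KeyError):
    """A state/observation/action label is not part of the relevant label set."""


class SupportMismatchError(EAIError, ValueError):
    """KL divergence is infinite: q places mass where p has none.

    Carries the offending index so callers can report *which* outcome broke
    absolute continuity instead of surfacing an overflow.
    """

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class ImpossibleObservationError(EAIError, ValueError):
    """An observation (or action, niche-side) has zero marginal probability."""


class ConvergenceError(EAIError, RuntimeError):
    """Variational optimization failed to reach tolerance within max_iter.

    Attributes
    ----------
    last_belief : the final iterate
    free_energy : its variational free energy (nats)
    """

    def __init__(self, message: str, last_belief=None, free_energy: float | None = None):
        super().__init__(message)
        self.last_belief = last_belief
        self.free_energy = free_energy


class ConfigError(EAIError, ValueError):
    """Scenario/run configuration failed validation.

    ``violations`` lists every problem found, not just the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations))
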