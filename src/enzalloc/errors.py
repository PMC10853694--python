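"""Exception hierarchy for enzalloc.

Errors are split by the contract they violate: domain errors (bad numbers),
specification errors (a rate law asked for kinetic constants that were not
supplied), infeasibility (no positive-flux state exists under the given
constraints), and numerical failures.
"""


class EnzallocError(Exception):
    """Base class for all enzalloc errors."""


class DomainError(EnzallocError, ValueError):
    """An argument lies outside the mathematical domain (e.g. a non-positive
    concentration where a logarithm is taken)."""


class MissingKineticsError(EnzallocError, ValueError):
    """A rate law requires a kinetic constant that was not supplied."""


class SchemaError(EnzallocError, ValueError):
    """A document violates the pathway/cell-model schema."""


class InfeasibleError(EnzallocError, RuntimeError):
    """No feasible state: non-positive overall driving force, an impossible
    constraint set, or a requested flux beyond capacity."""


class UnboundedMetaboliteError(InfeasibleError):
    """The Michaelis-Menten allocation problem without a metabolite bound:
    the optimum is attained only in the limit s_i -> infinity, which is not a
    well-defined metabolic state (any enzyme variation would break it)."""


class NoSteadyStateError(EnzallocError, RuntimeError):
    """The kinetic model admits no steady state for the given enzyme levels."""


class ControlUndefinedError(EnzallocError, RuntimeError):
    """Control coefficients are not defined for this state (e.g. the
    saturated irreversible limit, where any enzyme variation breaks the
    steady state)."""


class RuleScopeError(EnzallocError, RuntimeError):
    """An optimality rule was applied outside its scope (e.g. the plain
    enzyme-control rule at an optimum with an active metabolite bound)."""


class NumericalError(EnzallocError, RuntimeError):
    """A numerical routine failed to converge to its tolerance."""
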