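"""Exception and sentinel types shared across the package."""


class StepstoneError(Exception):
    """Base class for package errors."""


class AlignmentLengthError(StepstoneError):
    """Sequences in an alignment do not share a common length."""


class EmptyInputError(StepstoneError):
    """An input file or collection contained no records."""


class InvalidSymbolError(StepstoneError):
    """A sequence contained characters outside the accepted alphabet."""


class MappingError(StepstoneError):
    """An alignment identifier is missing from the population map."""


class UnknownPopulationError(StepstoneError):
    """A requested population label is not present."""


class InsufficientSampleError(StepstoneError):
    """Too few samples for the requested statistic."""


class IncomparablePairError(StepstoneError):
    """A pair of sequences shares no jointly scored sites."""


class ConfigurationError(StepstoneError):
    """A run setting is invalid."""


class ModelInvariantError(StepstoneError):
    """A metapopulation model violates its topology-specific invariants."""


class NonCoalescingError(StepstoneError):
    """Lineages in disconnected demes can never find a common ancestor."""


class PlacementError(StepstoneError):
    """Synthetic seascape patches overlap or fall off the grid."""


class DegenerateResponseError(StepstoneError):
    """A regression response vector has only one class."""


class DomainError(StepstoneError):
    """A numeric argument is outside its mathematical domain."""


# Sentinel for statistics that are undefined on the given data (for
# instance Fu's Fs on a monomorphic sample, or PhiST when the total
# variance is zero).  Carried as a flagged value rather than raised, so
# multi-population sweeps can continue past degenerate cells.
UNDEFINED = float("nan")


def is_undefined(x) -> bool:
    """True when ``x`` is the undefined-statistic sentinel (NaN)."""
    return x != x
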