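"""Exception hierarchy shared across the package."""


class MethsingleError(Exception):
    """Base class for all package errors."""


class ParseError(MethsingleError):
    """A count table line could not be parsed."""


class ValidationError(MethsingleError):
    """Input data violate an invariant (e.g. methylated count > total count)."""


class EmptyOverlapError(MethsingleError):
    """Intersection join of two samples produced no shared CpG sites."""


class DegenerateBinomialError(MethsingleError):
    """phi = 0 requested where the beta-binomial degenerates to a binomial."""


class SimulationError(MethsingleError):
    """Simulation cannot be carried out with the requested geometry."""
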