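"""Package-wide exception types."""


class MitovirError(Exception):
    """Base class for all package errors."""


class EmptyInputError(MitovirError, ValueError):
    """Raised when an analytical operation receives an empty/degenerate input."""


class InfeasibleParameterError(MitovirError, ValueError):
    """Raised when a synthetic-data request cannot be satisfied exactly.

    Generators refuse to drift silently: if the requested combination of
    constraints (e.g. a target AT content incompatible with the forced
    codons of an open reading frame) cannot be realized within the stated
    tolerance, this error is raised instead of emitting an off-target
    sequence.
    """
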