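"""Exception hierarchy shared across the pipeline."""


class CopetrendError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CopetrendError):
    """A file could not be parsed (bad Newick, malformed CSV cell, ...)."""


class ValidationError(CopetrendError):
    """Parsed data violate a domain invariant (negative length, bad ages, ...)."""


class NumericalError(CopetrendError):
    """A linear-algebra step failed (singular or non-positive-definite matrix)."""


class FitFailure(CopetrendError):
    """Maximum-likelihood optimization did not converge from any start point."""
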