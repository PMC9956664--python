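"""Typed exceptions shared across the package."""


class IoloptError(Exception):
    """Base class for all package-specific errors."""


class DegenerateVergenceError(IoloptError):
    """A vergence chain hit a (near-)zero denominator.

    Raised instead of returning NaN so that callers (in particular the
    optimiser) can penalise invalid parameter regions explicitly.
    """


class NoSolutionError(IoloptError):
    """A bracketed root search found no sign change in the bracket."""


class CohortError(IoloptError):
    """Invalid cohort data or configuration."""
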