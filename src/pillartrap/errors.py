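"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`PillarTrapError`, so callers (and the CLI) can distinguish
user/config mistakes from numerical failures.
"""


class PillarTrapError(Exception):
    """Base class for all pillartrap errors."""


class InvalidInputError(PillarTrapError, ValueError):
    """A scalar input violates its documented range (e.g. gap <= 0)."""


class InvalidGeometryError(InvalidInputError):
    """A trap geometry cannot be constructed (e.g. fillet too large)."""


class InvalidBinsError(InvalidInputError):
    """Cohort bins overlap or are otherwise malformed."""


class DegenerateGeneratorError(InvalidInputError):
    """Truncation range excludes essentially all probability mass."""


class InsufficientDataError(PillarTrapError):
    """Fewer data points than free parameters + 1."""


class UnidentifiableModelError(PillarTrapError):
    """The design matrix cannot identify the requested parameters
    (e.g. a free exponent with a single distinct diameter/gap ratio)."""


class UndefinedCorrelationError(PillarTrapError):
    """Correlation requested against a constant response."""


class MeshError(PillarTrapError):
    """Mesh generation or element-quality failure (inverted elements)."""


class ConvergenceError(PillarTrapError):
    """An iterative solver failed to converge; carries residual history."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []


class InconsistentOutcomeError(PillarTrapError):
    """Escape observed at a lower pressure than a trapped outcome,
    violating the monotonicity assumption of the bisection search."""


class ConfigError(PillarTrapError):
    """A run configuration failed schema validation; names the field."""
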