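"""Exception hierarchy.

``ValueError`` subclasses signal invalid inputs/configuration (CLI exit
code 2); ``RuntimeError`` subclasses signal failures of the computation
itself on otherwise valid inputs (CLI exit code 3).
"""


class ValidationError(ValueError):
    """Input data or configuration violates a precondition."""


class LeverRangeError(ValidationError):
    """Joint angle falls outside the tabulated lever-arm range."""


class EventDetectionError(RuntimeError):
    """Stance events could not be identified (fewer than two knee-angle minima)."""


class FitError(RuntimeError):
    """A model fit was rejected (e.g. non-concave force-length polynomial)."""
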