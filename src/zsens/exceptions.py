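"""Exception hierarchy for zsens.

Every error raised by the library derives from :class:`ZsensError`, so
callers (including the CLI) can catch a single base class.
"""


class ZsensError(Exception):
    """Base class for all zsens errors."""


class FormatError(ZsensError):
    """Input file does not have the required layout (e.g. missing column)."""


class ParseError(ZsensError):
    """A cell could not be coerced to the required type."""


class ValidationError(ZsensError):
    """Data violates a structural invariant (e.g. duplicate observation)."""


class EmptyDesignError(ZsensError):
    """No subjects survive complete-case filtering."""


class DesignError(ZsensError):
    """A statistical routine was given a design it cannot analyse."""


class DegenerateMeasureError(ZsensError):
    """A measure has zero pooled variance and cannot be standardized."""


class ConsistencyError(ZsensError):
    """Two inputs that must describe the same design do not."""


class ConfigError(ZsensError):
    """Invalid simulation or pipeline configuration."""


class PipelineError(ZsensError):
    """A pipeline stage failed; the message names the stage."""
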