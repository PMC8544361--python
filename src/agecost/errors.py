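"""Exception hierarchy for agecost.

All errors raised by the package derive from :class:`AgecostError`, so
callers (and the CLI) can catch one type at the pipeline boundary.
"""


class AgecostError(Exception):
    """Base class for all agecost errors."""


class SchemaError(AgecostError):
    """An input file is missing required columns or has an unusable layout."""


class ValidationError(AgecostError):
    """Row-level input data violates a domain invariant.

    The message names the offending row(s) so bad inputs can be located
    in the source file.
    """


class ConfigurationError(AgecostError):
    """An inconsistent run configuration, e.g. a service area with no fee."""
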