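"""Exception hierarchy.

Every error raised by the library derives from :class:`MgffError` so that the
command-line layer can map analysis failures to a single exit code.
"""


class MgffError(Exception):
    """Base class for all mgff errors."""


class DomainError(MgffError, ValueError):
    """A numeric argument is outside the mathematical domain (e.g. r <= 0)."""


class ConfigError(MgffError, ValueError):
    """Inconsistent configuration (cutoffs, generator specs, scaling tags)."""


class InputError(MgffError, ValueError):
    """Malformed or insufficient input data (empty groups, short series)."""


class GeometryError(MgffError, ValueError):
    """Periodic-box geometry violation (r_max beyond half the box, triclinic)."""


class AnalysisError(MgffError, RuntimeError):
    """The analysis precondition is not met by the data (no peak, no plateau)."""


class LookupError_(MgffError, KeyError):
    """Unknown registry key; the message lists the available entries."""


class ParseError(MgffError, ValueError):
    """A text file could not be parsed; carries the offending line number."""
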