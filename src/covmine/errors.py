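"""Exception hierarchy.

``DomainError`` signals invalid data handed to an operation (bad coordinates,
negative counts); ``ConfigurationError`` signals an inconsistent parameter
combination; ``BoundsError`` a coordinate range outside its container.
"""


class CovmineError(Exception):
    """Base class for all package errors."""


class DomainError(CovmineError, ValueError):
    """Input data violates a precondition of the operation."""


class ConfigurationError(CovmineError, ValueError):
    """Parameters are inconsistent with each other or with the data."""


class BoundsError(CovmineError, ValueError):
    """A sub-interval falls outside its enclosing region."""


class SampleLookupError(CovmineError, KeyError):
    """A sample id is not present in the container."""


class ChromosomeLookupError(CovmineError, KeyError):
    """A chromosome name is not present in the annotation."""
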